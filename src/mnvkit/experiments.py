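"""End-to-end recovery experiments on synthetic cohorts.

Each driver builds a cohort under controlled study conditions, runs the full
pipeline (plant -> VCF -> scan -> classify -> estimate) and returns the
estimated quantities next to the planted truth, so estimator calibration can
be checked.  The drivers are deterministic given their seed.

Study conditions: cohorts of 1000 diploid samples.  The excess-recovery
experiment uses a flat (context-independent) SNV rate table so every
substitution pattern receives a comparable null count, which is what gives
the q estimator measurable precision at this cohort size; the spectral-skew
behaviour of the null model is exercised separately with the
three-level rate table.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import fisher_exact

from .density import AnnotationInterval, correlate_density_methylation, mnv_density
from .discovery import scan_mnvs
from .mechanism import (
    estimate_q,
    genome_dinuc_counts,
    in_repeat_context,
    null_spectrum_weights,
    partition_by_context,
)
from .patterns import POL_ZETA_PATTERNS, Pattern, origin_class
from .ratetable import MutationRateTable
from .synthetic import CohortSpec, RepeatSpec, generate_reference, plant_cohort

PZ = [Pattern(r, a) for r, a in sorted(POL_ZETA_PATTERNS)]


def _tiled_annotations(length: int, n_tiles: int = 8, margin: int = 200):
    span = (length - 2 * margin) // n_tiles
    return [
        AnnotationInterval(
            "1",
            margin + i * span,
            margin + (i + 1) * span,
            f"tile{i}",
            methylation=0.1 + 0.8 * i / (n_tiles - 1),
        )
        for i in range(n_tiles)
    ]


def q_recovery(
    excess: float,
    workdir,
    seed: int,
    n_samples: int = 1000,
    n_null_events: int = 3000,
    genome_length: int = 250_000,
) -> dict:
    """Plant a pol-zeta excess over the SNV null and re-estimate it.

    ``excess`` is the target fraction of pol-zeta-pattern MNVs that are
    single-event doublets (0 plants a pure null cohort).  Returns the pooled
    q estimate over the two pol-zeta patterns, the planted truth from the
    manifest, and a Poisson-model standard error for the estimate.
    """
    if not 0 <= excess < 1:
        raise ValueError("excess must be in [0, 1)")
    table = MutationRateTable.uniform()
    bundle = generate_reference(
        genome_length, annotations=_tiled_annotations(genome_length), seed=seed
    )
    dinucs = genome_dinuc_counts(bundle.contigs)
    weights = null_spectrum_weights(table, dinucs)
    w_pz = sum(weights[p] for p in PZ) / sum(weights.values())
    n_doublets = int(round(excess / (1 - excess) * n_null_events * w_pz))
    n_events = n_null_events + n_doublets
    mix = {
        "independent_snv": n_null_events / n_events,
        "pol_zeta": n_doublets / n_events,
    }
    if n_doublets == 0:
        mix = {"independent_snv": 1.0}
    vcf = Path(workdir) / f"qrec_{excess:.2f}.vcf"
    spec = CohortSpec(
        n_samples=n_samples, n_events=n_events, mechanism_mix=mix,
        snv_rate_table=table,
    )
    manifest = plant_cohort(bundle, spec, vcf, seed=seed + 1)
    records = scan_mnvs(vcf, max_dist=10)
    nonrep, rep, onestep = partition_by_context(records, bundle.contigs)
    stats = {
        s.pattern: s
        for s in estimate_q(
            nonrep, table, dinucs, n_samples,
            repeat_counts=rep, one_step_counts=onestep,
        )
    }
    n_obs = sum(stats[p].n_obs for p in PZ)
    expected = sum(stats[p].expected for p in PZ)
    q_pooled = max(0.0, 1.0 - expected / n_obs) if n_obs else 0.0
    # planted truth: fraction of pol-zeta-pattern events that were doublets
    pz_events = [e for e in manifest.events if e.pattern in PZ]
    true_excess = (
        sum(e.mechanism == "pol_zeta" for e in pz_events) / len(pz_events)
        if pz_events
        else 0.0
    )
    ratio = expected / n_obs if n_obs else 1.0
    se = ratio * math.sqrt(1 / max(expected, 1) + 1 / max(n_obs, 1))
    return {
        "q_hat": q_pooled,
        "true_excess": true_excess,
        "se": se,
        "n_obs": n_obs,
        "expected": expected,
        "records": records,
        "bundle": bundle,
        "manifest": manifest,
        "stats": stats,
    }


def one_step_enrichment(result: dict) -> dict:
    """One-step fraction of pol-zeta patterns vs background, Fisher-tested.

    Takes the output of :func:`q_recovery` run with a positive excess.
    """
    records = [r for r in result["records"] if r.pattern is not None]
    pz_one = pz_tot = bg_one = bg_tot = 0
    for r in records:
        one = r.ac1 == r.ac2
        if r.pattern in PZ:
            pz_tot += 1
            pz_one += one
        else:
            bg_tot += 1
            bg_one += one
    _, p = fisher_exact(
        [[pz_one, pz_tot - pz_one], [bg_one, bg_tot - bg_one]],
        alternative="greater",
    )
    return {
        "pz_one_step_fraction": pz_one / pz_tot if pz_tot else float("nan"),
        "background_one_step_fraction": bg_one / bg_tot if bg_tot else float("nan"),
        "p_value": float(p),
    }


def repeat_classifier_recovery(
    workdir,
    seed: int,
    n_samples: int = 1000,
    n_events: int = 150,
) -> dict:
    """Recall/precision of the repeat-context classifier on planted truth.

    Slippage events (planted inside dinucleotide tracts) are the positives;
    independent-SNV events planted in clean contexts are the negatives.
    """
    tracts = [
        RepeatSpec("TA" if i % 2 else "CA", 8, 1500 + 60 * i) for i in range(80)
    ]
    bundle = generate_reference(60_000, repeat_spec=tracts, seed=seed)
    vcf = Path(workdir) / "repeat.vcf"
    spec = CohortSpec(
        n_samples=n_samples, n_events=n_events,
        mechanism_mix={"independent_snv": 0.6, "slippage": 0.4},
    )
    manifest = plant_cohort(bundle, spec, vcf, seed=seed + 1)
    records = {(r.pos1, r.pos2): r for r in scan_mnvs(vcf, max_dist=10)}
    seq = bundle.contigs["1"]
    tp = fp = fn = tn = 0
    for ev in manifest.events:
        r = records[(ev.pos1, ev.pos2)]
        called = in_repeat_context(
            seq, r.pos1, r.pos2, r.ref1 + r.ref2, r.alt1 + r.alt2
        )
        truth = ev.mechanism == "slippage"
        tp += called and truth
        fp += called and not truth
        fn += truth and not called
        tn += not called and not truth
    return {
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n_positive": tp + fn,
        "n_negative": fp + tn,
    }


def density_uniformity(result: dict) -> dict:
    """Aggregate normalized MNV density per annotation tile.

    On a cohort planted proportionally to dinucleotide opportunity, the
    per-category aggregate density (all patterns pooled) has expectation 1;
    the Poisson standard error is ~1/sqrt(n) per category.
    """
    bundle = result["bundle"]
    df = mnv_density(result["records"], bundle.annotations, bundle.contigs)
    out = []
    for cat, sub in df[df.category != "__genome__"].groupby("category"):
        n_mnv = sub["n_mnv"].sum()
        n_dinuc = sub["n_dinuc"].sum()
        genome = df[df.category == "__genome__"]
        d_norm = (n_mnv / n_dinuc) / (genome["n_mnv"].sum() / genome["n_dinuc"].sum())
        out.append(
            {"category": cat, "n_mnv": int(n_mnv), "d_norm": d_norm,
             "se": 1 / math.sqrt(n_mnv) if n_mnv else float("inf")}
        )
    return {"per_category": out, "density": df}


def methylation_correlation(
    workdir,
    seed: int,
    n_samples: int = 1000,
    n_events: int = 1500,
    genome_length: int = 150_000,
) -> dict:
    """Plant CpG-pattern MNVs at methylation-proportional intensity.

    Returns the per-pattern density/methylation Pearson correlations; the
    planted CpG-class patterns should correlate positively.
    """
    annotations = _tiled_annotations(genome_length)
    bundle = generate_reference(genome_length, annotations=annotations, seed=seed)
    vcf = Path(workdir) / "meth.vcf"
    spec = CohortSpec(
        n_samples=n_samples, n_events=n_events,
        mechanism_mix={"independent_snv": 1.0}, methylation_bias=1.0,
    )
    plant_cohort(bundle, spec, vcf, seed=seed + 1)
    records = scan_mnvs(vcf, max_dist=10)
    density = mnv_density(records, annotations, bundle.contigs)
    meth = {iv.category: iv.methylation for iv in annotations}
    corr = correlate_density_methylation(
        density[density.category != "__genome__"], meth
    )
    corr["origin_class"] = [
        origin_class(Pattern(*label.split("->"))) for label in corr["pattern"]
    ]
    return {"correlations": corr, "records": records}
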