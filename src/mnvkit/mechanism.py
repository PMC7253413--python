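"""Mutational-mechanism inference for MNVs.

Three mechanisms generate most adjacent MNVs:

1. **Independent SNVs** — two single-nucleotide mutations accumulating in
   different generations on the same haplotype.  Under this null model the
   probability of a doublet pattern WX->YZ is the sum over the two temporal
   orders of products of context-dependent SNV rates, e.g.
   ``p(CA->TG) ~ p(CA->TA) p(TA->TG) + p(CA->CG) p(CG->TG)``.
2. **Polymerase-zeta errors** — error-prone translesion synthesis producing
   the GA->TT and GC->AA doublets (and reverse complements) in a single
   generation, so both constituent SNVs share one allele count ("one-step").
3. **Polymerase slippage** — replication slippage at short tandem repeats,
   detected here from the +/-4 bp repeat structure around the MNV.

The observed count for each pattern is modelled as the null expectation plus
an excess term ``q``; the fitted ``q`` fraction is the share of MNVs of that
pattern attributed to single-event (non-SNV-combination, non-repeat)
mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .patterns import (
    BASES,
    POL_ZETA_PATTERNS,
    Pattern,
    canonical_pattern,
    enumerate_adjacent_patterns,
    origin_class,
    revcomp,
)
from .ratetable import MutationRateTable, is_transition

# ---------------------------------------------------------------------------
# one-step classification
# ---------------------------------------------------------------------------


def is_one_step(ac1: int, ac2: int, ac_mnv: int, strict: bool = False) -> bool:
    """Whether an MNV looks like a single-generation (one-step) event.

    Base mode requires the two constituent SNVs to have identical cohort
    allele counts; strict mode additionally requires the MNV allele count to
    be at least 90% of the constituent count (AC_mnv / AC1 >= 0.9), which
    guards against unrelated SNVs whose allele counts match by chance.
    """
    if ac1 <= 0 or ac2 <= 0 or ac_mnv <= 0:
        raise ValueError(
            f"allele counts must be positive for an observed MNV "
            f"(AC1={ac1}, AC2={ac2}, AC_mnv={ac_mnv})"
        )
    if ac1 != ac2:
        return False
    if strict:
        return ac_mnv / ac1 >= 0.9
    return True


# ---------------------------------------------------------------------------
# repeat-context classification
# ---------------------------------------------------------------------------


def repeat_unit_count(context: str, unit: str, d: int = 1) -> int:
    """Count (gapped, overlapping) occurrences of a 2-base unit in a context.

    The unit is the MNV's reference or alternate allele pair; when the
    constituent SNVs are ``d`` bp apart the unit is matched with a gap of
    ``d - 1`` bases between its two characters.  Overlapping occurrences all
    count, e.g. unit ``TT`` with d=2 occurs 3 times in ``TATATAT``.
    """
    if len(unit) != 2:
        raise ValueError(f"repeat unit must be 2 bases, got {unit!r}")
    if d < 1:
        raise ValueError("d must be >= 1")
    context = context.upper()
    return sum(
        1
        for i in range(len(context) - d)
        if context[i] == unit[0] and context[i + d] == unit[1]
    )


def in_repeat_context(
    contig_seq: str,
    pos1: int,
    pos2: int,
    ref_pair: str,
    alt_pair: str,
    flank: int = 4,
) -> bool:
    """Classify an MNV as lying in a repetitive (slippage-prone) context.

    The +/-4 bp context around the MNV is examined in both the reference and
    the alternate (MNV-applied) sequence, counting gapped occurrences of the
    reference and alternate allele pairs respectively.  The MNV is repetitive
    when both counts exceed 1 and either count exceeds 2.  For adjacent MNVs
    whose reference and/or alternate pair is a mononucleotide run (e.g. AA),
    the thresholds on that side are raised by one unit to compensate for the
    overlap of the run with itself.

    ``pos1``/``pos2`` are the 1-based positions of the constituent SNVs.  If
    the window does not fit on the contig the MNV is not classified
    (returns False).
    """
    d = pos2 - pos1
    if d < 1:
        raise ValueError("pos2 must exceed pos1")
    start = pos1 - 1 - flank
    end = pos2 + flank  # slice end, exclusive
    if start < 0 or end > len(contig_seq):
        return False  # context off the contig edge: skipped
    ref_ctx = contig_seq[start:end].upper()
    if ref_ctx[flank] != ref_pair[0] or ref_ctx[flank + d] != ref_pair[1]:
        raise ValueError(
            f"reference mismatch at {pos1}/{pos2}: expected {ref_pair}, "
            f"found {ref_ctx[flank]}{ref_ctx[flank + d]}"
        )
    alt_ctx = (
        ref_ctx[:flank]
        + alt_pair[0]
        + ref_ctx[flank + 1 : flank + d]
        + alt_pair[1]
        + ref_ctx[flank + d + 1 :]
    )
    n_ref = repeat_unit_count(ref_ctx, ref_pair, d)
    n_alt = repeat_unit_count(alt_ctx, alt_pair, d)
    ref_lo, ref_hi = 1, 2
    alt_lo, alt_hi = 1, 2
    if d == 1 and ref_pair[0] == ref_pair[1]:
        ref_lo, ref_hi = ref_lo + 1, ref_hi + 1
    if d == 1 and alt_pair[0] == alt_pair[1]:
        alt_lo, alt_hi = alt_lo + 1, alt_hi + 1
    return (n_ref > ref_lo and n_alt > alt_lo) and (n_ref > ref_hi or n_alt > alt_hi)


# ---------------------------------------------------------------------------
# independent-SNV null model
# ---------------------------------------------------------------------------


def _marginal_rate_5p(
    rates: MutationRateTable, ref: str, three: str, alt: str, w5: Mapping[str, float]
) -> float:
    return sum(w * rates.rate(f, ref, three, alt) for f, w in w5.items())


def _marginal_rate_3p(
    rates: MutationRateTable, five: str, ref: str, alt: str, w3: Mapping[str, float]
) -> float:
    return sum(w * rates.rate(five, ref, f, alt) for f, w in w3.items())


def null_path_probability(
    pattern: Pattern,
    rates: MutationRateTable,
    flanks: tuple[str, str] | None = None,
    flank_weights: Mapping[str, float] | None = None,
) -> tuple[float, list[tuple[str, float]]]:
    """Two-SNV-path probability of an adjacent doublet pattern.

    For WX->YZ the two temporal orders give the paths WX -> YX -> YZ and
    WX -> WZ -> YZ; each path's probability is the product of two
    context-dependent SNV rates, the second rate's context including the
    first substitution's product.  The bases flanking the dinucleotide are
    either supplied exactly (``flanks=(five, three)``) or marginalized over
    ``flank_weights`` (uniform by default).

    Only adjacent patterns (d=1) are modelled; for larger separations the
    two contexts decouple and no doublet-specific null is needed.

    Returns ``(p_null, paths)`` with ``paths`` a list of
    ``("WX->YX->YZ", probability)`` decompositions.
    """
    if pattern.d != 1:
        raise ValueError("null path model is defined for adjacent patterns (d=1)")
    w, x = pattern.ref
    y, z = pattern.alt
    if flanks is not None:
        w5 = {flanks[0]: 1.0}
        w3 = {flanks[1]: 1.0}
    elif flank_weights is not None:
        w5 = w3 = dict(flank_weights)
    else:
        w5 = w3 = {b: 0.25 for b in BASES}
    # order 1: position 1 mutates first (WX -> YX -> YZ)
    p1 = _marginal_rate_5p(rates, w, x, y, w5) * _marginal_rate_3p(rates, y, x, z, w3)
    # order 2: position 2 mutates first (WX -> WZ -> YZ)
    p2 = _marginal_rate_3p(rates, w, x, z, w3) * _marginal_rate_5p(rates, w, z, y, w5)
    paths = [
        (f"{w}{x}->{y}{x}->{y}{z}", p1),
        (f"{w}{x}->{w}{z}->{y}{z}", p2),
    ]
    return p1 + p2, paths


def genome_dinuc_counts(
    contigs: Mapping[str, str], d: int = 1
) -> dict[str, int]:
    """Counts of each canonical dinucleotide class over whole contigs.

    Positions ``i`` with bases ``(s[i], s[i+d])`` are tallied under the
    canonical class ``min(WX, revcomp(WX))``, so a class groups a
    dinucleotide with its reverse complement (both strands counted once,
    matching pattern canonicalization).
    """
    counts: dict[str, int] = {}
    for seq in contigs.values():
        seq = seq.upper()
        for i in range(len(seq) - d):
            wx = seq[i] + seq[i + d]
            if "N" in wx:
                continue
            counts[min(wx, revcomp(wx))] = counts.get(min(wx, revcomp(wx)), 0) + 1
    return counts


def null_spectrum_weights(
    rates: MutationRateTable,
    dinuc_counts: Mapping[str, int],
    flank_weights: Mapping[str, float] | None = None,
    d: int = 1,
) -> dict[Pattern, float]:
    """Unnormalized null expectation weight per canonical adjacent pattern.

    weight(p) = p_null(p) * N_WX(p), the path-sum probability scaled by the
    number of reference opportunities for the pattern's dinucleotide class.
    """
    weights = {}
    for p in enumerate_adjacent_patterns(d):
        p_null, _ = null_path_probability(
            Pattern(p.ref, p.alt, 1), rates, flank_weights=flank_weights
        )
        n_wx = dinuc_counts.get(min(p.ref, revcomp(p.ref)), 0)
        weights[p] = p_null * n_wx
    return weights


# ---------------------------------------------------------------------------
# excess factor q and origin fractions
# ---------------------------------------------------------------------------


@dataclass
class PatternStats:
    """Per-pattern observed counts, null expectation and origin fractions."""

    pattern: Pattern
    n_obs: int
    n_one_step: int
    n_repeat: int
    p_null: float
    expected: float
    q_hat: float
    fractions: dict[str, float] = field(default_factory=dict)
    predicted_mechanism: str = ""
    undefined: bool = False

    def __post_init__(self):
        if self.fractions:
            total = sum(self.fractions.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"origin fractions sum to {total}, not 1")


def predicted_mechanism(pattern: Pattern, repeat_fraction: float = 0.0) -> str:
    """Predicted dominant mechanism for an adjacent pattern.

    Ordered assignment: pol-zeta for the polymerase signature patterns
    (GA->TT, GC->AA); repeat when more than 10% of the pattern's MNVs sit in
    repetitive contexts; otherwise a label describing the least improbable
    two-SNV composition (CpG transition / transition / transversion steps),
    using only the pattern-internal neighbour bases to decide CpG status.
    """
    key = (pattern.ref, pattern.alt)
    if key in POL_ZETA_PATTERNS:
        return "pol_zeta"
    if repeat_fraction > 0.10:
        return "repeat"
    w, x = pattern.ref
    y, z = pattern.alt
    ti1 = is_transition(w, y)
    ti2 = is_transition(x, z)
    # CpG status of each step from the bases inside the doublet: position 1
    # (W->Y) sees X (before the second step) or Z (after it) as its 3'
    # neighbour; position 2 (X->Z) sees W or Y as its 5' neighbour.
    cpg1 = w == "C" and y == "T" and "G" in (x, z)
    cpg2 = x == "G" and z == "A" and "C" in (w, y)
    if ti1 and ti2:
        return "Ti at CpG" if (cpg1 or cpg2) else "Ti"
    if ti1 or ti2:
        cpg = (ti1 and cpg1) or (ti2 and cpg2)
        return "Ti at CpG + Tv" if cpg else "Ti + Tv"
    return "Tv combination"


def estimate_q(
    nonrepeat_counts: Mapping[Pattern, int],
    rates: MutationRateTable,
    dinuc_counts: Mapping[str, int],
    n_individuals: int,
    repeat_counts: Mapping[Pattern, int] | None = None,
    one_step_counts: Mapping[Pattern, int] | None = None,
    flank_weights: Mapping[str, float] | None = None,
    calibration: Iterable[Pattern] | None = None,
) -> list[PatternStats]:
    """Estimate the single-event excess fraction q per adjacent pattern.

    The observed non-repeat count for pattern ``p`` is modelled as
    ``E_p + Q_p`` where ``E_p = C * p_null(p) * N_WX(p) * n_individuals`` is
    the independent-SNV expectation.  The single scale ``C`` is fitted by
    least squares in log space over a calibration set of patterns with no
    known doublet mechanism (all canonical patterns outside the pol-zeta and
    repeat classes, by default).  The q fraction is then
    ``max(0, 1 - E_p / N_p)``.

    Origin fractions per pattern (summing to 1): ``repeat`` is the fraction
    of the pattern's MNVs in repetitive contexts; the remainder splits into
    ``snv_combination`` (null share, ``1 - q``) and ``other`` (the q share,
    attributed to single-event replication errors such as pol-zeta).
    """
    nonrepeat_counts = dict(nonrepeat_counts)
    repeat_counts = dict(repeat_counts or {})
    one_step_counts = dict(one_step_counts or {})
    if not any(v > 0 for v in nonrepeat_counts.values()):
        raise ValueError("all-zero spectrum: q is undefined")
    weights = null_spectrum_weights(rates, dinuc_counts, flank_weights)
    if calibration is None:
        calibration = [
            p for p in enumerate_adjacent_patterns()
            if origin_class(p) in ("CpG", "transversion", "others")
        ]
    calib = [
        p
        for p in calibration
        if nonrepeat_counts.get(p, 0) > 0 and weights.get(p, 0) > 0
    ]
    if not calib:
        raise ValueError("empty calibration set: cannot fit the null scale")
    log_c = float(
        np.mean(
            [
                np.log(nonrepeat_counts[p]) - np.log(weights[p] * n_individuals)
                for p in calib
            ]
        )
    )
    scale = np.exp(log_c)

    out = []
    for p in enumerate_adjacent_patterns():
        n_nr = nonrepeat_counts.get(p, 0)
        n_rep = repeat_counts.get(p, 0)
        n_obs = n_nr + n_rep
        expected = scale * weights[p] * n_individuals
        p_null, _ = null_path_probability(p, rates, flank_weights=flank_weights)
        undefined = n_nr == 0
        q_hat = 0.0 if undefined else max(0.0, 1.0 - expected / n_nr)
        rep_frac = n_rep / n_obs if n_obs else 0.0
        fractions = {
            "repeat": rep_frac,
            "snv_combination": (1.0 - rep_frac) * (1.0 - q_hat),
            "other": (1.0 - rep_frac) * q_hat,
        }
        out.append(
            PatternStats(
                pattern=p,
                n_obs=n_obs,
                n_one_step=one_step_counts.get(p, 0),
                n_repeat=n_rep,
                p_null=p_null,
                expected=expected,
                q_hat=q_hat,
                fractions=fractions,
                predicted_mechanism=predicted_mechanism(p, rep_frac),
                undefined=undefined,
            )
        )
    return out


def partition_by_context(
    records, contigs: Mapping[str, str]
) -> tuple[dict[Pattern, int], dict[Pattern, int], dict[Pattern, int]]:
    """Split adjacent MNV records into per-pattern count dictionaries.

    Returns ``(nonrepeat_counts, repeat_counts, one_step_counts)`` keyed by
    canonical pattern, as consumed by :func:`estimate_q`.
    """
    nonrep: dict[Pattern, int] = {}
    rep: dict[Pattern, int] = {}
    onestep: dict[Pattern, int] = {}
    for r in records:
        if r.pattern is None or r.pattern.d != 1:
            continue
        p = r.pattern
        if in_repeat_context(
            contigs[r.contig], r.pos1, r.pos2, r.ref1 + r.ref2, r.alt1 + r.alt2
        ):
            rep[p] = rep.get(p, 0) + 1
        else:
            nonrep[p] = nonrep.get(p, 0) + 1
        if is_one_step(r.ac1, r.ac2, r.ac_mnv):
            onestep[p] = onestep.get(p, 0) + 1
    return nonrep, rep, onestep


def pattern_stats_table(stats: Sequence[PatternStats]) -> pd.DataFrame:
    """Flatten PatternStats into a tidy table (one row per pattern)."""
    rows = []
    for s in stats:
        rows.append(
            {
                "pattern": s.pattern.label,
                "n_obs": s.n_obs,
                "n_one_step": s.n_one_step,
                "n_repeat": s.n_repeat,
                "p_null": s.p_null,
                "expected": s.expected,
                "q_hat": s.q_hat,
                "frac_snv_combination": s.fractions.get("snv_combination", np.nan),
                "frac_repeat": s.fractions.get("repeat", np.nan),
                "frac_other": s.fractions.get("other", np.nan),
                "predicted_mechanism": s.predicted_mechanism,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutation-rate estimation
# ---------------------------------------------------------------------------


def expected_events_per_generation(rate_per_2bp: float, n_dinuc: float) -> float:
    """Expected new MNV events per generation for one pattern.

    The per-2bp per-generation rate times the number of reference
    dinucleotide opportunities for that pattern.
    """
    return rate_per_2bp * n_dinuc


@dataclass
class RateEstimate:
    """Global and per-pattern MNV mutation rates.

    Built Watterson-style: the ratio of segregating MNV sites to segregating
    SNV sites, scaled by the global SNV mutation rate, gives the global MNV
    rate per 2 bp per generation.  The per-pattern rate redistributes the
    global rate according to each pattern's share of one-step MNV sites and
    the inverse of its dinucleotide opportunity count.
    """

    mu_snv: float
    n_mnv_sites: int
    n_snv_sites: int
    coverage_factor: float
    mu_mnv_global: float
    per_pattern: pd.DataFrame


def estimate_rates(
    n_mnv_sites: int,
    n_snv_sites: int,
    spectrum: Mapping[Pattern, int],
    dinuc_counts: Mapping[str, int],
    mu_snv: float = 1.2e-8,
    coverage_factor: float = 1.0,
) -> RateEstimate:
    """Estimate the global and per-pattern MNV mutation rate.

    Parameters
    ----------
    n_mnv_sites, n_snv_sites : int
        Numbers of distinct one-step adjacent MNV sites and of SNV sites in
        the cohort (assumes no recurrent mutation).
    spectrum : mapping Pattern -> int
        One-step adjacent MNV site counts per canonical pattern.
    dinuc_counts : mapping
        Reference dinucleotide-class counts (as from
        :func:`genome_dinuc_counts`).
    mu_snv : float
        Global SNV mutation rate per bp per generation.
    coverage_factor : float
        User-supplied multiplicative correction for coverage differences
        between the MNV and SNV callable genome (1.0 = no correction).
    """
    if n_snv_sites <= 0:
        raise ValueError("n_snv_sites must be positive")
    if n_mnv_sites < 0:
        raise ValueError("n_mnv_sites must be non-negative")
    mu_global = (n_mnv_sites / n_snv_sites) * mu_snv
    total_sites = sum(spectrum.values())
    total_dinucs = sum(dinuc_counts.values())
    rows = []
    for p in enumerate_adjacent_patterns():
        n_p = spectrum.get(p, 0)
        share = n_p / total_sites if total_sites else 0.0
        n_wx = dinuc_counts.get(min(p.ref, revcomp(p.ref)), 0)
        if n_wx > 0:
            rate = mu_global * share * (total_dinucs / n_wx) * coverage_factor
        else:
            rate = float("nan")
        rows.append(
            {
                "pattern": p.label,
                "n_one_step_sites": n_p,
                "share": share,
                "n_dinuc": n_wx,
                "rate_per_2bp": rate,
                "events_per_generation": expected_events_per_generation(rate, n_wx)
                if n_wx > 0
                else 0.0,
            }
        )
    return RateEstimate(
        mu_snv=mu_snv,
        n_mnv_sites=n_mnv_sites,
        n_snv_sites=n_snv_sites,
        coverage_factor=coverage_factor,
        mu_mnv_global=mu_global,
        per_pattern=pd.DataFrame(rows),
    )
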