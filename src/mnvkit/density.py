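"""MNV density across functional-annotation intervals.

Density of a substitution pattern WX->YZ in an interval set I is the
number of WX->YZ MNVs in I divided by the number of WX reference
dinucleotides in I (the mutational opportunities).  Dividing by the
genome-wide density gives a normalized density D_norm whose value k means
the per-opportunity MNV probability in I is k times the genome average.
Because patterns are canonicalized over strands, opportunity counts
include both WX and its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .discovery import MNVRecord
from .patterns import Pattern, enumerate_adjacent_patterns, origin_class, revcomp


@dataclass(frozen=True)
class AnnotationInterval:
    """A 0-based half-open interval with a category label.

    ``methylation`` is the fraction of methylated CpGs in the region,
    when known.
    """

    contig: str
    start: int
    end: int
    category: str
    methylation: float | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.contig}:{self.start}-{self.end}")
        if self.methylation is not None and not 0 <= self.methylation <= 1:
            raise ValueError("methylation level must be in [0, 1]")


def read_annotation_bed(path) -> list[AnnotationInterval]:
    """BED with 4th column = category and optional 5th = methylation."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            meth = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                meth = float(fields[4])
            out.append(
                AnnotationInterval(
                    contig=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    category=fields[3] if len(fields) >= 4 else "interval",
                    methylation=meth,
                )
            )
    return out


def write_annotation_bed(intervals: Sequence[AnnotationInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            meth = "." if iv.methylation is None else f"{iv.methylation:g}"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.category}\t{meth}\n")


def count_ref_dinucs(
    contigs: Mapping[str, str],
    intervals: Iterable[AnnotationInterval],
    wx: str,
    d: int = 1,
) -> int:
    """Opportunity count for dinucleotide class WX within intervals.

    Counts positions i (0-based) with both i and i+d inside an interval and
    bases (s[i], s[i+d]) equal to WX or its reverse complement (counted
    once for self-complementary WX).
    """
    units = {wx, revcomp(wx)}
    total = 0
    for iv in intervals:
        seq = contigs[iv.contig].upper()
        lo = max(iv.start, 0)
        hi = min(iv.end, len(seq)) - d  # i+d must stay inside the interval
        for i in range(lo, hi):
            if seq[i] + seq[i + d] in units:
                total += 1
    return total


def _in_intervals(rec: MNVRecord, intervals: Sequence[AnnotationInterval]) -> bool:
    # both constituent positions must fall in one interval, matching the
    # both-ends-inside convention of the opportunity count
    p1, p2 = rec.pos1 - 1, rec.pos2 - 1  # to 0-based
    return any(
        iv.contig == rec.contig and iv.start <= p1 and p2 < iv.end
        for iv in intervals
    )


def mnv_density(
    records: Iterable[MNVRecord],
    intervals: Sequence[AnnotationInterval],
    contigs: Mapping[str, str],
    d: int = 1,
    patterns: Sequence[Pattern] | None = None,
) -> pd.DataFrame:
    """Normalized per-pattern MNV density per annotation category.

    Overlapping categories are scored independently; an MNV contributes to
    every category containing it.  The genome-wide interval (all contigs
    end to end) defines the normalizer; categories with no opportunities
    get NaN density and are flagged in the ``undefined`` column.
    """
    if patterns is None:
        patterns = [p for p in enumerate_adjacent_patterns(d)]
    records = [r for r in records if r.pattern is not None and r.pattern.d == d]
    genome = [
        AnnotationInterval(name, 0, len(seq), "__genome__")
        for name, seq in contigs.items()
    ]
    by_cat: dict[str, list[AnnotationInterval]] = {"__genome__": genome}
    for iv in intervals:
        by_cat.setdefault(iv.category, []).append(iv)

    rows = []
    genome_density: dict[str, float] = {}
    for pat in patterns:
        n_mnv_g = sum(
            1 for r in records if (r.pattern.ref, r.pattern.alt) == (pat.ref, pat.alt)
        )
        n_dinuc_g = count_ref_dinucs(contigs, genome, pat.ref, d)
        genome_density[pat.label] = n_mnv_g / n_dinuc_g if n_dinuc_g else np.nan
    for cat, ivs in by_cat.items():
        for pat in patterns:
            n_mnv = sum(
                1
                for r in records
                if (r.pattern.ref, r.pattern.alt) == (pat.ref, pat.alt)
                and _in_intervals(r, ivs)
            )
            n_dinuc = count_ref_dinucs(contigs, ivs, pat.ref, d)
            density = n_mnv / n_dinuc if n_dinuc else np.nan
            g = genome_density[pat.label]
            rows.append(
                {
                    "pattern": pat.label,
                    "category": cat,
                    "n_mnv": n_mnv,
                    "n_dinuc": n_dinuc,
                    "density": density,
                    "density_norm": density / g if g and not np.isnan(density) else np.nan,
                    "undefined": n_dinuc == 0,
                }
            )
    return pd.DataFrame(rows)


def correlate_density_methylation(
    density: pd.DataFrame, methylation: Mapping[str, float]
) -> pd.DataFrame:
    """Pearson correlation of normalized density vs methylation per pattern.

    ``methylation`` maps category name to its methylation level; at least
    three categories are required.  Patterns with a constant density vector
    are flagged undefined.
    """
    cats = [c for c in methylation if c in set(density["category"])]
    if len(cats) < 3:
        raise ValueError("need >= 3 annotated categories for a correlation")
    meth = np.array([methylation[c] for c in cats])
    rows = []
    for pat, sub in density[density["category"].isin(cats)].groupby("pattern"):
        dvals = (
            sub.set_index("category").loc[cats, "density_norm"].to_numpy(dtype=float)
        )
        ok = ~np.isnan(dvals)
        if ok.sum() < 3 or np.allclose(dvals[ok], dvals[ok][0]) or np.ptp(meth[ok]) == 0:
            rows.append({"pattern": pat, "r": np.nan, "p": np.nan, "n": int(ok.sum())})
            continue
        r, p = pearsonr(dvals[ok], meth[ok])
        rows.append({"pattern": pat, "r": float(r), "p": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows)


ORIGIN_CLASS_ORDER = ("CpG", "pol_zeta", "repeat", "transversion", "others")


def origin_fractions_by_region(
    records: Iterable[MNVRecord],
    intervals: Sequence[AnnotationInterval],
) -> pd.DataFrame:
    """Fraction of MNVs per origin class within each annotation category.

    Classes partition the 78 adjacent patterns: 4 CpG-transition signal,
    2 pol-zeta, 3 repeat, 6 transversion, 63 others; fractions sum to 1 in
    every category.  Empty categories are flagged.
    """
    records = [r for r in records if r.pattern is not None and r.pattern.d == 1]
    by_cat: dict[str, list[AnnotationInterval]] = {}
    for iv in intervals:
        by_cat.setdefault(iv.category, []).append(iv)
    rows = []
    for cat, ivs in sorted(by_cat.items()):
        counts = {c: 0 for c in ORIGIN_CLASS_ORDER}
        total = 0
        for r in records:
            if _in_intervals(r, ivs):
                counts[origin_class(r.pattern)] += 1
                total += 1
        for cls in ORIGIN_CLASS_ORDER:
            rows.append(
                {
                    "category": cat,
                    "origin_class": cls,
                    "n": counts[cls],
                    "fraction": counts[cls] / total if total else np.nan,
                    "empty_category": total == 0,
                }
            )
    return pd.DataFrame(rows)
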