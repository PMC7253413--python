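"""Discovery of multi-nucleotide variants from phased cohort VCFs.

A windowed scan over a decomposed, normalized, multi-sample VCF finds pairs
of variants carried in cis (on the same haplotype) by at least one
QC-passing individual.  Genotype-level QC follows standard short-read
cohort filters: site FILTER = PASS, site outside low-complexity regions,
GQ >= 20, DP >= 10 and allele balance > 0.2 for heterozygous calls.

Cis-ness per sample and pair:

* hom-alt x hom-alt: both haplotypes carry both alternates regardless of
  phase (contributes 2 MNV haplotypes and one homozygous individual);
* het x hom-alt: the het's alternate haplotype necessarily also carries the
  hom-alt allele (contributes 1; no phase information needed);
* het x het: requires both calls phased in the same phase set; same
  haplotype side = cis (contributes 1), opposite = trans, otherwise the
  pair is unphased in that sample and contributes nothing.

Allele counts AC1/AC2 are cohort alternate-allele counts of the constituent
variants; AC_mnv counts haplotypes carrying both alternates in cis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .patterns import Pattern, canonical_pattern, enumerate_adjacent_patterns

MIN_GQ = 20
MIN_DP = 10
MIN_AB = 0.2

_AUTOSOMES = {str(i) for i in range(1, 23)}


class VcfFormatError(ValueError):
    """Raised for multiallelic or non-normalized input records."""


@dataclass(frozen=True)
class Variant:
    """A biallelic, normalized variant site."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str  # SNV | insertion | deletion
    filter_pass: bool = True
    ac: int = 0

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class SiteGenotypes:
    """Per-sample genotype arrays for one variant site."""

    variant: Variant
    a0: np.ndarray  # first allele index, -1 missing
    a1: np.ndarray
    phased: np.ndarray  # bool
    ps: np.ndarray  # phase-set id, -1 when absent
    gq: np.ndarray
    dp: np.ndarray
    ab: np.ndarray  # NaN when AD unavailable
    in_lcr: bool = False
    qc: np.ndarray | None = None

    @property
    def n_alt(self) -> np.ndarray:
        """Alternate-allele count per sample (0/1/2, 0 when missing)."""
        return (self.a0 == 1).astype(np.int64) + (self.a1 == 1)

    @property
    def called(self) -> np.ndarray:
        return (self.a0 >= 0) & (self.a1 >= 0)


def qc_pass(
    gq: float,
    dp: float,
    ab: float,
    is_het: bool,
    site_pass: bool = True,
    in_lcr: bool = False,
) -> bool:
    """Genotype/site QC for a single call (missing GQ or DP fails)."""
    if not site_pass or in_lcr:
        return False
    if gq is None or dp is None or gq < MIN_GQ or dp < MIN_DP:
        return False
    if is_het:
        if ab is None or np.isnan(ab):
            return False
        return ab > MIN_AB
    return True


def _qc_vector(site: SiteGenotypes) -> np.ndarray:
    ok = site.called & (site.gq >= MIN_GQ) & (site.dp >= MIN_DP)
    het = site.n_alt == 1
    with np.errstate(invalid="ignore"):
        ab_ok = ~np.isnan(site.ab) & (site.ab > MIN_AB)
    ok &= ~het | ab_ok
    if not site.variant.filter_pass or site.in_lcr:
        ok[:] = False
    return ok


def load_lcr_bed(path) -> dict[str, IntervalTree]:
    """Read a 0-based half-open BED mask into per-contig interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            contig, start, end = line.split("\t")[:3]
            trees.setdefault(contig, IntervalTree()).addi(int(start), int(end))
    return trees


def _classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        vtype = "insertion"
    elif len(ref) > len(alt):
        vtype = "deletion"
    else:
        raise VcfFormatError(f"non-decomposed MNP allele {ref}>{alt}")
    if len(ref) > 1 and len(alt) > 1:
        raise VcfFormatError(f"non-minimal indel representation {ref}>{alt}")
    return vtype


def iter_sites(
    vcf_path,
    lcr: Mapping[str, IntervalTree] | None = None,
) -> Iterator[tuple[SiteGenotypes, list[str]]]:
    """Yield :class:`SiteGenotypes` for every record of a VCF.

    Raises :class:`VcfFormatError` on multiallelic or non-normalized input,
    naming the offending record.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    for v in vcf:
        where = f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            raise VcfFormatError(f"multiallelic record at {where}: decompose first")
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        vtype = _classify_alleles(ref, alt)
        gts = np.asarray(v.genotypes, dtype=np.int64)
        a0, a1, phased = gts[:, 0], gts[:, 1], gts[:, 2].astype(bool)
        ps_raw = v.format("PS")
        if ps_raw is None:
            ps = np.full(len(samples), -1, dtype=np.int64)
        else:
            ps = ps_raw[:, 0].astype(np.int64)
            ps[ps < 0] = -1
        gq = np.asarray(v.gt_quals, dtype=float)
        dp = np.asarray(v.gt_depths, dtype=float)
        ad = v.format("AD")
        if ad is None:
            ab = np.full(len(samples), np.nan)
        else:
            ad = ad.astype(float)
            ad[ad < 0] = np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                ab = ad[:, 1] / ad.sum(axis=1)
        in_lcr = False
        if lcr and v.CHROM in lcr:
            in_lcr = bool(lcr[v.CHROM].overlaps(v.POS - 1, v.POS - 1 + len(ref)))
        called = (a0 >= 0) & (a1 >= 0)
        ac = int(((a0 == 1) & called).sum() + ((a1 == 1) & called).sum())
        variant = Variant(
            contig=v.CHROM,
            pos=v.POS,
            ref=ref,
            alt=alt,
            vtype=vtype,
            filter_pass=v.FILTER is None,  # cyvcf2: None means PASS
            ac=ac,
        )
        site = SiteGenotypes(
            variant=variant,
            a0=a0,
            a1=a1,
            phased=phased,
            ps=ps,
            gq=gq,
            dp=dp,
            ab=ab,
            in_lcr=in_lcr,
        )
        site.qc = _qc_vector(site)
        yield site, samples


@dataclass
class MNVRecord:
    """A canonicalized pair of in-cis variants with cohort allele counts."""

    contig: str
    pos1: int
    pos2: int
    ref1: str
    alt1: str
    ref2: str
    alt2: str
    ac1: int
    ac2: int
    ac_mnv: int
    n_hom: int
    n_indiv: int
    pattern: Pattern | None = None
    carriers: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.pos1 < self.pos2:
            raise ValueError("pos1 must be < pos2")
        if self.ac_mnv > min(self.ac1, self.ac2):
            raise ValueError("AC_mnv cannot exceed min(AC1, AC2)")
        if self.n_hom > self.n_indiv:
            raise ValueError("n_hom cannot exceed n_indiv")

    @property
    def d(self) -> int:
        return self.pos2 - self.pos1


def cis_haplotype_counts(s1: SiteGenotypes, s2: SiteGenotypes) -> np.ndarray:
    """Per-sample count of haplotypes carrying both alternates in cis.

    Applies the zygosity/phase rules in the module docstring; samples
    failing QC at either site contribute 0.
    """
    qc = s1.qc & s2.qc
    n1, n2 = s1.n_alt, s2.n_alt
    cis = np.zeros(len(n1), dtype=np.int64)
    hom1, hom2 = n1 == 2, n2 == 2
    het1, het2 = n1 == 1, n2 == 1
    cis[qc & hom1 & hom2] = 2
    cis[qc & ((hom1 & het2) | (het1 & hom2))] = 1
    hh = qc & het1 & het2 & s1.phased & s2.phased & (s1.ps == s2.ps) & (s1.ps >= 0)
    same_side = (s1.a0 == 1) == (s2.a0 == 1)
    cis[hh & same_side] = 1
    return cis


def _pair_record(
    s1: SiteGenotypes, s2: SiteGenotypes, samples: Sequence[str]
) -> MNVRecord | None:
    cis = cis_haplotype_counts(s1, s2)
    ac_mnv = int(cis.sum())
    if ac_mnv == 0:
        return None
    carriers = tuple(samples[i] for i in np.flatnonzero(cis > 0))
    v1, v2 = s1.variant, s2.variant
    pattern = None
    if v1.vtype == "SNV" and v2.vtype == "SNV":
        pattern = canonical_pattern(v1.ref + v2.ref, v1.alt + v2.alt, v2.pos - v1.pos)
    return MNVRecord(
        contig=v1.contig,
        pos1=v1.pos,
        pos2=v2.pos,
        ref1=v1.ref,
        alt1=v1.alt,
        ref2=v2.ref,
        alt2=v2.alt,
        ac1=v1.ac,
        ac2=v2.ac,
        ac_mnv=ac_mnv,
        n_hom=int((cis == 2).sum()),
        n_indiv=len(carriers),
        pattern=pattern,
        carriers=carriers,
    )


def _is_autosome(contig: str) -> bool:
    return contig.removeprefix("chr") in _AUTOSOMES


def scan_mnvs(
    vcf_path,
    max_dist: int = 10,
    variant_types: str = "snv",
    lcr: Mapping[str, IntervalTree] | None = None,
    autosomes_only: bool = False,
) -> list[MNVRecord]:
    """Windowed scan for in-cis variant pairs within ``max_dist`` bp.

    ``variant_types`` selects ``"snv"`` pairs (both constituents SNVs) or
    ``"indel"`` pairs (both insertions/deletions); mixed pairs are never
    emitted.  One record is produced per distinct (pos1, pos2, alleles)
    pair carried in cis by at least one QC-passing individual.
    """
    if variant_types not in ("snv", "indel"):
        raise ValueError("variant_types must be 'snv' or 'indel'")
    want_snv = variant_types == "snv"
    records: list[MNVRecord] = []
    window: list[SiteGenotypes] = []
    current_contig = None
    for site, samples in iter_sites(vcf_path, lcr=lcr):
        v = site.variant
        if autosomes_only and not _is_autosome(v.contig):
            continue
        if (v.vtype == "SNV") != want_snv:
            continue
        if v.contig != current_contig:
            window = []
            current_contig = v.contig
        window = [s for s in window if v.pos - s.variant.pos <= max_dist]
        for s1 in window:
            if s1.variant.pos == v.pos:
                continue
            rec = _pair_record(s1, site, samples)
            if rec is not None:
                records.append(rec)
        window.append(site)
    return records


def pattern_spectrum(records: Iterable[MNVRecord]) -> pd.DataFrame:
    """Per-canonical-pattern, per-distance MNV counts.

    All 78 canonical patterns are present for d=1 (zero-filled); other
    distances list only observed patterns.  The count total is conserved.
    """
    counts: dict[tuple[str, int], int] = {
        (p.label, 1): 0 for p in enumerate_adjacent_patterns()
    }
    for rec in records:
        if rec.pattern is None:
            continue
        key = (rec.pattern.label, rec.pattern.d)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"pattern": label, "d": d, "count": n}
        for (label, d), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tabular I/O (column layout mirrors released cohort MNV tables)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "contig", "pos1", "pos2", "ref1", "alt1", "ref2", "alt2", "d",
    "pattern", "ac1", "ac2", "ac_mnv", "n_hom", "n_indiv", "carriers",
]


def records_to_dataframe(records: Iterable[MNVRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "contig": r.contig, "pos1": r.pos1, "pos2": r.pos2,
                "ref1": r.ref1, "alt1": r.alt1, "ref2": r.ref2, "alt2": r.alt2,
                "d": r.d,
                "pattern": r.pattern.label if r.pattern else ".",
                "ac1": r.ac1, "ac2": r.ac2, "ac_mnv": r.ac_mnv,
                "n_hom": r.n_hom, "n_indiv": r.n_indiv,
                "carriers": ",".join(r.carriers),
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_records(records: Iterable[MNVRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)


def read_records(path) -> list[MNVRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"carriers": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        pattern = None
        if row.pattern and row.pattern != ".":
            ref2, alt2 = row.pattern.split("->")
            pattern = Pattern(ref2, alt2, int(row.pos2) - int(row.pos1))
        out.append(
            MNVRecord(
                contig=str(row.contig),
                pos1=int(row.pos1), pos2=int(row.pos2),
                ref1=row.ref1, alt1=row.alt1, ref2=row.ref2, alt2=row.alt2,
                ac1=int(row.ac1), ac2=int(row.ac2), ac_mnv=int(row.ac_mnv),
                n_hom=int(row.n_hom), n_indiv=int(row.n_indiv),
                pattern=pattern,
                carriers=tuple(c for c in str(row.carriers).split(",") if c),
            )
        )
    return out
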