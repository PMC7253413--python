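"""Relative-phase determination and read-based phasing evaluation.

Two sources of phase are compared for heterozygous variant pairs:

* **read-based** phase carried in the VCF (pipe-separated genotypes grouped
  by phase set, PS), which labels a pair cis, trans, or unphased;
* **trio-based** phase-by-transmission (PBT), which assigns each child
  alternate allele to a parental origin whenever the parental genotype
  configuration forces it; a pair is cis when both alternates trace to the
  same parent.  When either site cannot be assigned — notably when both
  parents are heterozygous — the pair is uninformative.

Sensitivity is the fraction of heterozygous pairs to which read-based
phasing assigns a relation; specificity is scored as cis-call concordance
against trio-informative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

Genotype = tuple[int, int] | None  # allele indices; None = missing


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site, with phase and quality fields."""

    sample: str
    alleles: tuple[int, int]
    phased: bool = False
    phase_set: int | None = None
    gq: float | None = None
    dp: float | None = None
    ab: float | None = None

    @property
    def is_het(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    @property
    def n_alt(self) -> int:
        return sum(1 for a in self.alleles if a == 1)


@dataclass(frozen=True)
class PairPhase:
    """Relative phase of an ordered variant pair from one phasing source."""

    relation: str  # cis | trans | unphased | uninformative
    source: str  # read_based | trio_based
    violation: bool = False

    def __post_init__(self):
        if self.relation not in ("cis", "trans", "unphased", "uninformative"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.relation == "uninformative" and self.source != "trio_based":
            raise ValueError("only trio-based phasing can be uninformative")


def read_based_pair_phase(g1: GenotypeCall, g2: GenotypeCall) -> PairPhase:
    """Relative phase of two calls from the phased-VCF representation.

    cis when both calls are phased in the same phase set with the alternate
    allele on the same haplotype side; trans when on opposite sides;
    unphased otherwise.
    """
    if g1.sample != g2.sample:
        raise ValueError(
            f"pair phase requires calls from one sample, got "
            f"{g1.sample!r} and {g2.sample!r}"
        )
    if (
        g1.phased
        and g2.phased
        and g1.phase_set is not None
        and g1.phase_set == g2.phase_set
    ):
        side1 = g1.alleles[0] == 1
        side2 = g2.alleles[0] == 1
        return PairPhase("cis" if side1 == side2 else "trans", "read_based")
    return PairPhase("unphased", "read_based")


def _alt_origin(child: GenotypeCall, father: Genotype, mother: Genotype) -> str:
    """Parental origin of a het child's alternate allele at one site.

    Returns ``father``/``mother`` when forced, ``ambiguous`` when both
    transmissions are consistent (or a parent is missing), ``violation``
    when neither is Mendelian-consistent.
    """
    if father is None or mother is None:
        return "ambiguous"
    f_alt = sum(1 for a in father if a == 1)
    f_ref = sum(1 for a in father if a == 0)
    m_alt = sum(1 for a in mother if a == 1)
    m_ref = sum(1 for a in mother if a == 0)
    paternal_alt = f_alt > 0 and m_ref > 0  # alt from father, ref from mother
    maternal_alt = m_alt > 0 and f_ref > 0
    if paternal_alt and maternal_alt:
        return "ambiguous"
    if paternal_alt:
        return "father"
    if maternal_alt:
        return "mother"
    return "violation"


def phase_by_transmission(
    child1: GenotypeCall,
    child2: GenotypeCall,
    father: tuple[Genotype, Genotype],
    mother: tuple[Genotype, Genotype],
) -> PairPhase:
    """Trio-based relative phase for a child heterozygous at both sites.

    Mendelian-inconsistent configurations are flagged (``violation=True``)
    and should be excluded from concordance summaries.
    """
    if not (child1.is_het and child2.is_het):
        raise ValueError("phase-by-transmission requires a het/het child pair")
    o1 = _alt_origin(child1, father[0], mother[0])
    o2 = _alt_origin(child2, father[1], mother[1])
    if "violation" in (o1, o2):
        return PairPhase("uninformative", "trio_based", violation=True)
    if "ambiguous" in (o1, o2):
        return PairPhase("uninformative", "trio_based")
    return PairPhase("cis" if o1 == o2 else "trans", "trio_based")


def read_ped(path) -> list[tuple[str, str, str, str]]:
    """(family, child, father, mother) rows with both parents recorded."""
    trios = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fam, iid, father, mother = line.split("\t")[:4]
            if father != "0" and mother != "0":
                trios.append((fam, iid, father, mother))
    return trios


def trio_pair_phases(
    vcf_path, ped_path, max_dist: int = 100
) -> list[tuple[int, PairPhase, PairPhase]]:
    """Read- and trio-based phase for every child het pair within a window.

    Pairs where either child call fails genotype QC are dropped; parental
    genotypes feed phase-by-transmission.  Returns
    ``(distance, read_phase, trio_phase, pos1, pos2)`` tuples;
    :func:`phasing_concordance` uses the first three fields.
    """
    from .discovery import iter_sites  # deferred: discovery pulls in cyvcf2

    trios = read_ped(ped_path)
    sites = []
    samples: list[str] = []
    for site, smp in iter_sites(vcf_path):
        sites.append(site)
        samples = smp
    col = {name: i for i, name in enumerate(samples)}

    def call(site, i) -> GenotypeCall:
        return GenotypeCall(
            sample=samples[i],
            alleles=(int(site.a0[i]), int(site.a1[i])),
            phased=bool(site.phased[i]),
            phase_set=int(site.ps[i]) if site.ps[i] >= 0 else None,
            gq=float(site.gq[i]),
            dp=float(site.dp[i]),
            ab=float(site.ab[i]),
        )

    def gt(site, i) -> Genotype:
        if site.a0[i] < 0 or site.a1[i] < 0:
            return None
        return (int(site.a0[i]), int(site.a1[i]))

    out = []
    for _, child, father, mother in trios:
        ci, fi, mi = col[child], col[father], col[mother]
        het_sites = [
            s
            for s in sites
            if s.variant.vtype == "SNV" and s.n_alt[ci] == 1 and s.qc[ci]
        ]
        for a in range(len(het_sites)):
            for b in range(a + 1, len(het_sites)):
                s1, s2 = het_sites[a], het_sites[b]
                if s1.variant.contig != s2.variant.contig:
                    continue
                d = s2.variant.pos - s1.variant.pos
                if not 1 <= d <= max_dist:
                    continue
                read = read_based_pair_phase(call(s1, ci), call(s2, ci))
                trio = phase_by_transmission(
                    call(s1, ci),
                    call(s2, ci),
                    (gt(s1, fi), gt(s2, fi)),
                    (gt(s1, mi), gt(s2, mi)),
                )
                out.append((d, read, trio, s1.variant.pos, s2.variant.pos))
    return out


DEFAULT_BINS = tuple(range(1, 11)) + tuple((lo, lo + 9) for lo in range(11, 101, 10))


def _bin_label(d: int, bins=DEFAULT_BINS) -> str | None:
    for b in bins:
        if isinstance(b, int):
            if d == b:
                return str(b)
        elif b[0] <= d <= b[1]:
            return f"{b[0]}-{b[1]}"
    return None


def phasing_concordance(
    pairs: Iterable[tuple[int, PairPhase, PairPhase]],
    bins: Sequence = DEFAULT_BINS,
) -> pd.DataFrame:
    """Summarise read-based vs trio-based phase per distance bin.

    ``pairs`` yields ``(distance, read_phase, trio_phase)`` for QC-passing
    heterozygous pairs.  Per bin the table reports:

    * ``sensitivity`` — fraction of pairs with a read-based relation
      assigned (cis or trans), among all pairs;
    * ``specificity_cis`` — among trio-informative pairs that reads call
      cis, the fraction trio phasing also calls cis;
    * ``concordance_all`` — among trio-informative, read-assigned pairs,
      the fraction where the two sources agree.

    Pairs flagged as Mendelian violations are excluded.  Empty input yields
    an empty table.
    """
    rows: dict[str, dict[str, float]] = {}
    for item in pairs:
        d, read, trio = item[0], item[1], item[2]
        if trio.violation:
            continue
        label = _bin_label(d, bins)
        if label is None:
            continue
        r = rows.setdefault(
            label,
            {
                "n_pairs": 0, "n_assigned": 0,
                "n_read_cis_informative": 0, "n_read_cis_trio_cis": 0,
                "n_comparable": 0, "n_agree": 0,
            },
        )
        r["n_pairs"] += 1
        assigned = read.relation in ("cis", "trans")
        informative = trio.relation in ("cis", "trans")
        if assigned:
            r["n_assigned"] += 1
        if assigned and informative:
            r["n_comparable"] += 1
            if read.relation == trio.relation:
                r["n_agree"] += 1
            if read.relation == "cis":
                r["n_read_cis_informative"] += 1
                if trio.relation == "cis":
                    r["n_read_cis_trio_cis"] += 1
    out = []
    for label, r in rows.items():
        out.append(
            {
                "distance_bin": label,
                "n_pairs": r["n_pairs"],
                "sensitivity": r["n_assigned"] / r["n_pairs"] if r["n_pairs"] else np.nan,
                "specificity_cis": (
                    r["n_read_cis_trio_cis"] / r["n_read_cis_informative"]
                    if r["n_read_cis_informative"]
                    else np.nan
                ),
                "concordance_all": (
                    r["n_agree"] / r["n_comparable"] if r["n_comparable"] else np.nan
                ),
            }
        )
    df = pd.DataFrame(
        out,
        columns=["distance_bin", "n_pairs", "sensitivity", "specificity_cis", "concordance_all"],
    )
    if not df.empty:
        df = df.sort_values(
            "distance_bin", key=lambda s: s.str.split("-").str[0].astype(int)
        ).reset_index(drop=True)
    return df
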