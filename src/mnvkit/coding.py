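"""Codon-level combined consequences of same-codon MNVs.

When two SNVs fall in one codon, the amino acid produced by the pair can
differ from what either variant produces alone: a pair of missense changes
can jointly create a stop codon (gained nonsense), a nonsense-causing SNV
can be rescued by its partner (rescued nonsense), two synonymous changes
can combine into a missense (gained missense), and so on.  This module
re-annotates MNVs against transcript models, classifies those categories,
tallies them per gene and per sample, tests constraint enrichment, and
finds frame-restoring indel pairs (two individually frameshifting indels
whose combined length change is a multiple of 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from scipy.stats import fisher_exact

from .discovery import MNVRecord, scan_mnvs

CATEGORIES = (
    "unchanged",
    "changed_missense",
    "gained_nonsense",
    "rescued_nonsense",
    "gained_missense",
    "other_changed",
    "cross_codon",
)


class NotCoding(Exception):
    """Position falls outside the transcript's CDS."""


@dataclass
class TranscriptModel:
    """A transcript's CDS intervals (1-based inclusive, genomic order)."""

    gene: str
    tx: str
    contig: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    canonical: bool = True
    loeuf_decile: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.cds = tuple(sorted(tuple(iv) for iv in self.cds))
        prev_end = 0
        for start, end in self.cds:
            if start <= prev_end:
                raise ValueError(f"CDS intervals overlap or are unsorted in {self.tx}")
            prev_end = end
        if self.cds_length % 3:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.tx} is not a multiple of 3"
            )
        self._cds_seq: str | None = None

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds)

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.cds)

    def cds_index(self, pos: int) -> int:
        """0-based index of a genomic position along the 5'->3' CDS."""
        offset = 0
        intervals = self.cds if self.strand == "+" else self.cds[::-1]
        for start, end in intervals:
            if start <= pos <= end:
                return offset + (pos - start if self.strand == "+" else end - pos)
            offset += end - start + 1
        raise NotCoding(f"{self.contig}:{pos} is outside the CDS of {self.tx}")

    def cds_sequence(self, contig_seq: str) -> str:
        if self._cds_seq is None:
            chunks = [contig_seq[start - 1 : end].upper() for start, end in self.cds]
            seq = "".join(chunks)
            if self.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            self._cds_seq = seq
        return self._cds_seq


def translate(codon_or_cds: str) -> str:
    """Standard-code translation; stop codons appear as ``*``."""
    return str(Seq(codon_or_cds).translate())


def codon_of(
    pos: int, transcript: TranscriptModel, contig_seq: str
) -> tuple[int, int, str]:
    """(codon index, offset within codon, reference codon) for a position.

    Strand-aware: on ``-`` transcripts codons are read off the reverse
    complement, so the genomic position maps to the complementary base at
    the returned offset.
    """
    i = transcript.cds_index(pos)
    codon_idx, offset = divmod(i, 3)
    cds = transcript.cds_sequence(contig_seq)
    return codon_idx, offset, cds[codon_idx * 3 : codon_idx * 3 + 3]


@dataclass
class ConsequenceRecord:
    """Individual vs combined codon consequence of a same-codon SNV pair."""

    mnv: MNVRecord | None
    gene: str
    tx: str
    codon_index: int
    ref_codon: str
    codon1: str
    codon2: str
    codon_mnv: str
    aa_ref: str
    aa1: str
    aa2: str
    aa_mnv: str
    category: str
    fully_rescued: bool | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_consequence(aa_ref: str, aa1: str, aa2: str, aa_mnv: str) -> str:
    """Category of a same-codon MNV from the four amino acids.

    Decision order (``*`` = stop):

    * gained_nonsense — the MNV creates a stop neither SNV creates;
    * rescued_nonsense — an SNV creates a stop but the MNV does not;
    * gained_missense — both SNVs are synonymous yet the MNV changes the
      amino acid;
    * unchanged — the MNV's amino acid is already produced by one of the
      individual SNVs, so combined annotation adds nothing;
    * changed_missense — the MNV amino acid differs from both individual
      outcomes, with the MNV and at least one SNV being missense;
    * other_changed — remaining combinations (e.g. the MNV restores the
      reference amino acid that both SNVs would change).
    """
    stop = "*"
    if aa_mnv == stop and aa1 != stop and aa2 != stop:
        return "gained_nonsense"
    if aa_mnv != stop and (aa1 == stop or aa2 == stop):
        return "rescued_nonsense"
    if aa1 == aa_ref and aa2 == aa_ref and aa_mnv != aa_ref:
        return "gained_missense"
    if aa_mnv in (aa1, aa2):
        return "unchanged"

    def missense(aa):
        return aa != aa_ref and aa != stop

    if missense(aa_mnv) and (missense(aa1) or missense(aa2)):
        return "changed_missense"
    return "other_changed"


_COMPL = str.maketrans("ACGT", "TGCA")


def combined_consequence(
    v1,
    v2,
    transcript: TranscriptModel,
    contig_seq: str,
    mnv: MNVRecord | None = None,
) -> ConsequenceRecord:
    """Consequence record for two SNVs in one transcript.

    ``v1``/``v2`` need ``pos``, ``ref`` and ``alt`` attributes (1-based
    SNVs, ``pos1 < pos2``).  Pairs landing in different codons yield a
    ``cross_codon`` record with no amino-acid comparison.
    """
    for v in (v1, v2):
        if len(v.ref) != 1 or len(v.alt) != 1:
            raise ValueError("combined consequence is defined for SNV pairs")
        if contig_seq[v.pos - 1].upper() != v.ref:
            raise ValueError(
                f"reference mismatch at {transcript.contig}:{v.pos}: "
                f"variant says {v.ref}, reference has {contig_seq[v.pos - 1]}"
            )
    ci1, off1, ref_codon = codon_of(v1.pos, transcript, contig_seq)
    ci2, off2, _ = codon_of(v2.pos, transcript, contig_seq)
    if ci1 != ci2:
        return ConsequenceRecord(
            mnv=mnv, gene=transcript.gene, tx=transcript.tx,
            codon_index=min(ci1, ci2), ref_codon=ref_codon,
            codon1="", codon2="", codon_mnv="",
            aa_ref="", aa1="", aa2="", aa_mnv="",
            category="cross_codon",
        )

    def alt_base(v):
        return v.alt if transcript.strand == "+" else v.alt.translate(_COMPL)

    def mutate(codon: str, offsets_bases):
        s = list(codon)
        for off, base in offsets_bases:
            s[off] = base
        return "".join(s)

    codon1 = mutate(ref_codon, [(off1, alt_base(v1))])
    codon2 = mutate(ref_codon, [(off2, alt_base(v2))])
    codon_m = mutate(ref_codon, [(off1, alt_base(v1)), (off2, alt_base(v2))])
    aa_ref, aa1, aa2, aa_m = map(translate, (ref_codon, codon1, codon2, codon_m))
    category = classify_consequence(aa_ref, aa1, aa2, aa_m)
    fully_rescued = None
    if category == "rescued_nonsense" and mnv is not None:
        nonsense_ac = mnv.ac1 if aa1 == "*" else mnv.ac2
        fully_rescued = mnv.ac_mnv == nonsense_ac
    return ConsequenceRecord(
        mnv=mnv, gene=transcript.gene, tx=transcript.tx,
        codon_index=ci1, ref_codon=ref_codon,
        codon1=codon1, codon2=codon2, codon_mnv=codon_m,
        aa_ref=aa_ref, aa1=aa1, aa2=aa2, aa_mnv=aa_m,
        category=category, fully_rescued=fully_rescued,
    )


@dataclass(frozen=True)
class _Snv:
    pos: int
    ref: str
    alt: str


def annotate_coding_mnvs(
    records: Iterable[MNVRecord],
    transcripts: Sequence[TranscriptModel],
    contigs: Mapping[str, str],
    canonical_only: bool = True,
) -> list[ConsequenceRecord]:
    """Consequence records for SNV-pair MNVs falling inside transcript CDS.

    Each MNV is annotated against the first (canonical) transcript whose
    CDS contains both constituent positions; MNVs outside any CDS are
    skipped.
    """
    out = []
    for rec in records:
        if rec.pattern is None:  # indel pair
            continue
        for tx in transcripts:
            if canonical_only and not tx.canonical:
                continue
            if tx.contig != rec.contig:
                continue
            if tx.contains(rec.pos1) and tx.contains(rec.pos2):
                out.append(
                    combined_consequence(
                        _Snv(rec.pos1, rec.ref1, rec.alt1),
                        _Snv(rec.pos2, rec.ref2, rec.alt2),
                        tx,
                        contigs[rec.contig],
                        mnv=rec,
                    )
                )
                break
    return out


def per_gene_tallies(
    records: Iterable[ConsequenceRecord], fully_rescued_only: bool = False
) -> pd.DataFrame:
    """Per-gene counts of each consequence category.

    With ``fully_rescued_only`` rescued-nonsense records are restricted to
    MNVs rescued in every carrier of the nonsense-introducing SNV.
    """
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        if (
            fully_rescued_only
            and rec.category == "rescued_nonsense"
            and rec.fully_rescued is False
        ):
            continue
        g = rows.setdefault(rec.gene, {c: 0 for c in CATEGORIES})
        g[rec.category] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene").reset_index()
    if not df.empty:
        df["has_nonsense_effect"] = (
            df["gained_nonsense"] + df["rescued_nonsense"]
        ) > 0
    return df


def per_sample_tallies(
    records: Iterable[ConsequenceRecord], n_samples: int
) -> pd.DataFrame:
    """Mean per-individual count of each consequence category.

    Each MNV contributes its number of carrier individuals; the mean is
    taken over the whole cohort.
    """
    totals = {c: 0 for c in CATEGORIES}
    for rec in records:
        if rec.mnv is None:
            continue
        totals[rec.category] += rec.mnv.n_indiv
    return pd.DataFrame(
        [
            {"category": c, "total_carriers": n, "mean_per_individual": n / n_samples}
            for c, n in totals.items()
        ]
    )


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    haldane_corrected: bool


def constraint_enrichment(
    records: Iterable[ConsequenceRecord],
    category: str,
    constrained_genes: set[str],
) -> EnrichmentResult:
    """Fisher's exact test of a category's enrichment in constrained genes.

    2x2 table: membership in ``category`` (vs all other categorized MNVs)
    against the gene being in ``constrained_genes``.  The odds ratio is
    ad/bc with a Haldane half-count correction applied (and flagged) only
    when a cell is zero; the two-sided p-value comes from the exact
    hypergeometric tail.
    """
    a = b = c = d = 0
    for rec in records:
        constrained = rec.gene in constrained_genes
        if rec.category == category:
            a, b = a + constrained, b + (not constrained)
        else:
            c, d = c + constrained, d + (not constrained)
    if a + b == 0:
        raise ValueError(f"no records in category {category!r}: OR undefined")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in (a, b, c, d)
    if haldane:
        oa, ob, oc, od = (x + 0.5 for x in (a, b, c, d))
    else:
        oa, ob, oc, od = a, b, c, d
    return EnrichmentResult(
        odds_ratio=(oa * od) / (ob * oc),
        p_value=float(p),
        table=((a, b), (c, d)),
        haldane_corrected=haldane,
    )


def find_frame_restoring_indel_pairs(
    vcf_path, max_dist: int = 30, lcr=None
) -> pd.DataFrame:
    """In-cis indel pairs that jointly restore the reading frame.

    Each constituent indel must be individually frameshifting (length
    change not a multiple of 3) while the summed length change is a
    multiple of 3, within ``max_dist`` bp.  Pairs of individually in-frame
    indels are not frame-restoring and are excluded.
    """
    pairs = scan_mnvs(vcf_path, max_dist=max_dist, variant_types="indel", lcr=lcr)
    rows = []
    for rec in pairs:
        lc1 = len(rec.alt1) - len(rec.ref1)
        lc2 = len(rec.alt2) - len(rec.ref2)
        if lc1 % 3 == 0 or lc2 % 3 == 0:
            continue
        if (lc1 + lc2) % 3 != 0:
            continue
        rows.append(
            {
                "contig": rec.contig, "pos1": rec.pos1, "pos2": rec.pos2,
                "ref1": rec.ref1, "alt1": rec.alt1,
                "ref2": rec.ref2, "alt2": rec.alt2,
                "d": rec.d, "len_change1": lc1, "len_change2": lc2,
                "net_change": lc1 + lc2, "ac_mnv": rec.ac_mnv,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos1", "pos2", "ref1", "alt1", "ref2", "alt2",
            "d", "len_change1", "len_change2", "net_change", "ac_mnv",
        ],
    )


# -- transcript model I/O ----------------------------------------------------


def read_transcripts_gff3(path) -> list[TranscriptModel]:
    """Build transcript models from the CDS features of a GFF3 file.

    CDS features are grouped by their ``Parent`` transcript; the gene name
    comes from the feature's ``gene_id``/``gene`` attribute when present,
    else the parent id.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    grouped: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parent = (cds.attributes.get("Parent") or [cds.id])[0]
        grouped.setdefault(parent, []).append(cds)
    out = []
    for tx_id, features in grouped.items():
        f0 = features[0]
        gene = (
            f0.attributes.get("gene_id") or f0.attributes.get("gene") or [tx_id]
        )[0]
        out.append(
            TranscriptModel(
                gene=gene,
                tx=tx_id,
                contig=f0.seqid,
                strand=f0.strand,
                cds=tuple((f.start, f.end) for f in features),
            )
        )
    return out


def read_transcripts_tsv(path) -> list[TranscriptModel]:
    """Read the 6+ column transcript TSV dialect.

    Columns: gene, tx, contig, strand, cds_starts, cds_ends (comma-joined,
    1-based inclusive) and optionally canonical (0/1) and loeuf_decile.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in row.cds_starts.split(",")]
        ends = [int(x) for x in row.cds_ends.split(",")]
        out.append(
            TranscriptModel(
                gene=row.gene,
                tx=row.tx,
                contig=str(row.contig),
                strand=row.strand,
                cds=tuple(zip(starts, ends)),
                canonical=bool(int(getattr(row, "canonical", "1") or 1)),
                loeuf_decile=(
                    int(row.loeuf_decile)
                    if "loeuf_decile" in df.columns and pd.notna(row.loeuf_decile)
                    else None
                ),
            )
        )
    return out


def write_transcripts_tsv(transcripts: Sequence[TranscriptModel], path) -> None:
    rows = []
    for t in transcripts:
        rows.append(
            {
                "gene": t.gene, "tx": t.tx, "contig": t.contig, "strand": t.strand,
                "cds_starts": ",".join(str(s) for s, _ in t.cds),
                "cds_ends": ",".join(str(e) for _, e in t.cds),
                "canonical": int(t.canonical),
                "loeuf_decile": "" if t.loeuf_decile is None else t.loeuf_decile,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def consequences_to_dataframe(records: Iterable[ConsequenceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene, "tx": r.tx,
                "contig": r.mnv.contig if r.mnv else "",
                "pos1": r.mnv.pos1 if r.mnv else "",
                "pos2": r.mnv.pos2 if r.mnv else "",
                "codon_index": r.codon_index, "ref_codon": r.ref_codon,
                "codon_mnv": r.codon_mnv,
                "aa_ref": r.aa_ref, "aa1": r.aa1, "aa2": r.aa2, "aa_mnv": r.aa_mnv,
                "category": r.category,
                "fully_rescued": "" if r.fully_rescued is None else r.fully_rescued,
                "ac1": r.mnv.ac1 if r.mnv else "",
                "ac2": r.mnv.ac2 if r.mnv else "",
                "ac_mnv": r.mnv.ac_mnv if r.mnv else "",
            }
        )
    return pd.DataFrame(rows)
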