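"""Synthetic phased cohorts with planted MNVs of known mechanism.

The generator builds a reference contig (optionally containing dinucleotide
repeat tracts and protein-coding genes), then plants MNV events on explicit
per-sample haplotypes according to a mechanism mixture:

* ``independent_snv`` — two SNVs on a shared haplotype whose pattern is
  drawn from the independent-SNV null spectrum (path-sum probability times
  dinucleotide opportunity) and whose constituent allele counts are drawn
  independently, emulating mutations from different generations;
* ``pol_zeta`` — single-generation doublets with the polymerase-zeta motif
  (GA->TT or GC->AA, either strand) and equal allele counts;
* ``slippage`` — single-generation doublets inside dinucleotide repeat
  tracts (unit XY -> YX), equal allele counts.

Because samples are represented as two explicit haplotype variant sets, the
cis/trans ground truth is exact; the VCF genotypes (GT with phase separator,
PS, GQ, DP, AD) are derived from the haplotypes.  Optional knobs degrade the
read-based phasing signal: unphased-genotype noise and phase-set
fragmentation.  All output is deterministic for a fixed seed.

Allele counts follow a geometric distribution (the field lacks a standard
generative choice here; the value used is recorded in the truth-manifest
metadata).  The model is diploid-autosome only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coding import TranscriptModel, translate
from .density import AnnotationInterval, write_annotation_bed
from .mechanism import genome_dinuc_counts, in_repeat_context, null_spectrum_weights
from .patterns import BASES, POL_ZETA_PATTERNS, Pattern, canonical_pattern, origin_class, revcomp
from .ratetable import MutationRateTable

GUARD = 12  # bp kept free around a planted event (exceeds the 10 bp scan window)
STOP_CODONS = {"TAA", "TAG", "TGA"}


class PlacementError(ValueError):
    """Requested repeat/gene placements overlap or fall off the contig."""


class CapacityError(RuntimeError):
    """More events requested than available genomic positions."""


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatSpec:
    unit: str
    copies: int
    position: int  # 0-based start

    def __post_init__(self):
        if not 1 <= len(self.unit) <= 2:
            raise ValueError("repeat units must be 1-2 bp")
        if self.copies < 2:
            raise ValueError("a tract needs >= 2 copies")

    @property
    def length(self) -> int:
        return len(self.unit) * self.copies


@dataclass(frozen=True)
class GeneSpec:
    name: str
    start: int  # 1-based CDS start
    length: int  # CDS length, multiple of 3
    strand: str = "+"

    def __post_init__(self):
        if self.length % 3 or self.length < 9:
            raise ValueError("CDS length must be a multiple of 3 and >= 9")


@dataclass
class ReferenceBundle:
    """Reference contigs plus the companion models the pipeline consumes."""

    contigs: dict[str, str]
    transcripts: list[TranscriptModel] = field(default_factory=list)
    annotations: list[AnnotationInterval] = field(default_factory=list)
    lcr_mask: list[tuple[str, int, int]] = field(default_factory=list)
    repeat_tracts: list[tuple[str, RepeatSpec]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not seq or set(seq) - set(BASES):
                raise ValueError(f"contig {name} must be nonempty uppercase ACGT")
        for contig, start, end in self.lcr_mask:
            if not 0 <= start < end <= len(self.contigs[contig]):
                raise ValueError("LCR interval outside contig bounds")
        for iv in self.annotations:
            if iv.end > len(self.contigs[iv.contig]):
                raise ValueError("annotation interval outside contig bounds")

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_lcr_bed(self, path) -> None:
        with open(path, "w") as fh:
            for contig, start, end in self.lcr_mask:
                fh.write(f"{contig}\t{start}\t{end}\tLCR\n")

    def write_annotations_bed(self, path) -> None:
        write_annotation_bed(self.annotations, path)


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """ATG + stop-free random codons + TAA."""
    n_mid = length // 3 - 2
    codons = ["ATG"]
    for _ in range(n_mid):
        codon = "".join(rng.choice(list(BASES), 3))
        while codon in STOP_CODONS:
            codon = "".join(rng.choice(list(BASES), 3))
        codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def generate_reference(
    length: int,
    repeat_spec: Sequence[RepeatSpec] = (),
    gene_spec: Sequence[GeneSpec] = (),
    annotations: Sequence[AnnotationInterval] = (),
    lcr_mask: Sequence[tuple[str, int, int]] = (),
    seed: int = 0,
    contig: str = "1",
) -> ReferenceBundle:
    """Build a single-contig reference with requested repeats and genes.

    The sequence is uniformly random outside the placed features; repeat
    tracts and gene CDS must not overlap.  Deterministic for a fixed seed.
    """
    if length < 1000:
        raise ValueError("contig length must be >= 1000")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(BASES), size=length)
    placements: list[tuple[int, int, str]] = []
    for rs in repeat_spec:
        placements.append((rs.position, rs.position + rs.length, f"repeat@{rs.position}"))
    for gs in gene_spec:
        placements.append((gs.start - 1, gs.start - 1 + gs.length, f"gene {gs.name}"))
    placements.sort()
    for (s1, e1, n1), (s2, e2, n2) in zip(placements, placements[1:]):
        if s2 < e1:
            raise PlacementError(f"{n1} overlaps {n2}")
    if placements and (placements[0][0] < 0 or placements[-1][1] > length):
        raise PlacementError("placement off the contig")
    for rs in repeat_spec:
        tract = (rs.unit * rs.copies)[: rs.length]
        seq[rs.position : rs.position + rs.length] = list(tract)
    transcripts = []
    for gs in gene_spec:
        cds = _random_cds(gs.length, rng)
        genomic = cds if gs.strand == "+" else revcomp(cds)
        seq[gs.start - 1 : gs.start - 1 + gs.length] = list(genomic)
        transcripts.append(
            TranscriptModel(
                gene=gs.name,
                tx=f"{gs.name}.t1",
                contig=contig,
                strand=gs.strand,
                cds=((gs.start, gs.start + gs.length - 1),),
            )
        )
    bundle = ReferenceBundle(
        contigs={contig: "".join(seq)},
        transcripts=transcripts,
        annotations=list(annotations),
        lcr_mask=list(lcr_mask),
        repeat_tracts=[(contig, rs) for rs in repeat_spec],
        seed=seed,
    )
    for tx in bundle.transcripts:
        aa = translate(tx.cds_sequence(bundle.contigs[contig]))
        assert "*" not in aa[:-1], "internal stop in generated CDS"
    return bundle


# ---------------------------------------------------------------------------
# cohort specification and truth manifest
# ---------------------------------------------------------------------------

MECHANISMS = ("independent_snv", "pol_zeta", "slippage")


@dataclass
class CohortSpec:
    """Study conditions for a planted cohort."""

    n_samples: int
    n_events: int = 200
    n_trios: int = 0
    mechanism_mix: dict[str, float] = field(
        default_factory=lambda: {"independent_snv": 1.0}
    )
    ac_geometric_p: float = 0.5
    max_distance: int = 1
    snv_rate_table: MutationRateTable | None = None
    noise_unphased_rate: float = 0.0
    trans_pair_rate: float = 0.0
    ps_fragment_rate: float = 0.0
    avoid_repeat_context: bool = True
    methylation_bias: float = 0.0

    def __post_init__(self):
        extra = set(self.mechanism_mix) - set(MECHANISMS)
        if extra:
            raise ValueError(f"unknown mechanisms {extra}")
        if not np.isclose(sum(self.mechanism_mix.values()), 1.0):
            raise ValueError("mechanism_mix probabilities must sum to 1")
        if self.n_trios * 3 > self.n_samples:
            raise ValueError("n_trios x 3 must not exceed n_samples")
        if self.snv_rate_table is None:
            self.snv_rate_table = MutationRateTable.default()


@dataclass(frozen=True)
class TruthEvent:
    """One planted in-cis MNV with its ground-truth bookkeeping."""

    contig: str
    pos1: int
    pos2: int
    ref1: str
    alt1: str
    ref2: str
    alt2: str
    mechanism: str
    ac1: int
    ac2: int
    ac_mnv: int
    in_repeat: bool
    cis_haps: tuple[int, ...]  # global haplotype ids (2*sample + hap)

    @property
    def pattern(self) -> Pattern:
        return canonical_pattern(
            self.ref1 + self.ref2, self.alt1 + self.alt2, self.pos2 - self.pos1
        )


@dataclass(frozen=True)
class TransPair:
    contig: str
    pos1: int
    pos2: int
    sample: int


@dataclass
class TruthManifest:
    events: list[TruthEvent] = field(default_factory=list)
    trans_pairs: list[TransPair] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n_haps = 2 * self.metadata.get("n_samples", 10**9)
        for ev in self.events:
            if any(h >= n_haps for h in ev.cis_haps):
                raise ValueError("carrier haplotype outside the cohort")
            if ev.mechanism in ("pol_zeta", "slippage") and not (
                ev.ac1 == ev.ac2 == ev.ac_mnv
            ):
                raise ValueError(
                    f"{ev.mechanism} events are single-generation: ACs must match"
                )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metadata: {json.dumps(self.metadata, sort_keys=True)}\n")
            cols = [
                "contig", "pos1", "pos2", "ref1", "alt1", "ref2", "alt2",
                "mechanism", "ac1", "ac2", "ac_mnv", "in_repeat", "cis_haps",
            ]
            fh.write("\t".join(cols) + "\n")
            for ev in self.events:
                fh.write(
                    "\t".join(
                        str(x)
                        for x in [
                            ev.contig, ev.pos1, ev.pos2, ev.ref1, ev.alt1,
                            ev.ref2, ev.alt2, ev.mechanism, ev.ac1, ev.ac2,
                            ev.ac_mnv, int(ev.in_repeat),
                            ",".join(map(str, ev.cis_haps)),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# cohort planting
# ---------------------------------------------------------------------------


class _Placer:
    """Tracks free positions and dinucleotide occurrence indexes."""

    def __init__(self, bundle: ReferenceBundle, rng: np.random.Generator):
        self.bundle = bundle
        self.rng = rng
        self.contig = next(iter(bundle.contigs))
        self.seq = bundle.contigs[self.contig]
        self.free = np.ones(len(self.seq), dtype=bool)
        self.free[:GUARD] = False
        self.free[-GUARD:] = False
        for contig, start, end in bundle.lcr_mask:
            if contig == self.contig:
                self.free[max(0, start - GUARD) : end + GUARD] = False
        self.tract_free: list[RepeatSpec] = []
        for contig, rs in bundle.repeat_tracts:
            if contig == self.contig:
                self.free[max(0, rs.position - GUARD) : rs.position + rs.length + GUARD] = False
                self.tract_free.append(rs)
        self._dinuc_index: dict[str, np.ndarray] = {}

    def dinuc_positions(self, dinuc: str) -> np.ndarray:
        if dinuc not in self._dinuc_index:
            arr = np.frombuffer(self.seq.encode(), dtype="S1")
            hits = np.flatnonzero((arr[:-1] == dinuc[0].encode()) & (arr[1:] == dinuc[1].encode()))
            self._dinuc_index[dinuc] = hits
        return self._dinuc_index[dinuc]

    def reserve(self, i: int, d: int) -> None:
        self.free[max(0, i - GUARD) : i + d + GUARD + 1] = False

    def pick_site(self, ref_pair: str, alt_pair: str, accept=None, tries: int = 400):
        """A free 0-based position whose dinucleotide equals ref_pair."""
        hits = self.dinuc_positions(ref_pair)
        if len(hits) == 0:
            return None
        for _ in range(tries):
            i = int(hits[self.rng.integers(len(hits))])
            if not (self.free[i] and self.free[i + 1]):
                continue
            if accept is not None and not accept(i):
                continue
            return i
        return None

    def pick_tract_site(self) -> tuple[int, str, str] | None:
        """A slippage site inside an unused hetero-dinucleotide tract."""
        candidates = [
            rs
            for rs in self.tract_free
            if len(rs.unit) == 2 and rs.unit[0] != rs.unit[1] and rs.copies >= 4
        ]
        self.rng.shuffle(candidates)
        for rs in candidates:
            # middle unit of the tract, aligned to the unit frame
            k = rs.copies // 2
            i = rs.position + 2 * k
            ref_pair = rs.unit
            alt_pair = rs.unit[::-1]
            if in_repeat_context(self.seq, i + 1, i + 2, ref_pair, alt_pair):
                self.tract_free.remove(rs)
                return i, ref_pair, alt_pair
            self.tract_free.remove(rs)
        return None


def _geometric(rng: np.random.Generator, p: float, cap: int) -> int:
    return int(min(rng.geometric(p), cap))


def plant_cohort(
    bundle: ReferenceBundle,
    spec: CohortSpec,
    vcf_path,
    seed: int = 0,
) -> TruthManifest:
    """Plant MNV events on sample haplotypes and emit a phased VCF.

    Returns the truth manifest; the VCF (4.2, FORMAT GT:PS:GQ:DP:AD) is
    written to ``vcf_path``.  Raises :class:`CapacityError` when the contig
    cannot host the requested number of events.
    """
    rng = np.random.default_rng(seed)
    placer = _Placer(bundle, rng)
    contig = placer.contig
    seq = placer.seq
    n_haps = 2 * spec.n_samples
    ac_cap = max(1, n_haps // 4)

    weights = null_spectrum_weights(
        spec.snv_rate_table, genome_dinuc_counts(bundle.contigs)
    )
    patterns = sorted(weights)
    pvec = np.array([weights[p] for p in patterns], dtype=float)
    pvec /= pvec.sum()

    meth_ivs = [iv for iv in bundle.annotations if iv.methylation is not None]

    def methylation_at(i: int) -> float:
        for iv in meth_ivs:
            if iv.contig == contig and iv.start <= i < iv.end:
                return iv.methylation
        return 0.5

    def clean(i: int, alt_pair: str) -> bool:
        ref_pair = seq[i : i + 2]
        if spec.avoid_repeat_context and in_repeat_context(
            seq, i + 1, i + 2, ref_pair, alt_pair
        ):
            return False
        return True

    mechanisms = sorted(spec.mechanism_mix)
    mech_p = np.array([spec.mechanism_mix[m] for m in mechanisms])
    events: list[TruthEvent] = []
    hap_variants: dict[tuple[int, str, str], set[int]] = {}

    def add_variant(pos0: int, ref: str, alt: str, haps) -> None:
        hap_variants.setdefault((pos0, ref, alt), set()).update(haps)

    for _ in range(spec.n_events):
        mech = mechanisms[int(rng.choice(len(mechanisms), p=mech_p))]
        if mech == "slippage":
            site = placer.pick_tract_site()
            if site is None:
                raise CapacityError("no free hetero-dinucleotide repeat tracts left")
            i, ref_pair, alt_pair = site
            ac = _geometric(rng, spec.ac_geometric_p, ac_cap)
            haps = rng.choice(n_haps, size=ac, replace=False)
            add_variant(i, ref_pair[0], alt_pair[0], haps)
            add_variant(i + 1, ref_pair[1], alt_pair[1], haps)
            events.append(
                TruthEvent(
                    contig, i + 1, i + 2, ref_pair[0], alt_pair[0],
                    ref_pair[1], alt_pair[1], mech, ac, ac, ac, True,
                    tuple(sorted(int(h) for h in haps)),
                )
            )
            continue

        if mech == "pol_zeta":
            ref_c, alt_c = sorted(POL_ZETA_PATTERNS)[int(rng.integers(2))]
        else:
            idx = int(rng.choice(len(patterns), p=pvec))
            ref_c, alt_c = patterns[idx].ref, patterns[idx].alt
        if rng.random() < 0.5:
            ref_pair, alt_pair = revcomp(ref_c), revcomp(alt_c)
        else:
            ref_pair, alt_pair = ref_c, alt_c

        def accept(i, _alt=alt_pair, _ref=ref_c, _altc=alt_c):
            if not clean(i, _alt):
                return False
            if (
                mech == "independent_snv"
                and spec.methylation_bias > 0
                and origin_class(Pattern(_ref, _altc)) == "CpG"
            ):
                return rng.random() < methylation_at(i)
            return True

        i = placer.pick_site(ref_pair, alt_pair, accept=accept)
        if i is None:
            raise CapacityError(
                f"no free position for pattern {ref_pair}->{alt_pair}"
            )
        placer.reserve(i, 1)
        if mech == "pol_zeta":
            ac = _geometric(rng, spec.ac_geometric_p, ac_cap)
            cis = rng.choice(n_haps, size=ac, replace=False)
            extra1 = extra2 = np.empty(0, dtype=int)
        else:
            ac_cis = _geometric(rng, spec.ac_geometric_p, ac_cap)
            e1 = _geometric(rng, spec.ac_geometric_p, ac_cap) - 1
            e2 = _geometric(rng, spec.ac_geometric_p, ac_cap) - 1
            chosen = rng.choice(n_haps, size=ac_cis + e1 + e2, replace=False)
            cis = chosen[:ac_cis]
            extra1 = chosen[ac_cis : ac_cis + e1]
            extra2 = chosen[ac_cis + e1 :]
        add_variant(i, ref_pair[0], alt_pair[0], list(cis) + list(extra1))
        add_variant(i + 1, ref_pair[1], alt_pair[1], list(cis) + list(extra2))
        events.append(
            TruthEvent(
                contig, i + 1, i + 2, ref_pair[0], alt_pair[0],
                ref_pair[1], alt_pair[1], mech,
                len(cis) + len(extra1), len(cis) + len(extra2), len(cis),
                False, tuple(sorted(int(h) for h in cis)),
            )
        )

    trans_pairs: list[TransPair] = []
    n_trans = int(round(spec.trans_pair_rate * spec.n_events))
    for _ in range(n_trans):
        i = None  # any free adjacent position will do
        for _try in range(400):
            j = int(rng.integers(GUARD, len(seq) - GUARD - 2))
            if placer.free[j] and placer.free[j + 1]:
                i = j
                break
        if i is None:
            raise CapacityError("no free position for a trans pair")
        placer.reserve(i, 1)
        sample = int(rng.integers(spec.n_samples))
        alt1 = rng.choice([b for b in BASES if b != seq[i]])
        alt2 = rng.choice([b for b in BASES if b != seq[i + 1]])
        add_variant(i, seq[i], str(alt1), [2 * sample])
        add_variant(i + 1, seq[i + 1], str(alt2), [2 * sample + 1])
        trans_pairs.append(TransPair(contig, i + 1, i + 2, sample))

    manifest = TruthManifest(
        events=events,
        trans_pairs=trans_pairs,
        metadata={
            "n_samples": spec.n_samples,
            "seed": seed,
            "ac_model": "geometric",
            "ac_geometric_p": spec.ac_geometric_p,
            "mechanism_mix": spec.mechanism_mix,
            "noise_unphased_rate": spec.noise_unphased_rate,
            "ps_fragment_rate": spec.ps_fragment_rate,
        },
    )
    _write_cohort_vcf(
        vcf_path, contig, len(seq), spec, hap_variants, rng
    )
    return manifest


def _write_cohort_vcf(path, contig, contig_len, spec, hap_variants, rng) -> None:
    n = spec.n_samples
    samples = [f"S{i:05d}" for i in range(n)]
    ordered = sorted(hap_variants.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    # one phase set per contig by default; fragmentation starts a new set
    # between consecutive variant positions with the given probability
    positions = sorted({pos for (pos, _, _) in hap_variants})
    ps_of: dict[int, int] = {}
    current = positions[0] + 1 if positions else 1
    prev = None
    for pos in positions:
        if prev is not None and rng.random() < spec.ps_fragment_rate:
            current = pos + 1
        ps_of[pos] = current
        prev = pos
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        hom_ref = "0|0:.:99:30:30,0"
        for (pos, ref, alt), haps in ordered:
            ps = ps_of[pos]
            fields = [hom_ref] * n
            by_sample: dict[int, list[int]] = {}
            for h in haps:
                by_sample.setdefault(h // 2, []).append(h % 2)
            for s, hs in by_sample.items():
                if len(hs) == 2:
                    fields[s] = "1|1:.:99:30:0,30"
                else:
                    gt = "0|1" if hs[0] == 1 else "1|0"
                    if rng.random() < spec.noise_unphased_rate:
                        fields[s] = f"{gt.replace('|', '/')}:.:99:30:15,15"
                    else:
                        fields[s] = f"{gt}:{ps}:99:30:15,15"
            fh.write(
                f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t100\tPASS\t.\t"
                "GT:PS:GQ:DP:AD\t" + "\t".join(fields) + "\n"
            )


# ---------------------------------------------------------------------------
# trio cohorts
# ---------------------------------------------------------------------------

TRIO_CONFIGS = ("informative_cis", "informative_trans", "uninformative", "denovo")


@dataclass(frozen=True)
class TrioTruthPair:
    contig: str
    pos1: int
    pos2: int
    trio: int
    config: str
    true_relation: str  # child's haplotype truth: cis or trans


def plant_trios(
    bundle: ReferenceBundle,
    n_trios: int,
    vcf_path,
    ped_path,
    seed: int = 0,
    pairs_per_trio: int = 6,
    config_mix: Mapping[str, float] | None = None,
    max_distance: int = 10,
) -> list[TrioTruthPair]:
    """Plant child het/het pairs with known transmission in trio families.

    Children's haplotypes are copied from one parental haplotype each (no
    recombination), so the child's true relative phase is exact.  Parental
    genotype configurations cover transmission-forced (one parent hom-ref),
    inherently uninformative (both parents het) and Mendelian-violation
    (de novo) cases.  Writes a phased VCF and a 6-column PED.
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    if config_mix is None:
        config_mix = {
            "informative_cis": 0.4,
            "informative_trans": 0.3,
            "uninformative": 0.3,
        }
    if set(config_mix) - set(TRIO_CONFIGS):
        raise ValueError("unknown trio configuration")
    rng = np.random.default_rng(seed)
    placer = _Placer(bundle, rng)
    contig, seq = placer.contig, placer.seq
    samples = []
    for t in range(n_trios):
        samples += [f"F{t:03d}", f"M{t:03d}", f"C{t:03d}"]
    idx = {name: i for i, name in enumerate(samples)}

    configs = sorted(config_mix)
    cfg_p = np.array([config_mix[c] for c in configs])
    hap_variants: dict[tuple[int, str, str], set[int]] = {}
    truth: list[TrioTruthPair] = []

    def add(pos0, ref, alt, sample_name, hap):
        hap_variants.setdefault((pos0, ref, alt), set()).add(2 * idx[sample_name] + hap)

    for t in range(n_trios):
        f, m, c = f"F{t:03d}", f"M{t:03d}", f"C{t:03d}"
        for _ in range(pairs_per_trio):
            cfg = configs[int(rng.choice(len(configs), p=cfg_p))]
            d = int(rng.integers(1, max_distance + 1))
            i = None
            for _try in range(400):
                j = int(rng.integers(GUARD, len(seq) - GUARD - d - 1))
                if placer.free[j] and placer.free[j + d]:
                    i = j
                    break
            if i is None:
                raise CapacityError("no free positions left for trio pairs")
            placer.reserve(i, d)
            ref1, ref2 = seq[i], seq[i + d]
            alt1 = str(rng.choice([b for b in BASES if b != ref1]))
            alt2 = str(rng.choice([b for b in BASES if b != ref2]))
            # child haplotype 0 = paternal, 1 = maternal
            if cfg == "informative_cis":
                # mother carries both alts on one haplotype; father hom-ref
                add(i, ref1, alt1, m, 0)
                add(i + d, ref2, alt2, m, 0)
                add(i, ref1, alt1, c, 1)
                add(i + d, ref2, alt2, c, 1)
                relation = "cis"
            elif cfg == "informative_trans":
                add(i, ref1, alt1, f, 0)
                add(i + d, ref2, alt2, m, 0)
                add(i, ref1, alt1, c, 0)
                add(i + d, ref2, alt2, c, 1)
                relation = "trans"
            elif cfg == "uninformative":
                # both parents het at both sites (cis on one haplotype each);
                # child inherits the paternal alt haplotype only
                add(i, ref1, alt1, f, 0)
                add(i + d, ref2, alt2, f, 0)
                add(i, ref1, alt1, m, 0)
                add(i + d, ref2, alt2, m, 0)
                add(i, ref1, alt1, c, 0)
                add(i + d, ref2, alt2, c, 0)
                relation = "cis"
            else:  # denovo: site 1 violates transmission, site 2 maternal
                add(i, ref1, alt1, c, 0)  # absent from both parents
                add(i + d, ref2, alt2, m, 0)
                add(i + d, ref2, alt2, c, 1)
                relation = "trans"
            truth.append(TrioTruthPair(contig, i + 1, i + d + 1, t, cfg, relation))

    _write_trio_vcf(vcf_path, contig, len(seq), samples, hap_variants)
    with open(ped_path, "w") as fh:
        for t in range(n_trios):
            fh.write(f"fam{t}\tF{t:03d}\t0\t0\t1\t0\n")
            fh.write(f"fam{t}\tM{t:03d}\t0\t0\t2\t0\n")
            fh.write(f"fam{t}\tC{t:03d}\tF{t:03d}\tM{t:03d}\t1\t0\n")
    return truth


def _write_trio_vcf(path, contig, contig_len, samples, hap_variants) -> None:
    # like the cohort writer but with explicit sample names, one phase set,
    # and no stochastic degradation
    n = len(samples)
    ordered = sorted(hap_variants.items())
    positions = sorted({pos for (pos, _, _) in hap_variants})
    ps = positions[0] + 1 if positions else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        hom_ref = "0|0:.:99:30:30,0"
        for (pos, ref, alt), haps in ordered:
            fields = [hom_ref] * n
            by_sample: dict[int, list[int]] = {}
            for h in haps:
                by_sample.setdefault(h // 2, []).append(h % 2)
            for s, hs in by_sample.items():
                if len(hs) == 2:
                    fields[s] = "1|1:.:99:30:0,30"
                else:
                    gt = "0|1" if hs[0] == 1 else "1|0"
                    fields[s] = f"{gt}:{ps}:99:30:15,15"
            fh.write(
                f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t100\tPASS\t.\t"
                "GT:PS:GQ:DP:AD\t" + "\t".join(fields) + "\n"
            )
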