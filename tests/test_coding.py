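"""Codon mapping, combined consequences, tallies, enrichment, indel pairs."""

from types import SimpleNamespace as NS

import numpy as np
import pytest
from scipy.stats import hypergeom

from mnvkit.coding import (
    NotCoding,
    TranscriptModel,
    codon_of,
    combined_consequence,
    constraint_enrichment,
    find_frame_restoring_indel_pairs,
    per_gene_tallies,
    per_sample_tallies,
    translate,
)
from mnvkit.patterns import revcomp

from conftest import HET, write_vcf

# single-exon gene: ATG CAC TCA CTG TAA at 1-based 11..25
SEQ = "T" * 10 + "ATGCACTCACTGTAA" + "G" * 975
TX = TranscriptModel("G1", "G1.t1", "1", "+", ((11, 25),))


class TestCodonOf:
    def test_plus_strand_arithmetic(self):
        assert codon_of(14, TX, SEQ) == (1, 0, "CAC")
        assert codon_of(16, TX, SEQ) == (1, 2, "CAC")

    def test_minus_strand_reads_reverse_complement(self):
        mirror_seq = revcomp(SEQ)
        tx = TranscriptModel("G1", "G1.m", "1", "-", ((976, 990),))
        # genomic position mirroring + strand position 14
        assert codon_of(1001 - 14, tx, mirror_seq) == (1, 0, "CAC")

    def test_intronic_position_flagged(self):
        tx = TranscriptModel("G2", "G2.t1", "1", "+", ((11, 16), (101, 103)))
        with pytest.raises(NotCoding):
            codon_of(50, tx, SEQ)

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            TranscriptModel("G", "t", "1", "+", ((11, 14),))


class TestCombinedConsequence:
    def test_gained_nonsense(self):
        r = combined_consequence(NS(pos=14, ref="C", alt="T"), NS(pos=16, ref="C", alt="A"), TX, SEQ)
        assert (r.aa_ref, r.aa1, r.aa2, r.aa_mnv) == ("H", "Y", "Q", "*")
        assert r.category == "gained_nonsense"

    def test_rescued_nonsense(self):
        r = combined_consequence(NS(pos=17, ref="T", alt="A"), NS(pos=18, ref="C", alt="G"), TX, SEQ)
        assert (r.aa_ref, r.aa1, r.aa2, r.aa_mnv) == ("S", "T", "*", "R")
        assert r.category == "rescued_nonsense"

    def test_two_synonymous_snvs_unchanged(self):
        r = combined_consequence(NS(pos=20, ref="C", alt="T"), NS(pos=22, ref="G", alt="A"), TX, SEQ)
        assert {r.aa_ref, r.aa1, r.aa2, r.aa_mnv} == {"L"}
        assert r.category == "unchanged"

    def test_cross_codon_pairs_not_categorized(self):
        r = combined_consequence(NS(pos=16, ref="C", alt="A"), NS(pos=17, ref="T", alt="A"), TX, SEQ)
        assert r.category == "cross_codon"

    def test_reference_mismatch_is_a_data_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            combined_consequence(NS(pos=14, ref="G", alt="T"), NS(pos=16, ref="C", alt="A"), TX, SEQ)

    def test_strand_symmetry(self):
        """A mirrored transcript yields the identical consequence."""
        mirror_seq = revcomp(SEQ)
        tx_m = TranscriptModel("G1", "G1.m", "1", "-", ((976, 990),))
        fwd = combined_consequence(NS(pos=14, ref="C", alt="T"), NS(pos=16, ref="C", alt="A"), TX, SEQ)
        m1 = NS(pos=1001 - 16, ref="G", alt="T")  # complement of pos-16 SNV
        m2 = NS(pos=1001 - 14, ref="G", alt="A")  # complement of pos-14 SNV
        rev = combined_consequence(m1, m2, tx_m, mirror_seq)
        assert (rev.aa_ref, rev.aa_mnv, rev.category) == (fwd.aa_ref, fwd.aa_mnv, fwd.category)
        assert {rev.aa1, rev.aa2} == {fwd.aa1, fwd.aa2}


class TestTallies:
    @staticmethod
    def _rec(gene, category, n_indiv=1, fully_rescued=None):
        mnv = NS(contig="1", pos1=1, pos2=2, ac1=2, ac2=2, ac_mnv=2, n_indiv=n_indiv)
        return NS(gene=gene, category=category, fully_rescued=fully_rescued, mnv=mnv)

    def test_per_gene_counts(self):
        recs = [
            self._rec("G", "gained_nonsense"),
            self._rec("G", "gained_nonsense"),
            self._rec("G", "rescued_nonsense", fully_rescued=True),
        ]
        df = per_gene_tallies(recs).set_index("gene")
        assert df.loc["G", "gained_nonsense"] == 2
        assert df.loc["G", "rescued_nonsense"] == 1
        assert bool(df.loc["G", "has_nonsense_effect"])

    def test_partial_rescues_excluded_on_request(self):
        recs = [self._rec("G", "rescued_nonsense", fully_rescued=False)]
        df = per_gene_tallies(recs, fully_rescued_only=True)
        assert df.empty or df["rescued_nonsense"].sum() == 0

    def test_per_sample_means(self):
        recs = [self._rec("G", "changed_missense", n_indiv=3)]
        df = per_sample_tallies(recs, n_samples=1).set_index("category")
        assert df.loc["changed_missense", "mean_per_individual"] == 3.0
        empty = per_sample_tallies([], n_samples=10)
        assert (empty["mean_per_individual"] == 0).all()


class TestConstraintEnrichment:
    @staticmethod
    def _records(a, b, c, d):
        recs = []
        recs += [NS(gene="CONSTRAINED", category="rescued_nonsense")] * a
        recs += [NS(gene="OTHER", category="rescued_nonsense")] * b
        recs += [NS(gene="CONSTRAINED", category="changed_missense")] * c
        recs += [NS(gene="OTHER", category="changed_missense")] * d
        return recs

    def test_odds_ratio_and_exact_p(self):
        res = constraint_enrichment(
            self._records(10, 90, 20, 380), "rescued_nonsense", {"CONSTRAINED"}
        )
        assert res.odds_ratio == pytest.approx(10 * 380 / (90 * 20), rel=1e-9)
        assert res.odds_ratio == pytest.approx(2.111, abs=0.001)
        # independent oracle: two-sided hypergeometric tail enumeration
        M, n, N = 500, 30, 100  # total, constrained, category size
        rv = hypergeom(M, n, N)
        p_obs = rv.pmf(10)
        p_oracle = sum(rv.pmf(k) for k in range(0, min(n, N) + 1) if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert res.p_value == pytest.approx(p_oracle, rel=1e-6)

    def test_identical_proportions_are_null(self):
        res = constraint_enrichment(
            self._records(10, 90, 30, 270), "rescued_nonsense", {"CONSTRAINED"}
        )
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_triggers_haldane(self):
        res = constraint_enrichment(
            self._records(0, 10, 5, 5), "rescued_nonsense", {"CONSTRAINED"}
        )
        assert res.haldane_corrected
        assert np.isfinite(res.odds_ratio)

    def test_empty_category_signalled(self):
        with pytest.raises(ValueError):
            constraint_enrichment(self._records(0, 0, 5, 5), "rescued_nonsense", set())


class TestFrameRestoringIndels:
    def _vcf(self, tmp_path, rows):
        return write_vcf(tmp_path / "indels.vcf", ["S1"], rows)

    def test_compensating_pair_reported(self, tmp_path):
        ps = HET.format(ps=5)
        path = self._vcf(
            tmp_path,
            [(100, "CAAAA", "C", [ps]), (112, "G", "GTTTTTTT", [ps])],  # -4 then +7
        )
        df = find_frame_restoring_indel_pairs(path)
        assert len(df) == 1
        assert df.loc[0, "net_change"] == 3

    def test_individually_inframe_pairs_excluded(self, tmp_path):
        ps = HET.format(ps=5)
        path = self._vcf(
            tmp_path, [(100, "CAAA", "C", [ps]), (112, "G", "GTTT", [ps])]  # -3, +3
        )
        assert find_frame_restoring_indel_pairs(path).empty

    def test_distance_cap(self, tmp_path):
        ps = HET.format(ps=5)
        path = self._vcf(
            tmp_path, [(100, "CAAAA", "C", [ps]), (135, "G", "GTTTTTTT", [ps])]
        )
        assert find_frame_restoring_indel_pairs(path, max_dist=30).empty


def test_translate_uses_the_standard_code():
    assert translate("ATGCACTGA") == "MH*"


class TestTranscriptIO:
    def test_tsv_round_trip(self, tmp_path):
        from mnvkit.coding import read_transcripts_tsv, write_transcripts_tsv

        t = TranscriptModel("G", "G.t1", "1", "-", ((11, 16), (101, 109)), loeuf_decile=2)
        write_transcripts_tsv([t], tmp_path / "tx.tsv")
        (back,) = read_transcripts_tsv(tmp_path / "tx.tsv")
        assert (back.gene, back.tx, back.strand, back.cds, back.loeuf_decile) == (
            "G", "G.t1", "-", ((11, 16), (101, 109)), 2
        )

    def test_gff3_cds_features(self, tmp_path):
        from mnvkit.coding import read_transcripts_gff3

        gff = tmp_path / "tx.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\t.\tgene\t11\t109\t.\t+\t.\tID=gene1;gene_id=G1\n"
            "1\t.\tmRNA\t11\t109\t.\t+\t.\tID=tx1;Parent=gene1\n"
            "1\t.\tCDS\t11\t16\t.\t+\t0\tID=c1;Parent=tx1;gene_id=G1\n"
            "1\t.\tCDS\t101\t109\t.\t+\t0\tID=c2;Parent=tx1;gene_id=G1\n"
        )
        (tx,) = read_transcripts_gff3(gff)
        assert (tx.gene, tx.tx, tx.cds) == ("G1", "tx1", ((11, 16), (101, 109)))
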