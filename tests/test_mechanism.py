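"""One-step/repeat classification, the SNV-path null model, q and rates."""

import numpy as np
import pytest

from mnvkit.mechanism import (
    estimate_q,
    estimate_rates,
    genome_dinuc_counts,
    in_repeat_context,
    is_one_step,
    null_path_probability,
    null_spectrum_weights,
    predicted_mechanism,
    repeat_unit_count,
)
from mnvkit.patterns import Pattern, enumerate_adjacent_patterns
from mnvkit.ratetable import MutationRateTable


class TestOneStep:
    def test_equal_allele_counts(self):
        assert is_one_step(5, 5, 5)
        assert not is_one_step(5, 7, 5)

    def test_strict_mode_requires_mnv_share(self):
        assert is_one_step(10, 10, 8)
        assert not is_one_step(10, 10, 8, strict=True)
        assert is_one_step(10, 10, 9, strict=True)

    def test_zero_counts_are_an_error(self):
        with pytest.raises(ValueError):
            is_one_step(0, 5, 0)


class TestRepeatContext:
    def test_gapped_unit_counting(self):
        # d=2 doublet T..T / A..A in a TA tract: both sides count 3
        assert repeat_unit_count("TATATAT", "TT", 2) == 3
        assert repeat_unit_count("TAAAAAT", "AA", 2) == 3
        assert repeat_unit_count("CACACACACA", "CA", 1) == 5
        assert repeat_unit_count("ACGTCAGTCC", "CA", 1) == 1

    def test_repeat_preserving_substitution_is_repetitive(self):
        seq = "G" * 10 + "TATATATATA" + "G" * 10
        # TA->AT at the central unit keeps both ref (TA x5) and alt (AT x3)
        # repeats above threshold
        assert in_repeat_context(seq, 15, 16, "TA", "AT")

    def test_repeat_destroying_substitution_is_not(self):
        # CA->TG in a CA tract leaves only one TG in the alternate context,
        # failing the both-sides requirement
        seq = "G" * 10 + "CACACACACA" + "G" * 10
        assert not in_repeat_context(seq, 15, 16, "CA", "TG")

    def test_unique_context_is_not_repetitive(self):
        seq = "G" * 10 + "ACGTCAGTCC" + "G" * 10
        assert not in_repeat_context(seq, 15, 16, "CA", "TG")

    def test_mononucleotide_alt_raises_threshold(self):
        # AA->TT inside a poly-A run: both sides mononucleotide; the alt
        # context TT count (1) cannot clear the raised threshold (>2)
        seq = "G" * 10 + "AAAAAAAAAA" + "G" * 10
        assert not in_repeat_context(seq, 15, 16, "AA", "TT")

    def test_edge_context_skipped(self):
        assert not in_repeat_context("CACACA", 1, 2, "CA", "TG")

    def test_reference_mismatch_detected(self):
        with pytest.raises(ValueError, match="mismatch"):
            in_repeat_context("G" * 20, 10, 11, "CA", "TG")


class TestNullModel:
    def test_uniform_rates_make_all_patterns_equal(self):
        table = MutationRateTable.uniform(1e-8)
        probs = [
            null_path_probability(p, table)[0] for p in enumerate_adjacent_patterns()
        ]
        assert np.allclose(probs, 2 * (1e-8) ** 2)

    def test_path_decomposition_of_cpg_pattern(self):
        table = MutationRateTable.default()
        _, paths = null_path_probability(Pattern("CA", "TG"), table)
        assert [label for label, _ in paths] == ["CA->TA->TG", "CA->CG->TG"]
        # the CpG-transition path (via the CG intermediate) dominates
        assert dict(paths)["CA->CG->TG"] > dict(paths)["CA->TA->TG"]

    def test_exact_flanks_change_the_answer(self):
        table = MutationRateTable.default()
        # with a 3' G flank the second-position C->T step is a CpG transition
        p_cpg, _ = null_path_probability(Pattern("AC", "GT"), table, flanks=("A", "G"))
        p_marg, _ = null_path_probability(Pattern("AC", "GT"), table)
        assert p_cpg > p_marg

    def test_missing_context_named_in_error(self):
        table = MutationRateTable.uniform()
        del table.rates[("A", "C", "A", "T")]
        with pytest.raises(KeyError, match="A\\[C->T\\]A"):
            null_path_probability(Pattern("CA", "TG"), table, flanks=("A", "A"))


class TestPredictedMechanism:
    @pytest.mark.parametrize(
        "ref,alt,rep_frac,label",
        [
            ("GA", "TT", 0.0, "pol_zeta"),
            ("GC", "AA", 0.5, "pol_zeta"),  # pol-zeta precedes repeat
            ("AA", "TT", 0.30, "repeat"),
            ("CA", "TG", 0.0, "Ti at CpG"),
            ("AA", "GG", 0.0, "Ti"),
            ("TA", "GC", 0.0, "Tv combination"),
        ],
    )
    def test_ordered_assignment(self, ref, alt, rep_frac, label):
        assert predicted_mechanism(Pattern(ref, alt), rep_frac) == label


class TestEstimateQ:
    @staticmethod
    def _null_spectrum(table, contigs, n_ind, total):
        weights = null_spectrum_weights(table, genome_dinuc_counts(contigs))
        wsum = sum(weights.values())
        return {p: round(total * w / wsum) for p, w in weights.items()}

    def test_null_spectrum_recovers_zero_excess(self):
        table = MutationRateTable.default()
        contigs = {"1": "ACGTTGCAACGGCTA" * 400}
        spectrum = self._null_spectrum(table, contigs, 100, 20_000)
        stats = estimate_q(spectrum, table, genome_dinuc_counts(contigs), 100)
        big = [s for s in stats if s.n_obs >= 50]
        assert big, "spectrum too sparse"
        assert np.median([s.q_hat for s in big]) < 0.05

    def test_planted_excess_recovered(self):
        table = MutationRateTable.default()
        contigs = {"1": "ACGTTGCAACGGCTA" * 400}
        spectrum = self._null_spectrum(table, contigs, 100, 20_000)
        target = Pattern("GC", "AA")
        spectrum[target] = 4 * spectrum[target]  # 4x excess -> q = 0.75
        stats = {s.pattern: s for s in estimate_q(
            spectrum, table, genome_dinuc_counts(contigs), 100
        )}
        assert stats[target].q_hat == pytest.approx(0.75, abs=0.05)

    def test_fractions_sum_to_one(self):
        table = MutationRateTable.default()
        contigs = {"1": "ACGTTGCAACGGCTA" * 200}
        spectrum = self._null_spectrum(table, contigs, 50, 5_000)
        stats = estimate_q(
            spectrum, table, genome_dinuc_counts(contigs), 50,
            repeat_counts={Pattern("TA", "AT"): 30},
        )
        for s in stats:
            assert all(f >= 0 for f in s.fractions.values())
            assert sum(s.fractions.values()) == pytest.approx(1.0)

    def test_all_zero_spectrum_rejected(self):
        table = MutationRateTable.uniform()
        with pytest.raises(ValueError, match="all-zero"):
            estimate_q({}, table, {"AA": 10}, 10)


class TestEstimateRates:
    def test_global_rate_scaling(self):
        # site ratio of 2.45e-3 at the canonical SNV rate
        est = estimate_rates(2450, 1_000_000, {}, {"AA": 100}, mu_snv=1.2e-8)
        assert est.mu_mnv_global == pytest.approx(2.94e-11, rel=1e-6)

    def test_zero_mnv_sites_give_zero_rates(self):
        est = estimate_rates(0, 1000, {}, {"AA": 100})
        assert est.mu_mnv_global == 0.0
        assert (est.per_pattern["rate_per_2bp"].fillna(0) == 0).all()

    def test_per_pattern_split_conserves_the_global_rate(self):
        rng = np.random.default_rng(2)
        contigs = {"1": "".join(rng.choice(list("ACGT"), 5000))}
        dinucs = genome_dinuc_counts(contigs)
        spectrum = {Pattern("GA", "TT"): 30, Pattern("CA", "TG"): 60, Pattern("TA", "AT"): 10}
        est = estimate_rates(100, 40_000, spectrum, dinucs, coverage_factor=1.0)
        events = (est.per_pattern["rate_per_2bp"] * est.per_pattern["n_dinuc"]).sum()
        assert events == pytest.approx(est.mu_mnv_global * sum(dinucs.values()))

    def test_no_snv_sites_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_rates(10, 0, {}, {})
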