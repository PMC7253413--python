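"""Reference/cohort generator: determinism, truth bookkeeping, trio logic."""

import numpy as np
import pytest

from mnvkit import (
    CohortSpec,
    GeneSpec,
    generate_reference,
    plant_cohort,
    plant_trios,
    scan_mnvs,
)
from mnvkit.coding import translate
from mnvkit.discovery import iter_sites
from mnvkit.mechanism import in_repeat_context
from mnvkit.patterns import POL_ZETA_PATTERNS
from mnvkit.synthetic import CapacityError, PlacementError, RepeatSpec


class TestGenerateReference:
    def test_repeat_tract_placed_verbatim(self):
        b = generate_reference(10_000, repeat_spec=[RepeatSpec("TA", 6, 500)], seed=1)
        assert b.contigs["1"][500:512] == "TATATATATATA"

    def test_deterministic_for_fixed_seed(self, tmp_path):
        paths = []
        for i in (0, 1):
            b = generate_reference(10_000, repeat_spec=[RepeatSpec("TA", 6, 500)], seed=1)
            p = tmp_path / f"ref{i}.fa"
            b.write_fasta(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_gene_cds_translates_without_internal_stop(self):
        b = generate_reference(10_000, gene_spec=[GeneSpec("G", 2001, 300, "+")], seed=2)
        (tx,) = b.transcripts
        aa = translate(tx.cds_sequence(b.contigs["1"]))
        assert aa[0] == "M" and aa[-1] == "*" and "*" not in aa[:-1]

    def test_minus_strand_gene(self):
        b = generate_reference(10_000, gene_spec=[GeneSpec("G", 2001, 300, "-")], seed=2)
        (tx,) = b.transcripts
        aa = translate(tx.cds_sequence(b.contigs["1"]))
        assert aa[0] == "M" and "*" not in aa[:-1]

    def test_overlapping_placements_rejected(self):
        with pytest.raises(PlacementError):
            generate_reference(
                10_000,
                repeat_spec=[RepeatSpec("TA", 6, 500)],
                gene_spec=[GeneSpec("G", 498, 300)],
                seed=1,
            )


class TestPlantCohort:
    def test_vcf_deterministic_for_fixed_seed(self, tract_bundle, tmp_path):
        spec = CohortSpec(n_samples=10, n_events=20)
        out = []
        for i in (0, 1):
            p = tmp_path / f"c{i}.vcf"
            plant_cohort(tract_bundle, spec, p, seed=5)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_planted_acs_match_the_emitted_vcf(self, mixed_cohort):
        vcf, manifest = mixed_cohort
        ac_by_site = {}
        for site, _ in iter_sites(vcf):
            v = site.variant
            ac_by_site[(v.pos, v.ref, v.alt)] = v.ac
        for ev in manifest.events:
            assert ac_by_site[(ev.pos1, ev.ref1, ev.alt1)] == ev.ac1
            assert ac_by_site[(ev.pos2, ev.ref2, ev.alt2)] == ev.ac2

    def test_pol_zeta_events_have_matched_acs_and_motifs(self, tract_bundle, tmp_path):
        spec = CohortSpec(n_samples=20, n_events=50, mechanism_mix={"pol_zeta": 1.0})
        man = plant_cohort(tract_bundle, spec, tmp_path / "pz.vcf", seed=3)
        for ev in man.events:
            assert ev.ac1 == ev.ac2 == ev.ac_mnv
            assert (ev.pattern.ref, ev.pattern.alt) in POL_ZETA_PATTERNS

    def test_slippage_events_satisfy_the_repeat_classifier(self, tract_bundle, tmp_path):
        spec = CohortSpec(n_samples=20, n_events=15, mechanism_mix={"slippage": 1.0})
        man = plant_cohort(tract_bundle, spec, tmp_path / "sl.vcf", seed=4)
        seq = tract_bundle.contigs["1"]
        for ev in man.events:
            assert ev.in_repeat
            assert in_repeat_context(
                seq, ev.pos1, ev.pos2, ev.ref1 + ev.ref2, ev.alt1 + ev.alt2
            )

    def test_capacity_error_when_no_tracts(self, tmp_path):
        b = generate_reference(2000, seed=6)
        spec = CohortSpec(n_samples=5, n_events=5, mechanism_mix={"slippage": 1.0})
        with pytest.raises(CapacityError):
            plant_cohort(b, spec, tmp_path / "x.vcf", seed=1)

    def test_mechanism_mix_converges(self, tmp_path):
        big = generate_reference(60_000, seed=12)
        mix = {"independent_snv": 0.6, "pol_zeta": 0.4}
        spec = CohortSpec(n_samples=10, n_events=1000, mechanism_mix=mix)
        man = plant_cohort(big, spec, tmp_path / "mix.vcf", seed=8)
        n_pz = sum(ev.mechanism == "pol_zeta" for ev in man.events)
        se = np.sqrt(0.4 * 0.6 / 1000)
        assert abs(n_pz / 1000 - 0.4) < 3 * se

    def test_strand_orientation_of_planting_is_balanced(self, tract_bundle, tmp_path):
        spec = CohortSpec(n_samples=10, n_events=400, mechanism_mix={"pol_zeta": 1.0})
        man = plant_cohort(tract_bundle, spec, tmp_path / "orient.vcf", seed=9)
        fwd = sum((ev.ref1 + ev.ref2, ev.alt1 + ev.alt2) in POL_ZETA_PATTERNS for ev in man.events)
        # raw pattern vs reverse-complement counts roughly symmetric
        assert 0.4 < fwd / 400 < 0.6

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_samples=10, mechanism_mix={"independent_snv": 0.5})
        with pytest.raises(ValueError):
            CohortSpec(n_samples=2, n_trios=1)

    def test_full_recall_with_clean_phasing(self, mixed_cohort):
        vcf, manifest = mixed_cohort
        found = {(r.pos1, r.pos2): r for r in scan_mnvs(vcf, max_dist=10)}
        for ev in manifest.events:
            assert found[(ev.pos1, ev.pos2)].ac_mnv == ev.ac_mnv
        trans = {(t.pos1, t.pos2) for t in manifest.trans_pairs}
        assert not trans & set(found)


class TestPlantTrios:
    def test_truth_phase_matches_transmission(self, tract_bundle, tmp_path):
        from mnvkit.phasing import phasing_concordance, trio_pair_phases

        truth = plant_trios(
            tract_bundle, 4, tmp_path / "t.vcf", tmp_path / "t.ped", seed=10,
            pairs_per_trio=6,
        )
        pairs = trio_pair_phases(tmp_path / "t.vcf", tmp_path / "t.ped")
        tmap = {(p.pos1, p.pos2): p for p in truth}
        checked = 0
        for d, read, trio, pos1, pos2 in pairs:
            assert read.relation in ("cis", "trans")
            if trio.relation in ("cis", "trans"):
                assert trio.relation == read.relation
                if (pos1, pos2) in tmap:
                    assert trio.relation == tmap[pos1, pos2].true_relation
                checked += 1
        assert checked > 0

    def test_de_novo_raises_violation(self, tract_bundle, tmp_path):
        from mnvkit.phasing import trio_pair_phases

        plant_trios(
            tract_bundle, 3, tmp_path / "d.vcf", tmp_path / "d.ped", seed=11,
            pairs_per_trio=4, config_mix={"denovo": 1.0},
        )
        pairs = trio_pair_phases(tmp_path / "d.vcf", tmp_path / "d.ped")
        assert pairs and all(t.violation for _, _, t, *_ in pairs)
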