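"""De novo mutation calling, SV filter rules and kinship estimation."""

import numpy as np
import pytest

from beaudit.genome import ReferenceGenome
from beaudit.simulate import SimulationConfig
from beaudit.trio import (
    DnmFilterParams,
    StructuralVariant,
    apply_dnm_filters,
    denovo_svs,
    flag_for_review,
    genotype_matrix,
    mendelian_denovo_candidates,
    pairwise_kinship,
)
from beaudit.variants import MemberCall, TrioGenotypes
from beaudit.workflows import kinship_experiment, run_simulated_audit


def member(gt=(0, 1), depth=30, pl=(120, 0, 120)):
    return MemberCall(genotype=gt, depth=depth, pl=pl)


def trio_site(off=None, sire=None, dam=None, pos=100, ref="C", alt="T"):
    return TrioGenotypes(
        contig="chr1", pos=pos, ref=ref, alt=alt,
        offspring=off or member(),
        sire=sire or member(gt=(0, 0), pl=(0, 120, 120)),
        dam=dam or member(gt=(0, 0), pl=(0, 120, 120)),
    )


class TestMendelianCandidates:
    def test_offspring_only_alt_is_candidate(self):
        candidates, _ = mendelian_denovo_candidates([trio_site()])
        assert len(candidates) == 1

    def test_parental_alt_excluded(self):
        rec = trio_site(sire=member(gt=(0, 1), pl=(120, 0, 120)))
        candidates, _ = mendelian_denovo_candidates([rec])
        assert candidates == []

    def test_missing_parent_genotype_counted_separately(self):
        rec = trio_site(dam=MemberCall(genotype=None, depth=0, pl=()))
        candidates, n_unresolvable = mendelian_denovo_candidates([rec])
        assert candidates == []
        assert n_unresolvable == 1

    def test_hom_ref_offspring_ignored(self):
        rec = trio_site(off=member(gt=(0, 0), pl=(0, 120, 120)))
        candidates, n_unresolvable = mendelian_denovo_candidates([rec])
        assert candidates == [] and n_unresolvable == 0


class TestDnmFilters:
    def test_low_parent_depth_dropped(self):
        rec = trio_site(dam=member(gt=(0, 0), depth=4, pl=(0, 120, 120)))
        assert apply_dnm_filters([rec], DnmFilterParams(min_depth_each_member=10)) == []

    def test_confident_offspring_pl_retained(self):
        rec = trio_site(off=member(pl=(50, 0, 90)))
        params = DnmFilterParams(min_pl_second_best_offspring=20)
        assert apply_dnm_filters([rec], params) == [rec]

    def test_ambiguous_offspring_pl_dropped(self):
        rec = trio_site(off=member(pl=(10, 0, 90)))
        params = DnmFilterParams(min_pl_second_best_offspring=20)
        assert apply_dnm_filters([rec], params) == []

    def test_parent_with_weak_homref_support_dropped(self):
        rec = trio_site(sire=member(gt=(0, 0), pl=(0, 5, 120)))
        params = DnmFilterParams(min_pl_homref_parents=20)
        assert apply_dnm_filters([rec], params) == []

    def test_false_positives_nonincreasing_in_depth_threshold(self):
        """Sweeping the depth threshold can only shrink the filtered set."""
        rng = np.random.default_rng(5)
        records = [
            trio_site(
                pos=50 * (i + 1),
                off=member(depth=int(rng.integers(2, 60))),
                sire=member(gt=(0, 0), depth=int(rng.integers(2, 60)), pl=(0, 120, 120)),
                dam=member(gt=(0, 0), depth=int(rng.integers(2, 60)), pl=(0, 120, 120)),
            )
            for i in range(50)
        ]
        sizes = [
            len(apply_dnm_filters(records, DnmFilterParams(min_depth_each_member=d)))
            for d in (0, 5, 10, 20, 40)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestReviewFlags:
    def test_clustered_candidates_flagged(self):
        a, b = trio_site(pos=100), trio_site(pos=103, ref="G", alt="A")
        flags = flag_for_review([a, b])
        assert flags[a.key] == ["clustered"]
        assert flags[b.key] == ["clustered"]

    def test_homopolymer_site_flagged_not_dropped(self):
        genome = ReferenceGenome(contigs={"chr1": "ACGT" * 20 + "AAAAAAA" + "ACGT" * 20})
        rec = trio_site(pos=84, ref="A", alt="T")  # inside the A7 run
        flags = flag_for_review([rec], genome=genome)
        assert flags[rec.key] == ["homopolymer"]

    def test_isolated_candidate_unflagged(self):
        rec = trio_site(pos=500)
        assert flag_for_review([rec]) == {rec.key: []}


class TestSpikeInRecovery:
    def test_noiseless_trio_perfect_sensitivity_no_fp(self, small_config):
        result = run_simulated_audit(small_config)
        for category in ("dnm_snp", "dnm_indel"):
            m = result["metrics"][category]
            assert m["sensitivity"] == 1.0
            assert m["n_false_positive"] == 0

    def test_discordant_callers_recover_both_caller_subset_exactly(self):
        config = SimulationConfig(
            seed=77, genome_length=200_000, n_inherited_snps=300,
            n_db_known_snps=60, n_denovo_snps=20, n_denovo_indels=10,
            caller_discordance_rate=0.2,
        )
        result = run_simulated_audit(config)
        assert result["metrics"]["dnm_snp"]["exact_recovery"]
        assert result["metrics"]["dnm_indel"]["exact_recovery"]


class TestSvFilters:
    def _sv(self, animal, contig="chr1", start=1000, end=6000, sv_type="DEL",
            support=30, depth=40):
        return StructuralVariant(
            contig=contig, start=start, end=end, sv_type=sv_type,
            supporting_reads=support, local_depth=depth, sample_id=animal,
        )

    @pytest.fixture
    def genome(self):
        return ReferenceGenome(contigs={"chr1": "A" * 50_000, "scaffold_7": "A" * 50_000})

    def test_founder_common_sv_removed_from_both(self, genome):
        shared_a = self._sv("a")
        shared_b = self._sv("b")
        kept = denovo_svs({"a": [shared_a], "b": [shared_b]}, genome)
        assert kept == {"a": [], "b": []}

    def test_low_support_fraction_removed(self, genome):
        sv = self._sv("a", support=10, depth=40)  # 0.25 < 0.5
        kept = denovo_svs({"a": [sv], "b": []}, genome)
        assert kept["a"] == []

    def test_scaffold_sv_removed(self, genome):
        sv = self._sv("a", contig="scaffold_7")
        kept = denovo_svs({"a": [sv], "b": []}, genome)
        assert kept["a"] == []

    def test_private_strong_sv_survives(self, genome):
        sv = self._sv("a")
        other = self._sv("b", start=20_000, end=30_000)
        kept = denovo_svs({"a": [sv], "b": [other]}, genome)
        assert kept["a"] == [sv] and kept["b"] == [other]

    def test_partial_overlap_below_reciprocal_threshold_kept(self, genome):
        sv_a = self._sv("a", start=1000, end=11_000)
        sv_b = self._sv("b", start=9000, end=19_000)  # 20% reciprocal
        kept = denovo_svs({"a": [sv_a], "b": [sv_b]}, genome)
        assert kept["a"] == [sv_a]

    def test_same_interval_different_type_kept(self, genome):
        sv_a = self._sv("a", sv_type="DEL")
        sv_b = self._sv("b", sv_type="INV")
        kept = denovo_svs({"a": [sv_a], "b": [sv_b]}, genome)
        assert kept["a"] == [sv_a]

    def test_idempotent_and_symmetric(self, genome):
        tables = {
            "a": [self._sv("a"), self._sv("a", start=20_000, end=25_000)],
            "b": [self._sv("b")],
        }
        once = denovo_svs(tables, genome)
        twice = denovo_svs(once, genome)
        assert once == twice

    def test_single_founder_warns(self, genome):
        with pytest.warns(UserWarning):
            denovo_svs({"a": [self._sv("a")]}, genome)


class TestKinship:
    def test_self_pairing_is_half(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(500, 2))
        phi = pairwise_kinship(g)
        assert phi.iloc[0, 0] == 0.5
        assert phi.iloc[1, 1] == 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(500, 3))
        phi = pairwise_kinship(g)
        assert np.allclose(phi.values, phi.values.T)

    def test_zero_denominator_is_nan(self):
        g = np.zeros((100, 2), dtype=int)  # nobody heterozygous
        phi = pairwise_kinship(g)
        assert np.isnan(phi.iloc[0, 1])

    def test_parent_offspring_and_founder_expectations(self):
        result = kinship_experiment(n_replicates=6, seed=3, n_sites=1200)
        assert abs(result["parent_offspring_mean"] - 0.25) <= 3 * result["parent_offspring_se"]
        assert abs(result["founder_mean"]) <= 3 * result["founder_se"]
        assert all(s == 0.5 for s in result["self_kinship"])

    def test_genotype_matrix_reflects_simulated_genotypes(self, small_config):
        import dataclasses

        from beaudit.simulate import simulate_genome, simulate_trio_calls

        config = dataclasses.replace(small_config, n_offtarget_edits=0)
        genome = simulate_genome(config)
        trio_a, _, _ = simulate_trio_calls(genome, config)
        matrix, ids = genotype_matrix([trio_a])
        assert ids == ["offspring", "sire", "dam"]
        assert matrix.shape[0] >= small_config.n_inherited_snps * 0.5
        assert set(np.unique(matrix)) <= {0, 1, 2}
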