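"""Simulator contracts: determinism, disjointness, round-trips, capacity."""

import dataclasses

import pytest

from beaudit.genome import ReferenceGenome
from beaudit.simulate import (
    DEFAULT_GUIDE,
    CapacityError,
    ConfigurationError,
    SimulationConfig,
    plant_offtarget_homologs,
    simulate_amplicon_reads,
    simulate_genome,
    simulate_trio_calls,
    write_simulation,
)
from beaudit.variants import read_sites_vcf, read_trio_vcf


class TestConfigValidation:
    def test_zero_contigs_rejected(self):
        with pytest.raises(ConfigurationError, match="n_contigs"):
            SimulationConfig(n_contigs=0)

    def test_tiny_genome_rejected(self):
        with pytest.raises(ConfigurationError, match="genome_length"):
            SimulationConfig(genome_length=10)

    def test_out_of_range_proportion_names_field(self):
        with pytest.raises(ConfigurationError, match="caller_discordance_rate"):
            SimulationConfig(caller_discordance_rate=1.5)

    def test_amplicon_fractions_must_fit(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(amplicon_edit_fraction=0.5, amplicon_indel_fraction=0.6)


class TestGenome:
    def test_contig_split_and_scaffold_flagging(self):
        config = SimulationConfig(seed=1, genome_length=10_000, n_contigs=2,
                                  scaffold_fraction=0.5)
        genome = simulate_genome(config)
        assert genome.total_length == 10_000
        assert sum(genome.is_scaffold(c) for c in genome.contigs) == 1

    def test_determinism(self):
        config = SimulationConfig(seed=1, genome_length=10_000, n_contigs=2)
        assert simulate_genome(config).contigs == simulate_genome(config).contigs

    def test_roughly_uniform_composition(self):
        genome = simulate_genome(SimulationConfig(seed=2, genome_length=100_000,
                                                  n_contigs=1))
        seq = genome["chr1"]
        for base in "ACGT":
            assert 0.22 <= seq.count(base) / len(seq) <= 0.28


class TestPlanting:
    def test_exact_target_planted_once(self):
        genome = simulate_genome(SimulationConfig(seed=3, genome_length=10_000,
                                                  n_contigs=1))
        genome, planted = plant_offtarget_homologs(genome, DEFAULT_GUIDE, 1, [0], seed=3)
        ((contig, start, end, strand, mm),) = planted
        assert mm == 0 and end - start == DEFAULT_GUIDE.site_length
        window = genome[contig][start:end]
        from beaudit.guides import revcomp

        oriented = window if strand == "+" else revcomp(window)
        assert oriented[: DEFAULT_GUIDE.length] == DEFAULT_GUIDE.protospacer

    def test_excessive_mismatch_request_rejected(self):
        genome = simulate_genome(SimulationConfig(seed=3, genome_length=10_000,
                                                  n_contigs=1))
        with pytest.raises(ValueError):
            plant_offtarget_homologs(genome, DEFAULT_GUIDE, 1, [21], seed=3)

    def test_capacity_error_when_genome_too_small(self):
        genome = ReferenceGenome(contigs={"chr1": "A" * 10})
        with pytest.raises(CapacityError):
            plant_offtarget_homologs(genome, DEFAULT_GUIDE, 1, [0], seed=0)


class TestTrioCalls:
    def test_ground_truth_categories_disjoint_by_position(self, small_config, guide):
        genome = simulate_genome(small_config)
        from beaudit.offtargets import find_offtarget_sites, sites_to_intervals

        genome, _ = plant_offtarget_homologs(genome, guide, 5, [1, 2, 2, 3, 3],
                                             seed=small_config.seed)
        sites = find_offtarget_sites(genome, guide, 5)
        intervals = sites_to_intervals(sites, genome=genome)
        _, _, truth = simulate_trio_calls(genome, small_config,
                                          planted_intervals=intervals)
        positions = [(k[0], k[1]) for k in truth.all_site_keys()]
        assert len(positions) == len(set(positions))

    def test_offtarget_edits_lie_inside_intervals(self, small_config, guide):
        genome = simulate_genome(small_config)
        from beaudit.offtargets import find_offtarget_sites, sites_to_intervals

        genome, _ = plant_offtarget_homologs(genome, guide, 5, [1, 2, 2, 3, 3],
                                             seed=small_config.seed)
        sites = find_offtarget_sites(genome, guide, 5)
        intervals = sites_to_intervals(sites, genome=genome)
        _, _, truth = simulate_trio_calls(genome, small_config,
                                          planted_intervals=intervals)
        assert len(truth.offtarget_edit_sites) == small_config.n_offtarget_edits
        for entry in truth.offtarget_edit_sites:
            assert any(
                c == entry["contig"] and lo < entry["pos"] <= hi
                for c, lo, hi in intervals
            )

    def test_mendelian_consistency_of_inherited_sites(self, small_config):
        config = dataclasses.replace(small_config, n_offtarget_edits=0)
        genome = simulate_genome(config)
        trio_a, _, truth = simulate_trio_calls(genome, config)
        segregating = truth.keys("inherited_sites") | truth.keys("db_known_sites")
        checked = 0
        for rec in trio_a:
            if rec.key not in segregating:
                continue
            child, sire, dam = rec.offspring.genotype, rec.sire.genotype, rec.dam.genotype
            assert child is not None
            # each child allele must be drawable from one parent
            a, b = child
            assert (a in sire and b in dam) or (a in dam and b in sire)
            checked += 1
        assert checked > 100

    def test_determinism_of_call_sets(self, small_config):
        config = dataclasses.replace(small_config, n_offtarget_edits=0)
        genome = simulate_genome(config)
        first = simulate_trio_calls(genome, config)
        second = simulate_trio_calls(genome, config)
        assert first[0] == second[0]
        assert first[1] == second[1]

    def test_amplicon_full_edit_zero_error_exact(self, guide):
        from beaudit.simulate import make_amplicon_reference

        ref = make_amplicon_reference(guide, seed=5)
        config = SimulationConfig(seed=5, amplicon_edit_fraction=1.0,
                                  amplicon_indel_fraction=0.0,
                                  amplicon_n_reads=200)
        reads, truth = simulate_amplicon_reads(guide, ref, config)
        assert truth["edit_fraction"] == 1.0
        assert len(set(reads)) == 1


class TestRoundTrips:
    def test_written_fixtures_reread_identically(self, tmp_path, small_config):
        paths = write_simulation(tmp_path, small_config)

        genome = ReferenceGenome.from_fasta(paths["genome"])
        assert (tmp_path / "genome.fa.fai").exists()

        trio_a = read_trio_vcf(paths["trio_callerA"], caller="callerA")
        trio_b = read_trio_vcf(paths["trio_callerB"], caller="callerB")
        assert trio_a and trio_b

        from beaudit.simulate import simulate_genome as regen

        genome2 = simulate_genome(small_config)
        genome2, _ = plant_offtarget_homologs(
            genome2, DEFAULT_GUIDE, 5, [1, 2, 2, 3, 3], seed=small_config.seed
        )
        assert genome.contigs == genome2.contigs

        trio_a_mem, _, truth = simulate_trio_calls(genome2, small_config,
                                                   planted_intervals=None,
                                                   guide=DEFAULT_GUIDE)
        assert sorted(r.key for r in trio_a) == sorted(r.key for r in trio_a_mem)
        by_key = {r.key: r for r in trio_a}
        for rec in trio_a_mem:
            got = by_key[rec.key]
            for role in ("offspring", "sire", "dam"):
                assert rec.member(role).genotype == got.member(role).genotype
                assert rec.member(role).depth == got.member(role).depth
                assert rec.member(role).pl == got.member(role).pl

        db = read_sites_vcf(paths["db_public"]) | read_sites_vcf(paths["db_cohort"])
        assert db == truth.keys("db_known_sites")
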