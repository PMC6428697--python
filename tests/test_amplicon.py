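"""Amplicon profiling: alignment, frequency recovery, mosaic calls, panel."""

import math

import numpy as np
import pytest

from beaudit.amplicon import (
    AmpliconError,
    call_genotype_summary,
    offtarget_panel_frequencies,
    profile_amplicon,
    window_in_amplicon,
)
from beaudit.guides import revcomp
from beaudit.simulate import (
    DEFAULT_GUIDE,
    SimulationConfig,
    make_amplicon_reference,
    simulate_amplicon_reads,
)

REF = make_amplicon_reference(DEFAULT_GUIDE, seed=9)


def amp_config(**kw):
    base = dict(
        seed=13, amplicon_n_reads=4000, amplicon_edit_fraction=0.0,
        amplicon_indel_fraction=0.0, sequencing_error_rate=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def binomial_se(p, n):
    return math.sqrt(p * (1 - p) / n)


class TestProfile:
    def test_reference_reads_give_one_hot_counts(self):
        reads = [REF] * 100
        profile = profile_amplicon(reads, REF, DEFAULT_GUIDE)
        assert profile.n_aligned == 100
        assert profile.n_discarded == 0
        cov = profile.coverage()
        assert (cov == 100).all()
        for pos, base in enumerate(REF):
            assert profile.substitution_frequency(pos, base) == 1.0
        assert profile.target_conversion_frequency() == 0.0

    def test_empty_pool_rejected(self):
        with pytest.raises(AmpliconError):
            profile_amplicon([], REF, DEFAULT_GUIDE)

    def test_count_conservation(self):
        config = amp_config(amplicon_edit_fraction=0.3, amplicon_indel_fraction=0.2,
                            sequencing_error_rate=0.01)
        reads, _ = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        profile = profile_amplicon(reads, REF, DEFAULT_GUIDE)
        assert profile.n_aligned + profile.n_discarded == profile.n_reads_total
        assert sum(profile.class_counts.values()) == profile.n_aligned

    def test_profile_invariant_to_read_order(self):
        config = amp_config(amplicon_edit_fraction=0.4, amplicon_indel_fraction=0.1)
        reads, _ = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        p1 = profile_amplicon(reads, REF, DEFAULT_GUIDE)
        p2 = profile_amplicon(reads[::-1], REF, DEFAULT_GUIDE)
        assert (p1.base_counts == p2.base_counts).all()
        assert (p1.deletion_counts == p2.deletion_counts).all()
        assert p1.class_counts == p2.class_counts

    def test_minus_oriented_amplicon_reports_ga_conversion(self):
        ref_rc = revcomp(REF)
        window, targets, strand = window_in_amplicon(ref_rc, DEFAULT_GUIDE)
        assert strand == "-"
        assert all(ref_rc[p] == "G" for p in targets)


class TestFrequencyRecovery:
    def test_full_edit_no_error_is_exact(self):
        config = amp_config(amplicon_edit_fraction=1.0)
        reads, _ = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        profile = profile_amplicon(reads, REF, DEFAULT_GUIDE)
        assert profile.target_conversion_frequency() == 1.0

    def test_partial_edit_within_three_binomial_se(self):
        config = amp_config(amplicon_edit_fraction=0.3, amplicon_n_reads=10_000)
        reads, truth = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        profile = profile_amplicon(reads, REF, DEFAULT_GUIDE)
        est = profile.target_conversion_frequency()
        assert abs(est - 0.3) <= 3 * binomial_se(0.3, 10_000)
        assert truth["edit_fraction"] == pytest.approx(0.3, abs=1e-4)

    def test_deletion_frequency_within_three_se(self):
        config = amp_config(amplicon_indel_fraction=0.4, amplicon_n_reads=5000)
        reads, truth = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        profile = profile_amplicon(reads, REF, DEFAULT_GUIDE)
        lo, hi = truth["deletion_interval"]
        for pos in range(lo, hi):
            est = profile.deletion_frequency(pos)
            assert abs(est - 0.4) <= 3 * binomial_se(0.4, 5000)

    def test_estimator_unbiased_over_replicates(self):
        """Mean of replicate frequency estimates sits within 1 SE of truth."""
        true_p = 0.2
        n_reads, n_rep = 600, 60
        estimates = []
        for seed in range(n_rep):
            config = amp_config(seed=seed, amplicon_edit_fraction=true_p,
                                amplicon_n_reads=n_reads,
                                sequencing_error_rate=0.001)
            reads, _ = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
            profile = profile_amplicon(reads, REF, DEFAULT_GUIDE)
            estimates.append(profile.class_counts["precise_edit"] / profile.n_aligned)
        mean = float(np.mean(estimates))
        se = float(np.std(estimates, ddof=1) / math.sqrt(n_rep))
        # rounding of read counts makes the per-replicate truth 0.2 exactly
        assert abs(mean - true_p) <= max(1.5 * se, 0.005)

    def test_conflicting_fractions_rejected(self):
        with pytest.raises(ValueError):
            amp_config(amplicon_edit_fraction=0.5, amplicon_indel_fraction=0.6)


class TestGenotypeSummary:
    def test_heterozygous_mixture_not_mosaic(self):
        config = amp_config(amplicon_edit_fraction=0.5)
        reads, _ = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        summary = call_genotype_summary(profile_amplicon(reads, REF, DEFAULT_GUIDE))
        assert not summary.mosaic_flag
        assert summary.fraction_precise_edit == pytest.approx(0.5, abs=1e-9)

    def test_edit_plus_deletion_mixture_is_mosaic(self):
        config = amp_config(amplicon_edit_fraction=0.3, amplicon_indel_fraction=0.25)
        reads, _ = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        summary = call_genotype_summary(profile_amplicon(reads, REF, DEFAULT_GUIDE))
        assert summary.mosaic_flag
        assert summary.fraction_indel == pytest.approx(0.25, abs=1e-9)

    def test_fractions_sum_to_one(self):
        config = amp_config(amplicon_edit_fraction=0.3, amplicon_indel_fraction=0.25,
                            sequencing_error_rate=0.002)
        reads, _ = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        summary = call_genotype_summary(profile_amplicon(reads, REF, DEFAULT_GUIDE))
        assert sum(summary.fractions().values()) == pytest.approx(1.0)

    def test_low_coverage_warns_but_produces_summary(self):
        config = amp_config(amplicon_n_reads=50)
        reads, _ = simulate_amplicon_reads(DEFAULT_GUIDE, REF, config)
        profile = profile_amplicon(reads, REF, DEFAULT_GUIDE)
        with pytest.warns(UserWarning):
            summary = call_genotype_summary(profile, min_reads=1000)
        assert summary.low_coverage


class TestPanel:
    def _panel(self, spiked_site=None, error_rate=0.0, n_reads=2000):
        pools, refs = {}, {}
        for i in range(5):
            name = f"OT{i + 1}"
            ref = make_amplicon_reference(DEFAULT_GUIDE, seed=100 + i)
            refs[name] = ref
            frac = 0.05 if name == spiked_site else 0.0
            config = amp_config(seed=200 + i, amplicon_edit_fraction=frac,
                                amplicon_n_reads=n_reads,
                                sequencing_error_rate=error_rate)
            pools[name], _ = simulate_amplicon_reads(DEFAULT_GUIDE, ref, config)
        return pools, refs

    def test_clean_reference_pools_unflagged(self):
        pools, refs = self._panel()
        table = offtarget_panel_frequencies(pools, refs, DEFAULT_GUIDE)
        assert (table["frequency"] == 0).all()
        assert not table["edited"].any()

    def test_error_only_pools_stay_below_threshold(self):
        pools, refs = self._panel(error_rate=0.002)
        table = offtarget_panel_frequencies(pools, refs, DEFAULT_GUIDE)
        se = binomial_se(0.002, 2000 * 2)  # two editable window cytosines
        assert (table["frequency"] <= 0.002 + 3 * se).all()
        assert not table["edited"].any()

    def test_single_spiked_site_flagged_alone(self):
        pools, refs = self._panel(spiked_site="OT3", error_rate=0.002)
        table = offtarget_panel_frequencies(pools, refs, DEFAULT_GUIDE).set_index("site")
        assert table.loc["OT3", "edited"]
        assert not table.drop("OT3")["edited"].any()

    def test_confidence_interval_brackets_frequency(self):
        pools, refs = self._panel(spiked_site="OT1")
        table = offtarget_panel_frequencies(pools, refs, DEFAULT_GUIDE).set_index("site")
        row = table.loc["OT1"]
        assert row["ci_low"] <= row["frequency"] <= row["ci_high"]
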