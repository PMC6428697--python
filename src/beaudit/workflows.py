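"""End-to-end experiment compositions over the library modules.

These functions wire simulator output through the audit pipeline and
are shared by the command-line interface, the validation suite and the
reproduction script.  Each is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from .filters import run_offtarget_cascade
from .genome import ReferenceGenome
from .guides import GuideSpec
from .offtargets import find_offtarget_sites, sites_to_intervals
from .rates import estimate_mutation_rate
from .simulate import (
    DEFAULT_GUIDE,
    GroundTruth,
    SimulationConfig,
    plant_offtarget_homologs,
    simulate_genome,
    simulate_trio_calls,
)
from .trio import DnmFilterParams, run_denovo_pipeline, split_snps_indels
from .variants import TrioGenotypes, VariantCall


def simulate_audit_inputs(
    config: SimulationConfig,
    guide: GuideSpec = DEFAULT_GUIDE,
    planted_mismatches: list[int] | None = None,
) -> tuple[
    ReferenceGenome,
    list[TrioGenotypes],
    list[TrioGenotypes],
    GroundTruth,
    list[tuple[str, int, int]],
]:
    """Genome with planted homologs, trio call sets, truth and intervals."""
    mismatches = planted_mismatches if planted_mismatches is not None else [1, 2, 2, 3, 3]
    genome = simulate_genome(config)
    if mismatches:
        genome, _ = plant_offtarget_homologs(
            genome, guide, len(mismatches), mismatches, seed=config.seed
        )
    sites = find_offtarget_sites(genome, guide, config.offtarget_max_mismatches)
    intervals = sites_to_intervals(sites, genome=genome)
    trio_a, trio_b, truth = simulate_trio_calls(
        genome, config, planted_intervals=intervals
    )
    return genome, trio_a, trio_b, truth, intervals


def run_simulated_audit(
    config: SimulationConfig,
    guide: GuideSpec = DEFAULT_GUIDE,
    planted_mismatches: list[int] | None = None,
    dnm_params: DnmFilterParams | None = None,
) -> dict:
    """Full off-target cascade + de novo pipeline on a simulated trio.

    Returns the surviving sets, funnels, truth and recovery metrics
    (sensitivity and false positives per spiked category).
    """
    genome, trio_a, trio_b, truth, intervals = simulate_audit_inputs(
        config, guide, planted_mismatches
    )
    databases = _split_databases(truth)

    offtarget_calls, ot_funnel = run_offtarget_cascade(
        trio_a, trio_b, databases, intervals
    )
    dnm_calls, flags, dnm_funnel = run_denovo_pipeline(
        trio_a, trio_b, databases, params=dnm_params, genome=genome
    )
    dnm_snps, dnm_indels = split_snps_indels(dnm_calls)

    # spiked off-target edits are offspring-only SNPs, hence legitimate
    # members of the de novo SNP truth set as well
    metrics = {
        "offtarget": _recovery(offtarget_calls, truth, ["offtarget_edit_sites"]),
        "dnm_snp": _recovery(
            dnm_snps, truth, ["denovo_snp_sites", "offtarget_edit_sites"]
        ),
        "dnm_indel": _recovery(dnm_indels, truth, ["denovo_indel_sites"]),
    }
    return {
        "genome": genome,
        "intervals": intervals,
        "truth": truth,
        "offtarget_calls": offtarget_calls,
        "offtarget_funnel": ot_funnel,
        "dnm_snps": dnm_snps,
        "dnm_indels": dnm_indels,
        "dnm_flags": flags,
        "dnm_funnel": dnm_funnel,
        "metrics": metrics,
    }


def _split_databases(truth: GroundTruth) -> list[set]:
    keys = sorted(truth.keys("db_known_sites"))
    half = len(keys) // 2
    return [set(keys[:half]), set(keys[half:])]


def _recovery(
    calls: list[VariantCall] | list[TrioGenotypes],
    truth: GroundTruth,
    categories: list[str],
) -> dict:
    """Sensitivity and false positives against the recoverable truth.

    A spiked site is recoverable only if it survived caller thinning
    in both emulated callers (the caller-intersection stage is, by
    design, blind to single-caller records).
    """
    recovered = {c.key for c in calls}
    recoverable: set = set()
    spiked: set = set()
    for category in categories:
        recoverable |= truth.both_caller_keys(category)
        spiked |= truth.keys(category)
    tp = recovered & recoverable
    fp = recovered - spiked
    return {
        "n_spiked": len(spiked),
        "n_recoverable": len(recoverable),
        "n_recovered": len(recovered),
        "n_true_positive": len(tp),
        "n_false_positive": len(fp),
        "sensitivity": len(tp) / len(recoverable) if recoverable else 1.0,
        "exact_recovery": recovered == recoverable,
    }


def rate_recovery_experiment(
    true_rate: float,
    genome_length: int,
    n_replicates: int,
    seed: int,
    mean_depth: float = 37.0,
) -> dict:
    """Spike de novo SNPs at a known per-bp per-generation rate and re-estimate.

    Each replicate draws the de novo count from Poisson(2 * G * rate),
    spikes that many SNPs into a fresh trio, runs the de novo pipeline
    and estimates the rate with the callable genome as denominator.
    """
    rng = np.random.default_rng([seed, 7])
    estimates = []
    counts = []
    for i in range(n_replicates):
        n_true = int(rng.poisson(2 * genome_length * true_rate))
        config = SimulationConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            genome_length=genome_length,
            n_contigs=2,
            scaffold_fraction=0.0,
            n_inherited_snps=30,
            n_db_known_snps=10,
            n_denovo_snps=n_true,
            n_denovo_indels=0,
            mean_depth=mean_depth,
        )
        genome = simulate_genome(config)
        trio_a, trio_b, truth = simulate_trio_calls(genome, config)
        databases = _split_databases(truth)
        dnm_calls, _flags, _funnel = run_denovo_pipeline(trio_a, trio_b, databases)
        snps, _ = split_snps_indels(dnm_calls)
        est = estimate_mutation_rate(len(snps), genome.total_length)
        estimates.append(est.rate)
        counts.append(len(snps))
    estimates_arr = np.array(estimates)
    return {
        "true_rate": true_rate,
        "n_replicates": n_replicates,
        "mean_rate": float(estimates_arr.mean()),
        "se_rate": float(estimates_arr.std(ddof=1) / np.sqrt(n_replicates)),
        "counts": counts,
        "rates": estimates,
    }


def kinship_experiment(
    n_replicates: int,
    seed: int,
    n_sites: int = 1500,
    genome_length: int = 100_000,
) -> dict:
    """Replicate trios; mean/SE of parent-offspring and founder kinship."""
    from .trio import genotype_matrix, pairwise_kinship

    rng = np.random.default_rng([seed, 8])
    po, founders, selfs = [], [], []
    for _ in range(n_replicates):
        config = SimulationConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            genome_length=genome_length,
            n_contigs=1,
            scaffold_fraction=0.0,
            n_inherited_snps=n_sites,
            n_db_known_snps=0,
            n_denovo_snps=0,
            n_denovo_indels=0,
        )
        genome = simulate_genome(config)
        trio_a, _trio_b, _truth = simulate_trio_calls(genome, config)
        matrix, ids = genotype_matrix([trio_a])
        phi = pairwise_kinship(matrix, ids)
        po.append(phi.loc["offspring", "sire"])
        po.append(phi.loc["offspring", "dam"])
        founders.append(phi.loc["sire", "dam"])
        selfs.append(phi.loc["sire", "sire"])
    po_arr, f_arr = np.array(po), np.array(founders)
    return {
        "parent_offspring_mean": float(po_arr.mean()),
        "parent_offspring_se": float(po_arr.std(ddof=1) / np.sqrt(len(po_arr))),
        "founder_mean": float(f_arr.mean()),
        "founder_se": float(f_arr.std(ddof=1) / np.sqrt(len(f_arr))),
        "self_kinship": [float(s) for s in selfs],
    }
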