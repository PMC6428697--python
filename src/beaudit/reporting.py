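"""Audit report assembly: funnels, mutation lists, rates, amplicon summaries."""

from __future__ import annotations

import json
from pathlib import Path

from .amplicon import GenotypeCallSummary
from .filters import FilterFunnel
from .rates import MutationRateEstimate
from .trio import StructuralVariant
from .variants import TrioGenotypes, VariantCall


def _call_row(c: VariantCall | TrioGenotypes) -> dict:
    return {"contig": c.contig, "pos": c.pos, "ref": c.ref, "alt": c.alt}


def _sv_row(sv: StructuralVariant) -> dict:
    return {
        "contig": sv.contig,
        "start": sv.start,
        "end": sv.end,
        "type": sv.sv_type,
        "supporting_reads": sv.supporting_reads,
        "depth": sv.local_depth,
    }


def build_audit_report(
    offtarget_funnel: FilterFunnel | None = None,
    offtarget_mutations: list[VariantCall] | None = None,
    dnm_funnel: FilterFunnel | None = None,
    dnm_snps: list[TrioGenotypes] | None = None,
    dnm_indels: list[TrioGenotypes] | None = None,
    denovo_sv_sets: dict[str, list[StructuralVariant]] | None = None,
    rate_estimates: dict[str, MutationRateEstimate] | None = None,
    amplicon_summaries: dict[str, GenotypeCallSummary] | None = None,
    external_cohort_rates: dict[str, float] | None = None,
) -> dict:
    """Assemble a machine-readable audit report.

    At least one analysis product must be supplied.  Counts in the
    report are the lengths of the underlying sets — nothing is
    recomputed.  ``external_cohort_rates`` is a user-supplied mapping
    of cohort name to per-bp per-generation rate for side-by-side
    comparison.
    """
    products = (
        offtarget_funnel,
        offtarget_mutations,
        dnm_funnel,
        dnm_snps,
        dnm_indels,
        denovo_sv_sets,
        rate_estimates,
        amplicon_summaries,
    )
    if all(p is None for p in products):
        raise ValueError("at least one analysis product is required")

    report: dict = {}
    if offtarget_funnel is not None or offtarget_mutations is not None:
        muts = offtarget_mutations or []
        report["offtarget_audit"] = {
            "n_offtarget_mutations": len(muts),
            "no_offtarget_mutations": len(muts) == 0,
            "mutations": [_call_row(c) for c in muts],
            "funnel": offtarget_funnel.to_rows() if offtarget_funnel else [],
        }
    if dnm_funnel is not None or dnm_snps is not None or dnm_indels is not None:
        snps = dnm_snps or []
        indels = dnm_indels or []
        report["denovo_mutations"] = {
            "n_denovo_snps": len(snps),
            "n_denovo_indels": len(indels),
            "snps": [_call_row(c) for c in snps],
            "indels": [_call_row(c) for c in indels],
            "funnel": dnm_funnel.to_rows() if dnm_funnel else [],
        }
    if denovo_sv_sets is not None:
        report["denovo_svs"] = {
            animal: {"n": len(svs), "svs": [_sv_row(s) for s in svs]}
            for animal, svs in denovo_sv_sets.items()
        }
    if rate_estimates is not None:
        table = {
            name: {
                "n_dnm": est.n_dnm,
                "callable_bp": est.callable_bp,
                "rate": est.rate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
            for name, est in rate_estimates.items()
        }
        report["mutation_rates"] = {
            "estimates": table,
            "external_cohorts": external_cohort_rates or {},
        }
    if amplicon_summaries is not None:
        report["amplicon_genotypes"] = {
            name: {
                **summary.fractions(),
                "mosaic": summary.mosaic_flag,
                "n_reads": summary.n_reads,
            }
            for name, summary in amplicon_summaries.items()
        }
    return report


def write_report(report: dict, outdir: str | Path) -> dict[str, Path]:
    """Write the report as JSON plus TSV/Markdown companions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    json_path = outdir / "audit_report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    paths["json"] = json_path

    for section, name in (
        ("offtarget_audit", "offtarget_funnel.tsv"),
        ("denovo_mutations", "denovo_funnel.tsv"),
    ):
        rows = report.get(section, {}).get("funnel")
        if rows:
            tsv = outdir / name
            with open(tsv, "w") as fh:
                fh.write("stage\tn_in\tn_out\tn_dropped\n")
                for r in rows:
                    fh.write(
                        f"{r['stage']}\t{r['n_in']}\t{r['n_out']}\t{r['n_dropped']}\n"
                    )
            paths[name] = tsv

    md = outdir / "audit_report.md"
    with open(md, "w") as fh:
        fh.write("# Base-editing audit report\n\n")
        if "offtarget_audit" in report:
            n = report["offtarget_audit"]["n_offtarget_mutations"]
            fh.write(f"Off-target mutations after the full cascade: **{n}**\n\n")
        if "denovo_mutations" in report:
            d = report["denovo_mutations"]
            fh.write(
                f"De novo mutations: {d['n_denovo_snps']} SNPs, "
                f"{d['n_denovo_indels']} indels\n\n"
            )
        if "mutation_rates" in report:
            fh.write("Per-generation mutation rates:\n\n")
            for name, est in report["mutation_rates"]["estimates"].items():
                fh.write(
                    f"- {name}: {est['rate']:.3g} per bp per generation "
                    f"(95% CI {est['ci_low']:.3g}-{est['ci_high']:.3g}, "
                    f"n={est['n_dnm']})\n"
                )
            fh.write("\n")
    paths["markdown"] = md
    return paths
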