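"""End-to-end orchestration: simulate -> filter -> estimate -> profile ->
annotate -> copy number, with a machine-readable JSON report.

The report aggregates every per-module output (filter audit trail, per-
subclone rate estimates, cohort summaries, spectra, strand bias, feature
fractions, chromosome densities, ploidy calls) and echoes the
configuration, so any number in it is traceable to a module call.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import annotate as ann
from . import cnv as cnv_mod
from . import rates as rates_mod
from . import spectra as spectra_mod
from .coverage import CoverageTrack, read_coverage, write_coverage
from .filtering import (
    CallSet,
    effective_genome_length,
    read_calls,
    run_cascade,
    write_calls,
)
from .genome import (
    ExpressionTable,
    GeneModel,
    GenomeModel,
    PolymorphismBlacklist,
    build_blacklist,
    build_gene_models,
    build_toy_genome,
    read_fixture,
    write_fixture,
)
from .simulate import (
    GS_SPECTRUM,
    MGS_SPECTRUM,
    ClonalDesign,
    SimulationParams,
    simulate_bulk_timepoints,
    simulate_clonal_experiment,
)

SCHEMA_VERSION = 1
OUTLIER_FACTOR = 3.0  # subclones above 3x the cohort median call count are flagged


@dataclass
class SubcloneData:
    """Inputs for one parent/subclone comparison."""

    subclone: str
    calls: CallSet
    parent_coverage: CoverageTrack
    subclone_coverage: CoverageTrack


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def analyze_clonal_cohort(
    subclones: list[SubcloneData],
    genome: GenomeModel,
    genes: list[GeneModel],
    expression: ExpressionTable,
    blacklist: PolymorphismBlacklist,
    design: ClonalDesign,
    snv_quality_threshold: float = 19.0,
    indel_quality_threshold: float = 14.0,
    exclude_subclones: set[str] = frozenset(),
) -> dict:
    """The full clonal analysis on a cohort of parent/subclone comparisons."""
    report: dict = {"schema_version": SCHEMA_VERSION, "mode": "clonal"}
    report["design"] = {
        "doublings": design.doublings,
        "tau": design.tau,
        "min_depth": design.min_depth,
        "snv_quality_threshold": snv_quality_threshold,
        "indel_quality_threshold": indel_quality_threshold,
    }

    trimmed: dict[str, CallSet] = {}
    l_effs: dict[str, float] = {}
    filter_reports: dict[str, list] = {}
    ratio_tracks: dict[str, cnv_mod.RatioTrack] = {}
    for sd in subclones:
        calls, frep = run_cascade(
            sd.calls,
            genome,
            blacklist,
            design.tau,
            design.min_depth,
            snv_quality_threshold,
            indel_quality_threshold,
        )
        trimmed[sd.subclone] = calls
        filter_reports[sd.subclone] = frep.to_dict()
        l_effs[sd.subclone] = effective_genome_length(
            sd.parent_coverage,
            sd.subclone_coverage,
            design.min_depth,
            genome.autosome_names,
        )
        ratio_tracks[sd.subclone] = cnv_mod.coverage_ratio(
            sd.subclone_coverage,
            sd.parent_coverage,
            min_control_depth=design.min_depth,
            autosomes=genome.autosome_names,
        )
    report["filters"] = filter_reports

    # outlier flagging: transparent, never auto-excluded
    snv_counts = {s: len(cs.of_class("SNV")) for s, cs in trimmed.items()}
    median_count = float(np.median(list(snv_counts.values()))) if snv_counts else 0.0
    flagged = [
        s
        for s, n in snv_counts.items()
        if median_count > 0 and n > OUTLIER_FACTOR * median_count
    ]
    report["outliers"] = {
        "flagged": flagged,
        "excluded": sorted(exclude_subclones),
        "snv_counts": snv_counts,
    }
    kept = [sd.subclone for sd in subclones if sd.subclone not in exclude_subclones]

    estimates: dict[str, dict] = {}
    for var_class in ("SNV", "INDEL"):
        per = rates_mod.estimate_cohort_rates(
            [trimmed[s] for s in kept],
            [l_effs[s] for s in kept],
            design.doublings,
            design.tau,
            var_class,
        )
        by_sub = dict(zip(kept, per))
        rates = [r["rate"] for r in per]
        estimates[var_class] = {
            "per_subclone": by_sub,
            "cohort": rates_mod.summarize_rates(rates) if rates else None,
        }
    report["rates"] = estimates

    pooled_snv = CallSet(
        [c for s in kept for c in trimmed[s].of_class("SNV")], ["pooled"]
    )
    pooled_indel = CallSet(
        [c for s in kept for c in trimmed[s] if c.var_class in ("INS", "DEL")],
        ["pooled"],
    )
    spec = spectra_mod.spectrum6(pooled_snv, genome)
    sig = spectra_mod.context96(pooled_snv, genome)
    istats = spectra_mod.indel_stats(pooled_indel)
    report["spectrum6"] = {
        "counts": spec.counts,
        "proportions": spec.proportions,
        "cpg_split": spec.cpg_split,
        "n_excluded": spec.n_excluded,
    }
    report["context96"] = {
        "counts": dict(zip(spectra_mod.CONTEXT96_LABELS, sig.counts.tolist())),
        "n_excluded": sig.n_excluded,
    }
    report["indels"] = {
        "length_histogram": istats.length_histogram,
        "n_insertions": istats.n_insertions,
        "n_deletions": istats.n_deletions,
        "ins_del_ratio": istats.ins_del_ratio,
    }

    densities = [
        spectra_mod.per_chromosome_density(trimmed[s].of_class("SNV"), genome)
        for s in kept
    ]
    report["chromosome_density"] = {
        "per_subclone": {s: d.to_dict() for s, d in zip(kept, densities)},
        "enrichment": (
            spectra_mod.test_chromosome_enrichment(densities)
            if len(densities) >= 2
            else None
        ),
    }

    annotated = ann.annotate_calls(pooled_snv, genes, genome)
    genic = [fc for fc in annotated if fc.gene_id is not None]
    hit_ids = sorted({fc.gene_id for fc in genic})
    by_id = {g.gene_id: g for g in genes}
    genes_hit = [by_id[g] for g in hit_ids]
    counts, ambiguous = ann.strand_bias_counts(annotated)
    bias = ann.strand_bias_test(counts, ambiguous)
    report["annotation"] = {
        "feature_fractions": (
            ann.feature_fractions(annotated) if annotated else None
        ),
        "n_genes_hit": len(genes_hit),
        "gene_length": None,
        "expression": None,
        "strand_bias": {
            "counts": bias.counts,
            "p_values": bias.p_values,
            "n_ambiguous": bias.n_ambiguous,
        },
    }
    if len(genes_hit) >= 3 and len(genes) >= 3:
        p, eff = ann.compare_gene_length(genes_hit, genes)
        report["annotation"]["gene_length"] = {"p_value": p, "effect_size": eff}
        expressed_hit = [g for g in genes_hit if expression.get(g.gene_id, 0) > 0]
        expressed_all = [g for g in genes if expression.get(g.gene_id, 0) > 0]
        if len(expressed_hit) >= 3 and len(expressed_all) >= 3:
            p, eff = ann.compare_expression(genes_hit, genes, expression)
            report["annotation"]["expression"] = {"p_value": p, "effect_size": eff}

    cnv_report = {}
    for s in (sd.subclone for sd in subclones):
        ploidy = cnv_mod.call_chromosome_ploidy(
            ratio_tracks[s], chromosomes=genome.autosome_names
        )
        segments = cnv_mod.detect_segments(ratio_tracks[s])
        cnv_report[s] = {
            "ploidy": [asdict(p) for p in ploidy],
            "segments": [asdict(seg) for seg in segments],
        }
    report["copy_number"] = cnv_report
    report["l_eff"] = l_effs
    return _jsonable(report)


def analyze_bulk(
    timepoint_calls: dict[int, CallSet],
    timepoint_coverage: dict[int, CoverageTrack],
    genome: GenomeModel,
    blacklist: PolymorphismBlacklist,
    tau: float = 0.4,
    min_depth: int = 10,
    snv_quality_threshold: float = 19.0,
    indel_quality_threshold: float = 14.0,
    het_hom_boundary: float = 0.75,
) -> dict:
    """Bulk-culture accumulation analysis: per-timepoint filtered sets,
    het/hom classification, pairwise overlaps, spectra, and segmental CNV
    against the earliest timepoint's coverage."""
    report: dict = {"schema_version": SCHEMA_VERSION, "mode": "bulk"}
    months = sorted(timepoint_calls)
    filtered: dict[int, CallSet] = {}
    for m in months:
        out, frep = run_cascade(
            timepoint_calls[m],
            genome,
            blacklist,
            tau,
            min_depth,
            snv_quality_threshold,
            indel_quality_threshold,
        )
        filtered[m] = out
        report.setdefault("filters", {})[m] = frep.to_dict()

    per_tp = {}
    for m in months:
        z = rates_mod.classify_bulk_zygosity(filtered[m], het_hom_boundary)
        snvs = filtered[m].of_class("SNV")
        spec = spectra_mod.spectrum6(snvs, genome)
        istats = spectra_mod.indel_stats(filtered[m])
        per_tp[m] = {
            "n_snv": len(snvs),
            "n_indel": istats.n_insertions + istats.n_deletions,
            "hom_fraction": z["hom_fraction"],
            "spectrum6": spec.proportions,
            "indel_length_histogram": istats.length_histogram,
        }
    report["timepoints"] = per_tp

    overlaps = {}
    for a, b in zip(months, months[1:]):
        n1, n2, inter = rates_mod.bulk_overlap(filtered[a], filtered[b])
        overlaps[f"{a}_vs_{b}"] = {"n_first": n1, "n_second": n2, "overlap": inter}
    report["overlaps"] = overlaps

    cov_months = sorted(timepoint_coverage)
    baseline = timepoint_coverage[cov_months[0]]
    cnv_report = {}
    for m in cov_months[1:]:
        ratio = cnv_mod.coverage_ratio(
            timepoint_coverage[m],
            baseline,
            min_control_depth=min_depth,
            autosomes=genome.autosome_names,
        )
        segments = cnv_mod.detect_segments(ratio)
        cnv_report[m] = [asdict(s) for s in segments]
    report["segmental_cnv"] = cnv_report
    return _jsonable(report)


# ---------------------------------------------------------------------------
# File-level runs used by the CLI
# ---------------------------------------------------------------------------


def default_simulation(config: dict, seed: int) -> tuple:
    """Build genome world and simulate a clonal cohort from a config dict."""
    gcfg = config.get("genome", {})
    genome = build_toy_genome(
        n_context_chromosomes=gcfg.get("n_context_chromosomes", 2),
        context_length=gcfg.get("context_length", 1_000_000),
        n_virtual_chromosomes=gcfg.get("n_virtual_chromosomes", 19),
        virtual_length=gcfg.get("virtual_length", 100_000_000),
        gc_fraction=gcfg.get("gc_fraction", 0.42),
        seed=seed,
    )
    genes, expression = build_gene_models(
        genome, n_genes=gcfg.get("n_genes", 50), seed=seed + 1
    )
    blacklist = build_blacklist(
        genome, site_density=gcfg.get("blacklist_density", 1e-5), seed=seed + 2
    )
    dcfg = config.get("design", {})
    design = ClonalDesign(
        doublings=dcfg.get("doublings", 100),
        tau=dcfg.get("tau", 0.3),
        min_depth=dcfg.get("min_depth", 10),
        mean_depth=dcfg.get("mean_depth", 30.0),
        coverage_bin_size=dcfg.get("coverage_bin_size", 100_000),
    )
    scfg = config.get("simulation", {})
    spectrum = scfg.get("spectrum", "GS")
    six = (
        dict(GS_SPECTRUM)
        if spectrum == "GS"
        else dict(MGS_SPECTRUM)
        if spectrum == "mGS"
        else dict(spectrum)
    )
    params = SimulationParams(
        snv_rate=scfg.get("snv_rate", 0.22e-9),
        indel_rate=scfg.get("indel_rate", 0.024e-9),
        six_type_probs=six,
        ins_del_ratio=scfg.get("ins_del_ratio", 0.84),
        contamination=scfg.get("contamination", 0.005),
        hom_fraction=scfg.get("hom_fraction", 0.0),
        gc_fraction=gcfg.get("gc_fraction", 0.42),
    )
    experiments = simulate_clonal_experiment(
        design,
        params,
        genome,
        n_subclones=scfg.get("n_subclones", 3),
        blacklist=blacklist,
        seed=seed + 3,
    )
    return genome, genes, expression, blacklist, design, params, experiments


def run_simulate(config: dict, seed: int, out_dir: str) -> dict:
    """Write a complete simulated data set (fixture, calls, coverage, truth)."""
    genome, genes, expression, blacklist, design, params, experiments = (
        default_simulation(config, seed)
    )
    fixture_dir = os.path.join(out_dir, "fixture")
    paths = write_fixture(genome, genes, blacklist, expression, fixture_dir)
    manifest = {"fixture": paths, "subclones": {}, "seed": seed}
    for exp in experiments:
        calls_path = os.path.join(out_dir, f"calls_{exp.subclone}.vcf")
        write_calls(exp.calls, calls_path, genome)
        pcov = os.path.join(out_dir, f"coverage_parent_{exp.subclone}.tsv")
        scov = os.path.join(out_dir, f"coverage_{exp.subclone}.tsv")
        write_coverage(exp.parent_coverage, pcov)
        write_coverage(exp.subclone_coverage, scov)
        truth_path = os.path.join(out_dir, f"truth_{exp.subclone}.tsv")
        with open(truth_path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tclass\tphase\tcell_fraction\ttrue_af\n")
            for ev in exp.truth:
                fh.write(
                    f"{ev.chrom}\t{ev.pos}\t{ev.ref}\t{ev.alt}\t{ev.var_class}\t"
                    f"{ev.phase}\t{ev.cell_fraction:.6g}\t{ev.true_af:.6g}\n"
                )
        manifest["subclones"][exp.subclone] = {
            "calls": calls_path,
            "parent_coverage": pcov,
            "subclone_coverage": scov,
            "truth": truth_path,
        }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_clonal_from_files(
    manifest: dict,
    design: ClonalDesign,
    snv_quality_threshold: float = 19.0,
    indel_quality_threshold: float = 14.0,
    exclude_subclones: set[str] = frozenset(),
) -> dict:
    """Clonal analysis from a simulate-run manifest (or equivalent paths)."""
    fixture_dir = os.path.dirname(manifest["fixture"]["chromosomes"])
    genome, genes, blacklist, expression = read_fixture(fixture_dir)
    subclones = []
    for name, entry in manifest["subclones"].items():
        subclones.append(
            SubcloneData(
                name,
                read_calls(entry["calls"]),
                read_coverage(entry["parent_coverage"]),
                read_coverage(entry["subclone_coverage"]),
            )
        )
    return analyze_clonal_cohort(
        subclones,
        genome,
        genes,
        expression,
        blacklist,
        design,
        snv_quality_threshold,
        indel_quality_threshold,
        exclude_subclones,
    )
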