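"""Canned parameter-recovery experiments at the full study scale.

Each function builds a ~2.1 Gb (autosomal) two-tier genome, simulates the
clonal design at the published parameter values, runs the complete analysis
chain, and returns the recovered quantities.  They are the package's
self-check that the estimator chain is unbiased under the conditions the
original study reports: D = 100 population doublings, ~30x depth, AF trim
0.3 (spermatogonial, GS-like) or 0.4 (multipotent, mGS-like), <1% feeder
contamination.
"""

from __future__ import annotations

import numpy as np

from .cnv import call_chromosome_ploidy, coverage_ratio
from .coverage import simulate_coverage
from .filtering import CallSet, effective_genome_length, run_cascade
from .genome import GenomeModel, PolymorphismBlacklist, build_blacklist, build_toy_genome
from .rates import estimate_cohort_rates, summarize_rates
from .simulate import (
    GS_SPECTRUM,
    MGS_SPECTRUM,
    ClonalDesign,
    SimulationParams,
    simulate_clonal_experiment,
    spike_cnv,
)
from .spectra import indel_stats, spectrum6

#: published per-base per-doubling truth rates (units of 1e-9)
GS_SNV_RATE = 0.22e-9
MGS_SNV_RATE = 1.0e-9
GS_INDEL_RATE = 0.024e-9
MGS_INDEL_RATE = 0.10e-9
INS_DEL_RATIO = 0.84


def build_world(seed: int) -> tuple[GenomeModel, PolymorphismBlacklist]:
    """Study-scale genome: 2 x 1 Mb context + 19 x 110.42 Mb virtual
    chromosomes (autosomal L ~ 2.1e9) plus sex-chromosome analogues."""
    genome = build_toy_genome(
        n_context_chromosomes=2,
        context_length=1_000_000,
        n_virtual_chromosomes=19,
        virtual_length=110_420_000,
        gc_fraction=0.42,
        seed=seed,
    )
    blacklist = build_blacklist(genome, site_density=1e-5, seed=seed + 1)
    return genome, blacklist


def rate_recovery(
    snv_rate: float,
    indel_rate: float,
    tau: float,
    n_subclones: int,
    seed: int,
    spectrum: dict | None = None,
    contamination: float = 0.005,
    world: tuple | None = None,
) -> dict:
    """Simulate a cohort, run the cascade, and estimate per-class rates.

    Returns mean recovered rates plus the pooled trimmed call sets, so
    spectrum- and INDEL-level summaries can reuse the same run.
    """
    genome, blacklist = world if world is not None else build_world(seed)
    design = ClonalDesign(tau=tau)
    params = SimulationParams(
        snv_rate=snv_rate,
        indel_rate=indel_rate,
        six_type_probs=dict(spectrum or GS_SPECTRUM),
        ins_del_ratio=INS_DEL_RATIO,
        contamination=contamination,
    )
    experiments = simulate_clonal_experiment(
        design, params, genome, n_subclones, blacklist, seed=seed + 2
    )
    trimmed, l_effs = [], []
    for exp in experiments:
        calls, _ = run_cascade(exp.calls, genome, blacklist, tau)
        trimmed.append(calls)
        l_effs.append(
            effective_genome_length(
                exp.parent_coverage,
                exp.subclone_coverage,
                design.min_depth,
                genome.autosome_names,
            )
        )
    out = {"genome": genome, "trimmed": trimmed, "l_effs": l_effs}
    for var_class in ("SNV", "INDEL"):
        per = estimate_cohort_rates(trimmed, l_effs, design.doublings, tau, var_class)
        out[var_class] = {
            "per_subclone": per,
            "mean_rate": summarize_rates([r["rate"] for r in per])["mean"],
        }
    return out


def spectrum_recovery(
    cell_type: str,
    seed: int,
    n_subclones: int,
    min_pooled_snvs: int = 500,
) -> dict:
    """Recover the six-type spectrum at a cell type's published truth
    parameters, pooling trimmed SNVs across subclones."""
    if cell_type == "GS":
        snv_rate, indel_rate, tau, spec = GS_SNV_RATE, GS_INDEL_RATE, 0.3, GS_SPECTRUM
    elif cell_type == "mGS":
        snv_rate, indel_rate, tau, spec = MGS_SNV_RATE, MGS_INDEL_RATE, 0.4, MGS_SPECTRUM
    else:
        raise ValueError(f"unknown cell type {cell_type}")
    run = rate_recovery(snv_rate, indel_rate, tau, n_subclones, seed, spectrum=spec)
    pooled = CallSet(
        [c for cs in run["trimmed"] for c in cs if c.var_class == "SNV"], ["pooled"]
    )
    if len(pooled) < min_pooled_snvs:
        raise RuntimeError(
            f"only {len(pooled)} pooled SNVs; increase n_subclones"
        )
    profile = spectrum6(pooled, run["genome"])
    return {"n": profile.total, "proportions": profile.proportions, "run": run}


def indel_ratio_recovery(seed: int, n_subclones: int = 20) -> dict:
    """Recover the insertion:deletion count ratio on a large INDEL cohort."""
    run = rate_recovery(
        snv_rate=0.0,
        indel_rate=1.0e-9,  # raised so >= 500 INDELs pool quickly
        tau=0.3,
        n_subclones=n_subclones,
        seed=seed,
    )
    pooled = CallSet(
        [c for cs in run["trimmed"] for c in cs if c.var_class in ("INS", "DEL")],
        ["pooled"],
    )
    stats_ = indel_stats(pooled)
    return {
        "n": stats_.n_insertions + stats_.n_deletions,
        "ratio": stats_.ins_del_ratio,
    }


def trisomy_ratio_recovery(
    seed: int,
    copies: int = 3,
    cell_fraction: float = 1.0,
    chrom: str = "virt3",
    world: tuple | None = None,
) -> dict:
    """Median coverage ratio of a spiked whole-chromosome event at 30x,
    100-kb bins, against an unspiked parent track."""
    genome, _ = world if world is not None else build_world(seed)
    rng = np.random.default_rng(seed + 5)
    parent = simulate_coverage(genome, 30.0, 100_000, rng, sample="parent")
    sub = simulate_coverage(genome, 30.0, 100_000, rng, sample="sub")
    sub = spike_cnv(sub, chrom, 1, genome[chrom].length, copies, cell_fraction)
    ratio = coverage_ratio(sub, parent, 10.0, genome.autosome_names)
    calls = {
        p.chrom: p
        for p in call_chromosome_ploidy(ratio, chromosomes=genome.autosome_names)
    }
    return {
        "median_ratio": calls[chrom].median_ratio,
        "state": calls[chrom].state,
        "mixture_fraction": calls[chrom].mixture_fraction,
        "all_states": {c: p.state for c, p in calls.items()},
    }
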