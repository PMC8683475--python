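"""Truncated-Gaussian count extrapolation and mutation-rate estimation.

After the AF trim at tau, only mutations with observed allele frequency
>= tau remain.  The allele-frequency distribution of genuine clonal
(parental-phase) mutations is modeled as a Gaussian; fitting a normal
distribution truncated to [tau, 1] by maximum likelihood and dividing the
observed count by the fitted probability mass above tau recovers the total
count over AF 0..1:

    N_est = n_obs * [Phi((1-mu)/sigma) - Phi((0-mu)/sigma)]
                  / [Phi((1-mu)/sigma) - Phi((tau-mu)/sigma)]

The per-base per-population-doubling rate then divides by the diploid
effective genome length and the number of doublings:

    r = N_est / (2 * L_eff * D)

A naive moment fit on the trimmed data is biased upward in mu (the trim
removes the left tail); the truncated-likelihood fit corrects this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .filtering import CallSet

SIGMA_FLOOR = 1e-3
MIN_FIT_OBS = 10


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float
    n_obs: int
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu {self.mu} outside (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class RateEstimate:
    n_est: float  # extrapolated count over AF 0..1
    l_eff: float  # haploid effective genome length (bases)
    doublings: int
    rate: float  # per base per population doubling
    var_class: str = ""

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("negative rate")


@dataclass(frozen=True)
class GroupComparison:
    labels: tuple[str, str]
    rates_a: tuple[float, ...]
    rates_b: tuple[float, ...]
    statistic: float  # Mann-Whitney U
    p_value: float


def retention_fraction(mu: float, sigma: float, tau: float) -> float:
    """P(tau <= X <= 1) / P(0 <= X <= 1) for X ~ Normal(mu, sigma) — the
    fraction of the AF-0..1 mass that survives the trim."""
    phi = stats.norm.cdf
    full = phi((1.0 - mu) / sigma) - phi((0.0 - mu) / sigma)
    kept = phi((1.0 - mu) / sigma) - phi((tau - mu) / sigma)
    return kept / full


def fit_truncated_gaussian(afs: np.ndarray, tau: float) -> GaussianFit:
    """Maximum-likelihood normal fit to AF observations truncated to [tau, 1].

    Optimizes (mu, log sigma) by Nelder-Mead from a moment-based start;
    degenerate spreads are floored at sigma = 1e-3.  Refuses fewer than 10
    observations (the fit is unstable).
    """
    afs = np.asarray(afs, dtype=float)
    if len(afs) < MIN_FIT_OBS:
        raise ValueError(
            f"refusing truncated-Gaussian fit on {len(afs)} observations "
            f"(need >= {MIN_FIT_OBS})"
        )
    if np.any(afs < tau - 1e-12) or np.any(afs > 1.0 + 1e-12):
        raise ValueError("observations outside [tau, 1]")

    m, s = float(np.mean(afs)), float(np.std(afs))
    if s <= SIGMA_FLOOR:
        return GaussianFit(min(max(m, 1e-6), 1 - 1e-6), SIGMA_FLOOR, len(afs), tau)

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        a, b = (tau - mu) / sigma, (1.0 - mu) / sigma
        with np.errstate(all="ignore"):
            ll = stats.truncnorm.logpdf(afs, a, b, loc=mu, scale=sigma).sum()
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        nll,
        x0=np.array([m, np.log(s)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    mu_hat = float(res.x[0])
    sigma_hat = max(float(np.exp(res.x[1])), SIGMA_FLOOR)
    mu_hat = min(max(mu_hat, 1e-6), 1 - 1e-6)
    return GaussianFit(mu_hat, sigma_hat, len(afs), tau)


def estimate_total_mutations(fit: GaussianFit) -> float:
    """Extrapolate the AF-trimmed count to the full AF 0..1 range."""
    ret = retention_fraction(fit.mu, fit.sigma, fit.tau)
    if ret < 0.05:
        warnings.warn(
            f"retention fraction {ret:.3g} < 0.05: extrapolation is wild",
            stacklevel=2,
        )
    return fit.n_obs / ret


def mutation_rate(
    n_est: float, l_eff: float, doublings: int, var_class: str = ""
) -> RateEstimate:
    """Per-base per-population-doubling rate over a diploid genome."""
    if n_est < 0 or l_eff <= 0 or doublings <= 0:
        raise ValueError("n_est must be >= 0 and l_eff, doublings positive")
    return RateEstimate(
        n_est=n_est,
        l_eff=l_eff,
        doublings=doublings,
        rate=n_est / (2.0 * l_eff * doublings),
        var_class=var_class,
    )


def summarize_rates(rates: list[float], confidence: float = 0.95) -> dict:
    """Mean and t-distribution confidence interval across subclones."""
    rates = [float(r) for r in rates]
    n = len(rates)
    if n == 0:
        raise ValueError("no rates to summarize")
    mean = float(np.mean(rates))
    if n == 1:
        return {"n": 1, "mean": mean, "ci_low": None, "ci_high": None, "ci_defined": False}
    sd = float(np.std(rates, ddof=1))
    tq = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    half = tq * sd / np.sqrt(n)
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "ci_defined": True,
    }


def compare_groups(
    rates_a: list[float],
    rates_b: list[float],
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Mann-Whitney test on per-subclone rates.

    Exact null distribution for small samples (n <= 10 per group, no ties);
    normal approximation with mid-ranks otherwise.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if has_ties:
        warnings.warn("ties present: using normal approximation", stacklevel=2)
        method = "asymptotic"
    elif max(len(a), len(b)) <= 10:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        labels, tuple(a.tolist()), tuple(b.tolist()), float(res.statistic), float(res.pvalue)
    )


def classify_bulk_zygosity(calls: CallSet, het_hom_boundary: float = 0.75) -> dict:
    """Split AF-trimmed bulk-culture calls into heterozygous (~0.5) and
    homozygous (~1.0) classes; AF exactly at the boundary counts as hom."""
    het = [c for c in calls if c.af < het_hom_boundary]
    hom = [c for c in calls if c.af >= het_hom_boundary]
    return {
        "het": CallSet(het, calls.provenance + ["zygosity=het"]),
        "hom": CallSet(hom, calls.provenance + ["zygosity=hom"]),
        "boundary": het_hom_boundary,
        "hom_fraction": len(hom) / len(calls) if len(calls) else float("nan"),
    }


def bulk_overlap(calls_t1: CallSet, calls_t2: CallSet) -> tuple[int, int, int]:
    """(|t1|, |t2|, |t1 & t2|) with allele-aware intersection."""
    k1, k2 = calls_t1.keys(), calls_t2.keys()
    return len(k1), len(k2), len(k1 & k2)


def estimate_cohort_rates(
    trimmed_callsets: list[CallSet],
    l_effs: list[float],
    doublings: int,
    tau: float,
    var_class: str,
) -> list[dict]:
    """Per-subclone rate estimates for one variant class.

    Subclones with enough trimmed calls get their own truncated-Gaussian
    fit; sparse subclones (fewer than 10 calls, typical for INDELs) reuse
    the cohort-pooled fit's retention fraction, which assumes a shared AF
    distribution across subclones of the same design.
    """
    per_class = [cs.of_class(var_class) if var_class != "INDEL" else
                 CallSet([c for c in cs if c.var_class in ("INS", "DEL")],
                         cs.provenance + ["class=INDEL"])
                 for cs in trimmed_callsets]
    pooled = np.concatenate([cs.afs() for cs in per_class]) if per_class else np.array([])
    pooled_fit = (
        fit_truncated_gaussian(pooled, tau) if len(pooled) >= MIN_FIT_OBS else None
    )
    results = []
    for cs, l_eff in zip(per_class, l_effs):
        n_obs = len(cs)
        fit = None
        if n_obs >= MIN_FIT_OBS:
            fit = fit_truncated_gaussian(cs.afs(), tau)
            n_est = estimate_total_mutations(fit)
        elif pooled_fit is not None:
            n_est = n_obs / retention_fraction(pooled_fit.mu, pooled_fit.sigma, tau)
        else:
            n_est = float(n_obs)  # nothing to extrapolate from
        est = mutation_rate(n_est, l_eff, doublings, var_class)
        results.append(
            {
                "n_obs": n_obs,
                "mu": fit.mu if fit else (pooled_fit.mu if pooled_fit else None),
                "sigma": fit.sigma if fit else (pooled_fit.sigma if pooled_fit else None),
                "pooled_fit": fit is None and pooled_fit is not None,
                "n_est": n_est,
                "l_eff": l_eff,
                "doublings": doublings,
                "rate": est.rate,
            }
        )
    return results
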