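"""TMRCA estimation, unit conversions, skyline and demographic-model fits.

Three routes to the age of the sampled variation:

* Thomson's SFS estimator: T = sum_i i xi_i / (n mu_frag), with mu_frag the
  fragment mutation rate per year; model-free given a polarized,
  infinite-sites-consistent SFS.  Dispersion by nonparametric bootstrap over
  sites (percentile CI).
* conversion of a TMRCA expressed in coalescent units (N_ef generations) to
  years: T_years = T_coal * N_ef * g, CI approximated by +/- 2 SD.
* theta-based female effective size: N_ef = theta / (2 L mu g) (per-fragment
  theta) or theta / (2 mu g) (per-site), rounded to the nearest integer for
  reporting before any conversion.

For genealogy-based demographic inference the module provides the classic
(single-tree) skyline — population-size-proportional estimates
M_i = i (i-1) gamma_i / 2 per intercoalescent interval — and maximum-
likelihood fits of constant / exponential-growth / expansion-growth
population models to the coalescent intervals, compared by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import exp, log

import dendropy
import numpy as np
from scipy.optimize import minimize

from .ancestral import SiteFrequencySpectrum


@dataclass(frozen=True)
class TmrcaEstimate:
    method: str
    point_years: float
    dispersion: float  # SE or SD, in years
    ci_years: tuple[float, float]
    assumptions: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.ci_years
        if not (lo - 1e-9 <= self.point_years <= hi + 1e-9):
            raise ValueError("CI does not contain the point estimate")


@dataclass(frozen=True)
class SkylineStep:
    index: int
    lineages: int  # i
    duration: float  # gamma_i, tree branch-length units
    t_start: float  # interval start, measured from the tips
    t_end: float

    @property
    def estimate(self) -> float:
        """Population-size-proportional estimate M_i = i (i-1) gamma_i / 2."""
        return self.lineages * (self.lineages - 1) * self.duration / 2.0


@dataclass(frozen=True)
class DemographicModelFit:
    model: str  # 'constant' | 'exponential' | 'expansion'
    parameters: dict
    log_likelihood: float
    n_parameters: int
    delta_aic: float | None = None
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.log_likelihood


# ---------------------------------------------------------------------------
# Thomson's estimator


def thomson_tmrca(sfs: SiteFrequencySpectrum, rate_per_site_year: float,
                  L: int, B: int = 1000,
                  seed: int | None = None) -> TmrcaEstimate:
    """Thomson's SFS-based TMRCA in years with site-bootstrap dispersion.

    T = (sum_i i xi_i) / (n mu_frag), mu_frag = L * rate per year.  The
    bootstrap resamples the multiset of derived-allele counts (one entry per
    segregating site) with replacement; SE is the bootstrap SD and the CI the
    2.5/97.5 percentiles.
    """
    if rate_per_site_year <= 0 or L <= 0:
        raise ValueError("rate and L must be positive")
    n = sfs.n
    mu_frag = L * rate_per_site_year
    counts = np.repeat(np.arange(1, n), sfs.counts)  # derived count per site
    if counts.size == 0:
        warnings.warn("empty SFS: TMRCA estimate is 0")
        return TmrcaEstimate("thomson", 0.0, 0.0, (0.0, 0.0),
                             {"rate_per_site_year": rate_per_site_year, "L": L})
    point = float(counts.sum() / (n * mu_frag))
    if B > 0:
        rng = np.random.default_rng(seed)
        reps = np.array([
            rng.choice(counts, size=counts.size, replace=True).sum() / (n * mu_frag)
            for _ in range(B)])
        se = float(np.std(reps, ddof=1))
        lo, hi = np.percentile(reps, [2.5, 97.5])
        ci = (min(float(lo), point), max(float(hi), point))
    else:  # point estimate only
        se = 0.0
        ci = (point, point)
    return TmrcaEstimate("thomson", point, se, ci,
                         {"rate_per_site_year": rate_per_site_year, "L": L,
                          "n": n, "S": int(counts.size), "B": B, "seed": seed})


# ---------------------------------------------------------------------------
# Unit conversions


def ne_from_theta(theta: float, rate_per_site_year: float,
                  generation_time: float, L: int | None = None) -> int:
    """Female effective size from theta = 2 N_ef mu (maternally inherited locus).

    With ``L`` given, ``theta`` is per fragment: N = theta / (2 L mu g);
    otherwise per site: N = theta / (2 mu g).  Rounded to the nearest integer
    for reporting.
    """
    if rate_per_site_year <= 0 or generation_time <= 0:
        raise ValueError("rate and generation time must be positive")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    mu_gen = rate_per_site_year * generation_time  # per site per generation
    if L is not None:
        mu_gen *= L
    return int(round(theta / (2.0 * mu_gen))) if theta > 0 else 0


def coalescent_units_to_years(T_coal: float, sd: float | None,
                              N_ef: int, generation_time: float) -> TmrcaEstimate:
    """Convert a TMRCA in coalescent units (N_ef generations) to years.

    T_years = T_coal * N_ef * g; the 95% CI is approximated by +/- 2 SD in
    coalescent units, mapped through the same linear conversion and floored
    at zero.
    """
    if N_ef <= 0 or generation_time <= 0:
        raise ValueError("N_ef and generation time must be positive")
    scale = N_ef * generation_time
    point = T_coal * scale
    if sd is None:
        ci = (point, point)
        disp = 0.0
    else:
        ci = (max(T_coal - 2.0 * sd, 0.0) * scale, (T_coal + 2.0 * sd) * scale)
        disp = sd * scale
    return TmrcaEstimate("coalescent-units", point, disp, ci,
                         {"N_ef": N_ef, "generation_time": generation_time,
                          "T_coal": T_coal, "sd_coal": sd})


# ---------------------------------------------------------------------------
# Classic (single-tree) skyline


def _coalescent_ages(tree: dendropy.Tree, tolerance: float) -> tuple[int, list[float]]:
    """(n tips, sorted internal-node ages) for an ultrametric binary tree."""
    tree.calc_node_root_distances()
    leaves = tree.leaf_nodes()
    depths = [lf.root_distance for lf in leaves]
    depth = max(depths)
    if depth > 0 and (max(depths) - min(depths)) > tolerance * depth:
        raise ValueError(
            f"tree is not ultrametric: tip depth spread "
            f"{max(depths) - min(depths):.4g} exceeds tolerance")
    ages = []
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            raise ValueError("skyline requires a strictly binary tree")
        ages.append(depth - node.root_distance)
    return len(leaves), sorted(ages)


def classic_skyline(tree: dendropy.Tree | str,
                    tolerance: float = 1e-6) -> list[SkylineStep]:
    """Classic skyline steps from an ultrametric genealogy.

    ``tree`` may be a dendropy Tree or a newick string.  While i lineages
    exist for a duration gamma_i, the population-size-proportional estimate
    is M_i = i (i-1) gamma_i / 2, in the tree's branch-length units.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    n, ages = _coalescent_ages(tree, tolerance)
    bounds = [0.0] + ages
    steps = []
    for k in range(n - 1):
        i = n - k
        steps.append(SkylineStep(index=k, lineages=i,
                                 duration=bounds[k + 1] - bounds[k],
                                 t_start=bounds[k], t_end=bounds[k + 1]))
    return steps


def coalescent_intervals(tree_or_steps) -> list[tuple[int, float]]:
    """Normalize input to [(lineage count i, duration gamma_i), ...]."""
    if isinstance(tree_or_steps, (dendropy.Tree, str)):
        steps = classic_skyline(tree_or_steps)
    else:
        steps = list(tree_or_steps)
    out = []
    for s in steps:
        if isinstance(s, SkylineStep):
            out.append((s.lineages, s.duration))
        else:
            out.append((int(s[0]), float(s[1])))
    return out


# ---------------------------------------------------------------------------
# Demographic model fits (AIC comparison)


def _interval_loglik(intervals: list[tuple[int, float]], model: str,
                     N0: float, rho: float = 0.0, alpha: float = 1.0) -> float:
    """Exact log-likelihood of intercoalescent intervals under N(t).

    Backwards time from the tips; relative size nu(t): constant N0;
    exponential N0 e^{-rho t}; expansion N0 (alpha + (1-alpha) e^{-rho t}).
    Rate while i lineages: lambda_i(t) = i(i-1) / (2 nu(t)).
    """
    from math import isfinite

    logL = 0.0
    t = 0.0
    for i, gamma in intervals:
        c = i * (i - 1) / 2.0
        s, e = t, t + gamma
        if model == "constant":
            integral = c * (e - s) / N0
            log_rate = log(c / N0)
        elif model == "exponential":
            if rho == 0.0:
                integral = c * (e - s) / N0
            else:
                integral = c * (exp(rho * e) - exp(rho * s)) / (rho * N0)
            log_rate = log(c / N0) + rho * e
        elif model == "expansion":
            def antideriv(x):
                if rho == 0.0:
                    return x
                return (x + log(alpha + (1 - alpha) * exp(-rho * x)) / rho) / alpha
            integral = c * (antideriv(e) - antideriv(s)) / N0
            nu_e = N0 * (alpha + (1 - alpha) * exp(-rho * e))
            if nu_e <= 0.0:
                return -float("inf")
            log_rate = log(c / nu_e)
        else:
            raise ValueError(f"unknown model {model!r}")
        logL += log_rate - integral
        t = e
    # degenerate parameter combinations can overflow to +/- inf silently
    return logL if isfinite(logL) else -float("inf")


def _interval_loglik_numeric(intervals, model, N0, rho=0.0, alpha=1.0) -> float:
    """Quadrature cross-check of the closed-form likelihood (tests only)."""
    from scipy.integrate import quad

    def nu(t):
        if model == "constant":
            return N0
        if model == "exponential":
            return N0 * exp(-rho * t)
        return N0 * (alpha + (1 - alpha) * exp(-rho * t))

    logL = 0.0
    t = 0.0
    for i, gamma in intervals:
        c = i * (i - 1) / 2.0
        integral, _err = quad(lambda x: c / nu(x), t, t + gamma, limit=200)
        logL += log(c / nu(t + gamma)) - integral
        t += gamma
    return logL


_MODEL_NPARAMS = {"constant": 1, "exponential": 2, "expansion": 3}


def coalescent_model_fit(tree_or_intervals, model: str) -> DemographicModelFit:
    """ML fit of one demographic model to coalescent intervals.

    Models: 'constant' N(t) = N0 (closed-form MLE), 'exponential'
    N(t) = N0 e^{-rho t}, 'expansion' N(t) = N0 (alpha + (1-alpha) e^{-rho t})
    with 0 < alpha < 1 the ancient/current size ratio.  Branch-length units
    are whatever the input tree uses; AIC comparisons are unit-free.
    """
    intervals = coalescent_intervals(tree_or_intervals)
    if model not in _MODEL_NPARAMS:
        raise ValueError(f"unknown model {model!r}")
    # closed-form constant-model MLE: N = sum c_i gamma_i / (#events)
    n_events = len(intervals)
    stat = sum(i * (i - 1) / 2.0 * g for i, g in intervals)
    N_const = stat / n_events
    if model == "constant":
        return DemographicModelFit(
            model="constant", parameters={"N0": N_const},
            log_likelihood=_interval_loglik(intervals, "constant", N_const),
            n_parameters=1)

    def unpack(x):
        # clip transformed parameters to a generous but safe range
        x = np.clip(x, -30.0, 30.0)
        N0 = exp(x[0])
        rho = exp(x[1])
        alpha = 1.0 / (1.0 + exp(-x[2])) if model == "expansion" else 1.0
        return N0, rho, alpha

    def objective(x):
        N0, rho, alpha = unpack(x)
        try:
            ll = _interval_loglik(intervals, model, N0, rho, alpha)
        except (OverflowError, ValueError, ZeroDivisionError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for rho_init in (0.1, 1.0, 10.0):
        x0 = [log(N_const), log(rho_init)]
        if model == "expansion":
            x0.append(0.0)  # alpha = 0.5
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    N0, rho, alpha = unpack(best.x)
    params = {"N0": N0, "rho": rho}
    if model == "expansion":
        params["alpha"] = alpha
    return DemographicModelFit(model=model, parameters=params,
                               log_likelihood=-best.fun,
                               n_parameters=_MODEL_NPARAMS[model],
                               converged=bool(best.success))


def compare_demographic_models(tree_or_intervals,
                               models: tuple[str, ...] = ("constant",
                                                          "exponential",
                                                          "expansion")
                               ) -> list[DemographicModelFit]:
    """Fit several demographic models and attach delta-AIC vs the best."""
    from dataclasses import replace
    fits = [coalescent_model_fit(tree_or_intervals, m) for m in models]
    best_aic = min(f.aic for f in fits)
    return [replace(f, delta_aic=f.aic - best_aic) for f in fits]
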