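"""Sudden-demographic-expansion fit to the mismatch distribution.

Under a sudden expansion, a pair of sequences either coalesces after the
expansion (adding a Poisson(tau) layer of mutations to the pre-expansion
equilibrium) or before it.  With time measured in mutational units
(tau = 2 u t for fragment mutation rate u), the expected distribution of
pairwise differences is

    F_i = sum_{j<=i} Pois(i - j; tau) * Fhat_j(theta0),
    Fhat_j(theta) = theta^j / (theta + 1)^{j+1},

in the default regime where the post-expansion size is effectively infinite
(theta1 = inf, two free parameters).  A finite theta1 adds the analytic
pre-tau coalescence term Fhat_j(theta1) * P(j+1, tau (theta1+1)/theta1)
(regularized lower incomplete gamma) and weights the convolution by
exp(-tau/theta1).

The model is fitted by least squares (grid initialisation + local
refinement), and goodness of fit is assessed by parametric bootstrap: data
are re-simulated from the fitted model (no coalescence before tau, a Kingman
coalescent with theta0 beyond), refitted on the grid, and the fraction of
replicates with SSD >= observed gives p_SSD.  Harpending's raggedness index
and its bootstrap p-value come from the same ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, isfinite

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import poisson

from .diversity import MismatchCounts

GRID_TAU = np.arange(0.0, 25.0 + 1e-9, 0.25)
GRID_THETA0 = np.arange(0.0, 10.0 + 1e-9, 0.25)
DEFAULT_BOOTSTRAP = 20_000


@dataclass(frozen=True)
class MismatchFit:
    tau: float
    theta0: float
    theta1: float  # inf in the default two-parameter fit
    ssd: float
    p_ssd: float | None
    raggedness: float
    p_raggedness: float | None
    tau_ci: tuple[float, float] | None
    bootstrap_replicates: int
    seed: int | None
    converged: bool = True


# ---------------------------------------------------------------------------
# Expected distribution


def _equilibrium(theta: float, i_max: int) -> np.ndarray:
    """Fhat_j(theta) = theta^j/(theta+1)^{j+1} for j = 0..i_max."""
    j = np.arange(i_max + 1)
    if theta == 0.0:
        out = np.zeros(i_max + 1)
        out[0] = 1.0
        return out
    return theta ** j / (theta + 1.0) ** (j + 1)


def expected_mismatch(tau: float, theta0: float, i_max: int,
                      theta1: float = inf) -> np.ndarray:
    """Expected pairwise-difference probabilities for classes 0..i_max.

    The tail mass beyond class i_max is folded into the last class, so the
    vector always sums to 1.
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ValueError("model parameters must be non-negative")
    j = np.arange(i_max + 1)
    pois = poisson.pmf(j, tau) if tau > 0 else np.eye(1, i_max + 1, 0).ravel()
    conv = np.convolve(pois, _equilibrium(theta0, i_max))[:i_max + 1]
    if isfinite(theta1):
        beta_tau = tau * (theta1 + 1.0) / theta1 if theta1 > 0 else inf
        pre = _equilibrium(theta1, i_max) * gammainc(j + 1, beta_tau)
        F = pre + np.exp(-tau / theta1) * conv
    else:
        F = conv
    F = np.clip(F, 0.0, 1.0)
    F[i_max] = max(1.0 - F[:i_max].sum(), 0.0)
    return F


# ---------------------------------------------------------------------------
# Raggedness


def raggedness(obs: MismatchCounts | np.ndarray) -> float:
    """Harpending's raggedness index with zero boundary classes.

    r = sum of squared successive differences of the relative frequencies,
    padding a zero class on both ends of the vector; a smooth unimodal
    (expansion-shaped) distribution gives a small r.
    """
    x = obs.frequencies if isinstance(obs, MismatchCounts) else np.asarray(obs, dtype=float)
    padded = np.concatenate([[0.0], x, [0.0]])
    return float(np.sum(np.diff(padded) ** 2))


# ---------------------------------------------------------------------------
# Fitting


def _ssd(observed_freq: np.ndarray, tau: float, theta0: float,
         theta1: float = inf) -> float:
    exp_f = expected_mismatch(tau, theta0, len(observed_freq) - 1, theta1)
    return float(np.sum((observed_freq - exp_f) ** 2))


def _grid_expected_matrix(i_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Expected vectors for the full (tau, theta0) grid; cached per i_max."""
    if i_max in _GRID_CACHE:
        return _GRID_CACHE[i_max]
    params = np.array([(t, th) for t in GRID_TAU for th in GRID_THETA0])
    mat = np.empty((len(params), i_max + 1))
    for r, (t, th) in enumerate(params):
        mat[r] = expected_mismatch(t, th, i_max)
    _GRID_CACHE[i_max] = (params, mat)
    return params, mat


_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _grid_fit(observed_freq: np.ndarray) -> tuple[float, float, float]:
    params, mat = _grid_expected_matrix(len(observed_freq) - 1)
    ssds = np.sum((mat - observed_freq) ** 2, axis=1)
    best = int(np.argmin(ssds))
    return float(params[best, 0]), float(params[best, 1]), float(ssds[best])


def fit_sudden_expansion(obs: MismatchCounts, B: int = DEFAULT_BOOTSTRAP,
                         seed: int | None = None,
                         three_parameter: bool = False) -> MismatchFit:
    """Least-squares fit of (tau, theta0) with parametric-bootstrap p-values.

    ``B`` bootstrap replicates simulate the fitted model, refit on the
    parameter grid, and yield p_SSD (fraction with SSD >= observed), the
    raggedness p-value, and a percentile CI for tau.  ``B = 0`` skips the
    bootstrap.  ``three_parameter=True`` additionally frees theta1 in the
    local refinement stage.
    """
    freq = obs.frequencies
    i_max = len(freq) - 1
    tau0, th0, ssd0 = _grid_fit(freq)

    if three_parameter:
        def objective(p):
            t, a, b = np.maximum(p, 0.0)
            return _ssd(freq, t, a, max(b, a + 1e-6))
        x0 = [tau0, th0, max(10.0 * th0, 50.0)]
    else:
        def objective(p):
            t, a = np.maximum(p, 0.0)
            return _ssd(freq, t, a)
        x0 = [tau0, th0]
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    refined = np.maximum(res.x, 0.0)
    if res.fun <= ssd0:
        tau_hat, theta0_hat = float(refined[0]), float(refined[1])
        theta1_hat = float(max(refined[2], refined[1])) if three_parameter else inf
        ssd_hat = float(res.fun)
    else:  # keep the grid optimum if polish wandered
        tau_hat, theta0_hat, theta1_hat, ssd_hat = tau0, th0, inf, ssd0
    converged = bool(res.success) and tau_hat < GRID_TAU[-1]
    r_obs = raggedness(obs)

    p_ssd = p_rag = tau_ci = None
    if B > 0:
        rng = np.random.default_rng(seed)
        ssd_sim = np.empty(B)
        r_sim = np.empty(B)
        tau_sim = np.empty(B)
        for b in range(B):
            sim_freq = _simulate_mismatch_freq(obs.n, tau_hat, theta0_hat,
                                               i_max, rng)
            t_b, _th_b, s_b = _grid_fit(sim_freq)
            ssd_sim[b] = s_b
            tau_sim[b] = t_b
            r_sim[b] = raggedness(sim_freq)
        p_ssd = float(np.mean(ssd_sim >= ssd_hat))
        p_rag = float(np.mean(r_sim >= r_obs))
        tau_ci = (float(np.percentile(tau_sim, 2.5)),
                  float(np.percentile(tau_sim, 97.5)))
    return MismatchFit(tau=tau_hat, theta0=theta0_hat, theta1=theta1_hat,
                       ssd=ssd_hat, p_ssd=p_ssd, raggedness=r_obs,
                       p_raggedness=p_rag, tau_ci=tau_ci,
                       bootstrap_replicates=B, seed=seed, converged=converged)


# ---------------------------------------------------------------------------
# Parametric bootstrap simulator (sudden-expansion coalescent, theta1 = inf)


def simulate_sudden_expansion_mismatch(n: int, tau: float, theta0: float,
                                       seed: int | np.random.Generator | None = None
                                       ) -> MismatchCounts:
    """Simulate pairwise-difference counts under the sudden-expansion model.

    Time runs in mutational units: no coalescence during [0, tau] (the
    theta1 = inf regime), then a Kingman coalescent with pairwise rate
    1/theta0; each branch of length x carries Poisson(x/2) mutations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = _simulate_pair_diffs(n, tau, theta0, rng)
    return MismatchCounts(tuple(int(c) for c in np.bincount(diffs)), n)


def _simulate_mismatch_freq(n: int, tau: float, theta0: float, i_max: int,
                            rng: np.random.Generator) -> np.ndarray:
    """One bootstrap replicate's frequencies, folded into classes 0..i_max."""
    diffs = np.minimum(_simulate_pair_diffs(n, tau, theta0, rng), i_max)
    counts = np.bincount(diffs, minlength=i_max + 1)
    return counts / counts.sum()


def _simulate_pair_diffs(n: int, tau: float, theta0: float,
                         rng: np.random.Generator) -> np.ndarray:
    # branches: (tip indicator columns, lengths)
    active = [(1 << i, 0.0) for i in range(n)]  # (mask, birth time)
    edges_mask = []
    edges_len = []
    t = tau
    for i in range(n, 1, -1):
        if theta0 > 0:
            # coalescence rate i(i-1)/(2 theta0) per mutational unit
            t += rng.exponential(2.0 * theta0 / (i * (i - 1)))
        a, b = sorted(int(x) for x in rng.choice(i, size=2, replace=False))
        ma, ta = active[a]
        mb, tb = active[b]
        edges_mask.append(ma)
        edges_len.append(t - ta)
        edges_mask.append(mb)
        edges_len.append(t - tb)
        active = [x for k, x in enumerate(active) if k not in (a, b)] + [(ma | mb, t)]
    muts = rng.poisson(np.asarray(edges_len) / 2.0)
    X = np.zeros((n, len(edges_mask)), dtype=np.int64)
    for j, m in enumerate(edges_mask):
        for i in range(n):
            if (m >> i) & 1:
                X[i, j] = 1
    s = X @ muts
    cross = X @ (X * muts).T
    D = s[:, None] + s[None, :] - 2 * cross
    iu = np.triu_indices(n, k=1)
    return D[iu]


# ---------------------------------------------------------------------------
# Calibration


def tau_to_years(tau: float, L: int, rate_per_site_year: float,
                 ci: tuple[float, float] | None = None
                 ) -> tuple[float, tuple[float, float] | None]:
    """Convert tau (mutational units) to years: t = tau / (2 L rate).

    A tau confidence interval maps through the same monotone conversion.
    """
    if L <= 0 or rate_per_site_year <= 0:
        raise ValueError("L and rate must be positive")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    scale = 1.0 / (2.0 * L * rate_per_site_year)
    years = tau * scale
    ci_years = (ci[0] * scale, ci[1] * scale) if ci is not None else None
    return years, ci_years
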