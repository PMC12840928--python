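"""Mutation-drift equilibrium tests with coalescent-simulation p-values.

Implements Tajima's D, Fu & Li's starred (no-outgroup) D* and F* with the
corrected published coefficients, Fu's F_S via the Ewens sampling formula
(log-scale unsigned Stirling-number recursion), and Ramos-Onsins & Rozas' R2.
Significance is assessed against constant-size coalescent nulls, by default
conditioned on the observed number of segregating sites (fixed-S mutation
placement); a theta-conditioned null (theta = mean pairwise differences) is
available.  For all five statistics the lower tail is the growth-sensitive
direction and is the default alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import inf, isnan, log, nan, sqrt

import numpy as np

from .alignment import Alignment, classify_sites, collapse_haplotypes, is_missing
from .coalsim import simulate_genealogy
from .diversity import harmonic, nucleotide_diversity

DEFAULT_REPS = 10_000


@dataclass(frozen=True)
class NeutralityResult:
    name: str
    value: float
    p_value: float | None = None
    applicable: bool = True
    null_settings: dict = field(default_factory=dict)

    def __repr__(self):
        if not self.applicable:
            return f"{self.name}: not applicable"
        p = f", p={self.p_value:.4g}" if self.p_value is not None else ""
        return f"{self.name}={self.value:.4g}{p}"


# ---------------------------------------------------------------------------
# Summaries shared between the alignment path and the simulated-null path


def _site_summaries(aln: Alignment) -> dict:
    """S, eta, eta_s (minor-allele-count-1 mutations), k, K, U vector."""
    sites = classify_sites(aln)
    n = aln.n
    eta = 0
    eta_s = 0
    U = np.zeros(n, dtype=float)
    for pos in sites.segregating_positions:
        col = aln.column(pos)
        present = [c for c in col if not is_missing(c)]
        state_counts = {b: present.count(b) for b in set(present)}
        eta += len(state_counts) - 1
        singles = [b for b, c in state_counts.items() if c == 1]
        n_singles = min(len(singles), len(state_counts) - 1)
        eta_s += n_singles
        for b in singles[:n_singles]:
            for i, ch in enumerate(col):
                if ch == b:
                    U[i] += 1
    _pi, _sd, k = nucleotide_diversity(aln)
    K = collapse_haplotypes(aln).n_haplotypes
    return {"n": n, "S": sites.S, "eta": eta, "eta_s": eta_s,
            "k": k, "K": K, "U": U}


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_coefficients(n: int) -> tuple[float, float]:
    """(e1, e2) from the standard a1,a2,b1,b2,c1,c2 chain."""
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def _tajimas_d_value(S: int, k: float, n: int) -> float:
    if S == 0:
        return nan
    a1 = harmonic(n - 1)
    e1, e2 = _tajima_coefficients(n)
    return (k - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def tajimas_d(aln: Alignment) -> NeutralityResult:
    """Tajima's D = (k - S/a1) / sqrt(e1 S + e2 S(S-1)); NA when S = 0."""
    if aln.n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    s = _site_summaries(aln)
    d = _tajimas_d_value(s["S"], s["k"], s["n"])
    return NeutralityResult("Tajima's D", d, applicable=not isnan(d))


# ---------------------------------------------------------------------------
# Fu & Li D* and F* (corrected coefficients)


def _fu_li_star_coefficients(n: int) -> tuple[float, float, float, float]:
    """(uD*, vD*, uF*, vF*) using the corrected published formulas."""
    an = harmonic(n - 1)
    bn = harmonic(n - 1, power=2)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2.0) / ((n - 1) ** 2) \
        + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
    vD = ((n / (n - 1.0)) ** 2 * bn + an ** 2 * dn
          - 2.0 * (n * an * (an + 1)) / ((n - 1.0) ** 2)) / (an ** 2 + bn)
    uD = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vD
    vF = ((2.0 * n ** 3 + 110.0 * n ** 2 - 255.0 * n + 153.0)
          / (9.0 * n ** 2 * (n - 1.0))
          + (2.0 * (n - 1.0) * an) / n ** 2
          - (8.0 * bn) / n) / (an ** 2 + bn)
    uF = ((4.0 * n ** 2 + 19.0 * n + 3.0 - 12.0 * (n + 1.0) * an1)
          / (3.0 * n * (n - 1.0))) / an - vF
    return uD, vD, uF, vF


def _fu_li_star_values(eta: int, eta_s: int, k: float, n: int) -> tuple[float, float]:
    if eta == 0:
        return nan, nan
    an = harmonic(n - 1)
    uD, vD, uF, vF = _fu_li_star_coefficients(n)
    d_star = ((n / (n - 1.0)) * eta - an * eta_s) / sqrt(uD * eta + vD * eta * eta)
    f_star = (k - ((n - 1.0) / n) * eta_s) / sqrt(uF * eta + vF * eta * eta)
    return d_star, f_star


def fu_li_star(aln: Alignment) -> tuple[NeutralityResult, NeutralityResult]:
    """Fu & Li's D* and F* (no-outgroup variants, corrected coefficients)."""
    if aln.n < 4:
        raise ValueError("Fu & Li's starred tests need n >= 4")
    s = _site_summaries(aln)
    d_star, f_star = _fu_li_star_values(s["eta"], s["eta_s"], s["k"], s["n"])
    ok = not isnan(d_star)
    return (NeutralityResult("Fu & Li's D*", d_star, applicable=ok),
            NeutralityResult("Fu & Li's F*", f_star, applicable=ok))


# ---------------------------------------------------------------------------
# Fu's F_S via the Ewens sampling formula


@lru_cache(maxsize=64)
def log_unsigned_stirling_first(n: int) -> np.ndarray:
    """log |S(n, k)| for k = 0..n via the recursion
    |S(n+1, k)| = n |S(n, k)| + |S(n, k-1)| carried in log space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    prev = np.full(n + 1, -inf)
    prev[1] = 0.0  # |S(1,1)| = 1
    for m in range(1, n):
        cur = np.full(n + 1, -inf)
        cur[1:m + 2] = np.logaddexp(log(m) + prev[1:m + 2], prev[0:m + 1])
        prev = cur
    return prev


def fs_probability_at_least(n: int, k_obs: int, theta: float) -> float:
    """S' = P(K >= k_obs) under Ewens' formula with parameter theta."""
    if k_obs <= 1 or theta <= 0.0:
        return 1.0
    log_stirling = log_unsigned_stirling_first(n)
    log_theta_rising = float(np.sum(np.log(theta + np.arange(n))))
    ks = np.arange(1, n + 1)
    log_probs = log_stirling[1:] + ks * log(theta) - log_theta_rising
    # normalization is exact; guard against drift
    total = np.logaddexp.reduce(log_probs)
    log_probs -= total
    tail = np.logaddexp.reduce(log_probs[k_obs - 1:])
    return float(np.exp(tail))


def _fus_fs_value(n: int, K: int, k: float) -> float:
    s_prime = fs_probability_at_least(n, K, k)
    if s_prime >= 1.0:
        return inf  # sentinel: no haplotype excess signal possible
    if s_prime <= 0.0:
        return -inf
    return log(s_prime / (1.0 - s_prime))


def fus_fs(aln: Alignment) -> NeutralityResult:
    """Fu's F_S = ln(S'/(1-S')) with S' = P(K >= K_obs | theta = k).

    K_obs is the observed haplotype count and theta is estimated by the mean
    pairwise difference count per fragment.  Returns +inf as a sentinel when
    K_obs = 1 (S' = 1).  An alpha of 0.02 on the simulation p-value
    corresponds to a 5% significance level for this test.
    """
    if aln.n < 2:
        raise ValueError("Fu's F_S needs n >= 2")
    s = _site_summaries(aln)
    fs = _fus_fs_value(s["n"], s["K"], s["k"])
    return NeutralityResult("Fu's F_S", fs, applicable=fs != inf)


# ---------------------------------------------------------------------------
# R2


def _r2_value(U: np.ndarray, k: float, S: int, n: int) -> float:
    if S == 0:
        return nan
    return float(sqrt(np.mean((U - k / 2.0) ** 2)) / S)


def r2_statistic(aln: Alignment) -> NeutralityResult:
    """R2 = sqrt(mean_i (U_i - k/2)^2) / S, U_i = singleton mutations on sequence i."""
    if aln.n < 2:
        raise ValueError("R2 needs n >= 2")
    s = _site_summaries(aln)
    r2 = _r2_value(s["U"], s["k"], s["S"], s["n"])
    return NeutralityResult("R2", r2, applicable=not isnan(r2))


# ---------------------------------------------------------------------------
# Coalescent null simulation


_STAT_NAMES = ("D", "D*", "F*", "FS", "R2")


def _stats_from_masks(masks: list[int], n: int,
                      which: tuple[str, ...]) -> dict[str, float]:
    """Compute requested statistics from derived-allele bitmasks of one dataset."""
    S = len(masks)
    d_counts = np.array([bin(m).count("1") for m in masks], dtype=int)
    k = float(np.sum(2.0 * d_counts * (n - d_counts)) / (n * (n - 1)))
    out: dict[str, float] = {}
    if "D" in which:
        out["D"] = _tajimas_d_value(S, k, n)
    if "D*" in which or "F*" in which:
        eta_s = int(np.sum((d_counts == 1) | (d_counts == n - 1)))
        d_star, f_star = _fu_li_star_values(S, eta_s, k, n)
        out["D*"] = d_star
        out["F*"] = f_star
    if "FS" in which or "R2" in which:
        geno = np.zeros((n, S), dtype=np.uint8)
        for j, m in enumerate(masks):
            for i in range(n):
                if (m >> i) & 1:
                    geno[i, j] = 1
        if "FS" in which:
            K = len(np.unique(geno, axis=0)) if S else 1
            out["FS"] = _fus_fs_value(n, K, k)
        if "R2" in which:
            U = np.zeros(n, dtype=float)
            for j, dc in enumerate(d_counts):
                if dc == 1:
                    U[int(np.argmax(geno[:, j]))] += 1
                elif dc == n - 1:
                    U[int(np.argmin(geno[:, j]))] += 1
            out["R2"] = _r2_value(U, k, S, n)
    return out


def simulate_null_statistics(stat: str, n: int, reps: int,
                             S: int | None = None, theta: float | None = None,
                             seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Null distribution of a statistic under the constant-size coalescent.

    Conditioning: fixed-S (exactly ``S`` mutations placed on branches with
    probability proportional to branch length) or theta (Poisson mutation
    numbers with the given per-fragment theta).  Exactly one of ``S`` /
    ``theta`` must be given.
    """
    if stat not in _STAT_NAMES:
        raise ValueError(f"unknown statistic {stat!r}; choose from {_STAT_NAMES}")
    if (S is None) == (theta is None):
        raise ValueError("give exactly one of S or theta")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.empty(reps)
    for r in range(reps):
        gen = simulate_genealogy(n, seed=rng)
        lengths = np.array([length for _m, length in gen.edges])
        branch_masks = [m for m, _length in gen.edges]
        if S is not None:
            m_count = S
        else:
            m_count = rng.poisson(theta / 2.0 * lengths.sum())
        if m_count == 0:
            values[r] = nan
            continue
        probs = lengths / lengths.sum()
        chosen = rng.choice(len(branch_masks), size=m_count, p=probs)
        masks = [branch_masks[int(c)] for c in chosen]
        values[r] = _stats_from_masks(masks, n, (stat,))[stat]
    return values


_STAT_FUNCS = {
    "D": lambda aln: tajimas_d(aln),
    "D*": lambda aln: fu_li_star(aln)[0],
    "F*": lambda aln: fu_li_star(aln)[1],
    "FS": lambda aln: fus_fs(aln),
    "R2": lambda aln: r2_statistic(aln),
}


def coalescent_pvalue(stat: str, aln: Alignment, reps: int = DEFAULT_REPS,
                      seed: int | None = None, conditioning: str = "S",
                      tail: str = "lower",
                      null_stats: np.ndarray | None = None) -> NeutralityResult:
    """Empirical p-value of a neutrality statistic against coalescent nulls.

    ``tail='lower'`` (default, growth-sensitive): p = fraction of null
    replicates with statistic <= observed.  A precomputed ``null_stats`` array
    (e.g. shared across datasets with identical n and conditioning) bypasses
    simulation.
    """
    if reps < 1000 and null_stats is None:
        raise ValueError("use at least 1000 null replicates")
    obs = _STAT_FUNCS[stat](aln)
    s = _site_summaries(aln)
    if null_stats is None:
        kwargs = {"S": s["S"]} if conditioning == "S" else {"theta": s["k"]}
        null_stats = simulate_null_statistics(stat, aln.n, reps, seed=seed, **kwargs)
    finite = null_stats[~np.isnan(null_stats)]
    if not obs.applicable or len(finite) == 0:
        return NeutralityResult(obs.name, obs.value, p_value=None, applicable=False,
                                null_settings={"reps": int(len(null_stats))})
    if tail == "lower":
        p = float(np.mean(finite <= obs.value))
    elif tail == "upper":
        p = float(np.mean(finite >= obs.value))
    elif tail == "two":
        p = float(2.0 * min(np.mean(finite <= obs.value),
                            np.mean(finite >= obs.value)))
        p = min(p, 1.0)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    settings = {"n": aln.n, "conditioning": conditioning,
                "reps": int(len(null_stats)), "seed": seed, "tail": tail}
    return NeutralityResult(obs.name, obs.value, p_value=p,
                            null_settings=settings)
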