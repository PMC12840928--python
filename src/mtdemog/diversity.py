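"""Diversity summaries and the observed mismatch distribution.

Implements the standard single-locus diversity estimators for a haploid
alignment: number of segregating sites S, haplotype number and diversity h,
per-site nucleotide diversity pi, Watterson's theta, mean pairwise
differences k, and the mismatch distribution (counts of pairs differing at
exactly i sites).

Variance conventions (the usual ones for these summaries):

* h uses the large-sample sampling variance of gene diversity
  (Nei 1987, eq. 8.12):
  V(h) = 2/(n(n-1)) * { 2(n-2) [sum p_i^3 - (sum p_i^2)^2]
                        + sum p_i^2 - (sum p_i^2)^2 }
* pi uses the no-recombination total variance (stochastic + sampling,
  Nei 1987, eq. 10.7):
  V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt

import numpy as np

from .alignment import Alignment, HaplotypeTable, classify_sites, collapse_haplotypes, is_missing


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    S: int
    n_haplotypes: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    theta_w_fragment: float
    theta_w_site: float
    k: float  # mean pairwise differences per fragment

    def to_dict(self) -> dict:
        return {
            "n": self.n, "S": self.S, "n_H": self.n_haplotypes,
            "h": self.h, "h_sd": self.h_sd,
            "pi": self.pi, "pi_sd": self.pi_sd,
            "theta_w_fragment": self.theta_w_fragment,
            "theta_w_site": self.theta_w_site,
            "k": self.k,
        }


@dataclass(frozen=True)
class MismatchCounts:
    """c[i] = number of sequence pairs differing at exactly i sites."""

    counts: tuple[int, ...]
    n: int

    @property
    def total_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.total_pairs

    @property
    def mean(self) -> float:
        c = np.asarray(self.counts, dtype=float)
        return float(np.arange(len(c)) @ c / c.sum())


def harmonic(n_minus_1: int, power: int = 1) -> float:
    """a_1 = sum_{i=1}^{m} 1/i^power for m = n-1 (Watterson's denominators)."""
    return float(sum(1.0 / i ** power for i in range(1, n_minus_1 + 1)))


def haplotype_diversity(table: HaplotypeTable) -> tuple[float, float]:
    """Sample-size-corrected haplotype (gene) diversity h and its SD."""
    n = table.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = np.asarray(table.counts, dtype=float) / n
    sum_p2 = float(np.sum(p ** 2))
    sum_p3 = float(np.sum(p ** 3))
    h = n * (1.0 - sum_p2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum_p3 - sum_p2 ** 2) + sum_p2 - sum_p2 ** 2)
    return h, sqrt(max(var, 0.0))


def pairwise_differences(a: str, b: str) -> tuple[int, int]:
    """(#differing sites, #jointly non-missing sites) under pairwise deletion."""
    diffs = 0
    compared = 0
    for x, y in zip(a, b):
        if is_missing(x) or is_missing(y):
            continue
        compared += 1
        if x != y:
            diffs += 1
    return diffs, compared


def nucleotide_diversity(aln: Alignment) -> tuple[float, float, float]:
    """Return (pi per site, SD of pi, mean pairwise differences k per fragment)."""
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    seqs = aln.sequences()
    n = aln.n
    ks = []
    pis = []
    for a, b in combinations(seqs, 2):
        d, m = pairwise_differences(a, b)
        ks.append(d)
        pis.append(d / m if m else 0.0)
    k = float(np.mean(ks))
    pi = float(np.mean(pis))
    var = ((n + 1) / (3.0 * (n - 1) * aln.length)) * pi \
        + (2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))) * pi * pi
    return pi, sqrt(max(var, 0.0)), k


def watterson_theta(S: int, n: int, L: int | None = None) -> tuple[float, float | None]:
    """Watterson's estimator theta_W = S / a_1 per fragment (and per site if L given)."""
    if n < 2:
        raise ValueError("Watterson's estimator needs n >= 2")
    if S == 0:
        return 0.0, (0.0 if L else None)
    theta = S / harmonic(n - 1)
    return theta, (theta / L if L else None)


def mismatch_observed(aln: Alignment) -> MismatchCounts:
    """Observed distribution of pairwise difference counts."""
    if aln.n < 2:
        raise ValueError("mismatch distribution needs n >= 2")
    diffs = [pairwise_differences(a, b)[0]
             for a, b in combinations(aln.sequences(), 2)]
    counts = np.bincount(diffs)
    return MismatchCounts(tuple(int(c) for c in counts), aln.n)


def diversity_summary(aln: Alignment) -> DiversitySummary:
    """Full diversity table for one alignment (the per-dataset summary row)."""
    table = collapse_haplotypes(aln)
    sites = classify_sites(aln)
    h, h_sd = haplotype_diversity(table)
    pi, pi_sd, k = nucleotide_diversity(aln)
    theta_frag, theta_site = watterson_theta(sites.S, aln.n, aln.length)
    return DiversitySummary(
        n=aln.n, S=sites.S, n_haplotypes=table.n_haplotypes,
        h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd,
        theta_w_fragment=theta_frag, theta_w_site=theta_site or 0.0, k=k)
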