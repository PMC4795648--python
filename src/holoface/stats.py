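"""Resampling and nonparametric inference.

Two tools: the neuron-level paired bootstrap (the C2 population is sampled
with replacement; both experimental conditions are evaluated on the same
resample; the p-value is the proportion of resamples for which the test
statistic is true under the null), and a Wilcoxon signed-rank test with
exact enumeration for small n. Hypotheses are directional throughout
(misaligned > aligned, upright > inverted, whole > part), so bootstrap
p-values are one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = ["BootstrapResult", "paired_neuron_bootstrap", "wilcoxon_signed_rank"]


@dataclass
class BootstrapResult:
    n_resamples: int
    resample_stats: np.ndarray
    point_estimate: Optional[float]
    sem: float
    p_value: float
    seed: Optional[int] = None

    def summary(self) -> dict:
        return {
            "n_resamples": int(self.n_resamples),
            "point_estimate": None if self.point_estimate is None else float(self.point_estimate),
            "sem": float(self.sem),
            "p_value": float(self.p_value),
            "seed": self.seed,
        }


def paired_neuron_bootstrap(
    stat_fn: Callable[[np.ndarray], float],
    n_neurons: int,
    n_resamples: int = 1000,
    subsample: Optional[int] = None,
    seed: int = 0,
    point_estimate: Optional[float] = None,
) -> BootstrapResult:
    """Bootstrap over the C2 neuron population.

    Per resample: optionally draw ``subsample`` neuron indices without
    replacement (the tuning-size compensation used for the inversion
    effect), then sample that set uniformly with replacement; ``stat_fn``
    receives the resulting index array and must evaluate the *paired*
    directional statistic (condition difference) on it. p-value = fraction
    of resamples with statistic <= 0 (the null); SEM = SD of the resample
    statistics.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if subsample is not None and not 1 <= subsample <= n_neurons:
        raise ValueError("subsample must be in 1..n_neurons")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_resamples)
    for r in range(n_resamples):
        if subsample is not None and subsample < n_neurons:
            pool = rng.choice(n_neurons, size=subsample, replace=False)
        else:
            pool = np.arange(n_neurons)
        idx = rng.choice(pool, size=pool.size, replace=True)
        try:
            stats[r] = stat_fn(idx)
        except Exception as err:  # propagate with resample context
            raise RuntimeError(f"stat_fn failed on resample {r}") from err
    if point_estimate is None:
        point_estimate = float(stat_fn(np.arange(n_neurons)))
    sem = float(stats.std(ddof=1)) if n_resamples > 1 else 0.0
    p = float(np.mean(stats <= 0.0))
    return BootstrapResult(n_resamples, stats, point_estimate, sem, p, seed)


def _signed_ranks(diffs: np.ndarray):
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("no signal: all paired differences are zero")
    order = np.abs(d)
    # mid-ranks for ties
    sorter = np.argsort(order, kind="stable")
    ranks = np.empty(d.size)
    sorted_abs = order[sorter]
    i = 0
    while i < d.size:
        j = i
        while j + 1 < d.size and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[sorter[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return d, ranks


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact null distribution of W+ by dynamic programming on 2x ranks."""
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(w_plus * 2))
    mu = total / 2.0
    dev = abs(w2 - mu)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(diffs, exact_limit: int = 15):
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; tied magnitudes get mid-ranks. For n <= exact_limit
    the p-value comes from the exact null distribution of W+ (valid with
    ties); otherwise from the normal approximation with tie correction and
    a 0.5 continuity correction. Returns (W+, p).
    """
    d, ranks = _signed_ranks(np.asarray(diffs, dtype=float))
    n = d.size
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        return w_plus, min(1.0, _exact_two_sided_p(w_plus, ranks))
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        raise ValueError("degenerate rank variance")
    from scipy.stats import norm

    z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * norm.sf(z)))
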