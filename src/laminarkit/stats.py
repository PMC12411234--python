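"""Bespoke inference utilities: Monte-Carlo permutation Welch t-tests,
Kendall-tau cutoff conversion and Theil-Sen robust regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PermTestResult", "perm_welch_t", "tau_from_r", "theil_sen_fit"]


@dataclass
class PermTestResult:
    t: float
    p: float
    ci: tuple[float, float]
    n_permutations: int
    mean_difference: float
    seed: int | None = None

    def __post_init__(self):
        if not (1.0 / self.n_permutations <= self.p <= 1.0):
            raise ValueError("p outside [1/n_perm, 1]")
        if self.ci[0] > self.ci[1]:
            raise ValueError("CI lower bound exceeds upper bound")


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = np.sqrt(vx / nx + vy / ny)
    if denom == 0:
        return 0.0
    return float((x.mean() - y.mean()) / denom)


def perm_welch_t(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100_000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> PermTestResult:
    """Independent-sample Monte-Carlo permutation Welch t-test.

    Group labels are permuted ``n_perm`` times; the two-sided equal-tail
    permutation p-value is 2 * min(lower-tail, upper-tail proportion),
    capped at 1 and floored at 1/n_perm.  The confidence interval for the
    mean difference is the percentile interval of the permutation
    distribution of difference estimates re-centered on the observed
    difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if x.var() == 0 and y.var() == 0:
        raise ValueError("zero variance in both samples")

    t_obs = _welch_t(x, y)
    d_obs = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    nx, ny = len(x), len(y)
    rng = np.random.default_rng(seed)

    # vectorized label permutation in blocks to bound memory
    t_perm = np.empty(n_perm)
    d_perm = np.empty(n_perm)
    block = max(1, min(n_perm, 2_000_000 // max(len(pooled), 1)))
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        idx = np.argsort(rng.random((m, len(pooled))), axis=1)
        perm = pooled[idx]
        a, b = perm[:, :nx], perm[:, nx:]
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        denom = np.sqrt(va / nx + vb / ny)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_blk = np.where(denom > 0, (ma - mb) / denom, 0.0)
        t_perm[done : done + m] = t_blk
        d_perm[done : done + m] = ma - mb
        done += m

    lower = float(np.mean(t_perm <= t_obs))
    upper = float(np.mean(t_perm >= t_obs))
    p = min(1.0, 2.0 * min(lower, upper))
    p = max(p, 1.0 / n_perm)

    a = (1.0 - ci_level) / 2.0
    centered = d_perm - d_perm.mean()
    ci = (
        d_obs + float(np.quantile(centered, a)),
        d_obs + float(np.quantile(centered, 1.0 - a)),
    )
    return PermTestResult(t_obs, p, ci, n_perm, d_obs, seed)


def tau_from_r(r: float) -> float:
    """Kendall-tau cutoff for a Pearson-r cutoff: tau = 2/pi * arcsin(r)."""
    r = float(r)
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    return 2.0 / np.pi * float(np.arcsin(r))


def theil_sen_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Theil-Sen robust line: slope = median of pairwise slopes, intercept =
    median(y - slope*x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct x values")
    res = sps.theilslopes(y, x, method="joint")
    return float(res.slope), float(res.intercept)
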