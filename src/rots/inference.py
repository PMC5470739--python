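"""Permutation-based p-values and FDR for the optimized statistic.

Once the optimizer has fixed (alpha1, alpha2), the final statistic d is
computed on the *original* data and its null distribution is built by
shuffling the sample labels: each permutation rearranges the columns and the
statistic is recomputed against the original group split.

* p-values pool the null values across all features and permutations; with
  G features and P permutations the smallest attainable p is 1 / (G * P).
* FDR follows the SAM recipe: for each threshold (each observed d), the
  expected number of null exceedances per permutation is divided by the
  observed number of exceedances, capped at 1, then monotonized so FDR never
  decreases as d decreases.
"""

from __future__ import annotations

import numpy as np

from .io import ExpressionMatrix, GroupAssignment
from .resampling import STREAM_INFERENCE, permutation_plan
from .statistic import StatisticParams, d_statistic, summarize_groups

__all__ = [
    "permutation_null",
    "empirical_pvalues",
    "permutation_fdr",
    "run_rots",
]


def permutation_null(
    m: ExpressionMatrix,
    g: GroupAssignment,
    params: StatisticParams,
    P: int,
    seed: int,
) -> np.ndarray:
    """G x P matrix of d values under label permutation.

    Column p holds d_alpha recomputed after applying permutation draw p to
    the sample columns.  Uses its own sub-stream of ``seed``, so it never
    disturbs the optimizer's draws.
    """
    if P < 2:
        raise ValueError("P must be >= 2")
    plan = permutation_plan(g, P, seed, stream=STREAM_INFERENCE)
    null = np.empty((m.n_features, P))
    for p_idx in range(P):
        shuffled = ExpressionMatrix(
            feature_ids=m.feature_ids,
            sample_ids=[m.sample_ids[j] for j in plan.draws[p_idx]],
            values=m.values[:, plan.draws[p_idx]],
        )
        null[:, p_idx] = d_statistic(summarize_groups(shuffled, g), params)
    return null


def empirical_pvalues(d_obs: np.ndarray, d_null: np.ndarray) -> np.ndarray:
    """Pooled empirical p-values, floored at 1 / (G * P).

    p_i is the fraction of the pooled G x P null values that reach or exceed
    d_obs[i]; pooling across features buys resolution far beyond what P
    permutations alone would give.
    """
    d_obs = np.asarray(d_obs, dtype=float)
    d_null = np.asarray(d_null, dtype=float)
    if d_null.size == 0:
        raise ValueError("null distribution is empty")
    pool = np.sort(d_null, axis=None)
    total = pool.size
    ge = total - np.searchsorted(pool, d_obs, side="left")
    p = ge / total
    return np.maximum(p, 1.0 / total)


def permutation_fdr(d_obs: np.ndarray, d_null: np.ndarray) -> np.ndarray:
    """SAM-style permutation FDR at the threshold of each observed d.

    raw_i = mean over permutations of #{null >= d_obs[i]} divided by
    #{observed >= d_obs[i]}, capped at 1, then made monotone (non-increasing
    in d) by a running minimum from the least significant feature upward.
    """
    d_obs = np.asarray(d_obs, dtype=float)
    d_null = np.asarray(d_null, dtype=float)
    if d_null.size == 0:
        raise ValueError("null distribution is empty")
    n_perm = d_null.shape[1] if d_null.ndim == 2 else 1
    pool = np.sort(d_null, axis=None)
    null_ge = pool.size - np.searchsorted(pool, d_obs, side="left")
    obs_sorted = np.sort(d_obs)
    obs_ge = d_obs.size - np.searchsorted(obs_sorted, d_obs, side="left")
    raw = np.minimum((null_ge / n_perm) / obs_ge, 1.0)
    # monotonize: along decreasing d, fdr[i] = min(raw[i:])
    order = np.argsort(-d_obs, kind="stable")
    q = np.minimum.accumulate(raw[order][::-1])[::-1]
    fdr = np.empty_like(q)
    fdr[order] = q
    return fdr


def run_rots(
    m: ExpressionMatrix,
    g: GroupAssignment,
    B: int = 1000,
    K: int | None = None,
    seed: int | None = None,
    lattice=None,
):
    """End-to-end convenience wrapper: optimize, test, return results.

    Equivalent to ``ROTS(m, g).fit(B=B, K=K, seed=seed)``.
    """
    from .model import ROTS

    return ROTS(m, g).fit(B=B, K=K, seed=seed, lattice=lattice)
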