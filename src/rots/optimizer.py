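"""Reproducibility optimization over the (alpha1, alpha2, k) lattice.

For every candidate statistic d_alpha and top-list size k, the optimizer
measures

* R_k   — observed reproducibility: the average fraction of shared features
          among the top-k lists of paired group-preserving bootstrap
          datasets;
* R0_k  — null reproducibility: the same quantity on datasets whose columns
          have been permuted, which estimates how much top-k overlap arises
          by chance alone;
* s_k   — the standard deviation of the pair-level bootstrap overlaps.

The reproducibility Z-score Z_k = (R_k - R0_k) / s_k is maximized over the
lattice; the winning (alpha1, alpha2) defines the statistic used for the
final output and the winning k is reported alongside it.

The implementation exploits two structural facts to stay fast: every
(alpha1, 0) cell shares one ranking (the |logfc| order), so the alpha2 = 0
branch is ranked once per dataset; and the overlap profile over all k for a
pair of rankings is a cumulative histogram of per-feature maximum ranks,
costing O(G) per pair rather than O(G*K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GroupAssignment
from .resampling import (
    ResamplingPlan,
    bootstrap_plan,
    permutation_plan,
)
from .statistic import D_SENTINEL, StatisticParams, rank_features

__all__ = [
    "Lattice",
    "OptimizationResult",
    "topk_overlap",
    "reproducibility_profile",
    "z_surface",
    "optimize",
]

DEFAULT_ALPHA1_STEP = 0.01
DEFAULT_ALPHA1_MAX = 5.0

# above this many stored pair-overlap cells, fall back to running sums
_DENSE_PAIR_LIMIT = 40_000_000


@dataclass(frozen=True)
class Lattice:
    """The search grid: alpha1 x alpha2 x top-list size k.

    Defaults follow the canonical grid alpha1 in {0, 0.01, ..., 5},
    alpha2 in {0, 1}; k runs over every integer 1..K (an optional stride
    subsamples the k grid for speed).  The degenerate pair (0, 0) is
    excluded.
    """

    K: int
    alpha1_grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    alpha2_grid: tuple = (0, 1)
    k_stride: int = 1

    def __post_init__(self) -> None:
        if self.alpha1_grid is None:
            grid = np.round(
                np.arange(0, round(DEFAULT_ALPHA1_MAX / DEFAULT_ALPHA1_STEP) + 1)
                * DEFAULT_ALPHA1_STEP,
                2,
            )
            object.__setattr__(self, "alpha1_grid", grid)
        else:
            grid = np.asarray(self.alpha1_grid, dtype=float)
            if grid.size == 0 or np.any(grid < 0):
                raise ValueError("alpha1_grid must be non-empty and non-negative")
            object.__setattr__(self, "alpha1_grid", grid)
        if not set(self.alpha2_grid) <= {0, 1} or len(self.alpha2_grid) == 0:
            raise ValueError("alpha2_grid must be a non-empty subset of {0, 1}")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.k_stride < 1:
            raise ValueError("k_stride must be >= 1")

    @property
    def k_grid(self) -> np.ndarray:
        return np.arange(1, self.K + 1, self.k_stride)

    @property
    def params(self) -> list[StatisticParams]:
        """Lattice points in (alpha2 desc, alpha1 asc) order, (0,0) excluded."""
        out = []
        for a2 in sorted(self.alpha2_grid, reverse=True):
            for a1 in self.alpha1_grid:
                if a1 == 0 and a2 == 0:
                    continue
                out.append(StatisticParams(alpha1=float(a1), alpha2=int(a2)))
        if not out:
            raise ValueError("lattice contains no valid (alpha1, alpha2) points")
        return out


@dataclass(frozen=True)
class OptimizationResult:
    """Z/R/R0/s surfaces over the lattice plus the maximizing cell."""

    params: list[StatisticParams]
    k_grid: np.ndarray
    R_surface: np.ndarray = field(repr=False)  # (P, n_k)
    R0_surface: np.ndarray = field(repr=False)
    s_surface: np.ndarray = field(repr=False)
    Z_surface: np.ndarray = field(repr=False)
    best_params: StatisticParams
    best_k: int
    best_Z: float
    best_R: float
    B: int
    seed: int

    @property
    def best(self) -> tuple[float, int, int]:
        return (self.best_params.alpha1, self.best_params.alpha2, self.best_k)

    def to_frame(self, selected_only: bool = False):
        """Long-format table (alpha1, alpha2, k, R, R0, s, Z) for export."""
        import pandas as pd

        if selected_only:
            rows = [self.params.index(self.best_params)]
        else:
            rows = range(len(self.params))
        frames = []
        for p_idx in rows:
            p = self.params[p_idx]
            frames.append(
                pd.DataFrame(
                    {
                        "alpha1": p.alpha1,
                        "alpha2": p.alpha2,
                        "k": self.k_grid,
                        "R": self.R_surface[p_idx],
                        "R0": self.R0_surface[p_idx],
                        "s": self.s_surface[p_idx],
                        "Z": self.Z_surface[p_idx],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def z_profile(self) -> np.ndarray:
        """Z as a function of k at the selected (alpha1, alpha2)."""
        return self.Z_surface[self.params.index(self.best_params)]


def topk_overlap(rank_a: np.ndarray, rank_b: np.ndarray, k: int) -> float:
    """Fraction of features shared by the two top-k lists."""
    rank_a = np.asarray(rank_a)
    rank_b = np.asarray(rank_b)
    g = rank_a.size
    if rank_b.size != g:
        raise ValueError("rankings must cover the same features")
    if not (1 <= k <= g):
        raise ValueError(f"k must be in 1..{g}, got {k}")
    return len(set(rank_a[:k].tolist()) & set(rank_b[:k].tolist())) / k


def z_surface(R: np.ndarray, R0: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Elementwise (R - R0) / s; degenerate cells (s == 0) become -inf so
    they can never win the argmax."""
    R, R0, s = np.broadcast_arrays(R, R0, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (R - R0) / s
    return np.where(np.asarray(s) == 0, -np.inf, z)


# ---------------------------------------------------------------------------
# internals


def _group_stats(values: np.ndarray, g: GroupAssignment):
    """(|mean difference|, pooled SE) per feature for one dataset."""
    x1 = values[:, g.group1]
    x2 = values[:, g.group2]
    n1, n2 = g.n1, g.n2
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((ss1 + ss2) / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2))
    return np.abs(m1 - m2), s


def _ranking_block(
    values: np.ndarray,
    g: GroupAssignment,
    a1_with_se: np.ndarray,
    has_fc_row: bool,
) -> np.ndarray:
    """Stable descending rank of every feature for each unique statistic.

    Rows 0..len(a1_with_se)-1 correspond to alpha2 = 1 with the given alpha1
    values; an optional final row is the shared alpha2 = 0 (|logfc|) order.
    Returns an int32 array (U, G) where entry (u, i) is feature i's rank.
    """
    num, s = _group_stats(values, g)
    g_feat = num.size
    rows = []
    if a1_with_se.size:
        denom = a1_with_se[:, None] + s[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = num[None, :] / denom
        zero = denom == 0
        if zero.any():
            d[zero & (num[None, :] > 0)] = D_SENTINEL
            d[zero & (num[None, :] == 0)] = 0.0
        rows.append(d)
    if has_fc_row:
        rows.append(num[None, :])
    dmat = np.concatenate(rows, axis=0)
    order = np.argsort(-dmat, axis=1, kind="stable")
    ranks = np.empty_like(order, dtype=np.int32)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(g_feat, dtype=np.int32), order.shape), 1
    )
    return ranks


def _pair_overlap_profiles(
    ranks_a: np.ndarray, ranks_b: np.ndarray, K: int
) -> np.ndarray:
    """Top-k overlap for k = 1..K between paired rankings, per statistic row.

    A feature sits in both top-k lists iff max(rank_a, rank_b) < k, so the
    overlap profile is a cumulative histogram of per-feature max ranks.
    """
    mx = np.maximum(ranks_a, ranks_b)
    np.minimum(mx, K, out=mx)  # ranks >= K never contribute for k <= K
    u = mx.shape[0]
    flat = mx + (np.arange(u, dtype=np.int64) * (K + 1))[:, None]
    bc = np.bincount(flat.ravel(), minlength=u * (K + 1)).reshape(u, K + 1)
    counts = np.cumsum(bc[:, :K], axis=1)  # counts[:, k-1] = #{mx <= k-1}
    return counts / np.arange(1, K + 1)


def _plan_overlaps(
    values: np.ndarray,
    g: GroupAssignment,
    plan: ResamplingPlan,
    a1_with_se: np.ndarray,
    has_fc_row: bool,
    K: int,
    want_std: bool,
):
    """Mean (and optionally SD) over pairs of the per-pair overlap profiles.

    Stores pair profiles densely when they fit; otherwise accumulates running
    sums, which changes nothing statistically.
    """
    n_pairs = plan.n_pairs
    u = a1_with_se.size + int(has_fc_row)
    dense = n_pairs * u * K <= _DENSE_PAIR_LIMIT
    if dense:
        store = np.empty((n_pairs, u, K))
    else:
        acc = np.zeros((u, K))
        acc2 = np.zeros((u, K))
        mn = np.full((u, K), np.inf)
        mx = np.full((u, K), -np.inf)
    for i, (draw_a, draw_b) in enumerate(plan.pairs()):
        ra = _ranking_block(values[:, draw_a], g, a1_with_se, has_fc_row)
        rb = _ranking_block(values[:, draw_b], g, a1_with_se, has_fc_row)
        ov = _pair_overlap_profiles(ra, rb, K)
        if dense:
            store[i] = ov
        else:
            acc += ov
            acc2 += ov * ov
            np.minimum(mn, ov, out=mn)
            np.maximum(mx, ov, out=mx)
    if dense:
        mean = store.mean(axis=0)
        sd = None
        if want_std and n_pairs > 1:
            sd = store.std(axis=0, ddof=1)
            # identical pair overlaps must register as exactly degenerate
            sd[store.max(axis=0) == store.min(axis=0)] = 0.0
    else:
        mean = acc / n_pairs
        sd = None
        if want_std and n_pairs > 1:
            var = (acc2 - acc * acc / n_pairs) / (n_pairs - 1)
            sd = np.sqrt(np.maximum(var, 0.0))
            sd[mx == mn] = 0.0
    if want_std and sd is None:
        sd = np.zeros_like(mean)
    return (mean, sd) if want_std else mean


def reproducibility_profile(
    m: ExpressionMatrix,
    g: GroupAssignment,
    plan: ResamplingPlan,
    p: StatisticParams,
    k_grid: np.ndarray | None = None,
):
    """R_k for one statistic over a resampling plan.

    Returns ``(R_k, pair_overlaps)`` where ``pair_overlaps`` has one row per
    disjoint draw pair and one column per k; ``R_k`` is its column mean.
    """
    if plan.B % 2:
        raise ValueError("plan must contain an even number of draws (pairs)")
    if k_grid is None:
        k_grid = np.arange(1, m.n_features + 1)
    k_grid = np.asarray(k_grid, dtype=int)
    if k_grid.size == 0 or k_grid.min() < 1 or k_grid.max() > m.n_features:
        raise ValueError(f"k values must lie in 1..{m.n_features}")
    K = int(k_grid.max())
    if p.alpha2 == 1:
        a1 = np.array([p.alpha1])
        has_fc = False
    else:
        a1 = np.array([])
        has_fc = True
    pair_overlaps = np.empty((plan.n_pairs, k_grid.size))
    for i, (draw_a, draw_b) in enumerate(plan.pairs()):
        ra = _ranking_block(m.values[:, draw_a], g, a1, has_fc)
        rb = _ranking_block(m.values[:, draw_b], g, a1, has_fc)
        prof = _pair_overlap_profiles(ra, rb, K)[0]
        pair_overlaps[i] = prof[k_grid - 1]
    return pair_overlaps.mean(axis=0), pair_overlaps


def optimize(
    m: ExpressionMatrix,
    g: GroupAssignment,
    B: int = 1000,
    K: int | None = None,
    lattice: Lattice | None = None,
    seed: int = 0,
    allow_degenerate: bool = False,
) -> OptimizationResult:
    """Maximize the reproducibility Z-score over the lattice.

    Parameters
    ----------
    m, g : data and two-group assignment (both groups >= 2 samples).
    B : even number of bootstrap draws; the same number of permutation draws
        feeds the null surface through an independent stream of ``seed``.
    K : maximum top-list size; defaults to the lattice's K or min(500, G).
    lattice : search grid; defaults to alpha1 in {0, .01, ..., 5} x
        alpha2 in {0, 1} with k = 1..K.
    seed : master seed for both resampling streams.
    """
    if g.n != m.n_samples:
        raise ValueError("group assignment does not match the matrix columns")
    if lattice is None:
        if K is None:
            K = min(500, m.n_features)
        lattice = Lattice(K=K)
    elif K is not None and K != lattice.K:
        raise ValueError("pass K either directly or via lattice, not both")
    if lattice.K > m.n_features:
        raise ValueError(
            f"K={lattice.K} exceeds the number of features G={m.n_features}"
        )
    params = lattice.params
    k_grid = lattice.k_grid
    Kmax = int(k_grid.max())

    # unique ranking rows: one per alpha1 with alpha2=1, plus a single shared
    # row for the whole alpha2=0 branch
    a1_with_se = np.array([p.alpha1 for p in params if p.alpha2 == 1])
    has_fc = any(p.alpha2 == 0 for p in params)
    row_of_param = []
    se_pos = {a1: i for i, a1 in enumerate(a1_with_se)}
    fc_row = a1_with_se.size
    for p in params:
        row_of_param.append(se_pos[p.alpha1] if p.alpha2 == 1 else fc_row)
    row_of_param = np.asarray(row_of_param)

    bplan = bootstrap_plan(g, B, seed)
    pplan = permutation_plan(g, B, seed)

    R_u, s_u = _plan_overlaps(
        m.values, g, bplan, a1_with_se, has_fc, Kmax, want_std=True
    )
    R0_u = _plan_overlaps(
        m.values, g, pplan, a1_with_se, has_fc, Kmax, want_std=False
    )

    sel = k_grid - 1
    R = R_u[row_of_param][:, sel]
    R0 = R0_u[row_of_param][:, sel]
    s = s_u[row_of_param][:, sel]
    Z = z_surface(R, R0, s)

    best_Z = float(np.max(Z))
    if not np.isfinite(best_Z):
        if not allow_degenerate:
            raise RuntimeError(
                "every lattice cell is degenerate (zero bootstrap spread); "
                "increase B"
            )
        warnings.warn(
            "every lattice cell is degenerate (zero bootstrap spread); "
            "falling back to the tie-break order over all cells",
            UserWarning,
            stacklevel=2,
        )
    cand = np.argwhere(Z == best_Z)
    # ties: smallest k, then smallest alpha1, then alpha2 = 1 before 0
    key = sorted(
        ((int(k_grid[kc]), params[pc].alpha1, -params[pc].alpha2, pc, kc)
         for pc, kc in cand)
    )
    _, _, _, best_p, best_kc = key[0]
    best_k = int(k_grid[best_kc])

    if best_k >= 0.95 * lattice.K:
        warnings.warn(
            f"selected top-list size k={best_k} is close to K={lattice.K}; "
            "the search may have been truncated — consider increasing K",
            UserWarning,
            stacklevel=2,
        )

    return OptimizationResult(
        params=params,
        k_grid=k_grid,
        R_surface=R,
        R0_surface=R0,
        s_surface=s,
        Z_surface=Z,
        best_params=params[best_p],
        best_k=best_k,
        best_Z=best_Z,
        best_R=float(R[best_p, best_kc]),
        B=int(B),
        seed=int(seed),
    )
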