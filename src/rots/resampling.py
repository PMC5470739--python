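"""Group-preserving bootstrap and label-permutation plans.

A plan is a reproducible batch of column-index draws.  Bootstrap draws
resample columns with replacement *within* each group, so every resampled
dataset keeps the original group sizes and the original labels apply
positionally.  Permutation draws shuffle all columns, destroying any real
group difference; they supply the null distribution for both the
reproducibility optimizer and the FDR estimate.

All randomness flows from one user-visible seed.  The bootstrap, optimizer
permutation and inference permutation streams are derived from it with fixed
tags, so e.g. enlarging the permutation count never perturbs the bootstrap
draws of the same run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GroupAssignment

__all__ = [
    "ResamplingPlan",
    "bootstrap_plan",
    "permutation_plan",
    "materialize",
    "stream_rng",
]

# fixed stream tags; values are arbitrary but frozen for reproducibility
STREAM_BOOTSTRAP = 1
STREAM_NULL = 2
STREAM_INFERENCE = 3


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for a named sub-stream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class ResamplingPlan:
    """B column-index draws of length N, plus the seed that produced them."""

    kind: str  # "bootstrap" | "permutation"
    draws: np.ndarray = field(repr=False)  # (B, N) int
    seed: int
    B: int

    def pairs(self):
        """Disjoint consecutive pairs (draw 2i, draw 2i+1), i = 0..B//2-1."""
        for i in range(self.B // 2):
            yield self.draws[2 * i], self.draws[2 * i + 1]

    @property
    def n_pairs(self) -> int:
        return self.B // 2


def bootstrap_plan(g: GroupAssignment, B: int, seed: int) -> ResamplingPlan:
    """Group-preserving bootstrap: B draws, paired as (2i, 2i+1).

    Positions belonging to a group draw only from that group's columns, with
    replacement.  B must be even: reproducibility is measured over disjoint
    consecutive pairs of draws.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if B % 2:
        raise ValueError(
            f"B must be even (draws are compared in disjoint pairs); got B={B}"
        )
    rng = stream_rng(seed, STREAM_BOOTSTRAP)
    draws = np.empty((B, g.n), dtype=np.intp)
    # groups are processed in first-column order, so the draws (and hence
    # best_Z) are invariant under relabeling group 1 <-> group 2
    for cols in sorted((g.group1, g.group2), key=lambda c: int(c.min())):
        draws[:, cols] = rng.choice(cols, size=(B, cols.size), replace=True)
    return ResamplingPlan(kind="bootstrap", draws=draws, seed=int(seed), B=int(B))


def permutation_plan(
    g: GroupAssignment, B: int, seed: int, stream: int = STREAM_NULL
) -> ResamplingPlan:
    """B full column permutations (labels shuffled over all samples)."""
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = stream_rng(seed, stream)
    draws = np.empty((B, g.n), dtype=np.intp)
    for b in range(B):
        draws[b] = rng.permutation(g.n)
    return ResamplingPlan(kind="permutation", draws=draws, seed=int(seed), B=int(B))


def materialize(m: ExpressionMatrix, draw: np.ndarray) -> ExpressionMatrix:
    """Matrix whose column j is column draw[j] of ``m``; features unchanged.

    When the draw repeats a source column (bootstrap), gathered sample IDs
    would collide, so every ID is suffixed with its position; draws without
    repeats (identity, permutations) keep the gathered IDs as-is.
    """
    draw = np.asarray(draw)
    if draw.min() < 0 or draw.max() >= m.n_samples:
        raise IndexError(
            f"draw indices must be in 0..{m.n_samples - 1}, got range "
            f"[{draw.min()}, {draw.max()}]"
        )
    gathered = [m.sample_ids[j] for j in draw]
    if len(set(gathered)) != len(gathered):
        gathered = [f"{sid}.{pos}" for pos, sid in enumerate(gathered)]
    return ExpressionMatrix(
        feature_ids=m.feature_ids,
        sample_ids=gathered,
        values=m.values[:, draw],
    )
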