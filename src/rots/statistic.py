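"""The modified t-statistic family d_alpha and per-feature summaries.

For each feature the statistic is

    d_alpha = |x1bar - x2bar| / (alpha1 + alpha2 * s)

where x1bar, x2bar are the two group means and s is the classical pooled
two-sample standard error.  The family interpolates between the absolute log
fold change (alpha1=1, alpha2=0) and the ordinary two-sample t-statistic
(alpha1=0, alpha2=1); the reproducibility optimizer picks the member best
suited to the data at hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GroupAssignment

__all__ = [
    "StatisticParams",
    "FeatureSummary",
    "summarize_groups",
    "d_statistic",
    "rank_features",
    "D_SENTINEL",
]

# finite stand-in for "infinite evidence": a zero-variance feature with a
# nonzero shift must rank first but keep every d value finite/sortable
D_SENTINEL = np.finfo(float).max


@dataclass(frozen=True)
class StatisticParams:
    """One (alpha1, alpha2) member of the statistic family.

    alpha1 >= 0 shifts the denominator away from zero (variance
    regularization); alpha2 in {0, 1} switches the pooled standard error on
    or off.  (0, 0) is excluded — the denominator would vanish everywhere.
    """

    alpha1: float
    alpha2: int

    def __post_init__(self) -> None:
        if self.alpha1 < 0:
            raise ValueError("alpha1 must be non-negative")
        if self.alpha2 not in (0, 1):
            raise ValueError("alpha2 must be 0 or 1")
        if self.alpha1 == 0 and self.alpha2 == 0:
            raise ValueError("(alpha1, alpha2) = (0, 0) gives a zero denominator")


@dataclass(frozen=True)
class FeatureSummary:
    """Per-feature group means, pooled standard error and log fold change."""

    mean1: np.ndarray
    mean2: np.ndarray
    pooled_se: np.ndarray
    logfc: np.ndarray

    @property
    def n_features(self) -> int:
        return self.mean1.size


def pooled_standard_error(
    values: np.ndarray, group1: np.ndarray, group2: np.ndarray
) -> np.ndarray:
    """Classical pooled two-sample SE per feature (row).

    s_i = sqrt( (SS1_i + SS2_i) / (n1 + n2 - 2) * (1/n1 + 1/n2) )

    so that |x1bar - x2bar| / s is exactly the magnitude of the ordinary
    pooled-variance two-sample t-statistic.
    """
    x1 = values[:, group1]
    x2 = values[:, group2]
    n1, n2 = x1.shape[1], x2.shape[1]
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = (ss1 + ss2) / (n1 + n2 - 2)
    return np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))


def summarize_groups(m: ExpressionMatrix, g: GroupAssignment) -> FeatureSummary:
    """Group means, pooled SE and signed mean difference for every feature."""
    if g.n != m.n_samples:
        raise ValueError(
            f"group assignment covers {g.n} samples but matrix has {m.n_samples}"
        )
    mean1 = m.values[:, g.group1].mean(axis=1)
    mean2 = m.values[:, g.group2].mean(axis=1)
    return FeatureSummary(
        mean1=mean1,
        mean2=mean2,
        pooled_se=pooled_standard_error(m.values, g.group1, g.group2),
        logfc=mean1 - mean2,
    )


def d_statistic(fs: FeatureSummary, p: StatisticParams) -> np.ndarray:
    """Evaluate d_alpha for every feature; always >= 0.

    With alpha1 = 0 a zero pooled SE makes the denominator vanish: a feature
    with zero numerator gets d = 0, one with a nonzero shift gets the finite
    ``D_SENTINEL`` so it ranks first without breaking the grid search.
    """
    num = np.abs(fs.logfc)
    denom = p.alpha1 + p.alpha2 * fs.pooled_se
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / denom
    zero_denom = denom == 0
    if np.any(zero_denom):
        d = np.where(zero_denom & (num > 0), D_SENTINEL, d)
        d = np.where(zero_denom & (num == 0), 0.0, d)
    return d


def rank_features(d: np.ndarray) -> np.ndarray:
    """Feature indices ordered by decreasing d; ties keep original row order.

    The stable descending sort makes rankings deterministic across platforms.
    """
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("d contains non-finite entries; cannot rank")
    return np.argsort(-d, kind="stable")
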