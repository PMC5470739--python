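"""Synthetic two-group expression data with known ground truth.

Emulates the spike-in benchmark designs used to validate differential
expression methods: a null background of features with no group difference,
plus a controlled fraction of features whose group means are shifted by a
known multiple of the noise SD.  Values are Gaussian on the log-intensity
scale, matching the preprocessed matrices the test operates on; a count
model (e.g. negative binomial with dropout) is deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GroupAssignment

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "evaluate_detection"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated study.

    G : number of features; n1, n2 : group sizes.
    pi_de : fraction of truly shifted features (rounded to a count).
    effect : mean shift of flagged features, in units of the feature's
        noise SD; the sign alternates across flagged features so both
        directions of change are exercised.
    noise_sd : within-group SD on the log-intensity scale.
    baseline_range : uniform range for per-feature baselines (log scale).
    heteroscedastic : draw a per-feature SD (log-normal around noise_sd)
        instead of a shared constant.
    """

    G: int = 1000
    n1: int = 5
    n2: int = 5
    pi_de: float = 0.1
    effect: float = 3.0
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (19.0, 26.0)
    heteroscedastic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 1 or self.n1 < 2 or self.n2 < 2:
            raise ValueError("need G >= 1 and both group sizes >= 2")
        if not 0 <= self.pi_de <= 1:
            raise ValueError("pi_de must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise ValueError("baseline_range must be (low, high)")
        if self.n_de > 0 and self.effect == 0:
            raise ValueError("flagged features must shift: effect == 0 "
                             "requires pi_de == 0")

    @property
    def n_de(self) -> int:
        return int(round(self.G * self.pi_de))


@dataclass(frozen=True)
class GroundTruth:
    """Which features were shifted, and by how much (signed, log scale)."""

    de_flags: np.ndarray
    true_shift: np.ndarray


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the matrix and its ground truth.

    value[i, j] = baseline_i + shift_i * [j in group 1] + N(0, sd_i),
    with shift_i = +-effect * sd_i for the first round(G * pi_de) features
    and 0 otherwise.  Fully deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 917]))
    g_tot, n = spec.G, spec.n1 + spec.n2
    baseline = rng.uniform(*spec.baseline_range, size=g_tot)
    if spec.heteroscedastic:
        sd = spec.noise_sd * rng.lognormal(mean=0.0, sigma=0.25, size=g_tot)
    else:
        sd = np.full(g_tot, spec.noise_sd)
    flags = np.zeros(g_tot, dtype=bool)
    flags[: spec.n_de] = True
    signs = np.where(np.arange(g_tot) % 2 == 0, 1.0, -1.0)
    shift = np.where(flags, signs * spec.effect * sd, 0.0)
    values = (
        baseline[:, None]
        + shift[:, None] * (np.arange(n) < spec.n1)[None, :]
        + rng.normal(0.0, sd[:, None], size=(g_tot, n))
    )
    m = ExpressionMatrix(
        feature_ids=[f"F{i + 1}" for i in range(g_tot)],
        sample_ids=[f"A{j + 1}" for j in range(spec.n1)]
        + [f"B{j + 1}" for j in range(spec.n2)],
        values=values,
    )
    return m, GroundTruth(de_flags=flags, true_shift=shift)


def groups_for(spec: SyntheticSpec) -> GroupAssignment:
    """The two-group assignment matching :func:`generate`'s column layout."""
    return GroupAssignment(["A"] * spec.n1 + ["B"] * spec.n2)


def evaluate_detection(result, truth: GroundTruth, cutoff: float = 0.05):
    """Precision / recall of FDR calls against the ground truth.

    detections = features with fdr < cutoff; precision = fraction of
    detections that are truly shifted (1.0 when nothing is detected);
    recall = fraction of truly shifted features detected.
    Returns ``(precision, recall, n_detected)``.
    """
    fdr = np.asarray(result.fdr)
    flags = np.asarray(truth.de_flags, dtype=bool)
    if fdr.size != flags.size:
        raise ValueError("result and truth cover different numbers of features")
    detected = fdr < cutoff
    n_det = int(detected.sum())
    n_true_det = int((detected & flags).sum())
    n_true = int(flags.sum())
    precision = 1.0 if n_det == 0 else n_true_det / n_det
    recall = 0.0 if n_true == 0 else n_true_det / n_true
    return precision, recall, n_det
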