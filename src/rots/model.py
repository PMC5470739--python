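"""Model / results interface for reproducibility-optimized testing.

``ROTS`` holds the data and group design; ``fit`` runs the reproducibility
optimization and permutation inference and returns a ``ROTSResults`` object
carrying the per-feature estimates, the selected statistic, the optimization
surfaces and the run metadata, with ``summary()``, ``to_frame()``,
``save()`` and ``plot()`` attached.

Typical use::

    from rots import ROTS, read_expression_matrix

    m = read_expression_matrix("expression.tsv")
    res = ROTS(m, groups=[0, 0, 0, 1, 1, 1]).fit(B=1000, K=500, seed=1)
    print(res.summary())
    res.save("results.tsv")
    res.plot("volcano", path="volcano.png")
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .inference import empirical_pvalues, permutation_fdr, permutation_null
from .io import ExpressionMatrix, GroupAssignment
from .optimizer import Lattice, OptimizationResult, optimize
from .statistic import d_statistic, summarize_groups

__all__ = ["ROTS", "ROTSResults"]


class ROTS:
    """Two-group differential expression model with a data-driven statistic.

    Parameters
    ----------
    data : ExpressionMatrix, DataFrame or ndarray
        Feature x sample matrix of preprocessed (normalized, typically
        log-scale) expression values.  A DataFrame supplies feature IDs from
        its index and sample IDs from its columns.
    groups : GroupAssignment or sequence
        Two-level label per sample column, e.g. ``[0,0,0,1,1,1]``.
    """

    def __init__(self, data, groups, feature_ids=None, sample_ids=None) -> None:
        if isinstance(data, ExpressionMatrix):
            m = data
        elif isinstance(data, pd.DataFrame):
            m = ExpressionMatrix.from_dataframe(data)
        else:
            arr = np.asarray(data, dtype=float)
            if feature_ids is None:
                feature_ids = [f"F{i + 1}" for i in range(arr.shape[0])]
            if sample_ids is None:
                sample_ids = [f"S{j + 1}" for j in range(arr.shape[1])]
            m = ExpressionMatrix(feature_ids, sample_ids, arr)
        self.data = m
        self.groups = (
            groups if isinstance(groups, GroupAssignment) else GroupAssignment(groups)
        )
        if self.groups.n != m.n_samples:
            raise ValueError(
                f"groups cover {self.groups.n} samples but the matrix has "
                f"{m.n_samples} columns"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, groups) -> "ROTS":
        return cls(ExpressionMatrix.from_dataframe(df), groups)

    def fit(
        self,
        B: int = 1000,
        K: int | None = None,
        seed: int | None = None,
        lattice: Lattice | None = None,
    ) -> "ROTSResults":
        """Optimize the statistic, then test on the original data.

        ``B`` even bootstrap draws drive the optimization; the same count of
        label permutations drives the p-value / FDR null.  ``K`` is the
        maximum top-list size (default min(500, G)); ``seed`` fixes all
        randomness.
        """
        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        try:
            opt = optimize(
                self.data, self.groups, B=B, K=K, lattice=lattice, seed=seed
            )
        except RuntimeError:
            # data with no resampling spread at all (e.g. constant features):
            # keep the run alive with the tie-break statistic so that the
            # trivial outputs (d = 0, p = 1) are still produced
            opt = optimize(
                self.data, self.groups, B=B, K=K, lattice=lattice, seed=seed,
                allow_degenerate=True,
            )
        fs = summarize_groups(self.data, self.groups)
        d = d_statistic(fs, opt.best_params)
        null = permutation_null(
            self.data, self.groups, opt.best_params, P=B, seed=seed
        )
        pvalue = empirical_pvalues(d, null)
        fdr = permutation_fdr(d, null)
        return ROTSResults(
            model=self,
            d=d,
            logfc=fs.logfc,
            pvalue=pvalue,
            fdr=fdr,
            optimization=opt,
            B=int(B),
            K=int(opt.k_grid.max()),
            seed=int(seed),
        )


@dataclass
class ROTSResults:
    """Fitted results: per-feature statistics plus the selected parameters."""

    model: ROTS
    d: np.ndarray = field(repr=False)
    logfc: np.ndarray = field(repr=False)
    pvalue: np.ndarray = field(repr=False)
    fdr: np.ndarray = field(repr=False)
    optimization: OptimizationResult = field(repr=False)
    B: int
    K: int
    seed: int

    # -- selected statistic -------------------------------------------------
    @property
    def alpha1(self) -> float:
        return self.optimization.best_params.alpha1

    @property
    def alpha2(self) -> int:
        return self.optimization.best_params.alpha2

    @property
    def k(self) -> int:
        return self.optimization.best_k

    @property
    def R(self) -> float:
        return self.optimization.best_R

    @property
    def Z(self) -> float:
        return self.optimization.best_Z

    @property
    def feature_ids(self) -> list[str]:
        return self.model.data.feature_ids

    @property
    def n_features(self) -> int:
        return self.d.size

    def significant(self, fdr_cutoff: float = 0.05) -> np.ndarray:
        """Boolean mask of features called at the given FDR cutoff."""
        return self.fdr < fdr_cutoff

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d": self.d,
                "logfc": self.logfc,
                "pvalue": self.pvalue,
                "fdr": self.fdr,
            },
            index=pd.Index(self.feature_ids, name="feature_id"),
        )

    def save(self, path) -> None:
        """Write the per-feature table with run metadata (TSV)."""
        _io.write_results(self, path)

    def save_surfaces(self, path, selected_only: bool = True) -> None:
        """Export the optimization surfaces as long-format TSV."""
        self.optimization.to_frame(selected_only=selected_only).to_csv(
            path, sep="\t", index=False
        )

    def plot(self, kind: str = "volcano", path=None, fdr_cutoff: float = 0.05, **kw):
        """Render one of the diagnostic plots (volcano, ma, reproducibility,
        pvalue, pca, heatmap); see :mod:`rots.visualization`."""
        from .visualization import PlotRequest, render

        req = PlotRequest(type=kind, fdr_cutoff=fdr_cutoff, output_path=path, **kw)
        return render(self, self.model.data, req)

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary."""
        g = self.model.groups
        lines = [
            "Reproducibility-Optimized Test Statistic",
            "=" * 58,
            f"Features (G): {self.n_features}    "
            f"Samples: {g.n1} + {g.n2} "
            f"({g.group_names[0]!r} vs {g.group_names[1]!r})",
            f"Bootstraps (B): {self.B}    Max top-list size (K): {self.K}    "
            f"Seed: {self.seed}",
            "-" * 58,
            f"Selected statistic:  alpha1 = {self.alpha1:g}, "
            f"alpha2 = {self.alpha2:d}",
            f"Top-list size k = {self.k}    R = {self.R:.4f}    "
            f"Z = {self.Z:.4f}",
            "Features at FDR < 0.01 / 0.05 / 0.10:  "
            f"{int(np.sum(self.fdr < 0.01))} / {int(np.sum(self.fdr < 0.05))} / "
            f"{int(np.sum(self.fdr < 0.10))}",
            "-" * 58,
            f"Top {min(top, self.n_features)} features by d:",
        ]
        tab = self.to_frame().sort_values("d", ascending=False).head(top)
        lines.append(
            tab.to_string(
                float_format=lambda v: f"{v:.4g}", index_names=False
            )
        )
        return "\n".join(lines)
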