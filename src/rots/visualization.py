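"""Diagnostic plots for fitted results.

Six plot types are provided, mirroring the standard visual checks of a
two-group differential expression analysis:

* ``volcano``          — log fold change vs -log10 p-value;
* ``ma``               — overall mean intensity (A) vs mean difference (M);
* ``reproducibility``  — reproducibility Z-score as a function of top-list
                         size k at the selected (alpha1, alpha2), maximum
                         marked;
* ``pvalue``           — p-value histogram (bin width 0.05); approximately
                         flat under the null, left-skewed with true signal;
* ``pca``              — samples projected on the top two principal
                         components of the significant-feature submatrix;
* ``heatmap``          — hierarchically clustered heatmap (euclidean
                         distance, complete linkage) of the significant
                         features.

Features are called significant at ``fdr < fdr_cutoff``; a cutoff of 1
selects every feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .io import ExpressionMatrix

__all__ = ["PlotRequest", "render", "PLOT_TYPES"]

PLOT_TYPES = ("volcano", "ma", "reproducibility", "pvalue", "pca", "heatmap")


@dataclass
class PlotRequest:
    type: str
    fdr_cutoff: float = 0.05
    output_path: str | None = None
    dpi: int = 100

    def __post_init__(self) -> None:
        if self.type not in PLOT_TYPES:
            raise ValueError(
                f"unknown plot type {self.type!r}; valid types: "
                + ", ".join(PLOT_TYPES)
            )
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must lie in (0, 1]")


def _sig_mask(fdr: np.ndarray, cutoff: float) -> np.ndarray:
    if cutoff >= 1:
        return np.ones_like(np.asarray(fdr), dtype=bool)
    return np.asarray(fdr) < cutoff


def render(r, m: ExpressionMatrix, req: PlotRequest):
    """Render one diagnostic plot for results ``r`` on matrix ``m``.

    Returns the matplotlib Figure; when ``req.output_path`` is set the
    figure is also written there (format chosen by extension: png/pdf/svg)
    and closed.
    """
    sig = _sig_mask(np.asarray(r.fdr), req.fdr_cutoff)
    if req.type == "volcano":
        fig = _volcano(r, sig)
    elif req.type == "ma":
        fig = _ma(r, m, sig)
    elif req.type == "reproducibility":
        fig = _reproducibility(r)
    elif req.type == "pvalue":
        fig = _pvalue_hist(r)
    elif req.type == "pca":
        fig = _pca(r, m, sig, req.fdr_cutoff)
    else:
        fig = _heatmap(r, m, sig, req.fdr_cutoff)
    if req.output_path is not None:
        fig.savefig(req.output_path, dpi=req.dpi)
        plt.close(fig)
    return fig


def render_z_profile(surface_frame, output_path=None):
    """Z-vs-k plot from a long-format surfaces table (columns k and Z for
    one (alpha1, alpha2) slice); the maximum is marked with a red dot."""
    df = surface_frame
    need = {"k", "Z"}
    if not need <= set(df.columns):
        raise ValueError(f"surfaces table must contain columns {sorted(need)}")
    k = np.asarray(df["k"])
    z = np.asarray(df["Z"], dtype=float)
    finite = np.isfinite(z)
    if not finite.any():
        raise ValueError("no finite Z values in the surfaces table")
    i = int(np.flatnonzero(finite)[np.argmax(z[finite])])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(k[finite], z[finite], lw=1.2)
    ax.plot([k[i]], [z[i]], "ro")
    ax.annotate(f"Z = {z[i]:.2f}", (k[i], z[i]),
                textcoords="offset points", xytext=(6, 4))
    ax.set_xlabel("top list size k")
    ax.set_ylabel("reproducibility Z-score")
    if {"alpha1", "alpha2"} <= set(df.columns):
        ax.set_title(f"alpha1 = {df['alpha1'].iloc[0]:g}, "
                     f"alpha2 = {int(df['alpha2'].iloc[0])}")
    fig.tight_layout()
    if output_path is not None:
        fig.savefig(output_path, dpi=100)
        plt.close(fig)
    return fig


def _scatter_sig(ax, x, y, sig):
    ax.scatter(x[~sig], y[~sig], s=8, c="0.5", alpha=0.6, linewidths=0)
    ax.scatter(x[sig], y[sig], s=10, c="red", alpha=0.8, linewidths=0)


def _volcano(r, sig):
    fig, ax = plt.subplots(figsize=(5, 4))
    y = -np.log10(np.asarray(r.pvalue))
    _scatter_sig(ax, np.asarray(r.logfc), y, sig)
    ax.set_xlabel("log fold change")
    ax.set_ylabel("-log10(p-value)")
    ax.set_title("Volcano plot")
    fig.tight_layout()
    return fig


def _ma(r, m, sig):
    fig, ax = plt.subplots(figsize=(5, 4))
    a = m.values.mean(axis=1)
    _scatter_sig(ax, a, np.asarray(r.logfc), sig)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("A (mean intensity)")
    ax.set_ylabel("M (mean difference)")
    ax.set_title("MA plot")
    fig.tight_layout()
    return fig


def _reproducibility(r):
    opt = getattr(r, "optimization", None)
    if opt is None:
        raise ValueError(
            "reproducibility plot needs the optimization surfaces; fit the "
            "model (or load the surfaces file produced by the run command)"
        )
    fig, ax = plt.subplots(figsize=(5, 4))
    z = opt.z_profile()
    finite = np.isfinite(z)
    ax.plot(opt.k_grid[finite], z[finite], lw=1.2)
    ax.plot([opt.best_k], [opt.best_Z], "ro")
    ax.annotate(
        f"Z = {opt.best_Z:.2f}",
        (opt.best_k, opt.best_Z),
        textcoords="offset points",
        xytext=(6, 4),
    )
    ax.set_xlabel("top list size k")
    ax.set_ylabel("reproducibility Z-score")
    ax.set_title(
        f"alpha1 = {opt.best_params.alpha1:g}, alpha2 = {opt.best_params.alpha2}"
    )
    fig.tight_layout()
    return fig


def _pvalue_hist(r):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(np.asarray(r.pvalue), bins=np.arange(0, 1.0001, 0.05),
            edgecolor="white", color="steelblue")
    ax.set_xlabel("p-value")
    ax.set_ylabel("frequency")
    ax.set_title("Histogram of p-values")
    fig.tight_layout()
    return fig


def _sig_submatrix(r, m, sig, cutoff):
    if sig.sum() < 2:
        raise ValueError(
            f"only {int(sig.sum())} feature(s) significant at FDR < {cutoff}; "
            "need >= 2 — consider a higher fdr_cutoff (1 selects all features)"
        )
    return m.values[sig, :]


def _pca(r, m, sig, cutoff):
    from sklearn.decomposition import PCA

    sub = _sig_submatrix(r, m, sig, cutoff)
    # samples as points, centered but not scaled, SVD-based
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(sub.T)
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = getattr(getattr(r, "model", None), "groups", None)
    if groups is not None:
        for idx, name, color in (
            (groups.group1, groups.group_names[0], "tab:blue"),
            (groups.group2, groups.group_names[1], "tab:orange"),
        ):
            ax.scatter(coords[idx, 0], coords[idx, 1], label=str(name), c=color)
        ax.legend(title="group")
    else:
        ax.scatter(coords[:, 0], coords[:, 1])
    for j, sid in enumerate(m.sample_ids):
        ax.annotate(sid, coords[j], fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    var = pca.explained_variance_ratio_ * 100
    ax.set_xlabel(f"PC1 ({var[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({var[1]:.1f}%)")
    ax.set_title(f"PCA of features at FDR < {cutoff:g}")
    fig.tight_layout()
    return fig


def _heatmap(r, m, sig, cutoff):
    import seaborn as sns

    sub = _sig_submatrix(r, m, sig, cutoff)
    ids = [f for f, s in zip(m.feature_ids, sig) if s]
    cg = sns.clustermap(
        np.asarray(sub),
        method="complete",
        metric="euclidean",
        z_score=0,  # per-feature scaling for display; distances on scaled rows
        cmap="RdBu_r",
        xticklabels=m.sample_ids,
        yticklabels=ids if len(ids) <= 60 else False,
        figsize=(6, 6),
    )
    cg.ax_heatmap.set_title(f"features at FDR < {cutoff:g}", pad=40)
    return cg.figure
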