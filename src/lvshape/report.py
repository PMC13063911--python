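"""Descriptive analytics and figures for a completed pipeline run.

Per-feature class-conditional KDE curves, the Kendall tau-b correlation
matrix with Ward clustering and dendrogram leaf order, 10th/90th-quantile
exemplar subjects per feature, ROC / pooled-confusion and
selection-frequency figures. Figures are pure functions of already
computed results; nothing here re-runs the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde, kendalltau

from .model import CVReport, selection_frequency

__all__ = [
    "CorrelationClustering",
    "kendall_matrix",
    "ward_order",
    "quantile_exemplars",
    "kde_by_response",
    "plot_kde_grid",
    "plot_correlation_heatmap",
    "plot_roc_confusion",
    "plot_selection_frequency",
    "plot_exemplar_meshes",
]


@dataclass
class CorrelationClustering:
    matrix: pd.DataFrame      # tau-b, symmetric, unit diagonal
    linkage: np.ndarray       # scipy linkage array (Ward on d = 1 - tau)
    leaf_order: list[str]     # dendrogram leaf order of the features


def kendall_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Kendall tau-b (tie-corrected). Constant columns get 0 off
    the diagonal, with a warning."""
    cols = list(X.columns)
    constant = [c for c in cols if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant feature column(s) {constant}: tau set to 0")
    p = len(cols)
    M = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if cols[i] in constant or cols[j] in constant:
                tau = 0.0
            else:
                tau = kendalltau(X[cols[i]], X[cols[j]]).statistic
            M[i, j] = M[j, i] = tau
    return pd.DataFrame(M, index=cols, columns=cols)


def ward_order(matrix: pd.DataFrame) -> CorrelationClustering:
    """Ward agglomeration on the distance d = 1 - tau; the heatmap leaf
    order follows the dendrogram."""
    M = matrix.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("need a symmetric correlation matrix")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="ward")
    order = [matrix.columns[i] for i in leaves_list(Z)]
    return CorrelationClustering(matrix=matrix, linkage=Z, leaf_order=order)


def quantile_exemplars(
    features: pd.DataFrame, q_low: float = 0.10, q_high: float = 0.90
) -> pd.DataFrame:
    """Per feature, the subject (row index) whose value is nearest the
    q_low and q_high percentiles (linear-interpolation convention; ties
    break to the lowest subject ID)."""
    if len(features) < 3:
        raise ValueError("need at least 3 subjects for quantile exemplars")
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        picks = {}
        for name, q in (("low", q_low), ("high", q_high)):
            target = np.percentile(vals, 100.0 * q)
            dist = np.abs(vals - target)
            picks[name] = int(np.flatnonzero(dist == dist.min())[0])
        rows.append({
            "feature": col,
            "low_subject": features.index[picks["low"]],
            "high_subject": features.index[picks["high"]],
        })
    return pd.DataFrame(rows).set_index("feature")


def kde_by_response(
    X: pd.DataFrame, y: np.ndarray, grid_points: int = 512
) -> dict[str, dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Gaussian KDE (Scott's rule) per feature per class on a grid wide
    enough that each curve integrates to 1 within 1e-3."""
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    out: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for col in X.columns:
        out[col] = {}
        for cls in classes:
            vals = X[col].to_numpy(dtype=float)[y == cls]
            if len(vals) < 2:
                raise ValueError(f"class {cls} has < 2 subjects")
            sd = vals.std() if vals.std() > 0 else 1e-6
            grid = np.linspace(vals.min() - 5 * sd, vals.max() + 5 * sd, grid_points)
            dens = gaussian_kde(vals)(grid)
            out[col][int(cls)] = (grid, dens)
    return out


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_kde_grid(X: pd.DataFrame, y: np.ndarray, path=None):
    curves = kde_by_response(X, y)
    cols = list(X.columns)
    ncol = 5
    nrow = int(np.ceil(len(cols) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow))
    for ax, col in zip(np.ravel(axes), cols):
        for cls, (grid, dens) in curves[col].items():
            ax.fill_between(grid, dens, alpha=0.4, label=f"class {cls}")
        ax.set_title(col, fontsize=9)
        ax.set_yticks([])
    for ax in np.ravel(axes)[len(cols):]:
        ax.axis("off")
    np.ravel(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_correlation_heatmap(matrix: pd.DataFrame, path=None):
    cc = ward_order(matrix)
    M = cc.matrix.loc[cc.leaf_order, cc.leaf_order]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(M.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(M)), M.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(M)), M.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Kendall tau-b")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_roc_confusion(report: CVReport, path=None):
    """Per-fold ROC curves with the mean AUC +/- SD, plus the pooled
    confusion matrix."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.4))
    aucs = report.folds["auc"]
    for _, row in report.folds.iterrows():
        yt = np.asarray(row["y_test"])
        sc = np.asarray(row["prob"])
        order = np.argsort(-sc)
        yt = yt[order]
        tpr = np.r_[0, np.cumsum(yt) / max(yt.sum(), 1)]
        fpr = np.r_[0, np.cumsum(1 - yt) / max((1 - yt).sum(), 1)]
        ax1.plot(fpr, tpr, color="steelblue", alpha=0.15, lw=0.8)
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax1.set_xlabel("1 - specificity")
    ax1.set_ylabel("sensitivity")
    ax1.set_title(f"ROC-AUC {aucs.mean():.3f} (SD {aucs.std():.3f})")
    cm = report.pooled_confusion
    mat = np.array([[cm["tn"], cm["fp"]], [cm["fn"], cm["tp"]]])
    ax2.imshow(mat, cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax2.text(j, i, str(mat[i, j]), ha="center", va="center")
    ax2.set_xticks([0, 1], ["pred 0", "pred 1"])
    ax2.set_yticks([0, 1], ["true 0", "true 1"])
    ax2.set_title("pooled confusion")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_exemplar_meshes(mesh_low, mesh_high, feature: str = "", path=None):
    """Side-by-side 3D renders of the 10th- and 90th-percentile exemplar
    meshes of one feature."""
    fig = plt.figure(figsize=(9, 4.2))
    for i, (mesh, tag) in enumerate(
        ((mesh_low, "10th percentile"), (mesh_high, "90th percentile"))
    ):
        ax = fig.add_subplot(1, 2, i + 1, projection="3d")
        v, f = np.asarray(mesh.vertices), np.asarray(mesh.faces)
        ax.plot_trisurf(v[:, 0], v[:, 1], f, v[:, 2],
                        color="lightsteelblue", edgecolor="none")
        ax.set_title(f"{feature} {tag}".strip(), fontsize=9)
        ax.set_axis_off()
        ax.set_box_aspect(np.ptp(v, axis=0))
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_selection_frequency(report: CVReport, path=None):
    """Selection-frequency ranking with the response-correlation panel."""
    sf = selection_frequency(report)
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(max(6, 0.35 * len(sf)), 6), sharex=True
    )
    ax1.bar(sf["feature"], sf["frequency"], color="steelblue")
    ax1.set_ylabel(f"selected / {report.n_evaluations} folds")
    ax2.bar(sf["feature"], sf["response_correlation"], color="indianred")
    ax2.set_ylabel("Pearson r with response")
    ax2.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
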