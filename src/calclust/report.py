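"""Static report figures for a pipeline run.

Three views summarise a run: a dual-dendrogram heatmap of z-scored features
(cells x features, both axes ordered by their hierarchical trees), a
two-feature scatter coloured by Gaussian-mixture cluster, and an MDS scatter
of the raw traces coloured by imaging field.  Figures are written as PNG;
a small markdown summary ties them together.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cluster import ClusterModel, DEFAULT_GMM_COLUMNS
from .features import FEATURE_NAMES

_CLUSTER_COLORS = {
    "non_responder": "tab:blue",
    "oscillating_responder": "tab:red",
    "non_oscillating_responder": "tab:green",
}


def feature_heatmap(
    table: pd.DataFrame,
    cell_model: ClusterModel,
    feature_model: ClusterModel,
    path: str | Path,
) -> None:
    """Heatmap of z-scored features with rows/columns in dendrogram order."""
    feats = [c for c in table.columns if c in FEATURE_NAMES and c in feature_model.ids]
    z = (table[feats] - table[feats].mean()) / table[feats].std(ddof=0)
    row_order = cell_model.leaf_order
    col_order = [feature_model.ids.index(f) for f in feats]
    z = z.iloc[row_order, :].iloc[:, np.argsort(np.argsort(col_order))]
    ordered_feats = [feature_model.ids[i] for i in feature_model.leaf_order]
    z = z[ordered_feats]
    fig, ax = plt.subplots(figsize=(7, 8))
    vmax = np.nanpercentile(np.abs(z.to_numpy()), 98)
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(ordered_feats)))
    ax.set_xticklabels(ordered_feats, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel(f"{len(z)} cells (dendrogram order)")
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def gmm_scatter(table: pd.DataFrame, model: ClusterModel, path: str | Path) -> None:
    """Two-feature scatter coloured by mixture cluster (labelled if K=3)."""
    xcol, ycol = model.columns if len(model.columns) == 2 else DEFAULT_GMM_COLUMNS
    fig, ax = plt.subplots(figsize=(6, 5))
    for k in range(1, model.n_clusters + 1):
        mask = model.assignments == k
        label = model.labels.get(k, f"cluster_{k}")
        ax.scatter(
            table.loc[mask, xcol],
            table.loc[mask, ycol],
            s=14,
            alpha=0.8,
            color=_CLUSTER_COLORS.get(label),
            label=f"{label} (n={int(mask.sum())})",
        )
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    ax.legend(fontsize=8)
    ax.set_title(f"GMM ({model.covariance_family}), K={model.n_clusters} by BIC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mds_scatter(
    coordinates: np.ndarray, field_ids: list[str], path: str | Path, dims: tuple[int, int] = (0, 1)
) -> None:
    """MDS embedding of raw traces coloured by imaging field."""
    fig, ax = plt.subplots(figsize=(6, 5))
    fields = pd.Series(field_ids)
    for f in sorted(fields.unique()):
        mask = (fields == f).to_numpy()
        ax.scatter(coordinates[mask, dims[0]], coordinates[mask, dims[1]], s=14, alpha=0.8, label=f)
    ax.set_xlabel(f"MDS dimension {dims[0] + 1}")
    ax.set_ylabel(f"MDS dimension {dims[1] + 1}")
    ax.legend(fontsize=8, title="field")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bic_curves(bic_table: pd.DataFrame, path: str | Path) -> None:
    """BIC against K per covariance family; lower is better."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for fam, grp in bic_table.dropna(subset=["bic"]).groupby("family"):
        ax.plot(grp["k"], grp["bic"], marker="o", label=fam)
    ax.set_xlabel("number of mixture components K")
    ax.set_ylabel("BIC (-2 logL + p log n)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_summary(path: str | Path, sections: dict[str, str]) -> None:
    """Markdown report stitching the figures and tables of a run together."""
    lines = ["# Trace clustering report", ""]
    for title, body in sections.items():
        lines += [f"## {title}", "", body, ""]
    Path(path).write_text("\n".join(lines))


__all__ = ["feature_heatmap", "gmm_scatter", "mds_scatter", "bic_curves", "write_summary"]
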