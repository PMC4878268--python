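"""Model-free and model-based clustering of cells.

Model-free route: a rank-based dissimilarity between full traces,
d_ij = (1 - rho_ij)/2 with rho the Spearman correlation of cells i and j,
embedded by classical (Torgerson) multidimensional scaling; MDS dimensions
can be ranked by how well they separate imaging fields (mean silhouette
width), a quick screen for field/batch structure.  Hierarchical clustering
organises either cells (Ward linkage on z-scored features) or the features
themselves (average linkage on 1 - |Spearman| between columns) for heatmap
display.

Model-based route: Gaussian mixture models of selected features fitted by
EM across a range of component counts K and covariance families, with the
number of components chosen by the Bayesian Information Criterion
BIC = -2 log L + p log n (minimised; p = number of free parameters).
Mixture components of a K = 3 model on the two headline features
(high-glucose response and oscillation) are given biological labels:
non-responder, oscillating responder, non-oscillating responder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .features import FEATURE_NAMES
from .io import TraceDataset

NON_RESPONDER = "non_responder"
OSCILLATING = "oscillating_responder"
NON_OSCILLATING = "non_oscillating_responder"

DEFAULT_GMM_COLUMNS = ("high_glucose_response", "high_glucose_oscillation")
COVARIANCE_FAMILIES = ("spherical", "diag", "tied", "full")


@dataclass
class DistanceMatrix:
    """Symmetric cell-by-cell dissimilarity, entries in [0, 1]."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if self.matrix.min() < -1e-12 or self.matrix.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class ClusterModel:
    """A fitted clustering: hard assignments plus method-specific extras.

    ``assignments`` are 1-based cluster indices aligned with ``ids``.  GMM
    fits carry per-cell responsibilities, the per-candidate BIC table and
    the selected component means/covariances; hierarchical fits carry the
    linkage matrix and leaf order for heatmap rendering.
    """

    method: str  # "gmm" | "hierarchical"
    ids: list[str]
    n_clusters: int
    assignments: np.ndarray
    responsibilities: np.ndarray | None = None
    bic_table: pd.DataFrame | None = None
    means: np.ndarray | None = None
    covariances: np.ndarray | None = None
    covariance_family: str | None = None
    linkage_matrix: np.ndarray | None = None
    leaf_order: np.ndarray | None = None
    columns: tuple[str, ...] = ()
    labels: dict[int, str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.shape != (len(self.ids),):
            raise ValueError("one assignment per id required")
        if self.assignments.size and (
            self.assignments.min() < 1 or self.assignments.max() > self.n_clusters
        ):
            raise ValueError("assignments must lie in 1..n_clusters")
        if self.responsibilities is not None:
            rowsum = self.responsibilities.sum(axis=1)
            if not np.allclose(rowsum, 1.0, atol=1e-6):
                raise ValueError("responsibility rows must sum to 1")

    def assignment_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.ids,
                "method": self.method,
                "k": self.n_clusters,
                "cluster": self.assignments,
                "label": [self.labels.get(a, f"cluster_{a}") for a in self.assignments],
            }
        )
        if self.responsibilities is not None:
            df["responsibility"] = self.responsibilities[
                np.arange(len(self.ids)), self.assignments - 1
            ]
        return df


# ---------------------------------------------------------------------------
# model-free route
# ---------------------------------------------------------------------------


def spearman_distance(dataset: TraceDataset) -> DistanceMatrix:
    """Pairwise trace dissimilarity d_ij = (1 - rho_ij) / 2.

    rho is the Spearman rank correlation of the two full traces (average
    ranks on ties).  A constant trace has undefined rank correlation; its
    rho is treated as 0 (d = 0.5 to every other cell) with a warning.
    """
    if dataset.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if dataset.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints per trace")
    ranks = np.apply_along_axis(rankdata, 1, dataset.values)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant trace(s); their rank correlation is "
            "undefined and treated as 0 (distance 0.5)",
            stacklevel=2,
        )
        sd = np.where(constant, 1.0, sd)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    rho = (centered @ centered.T) / dataset.n_timepoints / np.outer(sd, sd)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    d = (1.0 - rho) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(ids=list(dataset.cell_ids), matrix=d)


def classical_mds(distance: DistanceMatrix, n_dims: int = 5) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a dissimilarity matrix.

    Double-centres the squared dissimilarities, eigendecomposes, and scales
    the top eigenvectors by the square roots of their (non-negative)
    eigenvalues.  Dimensions are ordered by decreasing eigenvalue.  The sign
    of each axis is fixed so its largest-magnitude coordinate is positive,
    making the embedding deterministic.
    """
    n = len(distance.ids)
    if not 1 <= n_dims < n:
        raise ValueError(f"n_dims must be in [1, {n - 1}], got {n_dims}")
    d2 = distance.matrix**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1][:n_dims]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def rank_dims_by_silhouette(
    coordinates: np.ndarray, field_ids: list[str], top_k: int = 5
) -> pd.DataFrame:
    """Rank MDS dimensions by field separation (mean silhouette width).

    For each embedding dimension, the mean silhouette width of all cells is
    computed on that single coordinate with imaging fields as group labels;
    dimensions are returned sorted by decreasing width.  Large widths flag
    dimensions dominated by between-field (batch-like) structure.
    """
    coordinates = np.atleast_2d(np.asarray(coordinates, float))
    labels = np.asarray(field_ids)
    if len(set(labels)) < 2:
        raise ValueError("silhouette ranking needs at least 2 imaging fields")
    n_dims = coordinates.shape[1]
    if top_k > n_dims:
        warnings.warn(
            f"top_k={top_k} exceeds the {n_dims} available dimensions; returning all",
            stacklevel=2,
        )
        top_k = n_dims
    widths = [
        silhouette_score(coordinates[:, [d]], labels, metric="euclidean")
        for d in range(n_dims)
    ]
    out = pd.DataFrame({"dimension": np.arange(n_dims), "mean_silhouette_width": widths})
    return out.sort_values("mean_silhouette_width", ascending=False, ignore_index=True).head(top_k)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def _zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    feats = table[[c for c in table.columns if c in FEATURE_NAMES]] if any(
        c in FEATURE_NAMES for c in table.columns
    ) else table
    numeric = feats.select_dtypes("number").astype(float)
    sd = numeric.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant feature column(s) before z-scoring: {constant}",
                      stacklevel=3)
        numeric = numeric.drop(columns=constant)
        sd = sd.drop(constant)
    return (numeric - numeric.mean()) / sd


def hierarchical_cluster(
    table: pd.DataFrame,
    axis: str = "cells",
    n_clusters: int | None = None,
    ids: list[str] | None = None,
) -> ClusterModel:
    """Agglomerative clustering of cells or of the features themselves.

    Cells: Euclidean distance on per-column z-scored features, Ward linkage.
    Features: dissimilarity 1 - |Spearman correlation| between feature
    columns, average linkage.  Constant feature columns are dropped with a
    warning.  When ``n_clusters`` is given, flat clusters are cut from the
    tree; the leaf order is always returned for heatmap rendering.
    """
    z = _zscore_columns(table)
    if axis == "cells":
        items = (
            ids
            if ids is not None
            else table["cell_id"].tolist() if "cell_id" in table.columns else list(map(str, z.index))
        )
        x = z.to_numpy()
        if len(items) < 2:
            raise ValueError("need at least 2 cells to cluster")
        link = linkage(x, method="ward", metric="euclidean")
    elif axis == "features":
        items = list(z.columns)
        if len(items) < 2:
            raise ValueError("need at least 2 feature columns to cluster")
        rho = np.corrcoef(np.apply_along_axis(rankdata, 0, z.to_numpy()).T)
        dist = 1.0 - np.abs(rho)
        np.fill_diagonal(dist, 0.0)
        link = linkage(squareform(np.clip((dist + dist.T) / 2, 0, None), checks=False),
                       method="average")
    else:
        raise ValueError(f"axis must be 'cells' or 'features', got {axis!r}")
    if n_clusters is None:
        assignments = np.ones(len(items), dtype=int)
        k = 1
    else:
        assignments = fcluster(link, t=n_clusters, criterion="maxclust")
        k = int(assignments.max())
    return ClusterModel(
        method="hierarchical",
        ids=[str(i) for i in items],
        n_clusters=k,
        assignments=assignments,
        linkage_matrix=link,
        leaf_order=leaves_list(link),
        columns=tuple(z.columns),
    )


# ---------------------------------------------------------------------------
# model-based route
# ---------------------------------------------------------------------------


def _min_variance(gm: GaussianMixture) -> float:
    cov = gm.covariances_
    if gm.covariance_type == "full":
        return float(min(np.linalg.eigvalsh(c).min() for c in cov))
    if gm.covariance_type == "tied":
        return float(np.linalg.eigvalsh(cov).min())
    return float(np.min(cov))


def gmm_bic_select(
    table: pd.DataFrame,
    columns: tuple[str, ...] = DEFAULT_GMM_COLUMNS,
    k_range: range | tuple[int, ...] = range(1, 9),
    covariance_families: tuple[str, ...] = COVARIANCE_FAMILIES,
    seed: int = 0,
    n_init: int = 10,
    variance_floor: float = 1e-8,
) -> ClusterModel:
    """Fit Gaussian mixtures over (K, covariance family) and select by BIC.

    Every candidate is fitted by EM with ``n_init`` k-means-initialised
    restarts seeded from ``seed``; the candidate minimising
    BIC = -2 log L + p log n wins.  Candidates whose smallest component
    variance collapses below ``variance_floor`` are discarded with a warning
    rather than regularised, keeping the BIC comparison across candidates
    honest.  All candidate BICs are retained in ``bic_table``.
    """
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns not in table: {missing}")
    x = table[list(columns)].to_numpy(float)
    if len(x) < 10:
        raise ValueError(f"need at least 10 cells to fit mixtures, got {len(x)}")
    ids = (
        table["cell_id"].astype(str).tolist()
        if "cell_id" in table.columns
        else [str(i) for i in table.index]
    )
    records = []
    best = None
    for family in covariance_families:
        for k in k_range:
            gm = GaussianMixture(
                n_components=int(k),
                covariance_type=family,
                n_init=n_init,
                init_params="kmeans",
                reg_covar=1e-10,
                max_iter=300,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    gm.fit(x)
                except Exception:
                    warnings.warn(f"GMM candidate ({family}, K={k}) failed to fit; discarded")
                    records.append({"family": family, "k": int(k), "bic": np.nan,
                                    "converged": False})
                    continue
            if _min_variance(gm) < variance_floor:
                warnings.warn(
                    f"GMM candidate ({family}, K={k}) degenerate "
                    f"(variance below {variance_floor:g}); discarded"
                )
                records.append({"family": family, "k": int(k), "bic": np.nan,
                                "converged": bool(gm.converged_)})
                continue
            bic = float(gm.bic(x))
            records.append({"family": family, "k": int(k), "bic": bic,
                            "converged": bool(gm.converged_)})
            if best is None or bic < best[0]:
                best = (bic, family, int(k), gm)
    if best is None:
        raise RuntimeError("every GMM candidate was degenerate or failed")
    _, family, k, gm = best
    resp = gm.predict_proba(x)
    assignments = resp.argmax(axis=1) + 1
    return ClusterModel(
        method="gmm",
        ids=ids,
        n_clusters=k,
        assignments=assignments,
        responsibilities=resp,
        bic_table=pd.DataFrame.from_records(records),
        means=gm.means_,
        covariances=gm.covariances_,
        covariance_family=family,
        columns=tuple(columns),
        seed=seed,
    )


def label_clusters(model: ClusterModel, table: pd.DataFrame) -> dict[int, str]:
    """Attach biological labels to the components of a K = 3 model.

    The cluster with the lowest mean high-glucose response is the
    non-responder group; of the remaining two, the one with the higher mean
    high-glucose oscillation is the oscillating responder group and the
    other the non-oscillating responder group.  Models with K != 3 receive
    generic ``cluster_<i>`` labels.  Exact ties in cluster means are broken
    by cluster index with a warning.  The mapping is stored on the model and
    returned.
    """
    if model.n_clusters != 3:
        model.labels = {k: f"cluster_{k}" for k in range(1, model.n_clusters + 1)}
        return model.labels
    for col in DEFAULT_GMM_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"feature column {col!r} required for labelling")
    resp_mean = {
        k: float(table.loc[np.asarray(model.assignments) == k, "high_glucose_response"].mean())
        for k in (1, 2, 3)
    }
    ordered = sorted(resp_mean, key=lambda k: (resp_mean[k], k))
    if resp_mean[ordered[0]] == resp_mean[ordered[1]]:
        warnings.warn("tied mean high-glucose response; labelling by cluster index")
    non_resp = ordered[0]
    rest = ordered[1:]
    osc_mean = {
        k: float(table.loc[np.asarray(model.assignments) == k, "high_glucose_oscillation"].mean())
        for k in rest
    }
    rest_sorted = sorted(rest, key=lambda k: (-osc_mean[k], k))
    if osc_mean[rest_sorted[0]] == osc_mean[rest_sorted[1]]:
        warnings.warn("tied mean high-glucose oscillation; labelling by cluster index")
    model.labels = {
        non_resp: NON_RESPONDER,
        rest_sorted[0]: OSCILLATING,
        rest_sorted[1]: NON_OSCILLATING,
    }
    return model.labels


def responder_proportion(model: ClusterModel) -> float:
    """Fraction of (QC-passing) cells in either responder cluster."""
    if not model.labels:
        raise ValueError("model has no cluster labels; call label_clusters first")
    responder_clusters = {
        k for k, lab in model.labels.items() if lab in {OSCILLATING, NON_OSCILLATING}
    }
    is_resp = np.isin(model.assignments, list(responder_clusters))
    return float(is_resp.mean())


__all__ = [
    "DistanceMatrix",
    "ClusterModel",
    "NON_RESPONDER",
    "OSCILLATING",
    "NON_OSCILLATING",
    "DEFAULT_GMM_COLUMNS",
    "COVARIANCE_FAMILIES",
    "spearman_distance",
    "classical_mds",
    "rank_dims_by_silhouette",
    "hierarchical_cluster",
    "gmm_bic_select",
    "label_clusters",
    "responder_proportion",
]
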