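"""Sample-level QC and protein-profile clustering.

Sample QC flags LC-MS runs with too few quantified peptide-charges or
with first-two-principal-component scores far from their design-cell
centroid. Protein profiles are z-scored per protein and clustered either
hierarchically (Euclidean distances) or with a self-organizing tree
(SOTA): a divisive, growing self-organizing map that repeatedly splits
the most heterogeneous cell into two children, yielding a binary tree of
expression-profile clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)


# -- PCA --------------------------------------------------------------------


def pca_scores(matrix: np.ndarray, n_components: int | None = None):
    """Principal-component scores of row observations via SVD of the
    column-centered matrix (covariance PCA). Returns (scores, loadings,
    explained_variance)."""
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or len(s)
    scores = U[:, :k] * s[:k]
    explained = s[:k] ** 2 / max(len(X) - 1, 1)
    return scores, Vt[:k], explained


# -- sample QC --------------------------------------------------------------


def flag_outlier_samples(
    table: pd.DataFrame,
    design: pd.DataFrame,
    min_peptides: int = 40000,
    pca_sd_mult: float = 3.0,
) -> pd.DataFrame:
    """Flag inconsistent LC-MS samples.

    A sample is flagged when its number of quantified peptide-charges is
    below ``min_peptides`` or when its (PC1, PC2) score — from covariance
    PCA of the per-sample protein abundance matrix (mean log10 intensity
    per protein, protein-mean imputed) — lies farther from its design-cell
    (strain x medium x time) centroid than ``pca_sd_mult`` pooled
    within-cell standard deviations.
    """
    counts = table.groupby("sample_id").size()
    mat = table.pivot_table(
        index="sample_id", columns="protein", values="log10_intensity", aggfunc="mean"
    )
    mat = mat.fillna(mat.mean(axis=0))
    out = design[design["sample_id"].isin(mat.index)][
        ["sample_id", "strain", "medium", "time"]
    ].copy()
    out["n_peptides"] = out["sample_id"].map(counts).fillna(0).astype(int)
    out["flag_low_count"] = out["n_peptides"] < min_peptides

    if len(mat) <= 2:
        warnings.warn("too few samples for the PCA criterion; skipped", stacklevel=2)
        out["pc1"] = out["pc2"] = out["pca_distance"] = np.nan
        out["flag_pca"] = False
    else:
        scores, _, _ = pca_scores(mat.to_numpy(), n_components=2)
        sc = pd.DataFrame(scores, index=mat.index, columns=["pc1", "pc2"])
        out = out.merge(sc, left_on="sample_id", right_index=True, how="left")
        cell = out.groupby(["strain", "medium", "time"])[["pc1", "pc2"]]
        centroids = cell.transform("mean")
        d = np.sqrt(((out[["pc1", "pc2"]] - centroids) ** 2).sum(axis=1))
        n_cells = len(out[["strain", "medium", "time"]].drop_duplicates())
        dof = max(len(out) - n_cells, 1)
        pooled_sd = float(np.sqrt((d**2).sum() / dof))
        out["pca_distance"] = d
        out["flag_pca"] = d > pca_sd_mult * pooled_sd if pooled_sd > 0 else False
    out["flagged"] = out["flag_low_count"] | out["flag_pca"]
    return out.reset_index(drop=True)


# -- hierarchical clustering ------------------------------------------------


@dataclass
class ClusterResult:
    ids: list
    labels: np.ndarray  # contiguous from 1
    metric: str
    method: str
    linkage: np.ndarray | None = None
    tree: list = field(default_factory=list)  # SOTA (cell_id, parent_id) records
    objective_trace: list = field(default_factory=list)


def hierarchical_cluster(
    matrix: pd.DataFrame | np.ndarray,
    n_clusters: int | None = None,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of row profiles with Euclidean distances
    (the default metric) and a configurable linkage. Deterministic."""
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(range(len(X)))
    if len(X) < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.isfinite(X).all():
        raise ValueError("missing values must be resolved before clustering")
    Z = hierarchy.linkage(X, method=method, metric=metric)
    if n_clusters is None:
        labels = np.ones(len(X), dtype=int)
    else:
        raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        _, labels = np.unique(raw, return_inverse=True)
        labels = labels + 1
    return ClusterResult(ids=ids, labels=labels, metric=metric, method=method, linkage=Z)


# -- profile scaling --------------------------------------------------------


def scale_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score (mean 0, population SD 1). Constant rows carry no
    profile information and are dropped with a log note."""
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.info(
            "dropping %d constant profile(s): %s",
            int(constant.sum()),
            list(np.asarray(matrix.index)[constant])[:10],
        )
    keep = ~constant
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(Z, index=matrix.index[keep], columns=matrix.columns)


# -- SOTA -------------------------------------------------------------------


def _mean_sq_dist(X: np.ndarray, center: np.ndarray) -> float:
    return float(((X - center) ** 2).sum(axis=1).mean()) if len(X) else 0.0


def sota_cluster(
    profiles: pd.DataFrame | np.ndarray,
    max_clusters: int,
    growth_threshold: float = 0.0,
    seed: int = 0,
    max_lloyd_iter: int = 50,
) -> ClusterResult:
    """Self-organizing tree clustering of (scaled) expression profiles.

    Starts from a single cell at the data centroid and grows a binary
    tree: the leaf with the largest resource (mean squared distance of
    its members to the cell vector) is split into two children — one at
    the parent vector, one at the member farthest from it — whose vectors
    are then refined by alternating nearest-cell assignment and centroid
    updates within the split cell. Growth stops when every leaf's
    resource is at or below ``growth_threshold`` or ``max_clusters``
    leaves exist. Deterministic given the seed.
    """
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    if isinstance(profiles, pd.DataFrame):
        ids = list(profiles.index)
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        ids = list(range(len(X)))
    n = len(X)
    assign = np.zeros(n, dtype=int)
    centers = [X.mean(axis=0)]
    tree = [(0, -1)]
    objective = [float(((X - centers[0]) ** 2).sum())]
    leaves = [0]

    while len(leaves) < max_clusters:
        resources = {
            c: _mean_sq_dist(X[assign == c], centers[c]) for c in leaves
        }
        grow = [c for c in leaves if resources[c] > growth_threshold and (assign == c).sum() > 1]
        if not grow:
            break
        parent = max(grow, key=lambda c: (resources[c], -c))
        members = np.where(assign == parent)[0]
        Xm = X[members]
        d = ((Xm - centers[parent]) ** 2).sum(axis=1)
        far = members[int(np.argmax(d))]
        c1, c2 = len(centers), len(centers) + 1
        centers.append(centers[parent].copy())
        centers.append(X[far].copy())
        tree.extend([(c1, parent), (c2, parent)])
        # refine the two children on the parent's members (winner-take-all
        # assignment + centroid update; monotone in the squared-distance
        # objective because child 1 starts at the parent vector)
        sub_assign = np.zeros(len(members), dtype=int)
        for _ in range(max_lloyd_iter):
            d1 = ((Xm - centers[c1]) ** 2).sum(axis=1)
            d2 = ((Xm - centers[c2]) ** 2).sum(axis=1)
            new_assign = (d2 < d1).astype(int)
            if (new_assign == sub_assign).all() and _ > 0:
                break
            sub_assign = new_assign
            for ci, mask in ((c1, sub_assign == 0), (c2, sub_assign == 1)):
                if mask.any():
                    centers[ci] = Xm[mask].mean(axis=0)
        assign[members[sub_assign == 0]] = c1
        assign[members[sub_assign == 1]] = c2
        leaves.remove(parent)
        leaves.extend([c1, c2])
        objective.append(
            float(
                sum(((X[assign == c] - centers[c]) ** 2).sum() for c in leaves)
            )
        )

    label_of = {c: i + 1 for i, c in enumerate(sorted(leaves))}
    labels = np.array([label_of[c] for c in assign])
    return ClusterResult(
        ids=ids,
        labels=labels,
        metric="euclidean",
        method="sota",
        tree=tree,
        objective_trace=objective,
    )


def heatmap_matrix(
    xic_abundance: pd.DataFrame,
    sc_abundance: pd.DataFrame,
    proteins: set[str],
) -> pd.DataFrame:
    """Per-protein abundance matrix for heatmaps: XIC values wherever a
    protein was quantified by XIC, spectral-count values otherwise (XIC is
    the finer method). Rows are proteins, columns samples."""
    xic = xic_abundance[xic_abundance.index.isin(proteins)]
    sc = sc_abundance[
        sc_abundance.index.isin(proteins) & ~sc_abundance.index.isin(xic.index)
    ]
    return pd.concat([xic, sc]).sort_index()
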