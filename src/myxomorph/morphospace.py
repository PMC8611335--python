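"""PCA morphospace, treatment clustering and diversification statistics.

The four plate-level traits (fruiting-body count and the per-plate medians
of area, density and density heterogeneity) live on incommensurate scales,
so observations are z-scored per trait before any multivariate step.  The
morphospace is the PCA of the standardized trait matrix; groups (ancestor
subclones, or the evolved populations of one treatment) are summarised by
their centroid across the three biological-replicate assays together with a
95% confidence region for that centroid.  Within-group morphological
diversification is the mean pairwise Euclidean distance among the
replicate-population trait vectors in standardized space, computed per
assay and then averaged across assays (mean ± s.e.m., n = 3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

__all__ = [
    "Standardizer",
    "PCAResult",
    "ConfidenceEllipse",
    "DiversificationScore",
    "standardize",
    "fit_pca",
    "centroid_and_ellipse",
    "cluster_treatments",
    "diversification",
    "diversification_table",
    "build_morphospace",
]


@dataclass
class Standardizer:
    """Per-column z-scoring with stored statistics for later projection."""

    mean_: np.ndarray
    std_: np.ndarray
    columns_: list[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.std_


@dataclass
class PCAResult:
    """Loadings, scores and explained-variance fractions of the morphospace."""

    loadings: np.ndarray  # (n_traits, n_components), orthonormal columns
    scores: np.ndarray  # (n_obs, n_components)
    explained_var: np.ndarray  # fractions, non-increasing, summing to 1

    def project(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=np.float64) @ self.loadings


@dataclass
class ConfidenceEllipse:
    """Small-sample (Hotelling) confidence region of a 2-D group centroid."""

    center: np.ndarray
    semi_axes: np.ndarray  # lengths along the principal axes
    angle_rad: float  # orientation of the first axis, CCW from +x
    confidence: float
    n: int
    degenerate: bool = False

    def contains(self, point: np.ndarray) -> bool:
        """Whether a point lies inside the region (Mahalanobis test)."""
        if self.degenerate:
            return bool(np.allclose(point, self.center))
        c, s = math.cos(self.angle_rad), math.sin(self.angle_rad)
        R = np.array([[c, s], [-s, c]])
        local = R @ (np.asarray(point, dtype=np.float64) - self.center)
        return float(np.sum((local / self.semi_axes) ** 2)) <= 1.0 + 1e-12


@dataclass
class DiversificationScore:
    """Within-group trait dispersion: mean pairwise distance, per assay."""

    group: str
    cycle: int | None
    per_assay: dict = field(default_factory=dict)  # assay_id -> score
    mean: float = math.nan
    sem: float = math.nan
    n_assays: int = 0
    analysable: bool = True


def standardize(
    table: pd.DataFrame | np.ndarray, columns: list[str] | None = None
) -> tuple[np.ndarray, Standardizer]:
    """Z-score each trait column (sample SD, ddof=1) of the reference set.

    Zero-variance traits are dropped with a warning; an all-constant table
    is an error.  Returns the standardized matrix and the fitted statistics
    so further observations can be projected into the same space.
    """
    if isinstance(table, pd.DataFrame):
        cols = columns if columns is not None else list(table.columns)
        X = table[cols].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(table, dtype=np.float64)
        cols = columns if columns is not None else [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least two observations")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    keep = std > 0
    if not keep.any():
        raise ValueError("all trait columns are constant; nothing to standardize")
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping zero-variance traits: {dropped}", stacklevel=2)
    scaler = Standardizer(
        mean_=mean[keep], std_=std[keep], columns_=[c for c, k in zip(cols, keep) if k]
    )
    return scaler.transform(X[:, keep]), scaler


def fit_pca(Z: np.ndarray) -> PCAResult:
    """Principal components of a standardized observation matrix.

    Components are the eigenvectors of the sample covariance, ordered by
    decreasing eigenvalue; each component's sign is fixed so its
    largest-magnitude loading is positive, making runs reproducible.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least two observations")
    if not np.any(Z.std(axis=0) > 0):
        raise ValueError("rank-0 input: no variance to decompose")
    pca = PCA(n_components=min(Z.shape))
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()  # columns are components
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    total = pca.explained_variance_.sum()
    explained = pca.explained_variance_ / total
    return PCAResult(loadings=loadings, scores=scores, explained_var=explained)


def centroid_and_ellipse(
    points: np.ndarray, confidence: float = 0.95
) -> tuple[np.ndarray, ConfidenceEllipse]:
    """Centroid of replicate points in the PC1-PC2 plane plus its
    Hotelling-type confidence region.

    For ``n`` replicate points with sample covariance ``S`` the region is
    ``{mu : n (xbar-mu)' S^-1 (xbar-mu) <= p(n-1)/(n-p) * F_{p,n-p}(conf)}``
    with ``p = 2``.  Collinear or identical replicates give a degenerate
    (zero-area) region, flagged as such.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of PC1-PC2 points")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("insufficient replicates: need at least 3 points")
    center = pts.mean(axis=0)
    S = np.cov(pts, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    p = 2
    if eigval[-1] <= 1e-12 * max(eigval[0], 1.0):
        ellipse = ConfidenceEllipse(
            center=center,
            semi_axes=np.zeros(2),
            angle_rad=float(math.atan2(eigvec[1, 0], eigvec[0, 0])),
            confidence=confidence,
            n=n,
            degenerate=True,
        )
        return center, ellipse
    fval = stats.f.ppf(confidence, p, n - p)
    scale2 = p * (n - 1) / (n * (n - p)) * fval
    semi_axes = np.sqrt(np.maximum(eigval, 0.0) * scale2)
    angle = float(math.atan2(eigvec[1, 0], eigvec[0, 0]))
    ellipse = ConfidenceEllipse(
        center=center, semi_axes=semi_axes, angle_rad=angle, confidence=confidence, n=n
    )
    return center, ellipse


def cluster_treatments(
    means: pd.DataFrame, k: int | None = None, method: str = "ward"
) -> dict:
    """Agglomerative clustering of treatment-level mean trait vectors.

    Euclidean distance in standardized trait space with Ward linkage by
    default.  Returns the linkage matrix, a flat cut at ``k`` clusters
    (when requested) and a Newick rendering of the dendrogram whose branch
    lengths are derived from merge heights.
    """
    if means.isna().any().any():
        bad = sorted(means.index[means.isna().any(axis=1)])
        raise ValueError(f"treatments with missing trait means: {bad}")
    if len(means) < 2:
        raise ValueError("clustering needs at least two treatments")
    X = means.to_numpy(dtype=np.float64)
    Zlink = hierarchy.linkage(X, method=method, metric="euclidean")
    labels = [str(i) for i in means.index]
    out = {"linkage": Zlink, "labels": labels, "newick": _linkage_to_newick(Zlink, labels)}
    if k is not None:
        flat = hierarchy.fcluster(Zlink, t=k, criterion="maxclust")
        out["flat"] = dict(zip(labels, (int(c) for c in flat)))
    return out


def _linkage_to_newick(Zlink: np.ndarray, labels: list[str]) -> str:
    root = hierarchy.to_tree(Zlink)

    # ultrametric convention: a node hangs below its parent's merge height
    def render(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

    return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"


def diversification(vectors: np.ndarray) -> float:
    """Mean pairwise Euclidean distance among population trait vectors.

    The within-group dispersion statistic for one assay: zero iff all
    replicate populations are identical, symmetric under relabeling, and
    it scales linearly when deviations from the group mean are scaled.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("diversification needs at least two populations")
    return float(pdist(X, metric="euclidean").mean())


def diversification_table(
    table: pd.DataFrame,
    scaler: Standardizer,
    group_col: str = "treatment",
    min_populations: int = 2,
) -> list[DiversificationScore]:
    """Per-group diversification scores with cross-assay mean ± s.e.m.

    ``table`` is a plate-level trait frame (one row per population per
    assay, single cycle); trait vectors are standardized with the supplied
    reference statistics.  Groups with fewer than ``min_populations``
    populations in every assay are flagged not-analysable (the fate of
    treatments with many early extinctions).  Rows with missing traits are
    excluded.
    """
    scores: list[DiversificationScore] = []
    for (grp,), sub in table.groupby([group_col], observed=True):
        cycle = int(sub["cycle"].iloc[0]) if "cycle" in sub.columns else None
        rec = DiversificationScore(group=str(grp), cycle=cycle)
        for assay, asub in sub.groupby("assay_id", observed=True):
            vals = asub[scaler.columns_].dropna()
            if len(vals) < min_populations:
                continue
            Zg = scaler.transform(vals.to_numpy(dtype=np.float64))
            rec.per_assay[str(assay)] = diversification(Zg)
        if not rec.per_assay:
            rec.analysable = False
        else:
            vals = np.array(list(rec.per_assay.values()))
            rec.mean = float(vals.mean())
            rec.sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
            rec.n_assays = len(vals)
        scores.append(rec)
    return scores


def build_morphospace(
    table: pd.DataFrame,
    trait_columns: list[str],
    group_col: str = "treatment",
    confidence: float = 0.95,
) -> dict:
    """Full morphospace for one cycle's plate-level trait table.

    Fits the standardization and PCA on every complete observation
    (ancestor subclones and all evolved populations, all assays), then
    summarises each group by its per-assay mean position in the PC1-PC2
    plane, the centroid of those assay points, and the centroid's 95%
    confidence ellipse (n = number of assays).

    Returns a dict with the scaler, PCA result, a scores frame (one row
    per observation) and per-group centroid/ellipse entries.
    """
    complete = table.dropna(subset=trait_columns)
    n_dropped = len(table) - len(complete)
    Z, scaler = standardize(complete, columns=trait_columns)
    pca = fit_pca(Z)
    scores = complete[[c for c in ("assay_id", "cycle", group_col, "population_id") if c in complete.columns]].copy()
    for k in range(pca.scores.shape[1]):
        scores[f"PC{k + 1}"] = pca.scores[:, k]

    groups = {}
    for (grp,), sub in scores.groupby([group_col], observed=True):
        assay_pts = sub.groupby("assay_id", observed=True)[["PC1", "PC2"]].mean().to_numpy()
        if assay_pts.shape[0] < 3:
            groups[str(grp)] = {"assay_points": assay_pts, "centroid": assay_pts.mean(axis=0), "ellipse": None}
            continue
        center, ellipse = centroid_and_ellipse(assay_pts, confidence=confidence)
        groups[str(grp)] = {"assay_points": assay_pts, "centroid": center, "ellipse": ellipse}
    return {
        "scaler": scaler,
        "pca": pca,
        "scores": scores,
        "groups": groups,
        "n_excluded_incomplete": n_dropped,
    }
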