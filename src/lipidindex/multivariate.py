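"""Multivariate analysis of the functional index matrix.

PCA and PLS-DA operate on a complete, scaled matrix: indices with more than
a configurable fraction of NA values (default 20%) are dropped, the
remaining NAs are imputed with the per-index median, zero-variance columns
are removed and the matrix is centered and auto-scaled by default
(center-only and Pareto scaling are available).

VIP (variable importance in projection) for PLS-DA follows the standard
definition

    VIP_j = sqrt( p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a )

with SSY_a the Y sum of squares explained by component a, so that the mean
squared VIP over the p indices is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

SCALINGS = ("autoscale", "center", "pareto")

#: the seven selectable distance options for the clustered heatmap
DISTANCES = (
    "euclidean",
    "manhattan",
    "chebyshev",
    "canberra",
    "minkowski3",
    "correlation",
    "spearman",
)

LINKAGES = ("complete", "average", "single", "ward")


@dataclass
class ScaledMatrix:
    data: pd.DataFrame  # samples x indices, complete
    method: str
    dropped: list[str] = field(default_factory=list)
    imputed: int = 0


def scale_matrix(
    index_values: pd.DataFrame,
    method: str = "autoscale",
    max_na_fraction: float = 0.2,
) -> ScaledMatrix:
    """Prepare a complete, scaled samples x indices matrix."""
    if method not in SCALINGS:
        raise ValueError(f"unknown scaling {method!r}; choose from {SCALINGS}")
    if index_values.shape[0] < 3:
        raise ValueError("multivariate analysis needs at least 3 samples")
    df = index_values.copy()
    na_frac = df.isna().mean(axis=0)
    dropped = list(df.columns[na_frac > max_na_fraction])
    df = df.drop(columns=dropped)
    imputed = int(df.isna().to_numpy().sum())
    if imputed:
        df = df.fillna(df.median(axis=0))
    sd = df.std(axis=0, ddof=1)
    constant = list(df.columns[(sd == 0) | sd.isna()])
    df = df.drop(columns=constant)
    dropped.extend(constant)
    if df.shape[1] < 2:
        raise ValueError("fewer than 2 usable indices after NA/variance filtering")
    centered = df - df.mean(axis=0)
    if method == "autoscale":
        centered = centered / df.std(axis=0, ddof=1)
    elif method == "pareto":
        centered = centered / np.sqrt(df.std(axis=0, ddof=1))
    return ScaledMatrix(data=centered, method=method, dropped=dropped, imputed=imputed)


@dataclass
class LatentModel:
    """Scores/loadings decomposition of the index matrix."""

    kind: str  # "pca" | "plsda"
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # indices x components
    explained: np.ndarray  # per-component fraction of X variance
    vip: Optional[pd.Series] = None  # PLS-DA only
    groups: Optional[pd.Series] = None


def pca(scaled: ScaledMatrix, n_components: Optional[int] = None) -> LatentModel:
    """SVD-based principal component analysis of the scaled index matrix."""
    X = scaled.data.to_numpy(dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    n_components = max_comp if n_components is None else min(n_components, max_comp)
    fit = PCA(n_components=n_components, svd_solver="full").fit(X)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    return LatentModel(
        kind="pca",
        scores=pd.DataFrame(fit.transform(X), index=scaled.data.index, columns=comps),
        loadings=pd.DataFrame(fit.components_.T, index=scaled.data.columns, columns=comps),
        explained=fit.explained_variance_ratio_,
    )


def _one_hot(groups: pd.Series) -> np.ndarray:
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("PLS-DA needs at least two groups")
    return np.column_stack([(groups == lab).to_numpy(dtype=float) for lab in labels])


def vip_scores(pls: PLSRegression, feature_names: Sequence[str]) -> pd.Series:
    """VIP from a fitted NIPALS PLS model (x_weights_ columns are unit norm)."""
    t = pls.x_scores_
    w = pls.x_weights_
    q = pls.y_loadings_
    p = w.shape[0]
    ssy = np.sum(t**2, axis=0) * np.sum(q**2, axis=0)  # per-component SSY
    vip = np.sqrt(p * (w**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=list(feature_names), name="VIP")


def plsda(
    scaled: ScaledMatrix, groups: pd.Series, n_components: int = 2
) -> LatentModel:
    """PLS discriminant analysis (PLS2 on one-hot group membership)."""
    groups = groups.reindex(scaled.data.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label for PLS-DA")
    Y = _one_hot(groups)
    X = scaled.data.to_numpy(dtype=float)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pls = PLSRegression(n_components=n_components, scale=False).fit(X, Y)
    comps = [f"LV{i + 1}" for i in range(n_components)]
    t = pls.x_scores_
    pload = pls.x_loadings_
    total_ssx = (X - X.mean(axis=0)).__pow__(2).sum()
    explained = np.array(
        [(t[:, a] ** 2).sum() * (pload[:, a] ** 2).sum() / total_ssx for a in range(n_components)]
    )
    return LatentModel(
        kind="plsda",
        scores=pd.DataFrame(t, index=scaled.data.index, columns=comps),
        loadings=pd.DataFrame(pload, index=scaled.data.columns, columns=comps),
        explained=explained,
        vip=vip_scores(pls, scaled.data.columns),
        groups=groups,
    )


def hotelling_ellipse(points: np.ndarray, level: float = 0.95) -> dict:
    """95% Hotelling T^2 confidence ellipse parameters for 2-D scores."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("an ellipse needs at least 3 points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T)
    fcrit = sps.f.ppf(level, 2, n - 2)
    scale = 2 * (n - 1) / (n - 2) * fcrit  # Hotelling T^2 bound
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return {
        "center": mean,
        "width": 2 * np.sqrt(max(evals[0], 0) * scale),
        "height": 2 * np.sqrt(max(evals[1], 0) * scale),
        "angle_deg": float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0]))),
    }


def _distance_matrix(X: np.ndarray, distance: str) -> np.ndarray:
    if distance == "manhattan":
        return pdist(X, metric="cityblock")
    if distance == "minkowski3":
        return pdist(X, metric="minkowski", p=3)
    if distance == "spearman":
        ranked = np.apply_along_axis(sps.rankdata, 1, X)
        return pdist(ranked, metric="correlation")
    if distance in ("euclidean", "chebyshev", "canberra", "correlation"):
        return pdist(X, metric=distance)
    raise ValueError(f"unknown distance {distance!r}; choose from {DISTANCES}")


@dataclass
class HeatmapResult:
    matrix: pd.DataFrame  # reordered samples x indices
    sample_linkage: np.ndarray
    index_linkage: np.ndarray
    distance: str
    linkage: str


def cluster_heatmap(
    index_values: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
    top_n: Optional[int] = None,
    scaling: str = "autoscale",
) -> HeatmapResult:
    """Hierarchical clustering of both samples and indices.

    ``top_n`` keeps the most variable indices (clamped, with a warning-style
    no-op, when larger than the available panel).  Seven distance options
    are supported (:data:`DISTANCES`) and four linkage methods.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    scaled = scale_matrix(index_values, method=scaling)
    df = scaled.data
    if top_n is not None:
        top_n = min(top_n, df.shape[1])
        keep = df.var(axis=0, ddof=1).sort_values(ascending=False).index[:top_n]
        df = df[[c for c in df.columns if c in set(keep)]]
    sample_link = hierarchy.linkage(_distance_matrix(df.to_numpy(), distance), method=linkage)
    index_link = hierarchy.linkage(_distance_matrix(df.to_numpy().T, distance), method=linkage)
    sample_order = hierarchy.leaves_list(sample_link)
    index_order = hierarchy.leaves_list(index_link)
    ordered = df.iloc[sample_order, index_order]
    return HeatmapResult(
        matrix=ordered,
        sample_linkage=sample_link,
        index_linkage=index_link,
        distance=distance,
        linkage=linkage,
    )
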