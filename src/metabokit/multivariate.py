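"""Multivariate exploration: PCA and PLS-DA scores/loadings, group
confidence ellipses, clustered-heatmap layout (overview and auto-sized
detail view), correlation maps, and two-factor block clustering.

PLS-DA is a NIPALS-style latent-variable fit of the one-hot group indicator
on the centered data, with deflation on X only; VIP (variable importance in
projection) summarizes each feature's contribution, normalized so the mean
squared VIP over features is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core_data import DataTable, DataTableError

#: Detail-view geometry (pixels).
CELL_HEIGHT = 12
HEADER_HEIGHT = 120
OVERVIEW_SIZE = (900, 720)
#: Features beyond this cap are dropped (top variance retained) before
#: clustering in detail view.
FEATURE_CAP = 2000

MAX_PLS_COMPONENTS = 5


@dataclass
class ScoresLoadings:
    """Scores, loadings and explained-variance shares of a decomposition."""

    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    explained: np.ndarray           # proportion per component
    vip: pd.Series | None = None    # PLS-DA only
    method: str = "pca"


@dataclass
class HeatmapSpec:
    """Layout of a clustered heatmap: orderings, dendrograms and image size."""

    row_order: list
    col_order: list
    row_tree: np.ndarray | None     # scipy linkage matrix over samples
    col_tree: np.ndarray | None     # scipy linkage matrix over features
    color_scale: dict = field(default_factory=dict)
    image_width: int = OVERVIEW_SIZE[0]
    image_height: int = OVERVIEW_SIZE[1]
    view: str = "overview"
    notes: list = field(default_factory=list)
    blocks: list | None = None      # (label, start, stop) sample blocks


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _fix_signs(loadings: np.ndarray, *companions: np.ndarray):
    """Deterministic sign convention: the largest-|.| loading entry of each
    component is positive.  Companion matrices flip with the loadings."""
    for a in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, a]))
        if loadings[pivot, a] < 0:
            loadings[:, a] *= -1
            for c in companions:
                c[:, a] *= -1
    return loadings


def pca(dt: DataTable, n_components: int = 2) -> ScoresLoadings:
    """Column-mean-centered principal component analysis via SVD."""
    x = dt.values.to_numpy(dtype=float)
    max_comp = min(dt.n_samples - 1, dt.n_features)
    if not 1 <= n_components <= max_comp:
        raise DataTableError(
            f"n_components must be in [1, {max_comp}] for this table")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    load = vt[:n_components].T.copy()
    scores = xc @ load
    _fix_signs(load, scores)
    total_var = (s ** 2).sum()
    explained = (s[:n_components] ** 2) / total_var if total_var > 0 else \
        np.zeros(n_components)
    comp = [f"PC{i + 1}" for i in range(n_components)]
    return ScoresLoadings(
        scores=pd.DataFrame(scores, index=dt.values.index, columns=comp),
        loadings=pd.DataFrame(load, index=dt.values.columns, columns=comp),
        explained=explained, method="pca")


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def plsda(dt: DataTable, n_components: int = 2) -> ScoresLoadings:
    """PLS discriminant analysis of the group factor (one-hot encoded).

    NIPALS components maximize X–Y covariance; ``explained`` holds the
    Y-variance captured per component, and ``vip`` the per-feature VIP
    scores.
    """
    levels = dt.group_levels()
    if len(levels) < 2:
        raise DataTableError("PLS-DA needs at least 2 groups")
    n_components = min(n_components, MAX_PLS_COMPONENTS)
    x = dt.values.to_numpy(dtype=float)
    y = np.column_stack([(dt.group == g).to_numpy(dtype=float) for g in levels])
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if n_components > rank:
        raise DataTableError(f"n_components exceeds data rank {rank}")

    n, p = xc.shape
    W = np.zeros((p, n_components))   # X weights
    T = np.zeros((n, n_components))   # X scores
    P = np.zeros((p, n_components))   # X loadings
    ssy_total = (yc ** 2).sum()
    ssy_explained = np.zeros(n_components)
    xa, ya = xc.copy(), yc.copy()
    for a in range(n_components):
        # dominant eigenvector of X'YY'X via power iteration on X'Y
        m = xa.T @ ya
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        w = u[:, 0]
        t = xa @ w
        tt = float(t @ t)
        if tt <= 0:
            raise DataTableError("degenerate component in PLS-DA")
        pvec = xa.T @ t / tt
        q = ya.T @ t / tt
        ssy_explained[a] = tt * float(q @ q)
        W[:, a], T[:, a], P[:, a] = w, t, pvec
        xa = xa - np.outer(t, pvec)   # deflate X only
    _fix_signs(W, T, P)
    explained = ssy_explained / ssy_total if ssy_total > 0 else ssy_explained

    # VIP_j = sqrt( p * sum_a ssy_a * (w_ja / ||w_a||)^2 / sum_a ssy_a )
    wnorm2 = (W ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (W ** 2) / wnorm2
    denom = ssy_explained.sum()
    vip = np.sqrt(p * (contrib @ ssy_explained) / denom) if denom > 0 else \
        np.full(p, 1.0)
    comp = [f"Comp{i + 1}" for i in range(n_components)]
    return ScoresLoadings(
        scores=pd.DataFrame(T, index=dt.values.index, columns=comp),
        loadings=pd.DataFrame(P, index=dt.values.columns, columns=comp),
        explained=explained,
        vip=pd.Series(vip, index=dt.values.columns, name="VIP"),
        method="plsda")


# ---------------------------------------------------------------------------
# Confidence ellipses
# ---------------------------------------------------------------------------

@dataclass
class Ellipse:
    group: object
    center: np.ndarray
    axes: np.ndarray      # semi-axis lengths, major first
    angle: float          # radians, major axis vs first score axis
    degenerate: bool = False


def confidence_ellipse(scores: pd.DataFrame, group: pd.Series,
                       level: float = 0.95) -> list[Ellipse]:
    """Per-group scatter ellipses on a 2D scores plot.

    The region is the ``level`` chi-square (2 df) contour of the group's
    sample mean and covariance — a confidence region for the group scatter.
    Collinear groups yield a flagged degenerate ellipse.
    """
    if scores.shape[1] != 2:
        raise DataTableError("confidence_ellipse expects exactly 2 score columns")
    if not 0 < level < 1:
        raise DataTableError("level must be in (0, 1)")
    q = stats.chi2.ppf(level, df=2)
    out = []
    for g in sorted(group.dropna().unique().tolist()):
        pts = scores.loc[group[group == g].index].to_numpy(dtype=float)
        if pts.shape[0] < 3:
            raise DataTableError(f"group {g!r} has fewer than 3 samples")
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        evals = evals[::-1]
        evecs = evecs[:, ::-1]
        degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1.0))
        axes = np.sqrt(np.clip(evals, 0, None) * q)
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        out.append(Ellipse(group=g, center=center, axes=axes, angle=angle,
                           degenerate=degenerate))
    return out


# ---------------------------------------------------------------------------
# Clustered heatmaps
# ---------------------------------------------------------------------------

def _distance(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return pdist(x, metric="euclidean")
    if metric == "pearson":
        return pdist(x, metric="correlation")
    raise DataTableError(f"unknown distance {metric!r}")


def _linkage(x: np.ndarray, metric: str, method: str) -> np.ndarray:
    if method not in ("ward", "average", "complete"):
        raise DataTableError(f"unknown linkage {method!r}")
    return hierarchy.linkage(_distance(x, metric), method=method)


def _color_scale(values: np.ndarray) -> dict:
    lim = float(np.nanpercentile(np.abs(values), 99))
    lim = lim if lim > 0 else 1.0
    return {"cmap": "RdBu_r", "vmin": -lim, "vmax": lim}


def hclust_heatmap(dt: DataTable, distance: str = "euclidean",
                   linkage: str = "ward", view: str = "overview",
                   feature_cap: int = FEATURE_CAP) -> HeatmapSpec:
    """Hierarchical clustering of samples and features with image sizing.

    Overview uses a fixed canvas; detail view grows the image height
    linearly with the feature count (``HEADER_HEIGHT + CELL_HEIGHT * m``) so
    every row stays legible, retaining at most ``feature_cap`` top-variance
    features.
    """
    if view not in ("overview", "detail"):
        raise DataTableError("view must be 'overview' or 'detail'")
    if dt.n_samples < 2 or dt.n_features < 1:
        raise DataTableError("heatmap needs at least 2 samples and 1 feature")
    vals = dt.values
    notes = []
    if dt.n_features > feature_cap:
        keep = vals.var(ddof=1).sort_values(ascending=False).index[:feature_cap]
        keep = [c for c in vals.columns if c in set(keep)]
        vals = vals[keep]
        notes.append(f"retained top {feature_cap} features by variance "
                     f"out of {dt.n_features}")
    x = vals.to_numpy(dtype=float)
    row_tree = _linkage(x, distance, linkage)
    row_order = [vals.index[i] for i in hierarchy.leaves_list(row_tree)]
    if vals.shape[1] >= 2:
        col_tree = _linkage(x.T, distance, linkage)
        col_order = [vals.columns[i] for i in hierarchy.leaves_list(col_tree)]
    else:
        col_tree = None
        col_order = list(vals.columns)
    if view == "detail":
        width, height = OVERVIEW_SIZE[0], HEADER_HEIGHT + CELL_HEIGHT * len(col_order)
    else:
        width, height = OVERVIEW_SIZE
    return HeatmapSpec(row_order=row_order, col_order=col_order,
                       row_tree=row_tree, col_tree=col_tree,
                       color_scale=_color_scale(x), image_width=width,
                       image_height=height, view=view, notes=notes)


def correlation_map(dt: DataTable, axis: str = "features",
                    method: str = "pearson"):
    """Feature–feature (or sample–sample) correlation matrix with a
    clustered ordering.

    Zero-variance vectors have undefined correlations; they are reported as
    missing and excluded from the clustering.
    """
    if axis not in ("features", "samples"):
        raise DataTableError("axis must be 'features' or 'samples'")
    if method not in ("pearson", "spearman"):
        raise DataTableError("method must be 'pearson' or 'spearman'")
    frame = dt.values if axis == "features" else dt.values.T
    if frame.shape[0] < 3:
        raise DataTableError("need at least 3 observations per correlated pair")
    corr = frame.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    ok = [c for c in corr.columns if frame[c].std(ddof=1) > 0]
    sub = corr.loc[ok, ok]
    d = squareform(np.clip(1 - sub.to_numpy(), 0, None), checks=False)
    tree = hierarchy.linkage(d, method="average")
    order = [sub.index[i] for i in hierarchy.leaves_list(tree)]
    order += [c for c in corr.columns if c not in set(ok)]
    spec = HeatmapSpec(row_order=order, col_order=order, row_tree=tree,
                       col_tree=tree,
                       color_scale={"cmap": "RdBu_r", "vmin": -1, "vmax": 1})
    return corr, spec


def two_factor_cluster(dt: DataTable, distance: str = "euclidean",
                       linkage: str = "ward") -> HeatmapSpec:
    """Two-factor layout: samples ordered in (group, factor2) blocks rather
    than clustered; features clustered as usual."""
    if dt.factor2 is None:
        raise DataTableError("two_factor_cluster requires a second factor")
    keys = sorted(dt.values.index,
                  key=lambda s: (str(dt.group[s]), str(dt.factor2[s]), str(s)))
    x = dt.values.to_numpy(dtype=float)
    col_tree = _linkage(x.T, distance, linkage)
    col_order = [dt.values.columns[i] for i in hierarchy.leaves_list(col_tree)]
    blocks = []
    start = 0
    for i in range(1, len(keys) + 1):
        label = (str(dt.group[keys[i - 1]]), str(dt.factor2[keys[i - 1]]))
        if i == len(keys) or (str(dt.group[keys[i]]), str(dt.factor2[keys[i]])) != label:
            blocks.append((label, start, i))
            start = i
    return HeatmapSpec(row_order=keys, col_order=col_order, row_tree=None,
                       col_tree=col_tree, color_scale=_color_scale(x),
                       view="overview", blocks=blocks)
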