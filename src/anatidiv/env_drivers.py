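"""Environmental drivers of diversity: predictor construction and modeling.

This module covers four stages:

* productivity summaries from a dekadal (10-day composite) vegetation-index
  stack: growing-season peak (95th percentile), seasonality (within-year
  SD), interannual variation (SD of yearly peaks) and 3x3 spatial
  heterogeneity;
* iterative variance-inflation-factor (VIF) screening of the predictor set
  (drop the worst offender, recompute, repeat while max VIF > 10);
* Moran's I with permutation p-values on the cell lattice (queen
  contiguity, row-standardized weights), which motivates including cell
  latitude/longitude as covariates in the forests;
* regression random forests (1,000 trees, 11 candidate predictors per
  split) with out-of-bag variance explained, OOB permutation importance
  scaled to sum 100, minimal-depth predictor ranking and partial-dependence
  curves with a per-tree standard error band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils import check_random_state

__all__ = [
    "NDVIStack",
    "ndvi_summaries",
    "ndvi_summary_table",
    "vif_screen",
    "morans_i",
    "DriverModel",
    "fit_driver_model",
    "importance_scaled",
    "minimal_depth",
    "partial_dependence",
]


# ---------------------------------------------------------------------------
# productivity summaries


@dataclass
class NDVIStack:
    """Sub-cell vegetation-index series: (cells, p, p, years, dekads) in [-1, 1]."""

    data: np.ndarray
    cell_ids: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 5:
            raise ValueError("NDVI stack must be 5-dimensional (cells, p, p, years, dekads)")
        if self.data.shape[0] != len(self.cell_ids):
            raise ValueError("cell count mismatch")
        if np.nanmax(np.abs(self.data)) > 1 + 1e-9:
            raise ValueError("NDVI values must lie in [-1, 1]")

    def cell(self, i: int) -> np.ndarray:
        return self.data[i]


def ndvi_summaries(cell_series: np.ndarray) -> dict[str, float]:
    """Four productivity summaries for one cell's (p, p, years, dekads) block.

    mn: per-pixel 95th percentile over all year x dekad values, averaged over
    pixels.  season: per-pixel mean over years of the SD over dekads,
    averaged over pixels.  annvar: per-pixel SD over the yearly 95th
    percentiles, averaged over pixels.  het: SD of each full 3x3 window of
    the pixel-mean map, averaged over window positions (NaN when p < 3).
    All SDs use the n-1 denominator.
    """
    arr = np.asarray(cell_series, float)
    p1, p2, n_years, n_dekads = arr.shape
    flat = arr.reshape(p1, p2, n_years * n_dekads)
    mn = float(np.percentile(flat, 95, axis=-1).mean())
    # SDs are computed on slices centered on their first element: the SD is
    # translation-invariant, and this makes constant input give exactly 0
    season = float((arr - arr[..., :1]).std(axis=-1, ddof=1).mean(axis=-1).mean())
    yearly_peak = np.percentile(arr, 95, axis=-1)          # (p, p, years)
    annvar = float((yearly_peak - yearly_peak[..., :1]).std(axis=-1, ddof=1).mean())
    if min(p1, p2) < 3:
        het = float("nan")
    else:
        mean_map = flat.mean(axis=-1)
        sds = [
            (w - w[0, 0]).std(ddof=1)
            for w in (
                mean_map[i:i + 3, j:j + 3]
                for i in range(p1 - 2)
                for j in range(p2 - 2)
            )
        ]
        het = float(np.mean(sds))
    return {"mn": mn, "season": season, "annvar": annvar, "het": het}


def ndvi_summary_table(stack: NDVIStack, prefix: str = "NDVI") -> pd.DataFrame:
    """Summaries for every cell, with the study's column naming convention."""
    rows = [ndvi_summaries(stack.cell(i)) for i in range(len(stack.cell_ids))]
    out = pd.DataFrame(rows, index=stack.cell_ids)
    out.columns = [f"mn.{prefix}", f"season.{prefix}", f"annvar.{prefix}", f"het.{prefix}"]
    out.index.name = "cell_id"
    return out


# ---------------------------------------------------------------------------
# multicollinearity


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_k = 1/(1 - R^2) of column k regressed (with intercept) on the rest."""
    n, p = X.shape
    vifs = np.empty(p)
    for k in range(p):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            vifs[k] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        vifs[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_screen(
    X: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF predictor while max VIF > threshold.

    Returns the retained column names and the drop trace (one row per
    iteration: dropped predictor and its VIF at the time; +inf marks exact
    collinearity).  Exact ties on the maximum are resolved by dropping the
    later column in the current column order, so of two identical columns
    the second goes.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF screening needs more rows than predictors")
    cols = list(X.columns)
    trace = []
    while len(cols) >= 2:
        vifs = _vif_values(X[cols].to_numpy(float))
        vmax = vifs.max()
        if vmax <= threshold:
            break
        k = int(np.flatnonzero(vifs == vmax)[-1])   # later column on exact ties
        trace.append((cols[k], float(vmax), len(trace) + 1))
        cols.pop(k)
    trace_df = pd.DataFrame(trace, columns=["dropped", "vif", "iteration"])
    return cols, trace_df


# ---------------------------------------------------------------------------
# spatial autocorrelation


NEIGHBOR_OFFSETS = {
    "rook": ((-1, 0), (1, 0), (0, -1), (0, 1)),
    "queen": ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def _lattice_weights(lat: np.ndarray, lon: np.ndarray, contiguity: str = "rook") -> sparse.csr_matrix:
    """Row-standardized contiguity weights on the (lat, lon) lattice.

    Rook (4-neighbor) contiguity is the default: it is the sharpest detector
    of alternating small-scale structure, which queen contiguity partly
    cancels through the diagonal neighbors.
    """
    ulat = np.unique(lat)
    ulon = np.unique(lon)
    ri = np.searchsorted(ulat, lat)
    ci = np.searchsorted(ulon, lon)
    index = {(r, c): k for k, (r, c) in enumerate(zip(ri, ci))}
    rows, cols = [], []
    for k, (r, c) in enumerate(zip(ri, ci)):
        for dr, dc in NEIGHBOR_OFFSETS[contiguity]:
            nb = index.get((r + dr, c + dc))
            if nb is not None:
                rows.append(k)
                cols.append(nb)
    n = len(lat)
    W = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sparse.diags(1.0 / deg) @ W


def morans_i(
    values: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    contiguity: str = "rook",
) -> tuple[float, float]:
    """Moran's I with a two-sided permutation p-value.

    Weights are row-standardized lattice contiguity (rook by default, queen
    available) inferred from the unique sorted latitude/longitude values
    (cells are assumed to sit on a regular lattice).  The permutation test
    shuffles the values over cells;
    two-sidedness folds the null distribution around the theoretical
    expectation E[I] = -1/(n-1).  Constant input yields (nan, nan).
    """
    z = np.asarray(values, float)
    n = len(z)
    if n < 9:
        raise ValueError("Moran's I needs at least 9 cells")
    if np.all(z == z[0]):
        return float("nan"), float("nan")
    rng = rng or np.random.default_rng()
    W = _lattice_weights(np.asarray(lat, float), np.asarray(lon, float), contiguity)
    zc = z - z.mean()
    denom = float(zc @ zc)
    # row-standardized W sums to n, so I reduces to z'Wz / z'z
    i_obs = float(zc @ (W @ zc)) / denom
    e_i = -1.0 / (n - 1)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Zp = zc[perms]                         # (n_perm, n)
    i_perm = np.einsum("ij,ij->i", Zp, (W @ Zp.T).T) / denom
    extreme = np.abs(i_perm - e_i) >= np.abs(i_obs - e_i) - 1e-15
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return i_obs, float(p)


# ---------------------------------------------------------------------------
# random forest driver models


def _bootstrap_indices(estimator, n_samples: int) -> np.ndarray:
    """Reproduce the bootstrap sample indices of one fitted forest member.

    scikit-learn draws them as ``randint(0, n, n)`` from the estimator's
    seeded RandomState; the reconstruction is verified against the forest's
    own OOB predictions in the test suite.
    """
    rs = check_random_state(estimator.random_state)
    return rs.randint(0, n_samples, n_samples)


@dataclass
class DriverModel:
    """A fitted per-hemisphere random-forest model for one diversity index."""

    hemisphere: str
    response: str
    predictors: list[str]                 # model predictors incl. coordinates
    coordinate_cols: list[str]
    forest: RandomForestRegressor
    X: pd.DataFrame = field(repr=False)
    y: pd.Series = field(repr=False)
    var_explained: float = float("nan")   # OOB, percent
    raw_importance: pd.Series | None = None
    minimal_depth_: pd.Series | None = None

    def importance(self, include_coordinates: bool = False) -> pd.Series:
        return importance_scaled(self, include_coordinates=include_coordinates)

    def top_predictors(self, n: int = 5, include_coordinates: bool = False) -> list[str]:
        md = self.minimal_depth_
        if not include_coordinates:
            md = md.drop(index=[c for c in self.coordinate_cols if c in md.index])
        return list(md.sort_values().index[:n])

    def partial_dependence(self, predictor: str, grid_size: int = 25) -> pd.DataFrame:
        return partial_dependence(self, predictor, grid_size)


def fit_driver_model(
    y: pd.Series,
    X: pd.DataFrame,
    response: str = "TD",
    hemisphere: str = "global",
    n_trees: int = 1000,
    mtry: int = 11,
    seed: int = 0,
    coordinate_cols: tuple[str, ...] = ("lat", "lon"),
) -> DriverModel:
    """Fit the regression forest and its OOB diagnostics.

    Splits minimize node-size-weighted mean squared error; each split
    considers ``min(mtry, n_predictors)`` candidate predictors.  OOB
    variance explained is ``100 * (1 - MSE_OOB / Var(y))``.  Permutation
    importance and minimal depth are computed eagerly; partial dependence
    on demand.
    """
    if len(y) < 50:
        warnings.warn(f"only {len(y)} rows; OOB estimates will be unstable", stacklevel=2)
    X = X.copy()
    yv = y.to_numpy(float)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=min(mtry, X.shape[1]),
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when few trees leave rows in-bag
        forest.fit(X.to_numpy(float), yv)
    oob_pred = forest.oob_prediction_
    mse_oob = float(np.mean((yv - oob_pred) ** 2))
    var_y = float(np.var(yv))
    model = DriverModel(
        hemisphere=hemisphere,
        response=response,
        predictors=list(X.columns),
        coordinate_cols=[c for c in coordinate_cols if c in X.columns],
        forest=forest,
        X=X,
        y=y,
        var_explained=100.0 * (1.0 - mse_oob / var_y),
    )
    model.raw_importance = _oob_permutation_importance(model, seed)
    model.minimal_depth_ = minimal_depth(model)
    return model


def _oob_permutation_importance(model: DriverModel, seed: int) -> pd.Series:
    """Mean over trees of the OOB MSE increase after permuting one predictor."""
    rng = np.random.default_rng([int(seed), 0xB00])
    Xv = model.X.to_numpy(float)
    yv = model.y.to_numpy(float)
    n, p = Xv.shape
    deltas = np.zeros(p)
    n_used = 0
    for est in model.forest.estimators_:
        idx = _bootstrap_indices(est, n)
        oob = np.bincount(idx, minlength=n) == 0
        if oob.sum() < 2:
            continue
        n_used += 1
        Xo = Xv[oob]
        yo = yv[oob]
        base = float(np.mean((yo - est.predict(Xo)) ** 2))
        order = rng.permutation(oob.sum())
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[order, j]
            deltas[j] += float(np.mean((yo - est.predict(Xp)) ** 2)) - base
    return pd.Series(deltas / max(n_used, 1), index=model.X.columns)


def importance_scaled(model: DriverModel, include_coordinates: bool = False) -> pd.Series:
    """Permutation importance, negatives clipped to 0, scaled to sum 100.

    Latitude/longitude stay in the model but are excluded from the report
    by default; scaling is over the reported predictors.
    """
    imp = model.raw_importance.clip(lower=0.0)
    if not include_coordinates:
        imp = imp.drop(index=[c for c in model.coordinate_cols if c in imp.index])
    total = imp.sum()
    if total == 0:
        return imp * 0.0
    return 100.0 * imp / total


def minimal_depth(model: DriverModel) -> pd.Series:
    """Mean over trees of the depth of each predictor's first split.

    A predictor absent from a tree is charged that tree's height, so never-
    used predictors rank last.  Lower mean depth = more influential.
    """
    p = model.X.shape[1]
    totals = np.zeros(p)
    for est in model.forest.estimators_:
        t = est.tree_
        depth = np.zeros(t.node_count, dtype=int)
        first = {}
        stack = [(0, 0)]
        height = 0
        while stack:
            node, d = stack.pop()
            depth[node] = d
            height = max(height, d)
            if t.children_left[node] != -1:
                f = t.feature[node]
                if f not in first or d < first[f]:
                    first[f] = d
                stack.append((t.children_left[node], d + 1))
                stack.append((t.children_right[node], d + 1))
        for j in range(p):
            totals[j] += first.get(j, height)
    return pd.Series(totals / len(model.forest.estimators_), index=model.X.columns)


def partial_dependence(model: DriverModel, predictor: str, grid_size: int = 25) -> pd.DataFrame:
    """Partial-dependence curve with a per-tree standard-error band.

    The predictor is fixed at each of ``grid_size`` evenly spaced values of
    its observed range; the partial value is the mean prediction over the
    data, and the SE is the SD of the per-tree partial values divided by
    sqrt(T).
    """
    if predictor not in model.X.columns:
        raise KeyError(f"predictor {predictor!r} not in model")
    Xv = model.X.to_numpy(float)
    j = list(model.X.columns).index(predictor)
    lo, hi = Xv[:, j].min(), Xv[:, j].max()
    grid = np.linspace(lo, hi, grid_size)
    n = Xv.shape[0]
    stacked = np.tile(Xv, (grid_size, 1))
    stacked[:, j] = np.repeat(grid, n)
    T = len(model.forest.estimators_)
    per_tree = np.empty((T, grid_size))
    for t_i, est in enumerate(model.forest.estimators_):
        per_tree[t_i] = est.predict(stacked).reshape(grid_size, n).mean(axis=1)
    partial = per_tree.mean(axis=0)
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(T)
    return pd.DataFrame({"predictor": predictor, "x": grid, "partial": partial, "se": se})
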