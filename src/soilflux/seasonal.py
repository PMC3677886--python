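"""Correlation matrix, varimax factor analysis, seasonal clusters, hysteresis.

Exploratory structure of the multi-depth soil record: Pearson correlations
between all measured channels (tension in both kPa and pF), a two-factor
principal-component extraction with Kaiser varimax rotation (water variables
and soil CO2 typically load one factor, soil temperature the other), k-means
clustering of monthly mean factor scores into warm-wet / cool-dry / warm-dry
seasons, and signed-area hysteresis metrics for wetting/drying loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

SEASON_LABELS = ("warm-wet", "cool-dry", "warm-dry")


def correlation_matrix(data: pd.DataFrame):
    """Pairwise Pearson correlations with p-values.

    Rows with NaN in either member of a pair are dropped pairwise.  Raises
    on zero-variance channels.

    Returns (r, p) as DataFrames with unit diagonal.
    """
    cols = list(data.columns)
    for c in cols:
        v = data[c].dropna()
        if len(v) < 3:
            raise ValueError(f"channel {c!r} has fewer than 3 valid samples")
        if v.std() == 0:
            raise ValueError(f"channel {c!r} has zero variance")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = data.iloc[:, [i, j]].dropna()
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def _varimax(loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 500):
    """Kaiser varimax rotation (orthogonal); returns rotated loadings and T."""
    p, k = loadings.shape
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        L = loadings @ T
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (L @ np.diag(np.sum(L**2, axis=0))) / p))
        T = u @ vt
        d_new = s.sum()
        if d_new <= d * (1.0 + tol):
            break
        d = d_new
    return loadings @ T, T


@dataclass
class FactorResult:
    """Two-factor varimax solution with monthly aggregation and clusters."""

    loadings: pd.DataFrame            # variables x factors (rotated)
    variance_explained: np.ndarray    # rotated variance fraction per factor
    scores: pd.DataFrame              # per-sample rotated factor scores
    extraction_variance: np.ndarray | None = None  # unrotated (eigenvalue)
    monthly_means: pd.DataFrame | None = None
    cluster_labels: dict | None = None


def factor_varimax(data: pd.DataFrame, n_factors: int = 2) -> FactorResult:
    """Principal-component factor extraction with varimax rotation.

    Variables are standardized internally; factors are extracted as the
    leading eigenvectors of the correlation matrix (loadings scaled by
    sqrt(eigenvalue)), then rotated with Kaiser varimax.  Factor signs are
    fixed so each factor's largest-magnitude loading is positive.

    ``variance_explained`` reports the rotated sums of squared loadings;
    ``extraction_variance`` the unrotated eigenvalue shares.  The latter is
    the meaningful null-structure diagnostic: varimax may split a single
    dominant factor across two rotated columns (its criterion is degenerate
    there), while a near-zero second eigenvalue still reveals that only one
    latent factor is present.
    """
    x = data.dropna().to_numpy(dtype=float)
    nvar = x.shape[1]
    if nvar < 2:
        raise ValueError("need at least 2 variables")
    if x.shape[0] <= nvar:
        raise ValueError("need more samples than variables")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance variable")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:n_factors]
    evals, evecs = evals[order], evecs[:, order]
    if np.linalg.matrix_rank(corr) < n_factors:
        raise ValueError("rank-deficient input")
    loadings = evecs * np.sqrt(evals)
    rotated, T = _varimax(loadings) if n_factors > 1 else (loadings, np.eye(1))
    # rotated standardized scores: Z V lambda^-1/2 under the same rotation
    scores = (z @ evecs / np.sqrt(evals)) @ T

    # order factors by explained variance; fix signs so each factor's
    # largest-magnitude loading is positive (applied to scores identically)
    var_per = np.sum(rotated**2, axis=0)
    order = np.argsort(var_per)[::-1]
    rotated, scores, var_per = rotated[:, order], scores[:, order], var_per[order]
    signs = np.array([1.0 if rotated[np.argmax(np.abs(rotated[:, j])), j] >= 0
                      else -1.0 for j in range(n_factors)])
    rotated = rotated * signs
    scores = scores * signs

    idx = data.dropna().index
    cols = [f"factor{j + 1}" for j in range(n_factors)]
    return FactorResult(
        loadings=pd.DataFrame(rotated, index=data.columns, columns=cols),
        variance_explained=var_per / nvar,
        extraction_variance=evals / nvar,
        scores=pd.DataFrame(scores, index=idx, columns=cols))


def monthly_scores(result: FactorResult) -> pd.DataFrame:
    """Monthly mean factor coordinates (requires a DatetimeIndex)."""
    sc = result.scores
    if not isinstance(sc.index, pd.DatetimeIndex):
        raise TypeError("scores must be indexed by timestamp")
    return sc.groupby(sc.index.to_period("M")).mean()


def cluster_months(monthly: pd.DataFrame, k: int = 3, seed: int = 0) -> dict:
    """k-means clustering of monthly factor coordinates into seasons.

    For k = 3 the clusters are named by centroid position: the highest
    factor-1 centroid (wettest) is ``warm-wet``; the remaining two split on
    factor 2 (temperature) into ``warm-dry`` and ``cool-dry``.  Other k get
    generic ``cluster-i`` names.  Deterministic for a fixed seed.
    """
    if k > len(monthly):
        raise ValueError("k exceeds the number of months")
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    lab = km.fit_predict(monthly.to_numpy(dtype=float))
    centroids = km.cluster_centers_
    if k == 3 and monthly.shape[1] >= 2:
        wet = int(np.argmax(centroids[:, 0]))
        rest = [i for i in range(3) if i != wet]
        warm = rest[int(np.argmax(centroids[rest, 1]))]
        cool = [i for i in rest if i != warm][0]
        names = {wet: "warm-wet", warm: "warm-dry", cool: "cool-dry"}
    else:
        names = {i: f"cluster-{i + 1}" for i in range(k)}
    return {month: names[int(c)] for month, c in zip(monthly.index, lab)}


@dataclass
class HysteresisMetric:
    """Signed loop area of a standardized (x, y) daily trajectory."""

    signed_area: float
    direction: str                # clockwise | counterclockwise | degenerate
    window: tuple


_DEGENERATE_AREA = 1e-12


def hysteresis_loop(x_daily, y_daily, window=None) -> HysteresisMetric:
    """Shoelace signed area of the closed polygon of daily (x, y) points.

    Both series are z-standardized first so areas are comparable across
    variable pairs.  Positive area = counterclockwise temporal progression;
    a collinear out-and-back path is reported as degenerate with area 0.
    """
    x = np.asarray(x_daily, dtype=float)
    y = np.asarray(y_daily, dtype=float)
    if x.size != y.size:
        raise ValueError("series must be the same length")
    if x.size < 4:
        raise ValueError("need at least 4 points in the window")
    sx, sy = x.std(), y.std()
    if sx > 0:
        x = (x - x.mean()) / sx
    if sy > 0:
        y = (y - y.mean()) / sy
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if abs(area) < _DEGENERATE_AREA:
        return HysteresisMetric(0.0, "degenerate", window)
    direction = "counterclockwise" if area > 0 else "clockwise"
    return HysteresisMetric(area, direction, window)
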