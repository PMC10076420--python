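"""k-neighbourhood features of neuron point patterns.

Every neuron is characterised by statistics of its k nearest neighbours
(k in {50, 100, 250, 500, 1000} by default, a range that spans roughly the
biological scale of interlayer distances):

* distance statistics — distance to the k-th neighbour, mean/max/min,
  skewness, kurtosis and a histogram entropy of the k distances;
* neighbour-aggregated morphometry — mean/median/sd of area, circularity,
  roundness and Feret diameter over the k neighbours;
* convex-hull descriptors of the neighbourhood — hull area and perimeter,
  plus mean and sd of each member's nearest-neighbour distance *within* the
  neighbourhood;
* the nearest-neighbour index (NNI), a Clark-Evans-style dispersion measure:
  the mean within-neighbourhood nearest-neighbour distance divided by the
  expectation ``0.5 * sqrt(hull_area / k)`` for a random pattern of the same
  intensity.  NNI ~ 1 for complete spatial randomness, > 1 for regular
  dispersion, < 1 for clustering;
* angular-sector ("slice") diversity — the neighbourhood is divided into R
  equal sectors around the neuron and the sector occupancy proportions are
  summarised by the Shannon index (0 .. ln R) and Simpson index (1/R .. 1).

Neighbourhoods are defined by neighbour count rather than by a fixed radius,
so the features are invariant to image resolution and adapt to local density.
Coordinates are micrometres throughout.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

DEFAULT_K = (50, 100, 250, 500, 1000)
DEFAULT_R = 8
_ENTROPY_BINS = 10

#: morphometry columns aggregated over neighbours
AGGREGATE_COLUMNS = ("area_um2", "circularity", "roundness", "feret_um")
_AGG_SHORT = {"area_um2": "area", "circularity": "circ", "roundness": "round", "feret_um": "feret"}

DIST_STATS = ("kth", "mean", "max", "min", "skew", "kurt", "entropy")


class SpatialIndex:
    """Exact k-nearest-neighbour queries over neuron centroids (micrometres).

    A thin deterministic wrapper around a kd-tree: queries exclude the query
    point itself, results are sorted by nondecreasing distance and exact ties
    are broken by ascending neuron index.
    """

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        self.n = len(pts)
        self._tree = cKDTree(pts)

    def knn(self, i: int, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices and distances of the k nearest neighbours of point ``i``."""
        n = self.n
        if not 0 <= i < n:
            raise IndexError(f"point index {i} out of range")
        if k >= n:
            log.warning("k=%d >= n=%d; truncating to %d", k, n, n - 1)
            k = n - 1
        if k < 1:
            raise ValueError("k must be >= 1")
        q = min(n, k + 2)  # probe one past the cutoff to detect boundary ties
        d, j = self._tree.query(self.points[i], k=q)
        d, j = np.atleast_1d(d), np.atleast_1d(j)
        self_pos = np.nonzero(j == i)[0]
        if len(self_pos):
            keep = np.ones(len(j), bool)
            keep[self_pos[0]] = False
            d, j = d[keep], j[keep]
        else:  # self crowded out by >= q coincident points: exact fallback
            return self._brute_knn(i, k)
        order = np.lexsort((j, d))
        d, j = d[order], j[order]
        if len(d) > k and d[k - 1] == d[k]:
            return self._brute_knn(i, k)  # tie across the cutoff
        return j[:k], d[:k]

    def _brute_knn(self, i: int, k: int) -> tuple[np.ndarray, np.ndarray]:
        d = np.hypot(*(self.points - self.points[i]).T)
        j = np.arange(self.n)
        keep = j != i
        d, j = d[keep], j[keep]
        order = np.lexsort((j, d))[:k]
        return j[order], d[order]


def distance_stats(distances: Sequence[float]) -> dict:
    """Summary statistics of a neighbour-distance sample.

    Returns kth (largest), mean, max, min, Fisher-Pearson skewness, excess
    kurtosis, and the Shannon entropy (natural log) of a 10-bin equal-width
    histogram over [min, max].  A degenerate sample (all distances equal)
    yields zero skew/kurt/entropy and ``degenerate=True``.
    """
    d = np.sort(np.asarray(distances, float))
    if len(d) < 2:
        raise ValueError("need at least 2 distances")
    degenerate = d[0] == d[-1]
    out = {
        "kth": float(d[-1]),
        "mean": float(d.mean()),
        "max": float(d[-1]),
        "min": float(d[0]),
        "degenerate": bool(degenerate),
    }
    if degenerate:
        out.update(skew=0.0, kurt=0.0, entropy=0.0)
        return out
    out["skew"] = float(stats.skew(d))
    out["kurt"] = float(stats.kurtosis(d))
    counts, _ = np.histogram(d, bins=_ENTROPY_BINS, range=(d[0], d[-1]))
    p = counts / counts.sum()
    p = p[p > 0]
    out["entropy"] = float(-(p * np.log(p)).sum())
    return out


def neighbor_aggregate(
    index: SpatialIndex,
    values: Sequence[float],
    i: int,
    k: int,
    stat: str = "mean",
    max_absent: float = 0.2,
) -> float:
    """A summary statistic of ``values`` over the k neighbours of neuron i."""
    if stat not in ("mean", "median", "sd"):
        raise ValueError(f"stat must be mean/median/sd, got {stat!r}")
    values = np.asarray(values, float)
    if len(values) != index.n:
        raise ValueError("values must be defined for all neurons")
    j, _ = index.knn(i, k)
    v = values[j]
    absent = ~np.isfinite(v)
    if absent.mean() > max_absent:
        warnings.warn(f"> {max_absent:.0%} of neighbour values absent for neuron {i}")
    v = v[~absent]
    if stat == "mean":
        return float(v.mean())
    if stat == "median":
        return float(np.median(v))
    return float(v.std(ddof=1))


def hull_features(index: SpatialIndex, i: int, k: int) -> dict:
    """Convex-hull descriptors of the k-neighbourhood of neuron i.

    The hull is taken over the k neighbours plus the central neuron (for
    interior neurons the centre never changes the hull; for boundary neurons
    it stabilises it).  ``hull_nn_mean``/``hull_nn_sd`` summarise each
    member's nearest-neighbour distance within the membership set.
    """
    j, _ = index.knn(i, k)
    members = np.append(j, i)
    pts = index.points[members]
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return {
            "hull_area": 0.0,
            "hull_perimeter": 0.0,
            "hull_nn_mean": np.nan,
            "hull_nn_sd": np.nan,
            "degenerate": True,
        }
    tree = cKDTree(pts)
    dd, _ = tree.query(pts, k=2)
    nnd = dd[:, 1]
    return {
        "hull_area": float(hull.volume),
        "hull_perimeter": float(hull.area),
        "hull_nn_mean": float(nnd.mean()),
        "hull_nn_sd": float(nnd.std(ddof=1)),
        "degenerate": False,
    }


def nni(index: SpatialIndex, i: int, k: int, variant: str = "nearest") -> float:
    """Nearest-neighbour index of neuron i's k-neighbourhood.

    ``variant="nearest"`` (default) averages each member's within-set
    nearest-neighbour distance, which has expectation ``0.5*sqrt(A/n)``
    under complete spatial randomness and therefore calibrates to ~ 1 on a
    Poisson pattern.  ``variant="raw"`` instead averages the distances from
    the central neuron to its k neighbours (kept as a documented
    alternative reading of the ratio).
    """
    if variant not in ("nearest", "raw"):
        raise ValueError(f"unknown NNI variant {variant!r}")
    hf = hull_features(index, i, k)
    if hf["degenerate"] or hf["hull_area"] <= 0:
        return np.nan
    denom = 0.5 * np.sqrt(hf["hull_area"] / k)
    if variant == "nearest":
        return hf["hull_nn_mean"] / denom
    _, d = index.knn(i, k)
    return float(d.mean()) / denom


def slice_proportions(index: SpatialIndex, i: int, k: int, R: int = DEFAULT_R) -> np.ndarray:
    """Proportion of the k neighbours falling in each of R angular sectors.

    Sector r covers angles [2*pi*r/R, 2*pi*(r+1)/R) measured counter-
    clockwise from the image x-axis; a neighbour coincident with the centre
    has undefined direction and is assigned sector 0 (logged).
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    j, _ = index.knn(i, k)
    delta = index.points[j] - index.points[i]
    coincident = (delta == 0).all(axis=1)
    if coincident.any():
        log.info("%d neighbours coincident with neuron %d assigned sector 0", coincident.sum(), i)
    theta = np.mod(np.arctan2(delta[:, 1], delta[:, 0]), 2 * np.pi)
    s = np.minimum((R * theta / (2 * np.pi)).astype(int), R - 1)
    s[coincident] = 0
    return np.bincount(s, minlength=R) / len(j)


def shannon(p: Sequence[float]) -> float:
    """Shannon diversity index of a proportion vector, natural log."""
    p = _check_proportions(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson(p: Sequence[float]) -> float:
    """Simpson index (probability two random members share a sector)."""
    p = _check_proportions(p)
    return float((p**2).sum())


def _check_proportions(p) -> np.ndarray:
    p = np.asarray(p, float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    return p


# ---------------------------------------------------------------------------
# batch feature-table construction


def _batch_knn(pts: np.ndarray, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """All-points k-NN (self excluded, ties by ascending index)."""
    n = len(pts)
    tree = cKDTree(pts)
    d, j = tree.query(pts, k=kmax + 1)
    # move self to column 0 (coincident points can displace it)
    rows_bad = np.nonzero(j[:, 0] != np.arange(n))[0]
    for r in rows_bad:
        pos = np.nonzero(j[r] == r)[0]
        if len(pos) == 0:  # self beyond kmax+1 coincident points; overwrite col 0
            j[r, 0] = r
        else:
            j[r, 0], j[r, pos[0]] = j[r, pos[0]], j[r, 0]
    nb_d, nb_j = d[:, 1:], j[:, 1:]
    # deterministic tie order within each row
    row = np.repeat(np.arange(n), kmax)
    order = np.lexsort((nb_j.ravel(), nb_d.ravel(), row))
    return (
        nb_d.ravel()[order].reshape(n, kmax),
        nb_j.ravel()[order].reshape(n, kmax),
    )


def _batch_distance_stats(d_k: np.ndarray, k: int) -> dict[str, np.ndarray]:
    out = {
        "kth": d_k[:, -1],
        "mean": d_k.mean(axis=1),
        "max": d_k[:, -1],
        "min": d_k[:, 0],
    }
    span = d_k[:, -1] - d_k[:, 0]
    degenerate = span == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sk = stats.skew(d_k, axis=1)
        ku = stats.kurtosis(d_k, axis=1)
    out["skew"] = np.where(degenerate, 0.0, sk)
    out["kurt"] = np.where(degenerate, 0.0, ku)
    # vectorised 10-bin histogram entropy per row
    n = len(d_k)
    safe_span = np.where(degenerate, 1.0, span)
    b = ((d_k - d_k[:, :1]) / safe_span[:, None] * _ENTROPY_BINS).astype(int)
    np.clip(b, 0, _ENTROPY_BINS - 1, out=b)
    flat = (np.arange(n)[:, None] * _ENTROPY_BINS + b).ravel()
    counts = np.bincount(flat, minlength=n * _ENTROPY_BINS).reshape(n, _ENTROPY_BINS)
    p = counts / k
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    out["entropy"] = np.where(degenerate, 0.0, -plogp.sum(axis=1))
    return out


def _batch_sectors(theta: np.ndarray, coincident: np.ndarray, k: int, R: int) -> np.ndarray:
    """Sector proportions (n, R) for the first k neighbours of every neuron."""
    n = len(theta)
    s = np.minimum((R * theta[:, :k] / (2 * np.pi)).astype(int), R - 1)
    s[coincident[:, :k]] = 0
    flat = (np.arange(n)[:, None] * R + s).ravel()
    counts = np.bincount(flat, minlength=n * R).reshape(n, R)
    return counts / k


def _hull_and_nni_block(
    pts: np.ndarray,
    nb_j: np.ndarray,
    nb_d: np.ndarray,
    k: int,
    probe_j: np.ndarray,
    probe_d: np.ndarray,
) -> dict[str, np.ndarray]:
    """Hull descriptors + NNI for every neuron at one k (vectorised inner loop).

    Within-set nearest-neighbour distances are resolved from each member's
    global neighbour list prefix (``probe_j``/``probe_d``); members whose
    prefix contains no other member fall back to exact pairwise distances.
    """
    n = len(pts)
    cols = {
        name: np.full(n, np.nan)
        for name in ("hull_area", "hull_perimeter", "hull_nn_mean", "hull_nn_sd", "nni", "nni_raw")
    }
    n_degenerate = 0
    for i in range(n):
        members = np.sort(np.append(nb_j[i, :k], i))
        sub_j = probe_j[members]
        pos = np.searchsorted(members, sub_j)
        pos[pos >= len(members)] = 0
        inset = members[pos] == sub_j
        found = inset.any(axis=1)
        first = inset.argmax(axis=1)
        nnd = np.empty(len(members))
        nnd[found] = probe_d[members[found], first[found]]
        if not found.all():
            miss = np.nonzero(~found)[0]
            D = cdist(pts[members[miss]], pts[members])
            D[np.arange(len(miss)), miss] = np.inf
            nnd[miss] = D.min(axis=1)
        try:
            hull = ConvexHull(pts[members])
        except QhullError:
            n_degenerate += 1
            continue
        area = hull.volume
        cols["hull_area"][i] = area
        cols["hull_perimeter"][i] = hull.area
        cols["hull_nn_mean"][i] = nnd.mean()
        cols["hull_nn_sd"][i] = nnd.std(ddof=1)
        if area > 0:
            denom = 0.5 * np.sqrt(area / k)
            cols["nni"][i] = nnd.mean() / denom
            cols["nni_raw"][i] = nb_d[i, :k].mean() / denom
    if n_degenerate:
        log.info("k=%d: %d degenerate (collinear) neighbourhood hulls", k, n_degenerate)
    return cols


def build_feature_table(
    records,
    K: Sequence[int] = DEFAULT_K,
    R: int = DEFAULT_R,
    include_gray: bool = False,
    include_raw_nni: bool = True,
    max_nan_fraction: float = 0.05,
    nn_probe: int = 16,
) -> pd.DataFrame:
    """Assemble the full neurons x features table for a point pattern.

    ``records`` is a canonical neuron table (DataFrame) or a list of
    :class:`~laminar.morphometry.NeuronRecord`.  Columns are named
    ``"<k>_<family>_<stat>"`` (e.g. ``500_dist_mean``, ``100_area_mean``,
    ``500_hull_area``, ``500_nni``, ``500_shannon_8``) in deterministic
    order, indexed by neuron id.  Per-neuron body morphometry is carried
    through unchanged; grayscale statistics are excluded unless
    ``include_gray`` (intensity-derived values depend on staining and are
    not used for classification).
    """
    from .morphometry import records_to_frame, GRAY_COLUMNS

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        raise ValueError("empty record list")
    n = len(df)
    K_valid = [int(k) for k in K if k <= n - 1]
    if len(K_valid) < len(list(K)):
        log.warning("K truncated from %s to %s for n=%d neurons", list(K), K_valid, n)
    if not K_valid:
        K_valid = [n - 1]
    kmax = max(K_valid)
    pts = df[["x_um", "y_um"]].to_numpy(float)
    nb_d, nb_j = _batch_knn(pts, kmax)

    delta = pts[nb_j] - pts[:, None, :]
    coincident = (delta == 0).all(axis=2)
    theta = np.mod(np.arctan2(delta[..., 1], delta[..., 0]), 2 * np.pi)
    del delta

    probe = min(nn_probe, kmax)
    probe_j, probe_d = nb_j[:, :probe], nb_d[:, :probe]

    out: dict[str, np.ndarray] = {}
    passthrough = ["area_um2", "perimeter_um", "circularity", "roundness", "feret_um"]
    if include_gray:
        passthrough += [c for c in GRAY_COLUMNS if c in df.columns]
    for c in passthrough:
        if c in df.columns:
            out[c] = df[c].to_numpy(float)

    agg_values = {
        c: df[c].to_numpy(float) for c in AGGREGATE_COLUMNS if c in df.columns
    }
    for k in K_valid:
        d_k = nb_d[:, :k]
        for name, vals in _batch_distance_stats(d_k, k).items():
            out[f"{k}_dist_{name}"] = vals
        for col, vals in agg_values.items():
            short = _AGG_SHORT[col]
            nb_vals = vals[nb_j[:, :k]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[f"{k}_{short}_mean"] = np.nanmean(nb_vals, axis=1)
                out[f"{k}_{short}_median"] = np.nanmedian(nb_vals, axis=1)
                out[f"{k}_{short}_sd"] = np.nanstd(nb_vals, axis=1, ddof=1)
        hull_cols = _hull_and_nni_block(pts, nb_j, nb_d, k, probe_j, probe_d)
        for name in ("hull_area", "hull_perimeter", "hull_nn_mean", "hull_nn_sd"):
            out[f"{k}_{name}"] = hull_cols[name]
        out[f"{k}_nni"] = hull_cols["nni"]
        if include_raw_nni:
            out[f"{k}_nni_raw"] = hull_cols["nni_raw"]
        p = _batch_sectors(theta, coincident, k, R)
        nzp = np.where(p > 0, p, 1.0)
        out[f"{k}_shannon_{R}"] = -(np.where(p > 0, p * np.log(nzp), 0.0)).sum(axis=1)
        out[f"{k}_simpson_{R}"] = (p**2).sum(axis=1)

    table = pd.DataFrame(out, index=pd.Index(df["id"].astype(int), name="id"))
    nan_frac = float(table.isna().to_numpy().mean())
    if nan_frac > max_nan_fraction:
        raise ValueError(
            f"feature table has {nan_frac:.1%} NaN cells (> {max_nan_fraction:.0%}); "
            "check for degenerate geometry"
        )
    table.attrs["provenance"] = feature_provenance(table.columns)
    return table


def feature_provenance(columns: Sequence[str]) -> dict:
    """Family / k / R provenance for each feature column (sidecar metadata)."""
    prov = {}
    for c in columns:
        parts = c.split("_")
        if parts[0].isdigit():
            k = int(parts[0])
            if parts[1] in ("shannon", "simpson"):
                prov[c] = {"family": "slice_diversity", "index": parts[1], "k": k, "R": int(parts[2])}
            elif parts[1] == "dist":
                prov[c] = {"family": "distance", "stat": parts[2], "k": k}
            elif parts[1] == "hull":
                prov[c] = {"family": "hull", "stat": "_".join(parts[2:]) or parts[1], "k": k}
            elif parts[1] == "nni":
                prov[c] = {"family": "nni", "variant": "raw" if c.endswith("raw") else "nearest", "k": k}
            else:
                prov[c] = {"family": "neighbor_morphometry", "source": parts[1], "stat": parts[2], "k": k}
        else:
            prov[c] = {"family": "body_morphometry"}
    return prov


def save_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table (CSV, or Parquet for ``.parquet`` paths) with a
    ``.provenance.json`` sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".parquet":
        table.to_parquet(path)
    else:
        table.to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    prov = table.attrs.get("provenance") or feature_provenance(table.columns)
    sidecar.write_text(json.dumps(prov, indent=1))


def load_feature_table(path) -> pd.DataFrame:
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".parquet":
        table = pd.read_parquet(path)
    else:
        table = pd.read_csv(path, index_col="id")
    table.attrs["provenance"] = feature_provenance(table.columns)
    return table


class NeighborhoodFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: canonical neuron table -> feature table.

    Stateless (``fit`` only validates); composes with sklearn pipelines.
    """

    def __init__(
        self,
        K: Sequence[int] = DEFAULT_K,
        R: int = DEFAULT_R,
        include_gray: bool = False,
        include_raw_nni: bool = True,
    ):
        self.K = K
        self.R = R
        self.include_gray = include_gray
        self.include_raw_nni = include_raw_nni

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else None
        if df is None or not {"x_um", "y_um", "id"} <= set(df.columns):
            raise ValueError("X must be a canonical neuron table with id/x_um/y_um columns")
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        return build_feature_table(
            X,
            K=self.K,
            R=self.R,
            include_gray=self.include_gray,
            include_raw_nni=self.include_raw_nni,
        )
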