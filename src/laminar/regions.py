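"""Region-level laminar features derived without cortical profiles.

The laminar structure is recovered from 1-D multimodal feature
distributions: a local-density proxy (the inverse mean distance to the
k=100 nearest neighbours) separates neurons into sparse / average / dense
populations by minimisation of intraclass variance (multi-level Otsu on a
256-bin quantisation).  Sparse neurons split further into layer I versus
white matter by their neighbourhood hull area — a white-matter neuron's
hull is large, while a layer-I neuron's hull is pinched between the tissue
border and the dense layer II.  Distances to the recovered regions then
yield per-neuron cortical depth (distance to layer I), cortical thickness
(depth + distance to white matter) and relative depth in [0, 1] — all
without drawing a single profile perpendicular to the cortex.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

DEFAULT_NBINS = 256
DEFAULT_DENSITY_K = 100
DEFAULT_HULL_K = 500
DENSITY_CLASSES = ("sparse", "average", "dense")
SPARSE_SUBTYPES = ("layerI", "WM", "none")


class SplitError(ValueError):
    """No valid intraclass-variance split exists for the input."""


class SplitQualityWarning(UserWarning):
    """The accepted split explains less than half the total variance."""


def intraclass_variance_split(
    values: Sequence[float],
    n_classes: int = 2,
    nbins: int = DEFAULT_NBINS,
    min_between_fraction: float = 0.5,
) -> np.ndarray:
    """Thresholds minimising total within-class variance (multi-level Otsu).

    The value range is quantised into ``nbins`` equal-width bins and all
    bin-boundary threshold combinations are searched exhaustively, which
    makes the result deterministic and directly checkable against a
    brute-force oracle.  Thresholds are returned ascending, as bin-edge
    values.  A between-class variance fraction below
    ``min_between_fraction`` indicates the input is not convincingly
    multimodal and raises :class:`SplitQualityWarning`.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    if len(v) < 10 * n_classes:
        raise SplitError(f"need >= {10 * n_classes} finite values, got {len(v)}")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise SplitError("constant input has no valid split")
    counts, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    p = counts / counts.sum()
    # centre the bin values: avoids catastrophic cancellation in m2 - m1^2/w
    centers = 0.5 * (edges[:-1] + edges[1:]) - v.mean()
    # cumulative zeroth/first/second moments; segment [a, b) via differences
    w = np.concatenate([[0.0], np.cumsum(p)])
    s1 = np.concatenate([[0.0], np.cumsum(p * centers)])
    s2 = np.concatenate([[0.0], np.cumsum(p * centers**2)])

    def seg_wcv(a, b):
        """weight * variance of bins [a, b), elementwise over arrays."""
        ww = w[b] - w[a]
        m1 = s1[b] - s1[a]
        m2 = s2[b] - s2[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = m2 - m1**2 / ww
        return np.where(ww > 0, out, np.inf)

    t = np.arange(1, nbins)
    if n_classes == 2:
        wcv = seg_wcv(np.zeros_like(t), t) + seg_wcv(t, np.full_like(t, nbins))
        best_wcv = float(wcv.min())
        # empty bins between modes create runs of exact co-optima; take the
        # middle of the tied set so the threshold sits centred in the valley
        tied = np.nonzero(wcv <= best_wcv + 1e-9 * abs(best_wcv))[0]
        best = int(tied[len(tied) // 2])
        thresholds = np.array([edges[t[best]]])
    else:
        t1 = t[:, None]
        t2 = t[None, :]
        wcv = (
            seg_wcv(np.zeros_like(t1), t1)
            + seg_wcv(np.broadcast_to(t1, (len(t), len(t))), np.broadcast_to(t2, (len(t), len(t))))
            + seg_wcv(t2, np.full_like(t2, nbins))
        )
        wcv = np.where(t1 < t2, wcv, np.inf)
        best_wcv = float(wcv.min())
        tied = np.argwhere(wcv <= best_wcv + 1e-9 * abs(best_wcv))
        i1, i2 = tied[len(tied) // 2]
        thresholds = np.array([edges[t[i1]], edges[t[i2]]])
    total_var = seg_wcv(np.array([0]), np.array([nbins]))[0]
    if total_var > 0:
        between_fraction = 1.0 - best_wcv / total_var
        if between_fraction < min_between_fraction:
            warnings.warn(
                f"split explains only {between_fraction:.1%} of variance; "
                "input may not be multimodal",
                SplitQualityWarning,
            )
    return thresholds


def classify_density(
    features: pd.DataFrame,
    k_density: int = DEFAULT_DENSITY_K,
    proxy: Optional[Sequence[float]] = None,
    log_scale: bool = True,
) -> pd.Series:
    """Assign each neuron a sparse/average/dense class from local density.

    The density proxy is the inverse of the mean distance to the
    ``k_density`` nearest neighbours (monotone in local density and robust
    at layer borders); the three populations mirror the laminar
    composition: layers II and IV dense, III/V/VI average, layer I and
    white matter sparse.  By default the intraclass-variance split is run
    on the log of the proxy: density spreads multiplicatively, so
    log-spaced quantisation keeps the sparse mode (a few percent of the
    neurons) from being absorbed by the broad dense mode.  If the 3-class
    split leaves a class essentially empty the split is downgraded to 2
    classes (sparse/dense) with a warning.
    """
    if proxy is None:
        col = f"{k_density}_dist_mean"
        if col not in features.columns:
            raise KeyError(f"feature column {col!r} required for the density proxy")
        proxy = 1.0 / features[col].to_numpy(float)
    proxy = np.asarray(proxy, float)
    split_values = np.log(proxy) if log_scale else proxy
    thresholds = intraclass_variance_split(split_values, n_classes=3)
    labels = np.take(DENSITY_CLASSES, np.searchsorted(thresholds, split_values))
    counts = pd.Series(labels).value_counts()
    min_count = max(5, int(0.005 * len(proxy)))
    if counts.reindex(DENSITY_CLASSES).fillna(0).min() < min_count:
        log.warning("3-class density split left a near-empty class; downgrading to 2")
        thresholds = intraclass_variance_split(split_values, n_classes=2)
        labels = np.take(["sparse", "dense"], np.searchsorted(thresholds, split_values))
    return pd.Series(
        pd.Categorical(labels, categories=DENSITY_CLASSES), index=features.index, name="density_class"
    )


def split_sparse(
    features: pd.DataFrame,
    density_class: pd.Series,
    k_hull: int = DEFAULT_HULL_K,
    min_sparse: int = 20,
    log_scale: bool = True,
) -> pd.Series:
    """Disambiguate sparse neurons into layer I versus white matter.

    A 2-class intraclass-variance split of the neighbourhood hull area
    among sparse neurons: the larger-hull class is white matter, the
    smaller layer I.  The separation is strongest at large k (default
    500): a layer-I neuron's hull stays pinned between the tissue border
    and the dense layer II however many neighbours are taken, while a
    white-matter hull keeps growing.  If the requested hull column is not
    in the table, the largest available k is used with a warning.
    """
    col = f"{k_hull}_hull_area"
    if col not in features.columns:
        available = sorted(
            int(c.split("_")[0]) for c in features.columns if c.endswith("_hull_area")
        )
        if not available:
            raise KeyError("no <k>_hull_area column available for the sparse split")
        k_hull = available[-1]
        log.warning("hull k=%s not available; falling back to k=%d", col, k_hull)
        col = f"{k_hull}_hull_area"
    sparse = density_class == "sparse"
    n_sparse = int(sparse.sum())
    if n_sparse < min_sparse:
        raise SplitError(
            f"only {n_sparse} sparse neurons (< {min_sparse}); set a manual threshold instead"
        )
    hull = features.loc[sparse, col].to_numpy(float)
    split_values = np.log(hull) if log_scale else hull
    threshold = intraclass_variance_split(split_values, n_classes=2)[0]
    subtype = np.where(split_values > threshold, "WM", "layerI")
    for name in ("layerI", "WM"):
        if (subtype == name).sum() == 0:
            log.warning("sparse split left the %s class empty", name)
    out = pd.Series(
        pd.Categorical(["none"] * len(features), categories=SPARSE_SUBTYPES),
        index=features.index,
        name="sparse_subtype",
    )
    out[sparse] = subtype
    return out


def coherent_members(coords: np.ndarray, mask: np.ndarray, factor: float = 3.0) -> np.ndarray:
    """Drop spatially isolated members of a region.

    A handful of density-misclassified neurons far from the true band would
    otherwise act as false anchors and corrupt every distance-to-region
    feature.  Members are linked when closer than ``factor`` times the
    median nearest-neighbour distance within the region; only the largest
    connected component is kept.
    """
    mask = np.asarray(mask, bool)
    idx = np.nonzero(mask)[0]
    if len(idx) < 3:
        return mask
    pts = np.asarray(coords, float)[idx]
    tree = cKDTree(pts)
    nnd = tree.query(pts, k=2)[0][:, 1]
    radius = factor * float(np.median(nnd))
    n_comp, labels = _connected_components(tree, len(pts), radius)
    keep = labels == np.bincount(labels).argmax()
    out = np.zeros_like(mask)
    out[idx[keep]] = True
    dropped = int((~keep).sum())
    if dropped:
        log.info("region coherence filter dropped %d isolated members", dropped)
    return out


def _connected_components(tree: cKDTree, n: int, radius: float) -> tuple[int, np.ndarray]:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    pairs = tree.query_pairs(radius, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    return n_comp, labels


def region_distances(
    coords: np.ndarray, membership: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Euclidean distance (um) from every neuron to each named region.

    ``membership`` maps region name -> boolean mask over neurons; members
    of a region are at distance 0 from it.  Empty regions are skipped with
    a warning.
    """
    coords = np.asarray(coords, float)
    out = {}
    for name, mask in membership.items():
        mask = np.asarray(mask, bool)
        if mask.sum() == 0:
            log.warning("region %r is empty; distance feature absent", name)
            continue
        tree = cKDTree(coords[mask])
        d, _ = tree.query(coords)
        d[mask] = 0.0
        out[f"dist_to_{name}"] = d
    return pd.DataFrame(out)


def depth_thickness(
    dist_to_layerI: np.ndarray, dist_to_wm: np.ndarray
) -> pd.DataFrame:
    """Per-neuron cortical depth, thickness and relative depth.

    depth = distance to the nearest layer-I neuron; thickness = depth +
    distance to the nearest white-matter neuron (a profile-free,
    per-neuron approximation of pial-to-WM thickness); relative depth =
    depth / thickness, 0 at layer I and 1 in white matter.
    """
    depth = np.asarray(dist_to_layerI, float)
    d_wm = np.asarray(dist_to_wm, float)
    thickness = depth + d_wm
    assert (thickness > 0).all(), "zero thickness: neuron in both layer I and WM"
    rel = depth / thickness
    return pd.DataFrame(
        {"cortical_depth": depth, "cortical_thickness": thickness, "relative_depth": rel}
    )


def partition_regions(
    records: pd.DataFrame,
    features: pd.DataFrame,
    k_density: int = DEFAULT_DENSITY_K,
    k_hull: int = DEFAULT_HULL_K,
) -> pd.DataFrame:
    """Full region partition: density classes, layer-I/WM split, distances,
    depth/thickness.  ``records`` provides coordinates (canonical table),
    ``features`` the neighbourhood features; both must align on neuron id."""
    if len(records) != len(features):
        raise ValueError("records and features must align")
    density = classify_density(features, k_density=k_density)
    subtype = split_sparse(features, density, k_hull=k_hull)
    coords = records[["x_um", "y_um"]].to_numpy(float)
    membership = {
        "layerI": coherent_members(coords, (subtype == "layerI").to_numpy()),
        "wm": coherent_members(coords, (subtype == "WM").to_numpy()),
        "dense": (density == "dense").to_numpy(),
    }
    dists = region_distances(coords, membership).set_index(features.index)
    anchors = pd.DataFrame(
        {f"anchor_{name}": mask for name, mask in membership.items() if name != "dense"},
        index=features.index,
    )
    parts = [density, subtype, anchors, dists]
    if {"dist_to_layerI", "dist_to_wm"} <= set(dists.columns):
        dt = depth_thickness(dists["dist_to_layerI"], dists["dist_to_wm"]).set_index(features.index)
        parts.append(dt)
    return pd.concat(parts, axis=1)


def partition_to_features(partition: pd.DataFrame) -> pd.DataFrame:
    """Numeric (one-hot + distance) encoding of a region partition, suitable
    as classifier input columns."""
    out = {}
    for cls in DENSITY_CLASSES:
        out[f"density_{cls}"] = (partition["density_class"] == cls).astype(float)
    out["sparse_layerI"] = (partition["sparse_subtype"] == "layerI").astype(float)
    out["sparse_wm"] = (partition["sparse_subtype"] == "WM").astype(float)
    for c in ("dist_to_dense", "dist_to_wm", "cortical_depth", "cortical_thickness", "relative_depth"):
        if c in partition.columns:
            out[c] = partition[c].astype(float)
    return pd.DataFrame(out, index=partition.index)


class RegionPartitioner(BaseEstimator, TransformerMixin):
    """Transformer appending region-derived columns to a feature table.

    The partition is a scene-level (transductive) operation: ``transform``
    recomputes density classes and region distances for the table it is
    given; ``fit`` records the thresholds found on the fitting data for
    inspection.  ``transform`` expects the merged records+features table
    (it needs ``x_um``/``y_um`` alongside the neighbourhood columns).
    """

    def __init__(self, k_density: int = DEFAULT_DENSITY_K):
        self.k_density = k_density

    def fit(self, X, y=None):
        records, features = self._split_input(X)
        proxy = 1.0 / features[f"{self.k_density}_dist_mean"].to_numpy(float)
        self.density_thresholds_ = intraclass_variance_split(proxy, n_classes=3)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        records, features = self._split_input(X)
        partition = partition_regions(records, features, k_density=self.k_density)
        return pd.concat([X, partition_to_features(partition)], axis=1)

    def _split_input(self, X):
        if not isinstance(X, pd.DataFrame) or not {"x_um", "y_um"} <= set(X.columns):
            raise ValueError("X must be a DataFrame containing x_um/y_um plus feature columns")
        return X[["x_um", "y_um"]], X
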