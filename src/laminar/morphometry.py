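"""Per-neuron body morphometry from instance-segmentation label masks.

This module re-implements the particle-measurement step of the classical
ImageJ "Analyze Particles" workflow on calibrated label rasters: for every
labelled connected component (a segmented neuron body) it measures centroid,
area, perimeter, circularity, roundness and Feret diameter, plus optional
first-order grayscale statistics when an intensity image is supplied.  All
outputs are in micrometres; downstream modules never see pixels.

Conventions (declared once, tested):

* 8-connectivity; components below 4 px are flagged degenerate and excluded.
* Perimeter: weighted boundary-step estimator on the 8-connected outer
  boundary chain (straight step 1, diagonal sqrt(2)).
* circularity = 4*pi*area / perimeter**2, clipped to <= 1.
* roundness = 4*area / (pi * major_axis**2) with the moment-derived best-fit
  ellipse major axis, clipped to <= 1.
* Feret diameter: maximum pairwise distance over the convex hull of the
  component's boundary pixel centres.
* Skewness is Fisher-Pearson; kurtosis is excess kurtosis (normal -> 0).
* Pixel origin top-left, x rightward, y downward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.ndimage import binary_erosion
from skimage import measure

log = logging.getLogger(__name__)

#: default scanner calibration, micrometres per pixel (40x digitization)
DEFAULT_RESOLUTION = 0.226

#: canonical neuron-table column order used by every writer/reader in the package
CANONICAL_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "area_um2",
    "perimeter_um",
    "circularity",
    "roundness",
    "feret_um",
    "gray_mean",
    "gray_median",
    "gray_skew",
    "gray_kurt",
]

GRAY_COLUMNS = ["gray_mean", "gray_median", "gray_skew", "gray_kurt"]

#: column-name dialects for particle tables.  "imagej" matches the headers
#: written by ImageJ's Analyze Particles results table.
DIALECTS = {
    "imagej": {
        "id": " ",
        "x_um": "X",
        "y_um": "Y",
        "area_um2": "Area",
        "perimeter_um": "Perim.",
        "circularity": "Circ.",
        "roundness": "Round",
        "feret_um": "Feret",
        "gray_mean": "Mean",
        "gray_median": "Median",
        "gray_skew": "Skew",
        "gray_kurt": "Kurt",
    },
    "canonical": {c: c for c in CANONICAL_COLUMNS},
}

MANDATORY_FIELDS = ("x_um", "y_um", "area_um2")


class MaskError(ValueError):
    """Raised when a label/intensity raster pair violates its contract."""


@dataclass(frozen=True)
class NeuronRecord:
    """Morphometry of one segmented neuron body (micrometre units)."""

    id: int
    x_um: float
    y_um: float
    area_um2: float
    perimeter_um: Optional[float] = None
    circularity: Optional[float] = None
    roundness: Optional[float] = None
    feret_um: Optional[float] = None
    gray_mean: Optional[float] = None
    gray_median: Optional[float] = None
    gray_skew: Optional[float] = None
    gray_kurt: Optional[float] = None


@dataclass(frozen=True)
class CalibratedMask:
    """An integer label raster with optional intensity image and calibration.

    ``labels`` is 2-D, 0 = background, k = neuron k; labels are expected to be
    disjoint connected components (the output contract of the upstream
    segmentation).  ``resolution`` is micrometres per pixel.
    """

    labels: np.ndarray
    intensity: Optional[np.ndarray] = None
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise MaskError(f"label raster must be 2-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise MaskError(f"label raster must be integer-typed, got {labels.dtype}")
        if self.intensity is not None and np.asarray(self.intensity).shape != labels.shape:
            raise MaskError(
                "intensity shape "
                f"{np.asarray(self.intensity).shape} does not match labels {labels.shape}"
            )
        if not self.resolution > 0:
            raise MaskError(f"resolution must be > 0 um/px, got {self.resolution}")


# 8 Moore-neighbourhood offsets (row, col), clockwise starting at North.
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)], dtype=int
)
_STEP_LENGTH = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])


def _chain_perimeter(img: np.ndarray) -> float:
    """Boundary-step perimeter of a single 8-connected component (pixels).

    Traces the outer boundary with Moore-neighbour tracing and sums step
    lengths (1 for axis-aligned, sqrt(2) for diagonal moves).  Holes are
    ignored; a single isolated pixel has perimeter 0 by this estimator but
    such components never reach here (< 4 px are excluded upstream).
    """
    padded = np.pad(np.asarray(img, bool), 1)
    rows, cols = np.nonzero(padded)
    if len(rows) == 1:
        return 0.0
    # topmost-leftmost foreground pixel; its west neighbour is background
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    dir_of = {(int(dr), int(dc)): i for i, (dr, dc) in enumerate(_MOORE)}
    current = start
    backtrack = (start[0], start[1] - 1)
    perimeter = 0.0
    first_move = None
    max_steps = 8 * len(rows) + 8
    for _ in range(max_steps):
        d0 = dir_of[(backtrack[0] - current[0], backtrack[1] - current[1])]
        nxt = None
        for step in range(1, 9):
            d = (d0 + step) % 8
            cand = (current[0] + _MOORE[d, 0], current[1] + _MOORE[d, 1])
            if padded[cand]:
                nxt = cand
                prev_d = (d0 + step - 1) % 8
                new_backtrack = (
                    current[0] + _MOORE[prev_d, 0],
                    current[1] + _MOORE[prev_d, 1],
                )
                break
        if nxt is None:  # isolated pixel
            return 0.0
        move = (current, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            return perimeter
        perimeter += _STEP_LENGTH[d]
        current, backtrack = nxt, new_backtrack
    log.warning("boundary tracing did not close; returning accumulated length")
    return perimeter


def _feret_diameter(boundary_coords: np.ndarray) -> float:
    """Max caliper diameter (pixels) over the boundary-pixel convex hull."""
    pts = np.asarray(boundary_coords, float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear: brute force below
    return float(pdist(pts).max())


def _gray_stats(values: np.ndarray) -> dict:
    values = np.asarray(values, float)
    sd = values.std()
    return {
        "gray_mean": float(values.mean()),
        "gray_median": float(np.median(values)),
        "gray_skew": float(stats.skew(values)) if sd > 0 else 0.0,
        "gray_kurt": float(stats.kurtosis(values)) if sd > 0 else 0.0,
    }


def measure_particles(mask: CalibratedMask, min_pixels: int = 4) -> list[NeuronRecord]:
    """Measure every labelled neuron body in a calibrated mask.

    Returns one :class:`NeuronRecord` per label, in ascending label order,
    with all measurements scaled to micrometres.  Components smaller than
    ``min_pixels`` are degenerate (shape statistics are meaningless at that
    scale): they are excluded and their count logged.
    """
    labels = np.asarray(mask.labels)
    if labels.size == 0 or labels.max() == 0:
        raise MaskError("label raster has no nonzero labels")
    res = mask.resolution
    props = measure.regionprops(
        labels, intensity_image=mask.intensity if mask.intensity is not None else None
    )
    records: list[NeuronRecord] = []
    n_degenerate = 0
    for prop in props:
        if prop.area < min_pixels:
            n_degenerate += 1
            continue
        img = prop.image
        area_px = float(prop.area)
        perim_px = _chain_perimeter(img)
        circularity = (
            min(1.0, 4.0 * np.pi * area_px / perim_px**2) if perim_px > 0 else None
        )
        major = prop.axis_major_length
        roundness = min(1.0, 4.0 * area_px / (np.pi * major**2)) if major > 0 else None
        boundary = img & ~binary_erosion(img)
        rr, cc = np.nonzero(boundary)
        feret_px = _feret_diameter(np.column_stack([rr, cc]))
        row_c, col_c = prop.centroid
        gray = {}
        if mask.intensity is not None:
            gray = _gray_stats(np.asarray(mask.intensity)[prop.slice][img])
        records.append(
            NeuronRecord(
                id=int(prop.label),
                x_um=float(col_c) * res,
                y_um=float(row_c) * res,
                area_um2=area_px * res**2,
                perimeter_um=perim_px * res,
                circularity=circularity,
                roundness=roundness,
                feret_um=feret_px * res,
                **gray,
            )
        )
    if n_degenerate:
        log.info("excluded %d degenerate components (< %d px)", n_degenerate, min_pixels)
    if not records:
        raise MaskError(f"all components smaller than {min_pixels} px")
    return records


def records_to_frame(records: Sequence[NeuronRecord]) -> pd.DataFrame:
    """Canonical neuron table (one row per record, canonical column order)."""
    if len(records) == 0:
        raise ValueError("empty record list")
    rows = [
        {f.name: getattr(r, f.name) for f in dataclass_fields(NeuronRecord)}
        for r in records
    ]
    df = pd.DataFrame(rows)[CANONICAL_COLUMNS]
    if df[GRAY_COLUMNS].isna().all().all():
        df = df.drop(columns=GRAY_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[NeuronRecord]:
    recs = []
    for _, row in df.iterrows():
        kwargs = {
            c: (None if pd.isna(row[c]) else float(row[c]))
            for c in CANONICAL_COLUMNS
            if c in df.columns and c != "id"
        }
        recs.append(NeuronRecord(id=int(row["id"]), **kwargs))
    return recs


def write_particle_table(records, path) -> None:
    """Write records (or a canonical frame) as the canonical neuron CSV."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)


def read_particle_table(
    path,
    dialect: str = "canonical",
    resolution: Optional[float] = None,
) -> list[NeuronRecord]:
    """Read a particle table (ImageJ results table or canonical CSV).

    ``dialect`` maps column names; ``resolution`` (um/px), when given,
    converts a pixel-unit table to micrometres (coordinates and feret scale
    by it, areas by its square).  Missing optional columns yield absent
    fields; circularity is recomputed from area and perimeter when the
    column is absent but both are present.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    colmap = DIALECTS[dialect]
    df = pd.read_csv(path)
    missing = [
        colmap[f] for f in MANDATORY_FIELDS if colmap[f] not in df.columns
    ]
    if missing:
        raise ValueError(f"particle table {path} is missing mandatory columns: {missing}")
    out = {}
    for field, col in colmap.items():
        if col not in df.columns:
            continue
        if field == "id":
            out[field] = df[col]
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row {int(np.nonzero(bad.values)[0][0])}"
            )
        out[field] = numeric
    table = pd.DataFrame(out)
    if "id" not in table.columns:
        table.insert(0, "id", np.arange(1, len(table) + 1))
    table["id"] = table["id"].astype(int)
    if resolution is not None:
        for c in ("x_um", "y_um", "perimeter_um", "feret_um"):
            if c in table.columns:
                table[c] = table[c] * resolution
        table["area_um2"] = table["area_um2"] * resolution**2
    if "circularity" not in table.columns and "perimeter_um" in table.columns:
        table["circularity"] = np.minimum(
            1.0, 4.0 * np.pi * table["area_um2"] / table["perimeter_um"] ** 2
        )
    return frame_to_records(table)


def load_mask(labels_path, intensity_path=None, resolution: float = DEFAULT_RESOLUTION) -> CalibratedMask:
    """Load a TIFF/PNG label mask (and optional grayscale image) from disk."""
    labels = _imread(labels_path).astype(np.int32)
    intensity = _imread(intensity_path) if intensity_path is not None else None
    return CalibratedMask(labels=labels, intensity=intensity, resolution=resolution)


def _imread(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)
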