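"""Synthetic laminar cortex: point patterns, rendered masks, simulated raters.

The generator emulates the statistical structure of a NeuN-stained
isocortical section that the analysis pipeline assumes: seven parallel
horizontal bands (layers I-VI plus white matter, layer I at the top,
y increasing with depth), each a homogeneous Poisson point process with a
band-specific intensity, log-normal soma areas and beta-distributed shape
factors.  The default scene encodes the qualitative laminar composition of
the homotypic prefrontal isocortex: layers II and IV densest, layer I and
white matter sparsest, layers III/V/VI intermediate with layer III holding
the largest somata (then V, then VI).  At the default section width the
scene holds roughly 12-13 thousand neurons, the scale of a manually
labelled histology dataset.

Simulated "raters" annotate every neuron by its position relative to
*jittered* layer boundaries: each rater's boundaries are displaced by a
smooth, spatially correlated 1-D field, so disagreement is coherent and
confined to boundary strips — the empirical signature of expert
disagreement — rather than i.i.d. label noise.  The layer I/II boundary
receives reduced jitter (experts find it unmistakable).  The default
amplitude is calibrated so that pairwise rater agreement falls in the
0.75-0.81 range reported for human experts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .morphometry import CalibratedMask

log = logging.getLogger(__name__)

MAX_EXPECTED_NEURONS = 1_000_000


@dataclass(frozen=True)
class BandConfig:
    """One laminar band: geometry and neuron phenotype distributions.

    ``intensity`` is the 2-D Poisson intensity in neurons/um^2; soma areas
    are log-normal (``area_median_um2``, ``area_log_sd``); circularity and
    aspect (minor/major axis ratio, which equals roundness for an ellipse)
    are Beta-distributed on (0, 1], aspect rescaled to [0.35, 1].
    """

    name: str
    width_um: float
    intensity: float
    area_median_um2: float
    area_log_sd: float = 0.35
    circ_beta: tuple[float, float] = (8.0, 2.0)
    aspect_beta: tuple[float, float] = (6.0, 2.5)

    def __post_init__(self):
        if self.width_um <= 0 or self.intensity <= 0:
            raise ValueError(f"band {self.name}: width and intensity must be > 0")


#: default laminar composition (widths and 2-D densities chosen to give the
#: three density populations and the layer-III size dominance the pipeline
#: is designed to recover)
DEFAULT_BANDS = (
    BandConfig("I", width_um=250, intensity=0.0004, area_median_um2=45),
    BandConfig("II", width_um=250, intensity=0.010, area_median_um2=60),
    BandConfig("III", width_um=700, intensity=0.0025, area_median_um2=140),
    BandConfig("IV", width_um=200, intensity=0.010, area_median_um2=55),
    BandConfig("V", width_um=500, intensity=0.0025, area_median_um2=110),
    BandConfig("VI", width_um=450, intensity=0.0025, area_median_um2=90, circ_beta=(4.0, 3.0)),
    BandConfig("WM", width_um=700, intensity=0.0008, area_median_um2=40),
)


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of a synthetic section.

    ``curvature_amplitude_um`` optionally bends all bands along a shared
    sinusoid (period ``curvature_period_um``) to stress depth features on
    non-flat geometry.
    """

    bands: tuple[BandConfig, ...] = DEFAULT_BANDS
    section_width_um: float = 1400.0
    seed: int = 17
    curvature_amplitude_um: float = 0.0
    curvature_period_um: float = 2000.0


@dataclass(frozen=True)
class RaterNoiseConfig:
    """Smooth correlated boundary jitter emulating expert disagreement.

    ``amplitude_um`` is the standard deviation of the boundary displacement
    field; ``correlation_length_um`` its smoothness scale;
    ``boundary_scale`` multiplies the amplitude per internal boundary
    (first entry = layer I/II boundary, kept small: experts agree there).
    """

    amplitude_um: float = 85.0
    correlation_length_um: float = 150.0
    boundary_scale: Optional[tuple[float, ...]] = None  # default: (0.3, 1, 1, ...)


def band_boundaries(config: SceneConfig) -> np.ndarray:
    """Internal band boundary depths (y, um): len(bands) - 1 values."""
    widths = np.array([b.width_um for b in config.bands])
    return np.cumsum(widths)[:-1]


def _curvature(config: SceneConfig, x: np.ndarray) -> np.ndarray:
    if config.curvature_amplitude_um == 0:
        return np.zeros_like(x)
    return config.curvature_amplitude_um * np.sin(2 * np.pi * x / config.curvature_period_um)


def generate_scene(config: SceneConfig = SceneConfig(), seed: Optional[int] = None):
    """Sample a synthetic section.

    Returns ``(records, geometry)``: a canonical neuron table with an extra
    ``true_layer`` column (plus the sampled ``orientation_rad`` used when
    rendering), and a geometry dict (band names, boundary depths, section
    width, curvature) consumed by :func:`simulate_raters`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = config.section_width_um
    expected = sum(b.intensity * b.width_um * X for b in config.bands)
    if expected > MAX_EXPECTED_NEURONS:
        raise ValueError(f"expected neuron count {expected:.0f} exceeds desk-scale guard")
    rows = []
    y0 = 0.0
    for band in config.bands:
        n = rng.poisson(band.intensity * band.width_um * X)
        x = rng.uniform(0, X, n)
        y = rng.uniform(y0, y0 + band.width_um, n)
        area = rng.lognormal(np.log(band.area_median_um2), band.area_log_sd, n)
        circ = np.clip(rng.beta(*band.circ_beta, n), 1e-3, 1.0)
        aspect = 0.35 + 0.65 * rng.beta(*band.aspect_beta, n)
        rows.append(
            pd.DataFrame(
                {
                    "x_um": x,
                    "y_um": y + _curvature(config, x),
                    "area_um2": area,
                    "perimeter_um": np.sqrt(4 * np.pi * area / circ),
                    "circularity": circ,
                    "roundness": aspect,
                    "feret_um": 2 * np.sqrt(area / (np.pi * aspect)),
                    "orientation_rad": rng.uniform(0, np.pi, n),
                    "true_layer": band.name,
                }
            )
        )
        y0 += band.width_um
    records = pd.concat(rows, ignore_index=True)
    records.insert(0, "id", np.arange(1, len(records) + 1))
    geometry = {
        "band_names": [b.name for b in config.bands],
        "boundaries_um": band_boundaries(config).tolist(),
        "section_width_um": X,
        "total_depth_um": float(sum(b.width_um for b in config.bands)),
        "curvature_amplitude_um": config.curvature_amplitude_um,
        "curvature_period_um": config.curvature_period_um,
    }
    log.info("generated scene: %d neurons in %d bands", len(records), len(config.bands))
    return records, geometry


_FIELD_SIGMA_CELLS = 4.0


def _smooth_unit_field(rng, X: float, correlation_length_um: float) -> tuple[np.ndarray, np.ndarray]:
    """A smooth Gaussian field on [0, X] with unit *process* variance.

    White noise on a grid of spacing ``correlation_length/4`` smoothed with
    a Gaussian kernel; the result is rescaled by the kernel's l2 norm
    (computed from an impulse response), not by the realisation's empirical
    std — a nearly-flat realisation must stay nearly flat.
    """
    h = correlation_length_um / _FIELD_SIGMA_CELLS
    pad = 5 * _FIELD_SIGMA_CELLS * h
    xs = np.arange(-pad, X + pad + h, h)
    z = rng.normal(size=len(xs))
    f = gaussian_filter1d(z, sigma=_FIELD_SIGMA_CELLS, mode="reflect")
    impulse = np.zeros(int(16 * _FIELD_SIGMA_CELLS) + 1)
    impulse[len(impulse) // 2] = 1.0
    kernel = gaussian_filter1d(impulse, sigma=_FIELD_SIGMA_CELLS)
    f = f / np.sqrt((kernel**2).sum())
    return xs, f


def simulate_raters(
    records: pd.DataFrame,
    geometry: dict,
    noise: RaterNoiseConfig = RaterNoiseConfig(),
    n_raters: int = 3,
    seed: int = 17,
) -> pd.DataFrame:
    """Label every neuron by ``n_raters`` simulated annotators.

    Each rater displaces every internal band boundary by an independent
    smooth field; a neuron's label is the band containing it under that
    rater's boundaries.  Returns a DataFrame indexed by neuron id with one
    column per rater.  Amplitude zero reproduces the ground truth exactly.
    """
    bounds = np.asarray(geometry["boundaries_um"], float)
    names = list(geometry["band_names"])
    widths = np.diff(np.concatenate([[0.0], bounds, [geometry["total_depth_um"]]]))
    scale = noise.boundary_scale
    if scale is None:
        scale = tuple([0.3] + [1.0] * (len(bounds) - 1))
    if len(scale) != len(bounds):
        raise ValueError(f"boundary_scale needs {len(bounds)} entries, got {len(scale)}")
    for b, s in enumerate(scale):
        adjacent = min(widths[b], widths[b + 1])
        if noise.amplitude_um * s >= adjacent:
            raise ValueError(
                f"jitter amplitude {noise.amplitude_um * s:.0f} um >= adjacent band width "
                f"{adjacent:.0f} um at boundary {b}"
            )
    x = records["x_um"].to_numpy(float)
    y = records["y_um"].to_numpy(float)
    curve = np.zeros_like(x)
    if geometry.get("curvature_amplitude_um", 0.0):
        curve = geometry["curvature_amplitude_um"] * np.sin(
            2 * np.pi * x / geometry["curvature_period_um"]
        )
    out = {}
    for r in range(n_raters):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        jittered = np.empty((len(bounds), len(x)))
        for b, base in enumerate(bounds):
            xs, f = _smooth_unit_field(rng, geometry["section_width_um"], noise.correlation_length_um)
            delta = noise.amplitude_um * scale[b] * np.interp(x, xs, f)
            clip = 0.49 * min(widths[b], widths[b + 1])
            jittered[b] = base + np.clip(delta, -clip, clip) + curve
        # enforce band order per column (clipping makes violations rare)
        jittered = np.maximum.accumulate(jittered, axis=0)
        layer_idx = (y[None, :] > jittered).sum(axis=0)
        out[f"rater_{r + 1}"] = np.take(names, layer_idx)
    labels = pd.DataFrame(out, index=pd.Index(records["id"].astype(int), name="id"))
    return labels


def render_mask(
    records: pd.DataFrame,
    resolution: float = 0.226,
    shape: Optional[tuple[int, int]] = None,
    seed: int = 17,
    background: int = 235,
    return_stats: bool = False,
):
    """Rasterise neuron records into a label mask + synthetic intensity image.

    Each neuron is drawn as a rotated ellipse with the record's area and
    aspect (roundness); overlaps are resolved by id priority (later id
    wins; the overlap fraction is logged).  Off-canvas neurons are clipped.
    The intensity image gives each neuron a gray level (darker than the
    background, with pixel noise), emulating stained somata.
    """
    from skimage.draw import ellipse as draw_ellipse

    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    rng = np.random.default_rng(seed)
    x = records["x_um"].to_numpy(float) / resolution
    y = records["y_um"].to_numpy(float) / resolution
    area_px = records["area_um2"].to_numpy(float) / resolution**2
    aspect = records["roundness"].to_numpy(float)
    orient = (
        records["orientation_rad"].to_numpy(float)
        if "orientation_rad" in records.columns
        else np.zeros(len(records))
    )
    a = np.sqrt(area_px / (np.pi * aspect))  # semi-major (px)
    b = area_px / (np.pi * a)
    if shape is None:
        pad = int(np.ceil(a.max())) + 2 if len(a) else 2
        shape = (int(np.ceil(y.max())) + pad if len(y) else 4, int(np.ceil(x.max())) + pad if len(x) else 4)
    labels = np.zeros(shape, dtype=np.int32)
    intensity = np.full(shape, float(background))
    painted = 0
    overwritten = 0
    clipped_ids = []
    for i in range(len(records)):
        rr, cc = draw_ellipse(y[i], x[i], b[i], a[i], shape=shape, rotation=orient[i])
        if len(rr) == 0:
            clipped_ids.append(int(records["id"].iloc[i]))
            continue
        overwritten += int((labels[rr, cc] != 0).sum())
        painted += len(rr)
        labels[rr, cc] = int(records["id"].iloc[i])
        gray = rng.uniform(60, 160)
        intensity[rr, cc] = gray + rng.normal(0, 3, len(rr))
    intensity += rng.normal(0, 4, shape)
    intensity = np.clip(intensity, 0, 255).astype(np.uint8)
    overlap_fraction = overwritten / painted if painted else 0.0
    if overlap_fraction > 0:
        log.info("render overlap fraction: %.4f", overlap_fraction)
    if clipped_ids:
        log.warning("%d neurons fell outside the canvas and were clipped", len(clipped_ids))
    mask = CalibratedMask(labels=labels, intensity=intensity, resolution=resolution)
    if return_stats:
        return mask, {"overlap_fraction": overlap_fraction, "clipped_ids": clipped_ids}
    return mask


def save_scene(records: pd.DataFrame, geometry: dict, out_dir) -> None:
    """Write a scene as neuron-table CSV + geometry JSON."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records.to_csv(out_dir / "neurons.csv", index=False)
    (out_dir / "geometry.json").write_text(json.dumps(geometry, indent=1))


def load_scene(out_dir):
    from pathlib import Path

    out_dir = Path(out_dir)
    records = pd.read_csv(out_dir / "neurons.csv")
    geometry = json.loads((out_dir / "geometry.json").read_text())
    return records, geometry
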