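"""Synthetic spatial scenes and fibril images with known ground truth.

Emulates the study inputs end-to-end so every downstream stage is testable
without external data:

* a regular spot lattice with a disk-shaped "anlagen" region marked in the
  same pixel frame;
* per-spot cell-type prediction-score fields — by default a macrophage-like
  field highest inside the region and a mesenchymal-progenitor-like field
  peaking outside the region border — with additive Gaussian noise clipped
  to [0, 1];
* gene-by-spot counts drawn from a negative binomial (variance
  mu + mu^2/theta) around a mean that follows a decreasing, peaked or flat
  gradient along the true SpatialTime axis;
* grayscale fibril images rendered from line segments whose orientations
  follow a wrapped normal on the half-circle, with the nematic order
  parameter of the sampled angles as analytic ground-truth anisotropy.

Every generator takes one integer seed and derives per-gene / per-cell-type
substreams from it deterministically, so identical calls are byte-identical
and adding a gene never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.optimize import brentq

from .distance import SpatialTimeScores
from .exceptions import ConfigurationError
from .io import (
    RegionMask,
    SpotTable,
    polygon_to_geojson,
    write_region_mask,
    write_spot_table,
)

__all__ = [
    "GradientSpec",
    "LayoutSpec",
    "Scene",
    "FibrilSample",
    "generate_layout",
    "true_spatialtime",
    "generate_prediction_scores",
    "generate_counts",
    "generate_fibril_image",
    "default_scenario",
    "build_scene",
    "generate_fibril_cohorts",
    "write_scene",
]

GRADIENT_SHAPES = ("decreasing", "peaked", "flat")


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientSpec:
    """Mean profile of a value along SpatialTime plus count noise.

    ``shape`` is one of decreasing / peaked / flat. ``amplitude`` is the
    expected excess over ``baseline`` at the gradient's extremum; ``width``
    is the length-scale on the SpatialTime axis (decay constant for
    decreasing, Gaussian sd for peaked); ``dispersion`` is the negative
    binomial theta (variance = mu + mu^2/theta).
    """

    shape: str
    amplitude: float = 30.0
    baseline: float = 0.5
    width: float = 0.12
    peak_position: float | None = None
    dispersion: float = 8.0

    def __post_init__(self) -> None:
        if self.shape not in GRADIENT_SHAPES:
            raise ConfigurationError(
                f"unknown gradient shape {self.shape!r}; "
                f"expected one of {GRADIENT_SHAPES}"
            )
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.baseline < 0:
            raise ConfigurationError("baseline must be >= 0")
        if self.width <= 0:
            raise ConfigurationError("width must be > 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.shape == "peaked":
            if self.peak_position is None:
                raise ConfigurationError("peaked shape requires peak_position")
            if not 0 <= self.peak_position <= 1:
                raise ConfigurationError("peak_position must be in [0, 1]")
        elif self.peak_position is not None:
            raise ConfigurationError(
                f"peak_position only applies to the peaked shape, "
                f"not {self.shape!r}"
            )

    def mean_at(self, spatialtime: np.ndarray) -> np.ndarray:
        """Expected value at each SpatialTime position."""
        st = np.asarray(spatialtime, dtype=float)
        if self.shape == "flat" or self.amplitude == 0:
            return np.full_like(st, self.baseline)
        if self.shape == "decreasing":
            return self.baseline + self.amplitude * np.exp(-st / self.width)
        # peaked
        z = (st - self.peak_position) / self.width
        return self.baseline + self.amplitude * np.exp(-0.5 * z**2)

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "amplitude": self.amplitude,
            "baseline": self.baseline,
            "width": self.width,
            "peak_position": self.peak_position,
            "dispersion": self.dispersion,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GradientSpec":
        return cls(**{k: d[k] for k in d})


@dataclass(frozen=True)
class LayoutSpec:
    """Spot lattice plus a disk-shaped marked region, all in pixel units."""

    grid_nx: int = 45
    grid_ny: int = 45
    pixel_pitch: float = 10.0
    region_center: tuple[float, float] | None = None  # default: frame center
    region_radius: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ConfigurationError("grid dimensions must be >= 1")
        if self.pixel_pitch <= 0:
            raise ConfigurationError("pixel_pitch must be > 0")
        if self.region_radius < 0:
            raise ConfigurationError("region_radius must be >= 0")
        cx, cy = self.center
        w, h = self.frame_width, self.frame_height
        r = self.region_radius
        if cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
            raise ConfigurationError(
                "region disk extends outside the lattice bounding box"
            )

    @property
    def frame_width(self) -> int:
        return int(round((self.grid_nx - 1) * self.pixel_pitch)) + 1

    @property
    def frame_height(self) -> int:
        return int(round((self.grid_ny - 1) * self.pixel_pitch)) + 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.frame_height, self.frame_width)

    @property
    def center(self) -> tuple[float, float]:
        if self.region_center is not None:
            return tuple(self.region_center)
        return ((self.frame_width - 1) / 2.0, (self.frame_height - 1) / 2.0)

    def spot_coordinates(self) -> np.ndarray:
        jj, ii = np.meshgrid(np.arange(self.grid_nx), np.arange(self.grid_ny))
        return np.column_stack(
            [jj.ravel() * self.pixel_pitch, ii.ravel() * self.pixel_pitch]
        ).astype(float)

    def to_dict(self) -> dict:
        return {
            "grid_nx": self.grid_nx,
            "grid_ny": self.grid_ny,
            "pixel_pitch": self.pixel_pitch,
            "region_center": list(self.center),
            "region_radius": self.region_radius,
            "seed": self.seed,
        }


def _substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-name RNG substream from one integer seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Layout and ground-truth axis
# ---------------------------------------------------------------------------

def generate_layout(spec: LayoutSpec) -> tuple[SpotTable, RegionMask]:
    """One spot per lattice node plus the rasterized disk region."""
    xy = spec.spot_coordinates()
    n = len(xy)
    spots = pd.DataFrame(
        {
            "spot_id": [f"spot_{k:05d}" for k in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    table = SpotTable(spots=spots, counts=np.zeros((0, n), dtype=np.int64), genes=[])
    h, w = spec.frame_shape
    cx, cy = spec.center
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    raster = (jj - cx) ** 2 + (ii - cy) ** 2 <= spec.region_radius**2
    mask = RegionMask(raster=raster, meta={"source": "disk", **spec.to_dict()})
    return table, mask


def true_spatialtime(
    spec: LayoutSpec, signed: bool = True
) -> tuple[np.ndarray, float]:
    """Analytic SpatialTime of every lattice spot, plus the border position.

    Uses the exact disk geometry (no rasterization): the signed distance of
    a spot is its center distance to the disk center minus the radius, then
    min-max scaled over the spot set. Returns (spatialtime, border), where
    ``border`` is the scaled position of raw distance 0 (the region edge).
    """
    xy = spec.spot_coordinates()
    cx, cy = spec.center
    d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) - spec.region_radius
    if not signed:
        d = np.maximum(d, 0.0)
    lo, hi = d.min(), d.max()
    if hi == lo:
        return np.zeros(len(d)), 0.0
    st = (d - lo) / (hi - lo)
    border = float(np.clip((0.0 - lo) / (hi - lo), 0.0, 1.0))
    return st, border


# ---------------------------------------------------------------------------
# Prediction scores and counts
# ---------------------------------------------------------------------------

def generate_prediction_scores(
    layout: LayoutSpec,
    celltype_specs: Mapping[str, GradientSpec],
    noise_sd: float = 0.05,
    seed: int = 0,
    signed: bool = True,
) -> pd.DataFrame:
    """Per-spot prediction scores in [0, 1] for each cell type.

    Each cell type's noiseless score is its gradient profile evaluated at
    the spot's true SpatialTime; additive Gaussian noise (sd ``noise_sd``)
    is then applied and the result clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    st, _ = true_spatialtime(layout, signed=signed)
    cols = {}
    for name, spec in celltype_specs.items():
        mu = spec.mean_at(st)
        if noise_sd > 0:
            mu = mu + _substream(seed, f"score:{name}").normal(0, noise_sd, len(st))
        cols[name] = np.clip(mu, 0.0, 1.0)
    return pd.DataFrame(cols)


def generate_counts(
    layout: LayoutSpec,
    scores: SpatialTimeScores | np.ndarray,
    gene_specs: Mapping[str, GradientSpec],
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Gene-by-spot negative binomial counts along the SpatialTime axis.

    The expected count of gene g at a spot is ``gene_specs[g].mean_at(st)``;
    counts are drawn NB(mean mu, dispersion theta) so that
    var = mu + mu^2/theta. Returns (counts, gene_names).
    """
    st = scores.spatialtime if isinstance(scores, SpatialTimeScores) else scores
    st = np.asarray(st, dtype=float)
    genes = list(gene_specs)
    counts = np.zeros((len(genes), len(st)), dtype=np.int64)
    for gi, name in enumerate(genes):
        spec = gene_specs[name]
        mu = spec.mean_at(st)
        if np.any(mu < 0):
            raise ConfigurationError(f"gene {name!r}: negative mean counts")
        rng = _substream(seed, f"gene:{name}")
        theta = spec.dispersion
        pos = mu > 0
        p = np.ones_like(mu)
        p[pos] = theta / (theta + mu[pos])
        counts[gi, pos] = rng.negative_binomial(theta, p[pos])
    return counts, genes


# ---------------------------------------------------------------------------
# Fibril images
# ---------------------------------------------------------------------------

@dataclass
class FibrilSample:
    """A rendered fibril image plus analytic ground truth."""

    image: np.ndarray  # float in [0, 1]
    truth_anisotropy: float  # nematic order parameter of the sampled angles
    mean_angle_deg: float
    concentration: float
    angles: np.ndarray = field(repr=False, default=None)


def _nematic_order(angles: np.ndarray) -> float:
    """|mean(exp(2i*theta))| — 1 for perfect alignment, ~0 for uniform."""
    return float(np.abs(np.mean(np.exp(2j * angles))))


def generate_fibril_image(
    width: int,
    height: int,
    mean_angle_deg: float = 0.0,
    concentration: float = 8.0,
    n_fibers: int = 18,
    noise_sd: float = 0.0,
    seed: int = 0,
    fiber_width_sigma: float = 1.5,
) -> FibrilSample:
    """Render straight fibril bundles with wrapped-normal orientations.

    ``concentration`` parameterizes the wrapped normal on the half-circle as
    1/sigma^2: 0 means uniformly random orientations, infinity puts every
    fiber exactly at ``mean_angle_deg``. Angles are measured from +x toward
    +y (row direction).

    Each fiber is a full-frame chord with a Gaussian cross-section
    (``fiber_width_sigma`` pixels); fibers compose by occlusion (per-pixel
    maximum), as in a projection image, so the local intensity gradient
    stays perpendicular to whichever fiber is locally brightest. The
    returned ground truth is the nematic order parameter of the actually
    sampled angles. Additive background noise (``noise_sd``) is available
    for robustness studies; note that diffuse background texture biases an
    unweighted gradient-tensor readout toward isotropy, so the default
    background is clean.
    """
    if width <= 0 or height <= 0:
        raise ConfigurationError("image dimensions must be positive")
    if concentration < 0:
        raise ConfigurationError("concentration must be >= 0")
    if n_fibers < 1:
        raise ConfigurationError("n_fibers must be >= 1")
    rng = _substream(seed, "fibrils")
    mean_rad = np.radians(mean_angle_deg)
    if np.isinf(concentration):
        angles = np.full(n_fibers, mean_rad)
    elif concentration == 0:
        angles = rng.uniform(-np.pi / 2, np.pi / 2, n_fibers)
    else:
        angles = mean_rad + rng.normal(0, 1 / np.sqrt(concentration), n_fibers)
    # wrap onto the half-circle (irrelevant for the order parameter)
    angles = ((angles + np.pi / 2) % np.pi) - np.pi / 2
    truth = _nematic_order(angles)

    jj, ii = np.meshgrid(np.arange(width, dtype=float),
                         np.arange(height, dtype=float))
    canvas = np.zeros((height, width), dtype=float)
    for theta in angles:
        cx = rng.uniform(0, width - 1)
        cy = rng.uniform(0, height - 1)
        # signed perpendicular distance of each pixel to the fiber axis
        d = (jj - cx) * (-np.sin(theta)) + (ii - cy) * np.cos(theta)
        np.maximum(canvas, np.exp(-0.5 * (d / fiber_width_sigma) ** 2),
                   out=canvas)
    peak = canvas.max()
    if peak > 0:
        canvas /= peak
    if noise_sd > 0:
        canvas = canvas + rng.normal(0, noise_sd, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    return FibrilSample(
        image=canvas,
        truth_anisotropy=truth,
        mean_angle_deg=mean_angle_deg,
        concentration=concentration,
        angles=angles,
    )


def generate_fibril_cohorts(
    seed: int = 0,
    n_per_group: int = 3,
    concentration_high: float = 16.0,
    concentration_low: float = 1.0,
    width: int = 384,
    height: int = 384,
) -> dict[str, list[FibrilSample]]:
    """Two image cohorts mimicking organized vs disorganized collagen.

    The high-concentration group plays the role of well-aligned wild-type
    matrix, the low-concentration group the disorganized knockout matrix.
    """
    cohorts: dict[str, list[FibrilSample]] = {"aligned": [], "disorganized": []}
    for g, conc in (("aligned", concentration_high),
                    ("disorganized", concentration_low)):
        for k in range(n_per_group):
            cohorts[g].append(
                generate_fibril_image(
                    width, height,
                    mean_angle_deg=30.0,
                    concentration=conc,
                    seed=int(np.random.SeedSequence(
                        [int(seed), zlib.crc32(f"{g}:{k}".encode())]
                    ).generate_state(1)[0] % (2**31)),
                )
            )
    return cohorts


# ---------------------------------------------------------------------------
# Full scene (spot lattice + scores + counts + ground truth)
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """A complete simulated study input with its generating ground truth."""

    table: SpotTable
    mask: RegionMask
    layout: LayoutSpec
    gene_specs: dict[str, GradientSpec]
    celltype_specs: dict[str, GradientSpec]
    ground_truth: dict
    scenario: dict


def _solve_inside_width(border: float, outside: GradientSpec) -> float:
    """Width of the inside-high score profile so that, after per-profile
    min-max scaling, the noiseless inside-high and outside-peaked curves
    cross exactly at the region border."""
    p, w = outside.peak_position, outside.width
    grid = np.linspace(0, 1, 2001)
    bvals = np.exp(-0.5 * ((grid - p) / w) ** 2)
    b_scaled = (np.interp(border, grid, bvals) - bvals.min()) / (
        bvals.max() - bvals.min()
    )

    def f(wa: float) -> float:
        a = (np.exp(-border / wa) - np.exp(-1 / wa)) / (1 - np.exp(-1 / wa))
        return a - b_scaled

    return float(brentq(f, 0.02, 5.0))


def default_scenario(seed: int = 0) -> dict:
    """The default simulated scene.

    A 45x45 spot lattice (2025 spots, pitch 10 px) with a radius-60 disk as
    the marked region; a decreasing Thbs1-like gene, a Thbs2-like gene
    peaking outside the region border, and 30 flat background genes; an
    inside-high macrophage score field and an MPC score field peaking
    beyond the border, constructed so the two scaled score profiles cross
    at the border itself.
    """
    return {
        "seed": int(seed),
        "signed": True,
        "score_noise_sd": 0.05,
        "layout": {
            "grid_nx": 45,
            "grid_ny": 45,
            "pixel_pitch": 10.0,
            "region_radius": 60.0,
        },
        "genes": {
            "Thbs1": {"shape": "decreasing", "amplitude": 60.0,
                      "baseline": 0.5, "width": 0.2, "dispersion": 20.0},
            "Thbs2": {"shape": "peaked", "amplitude": 60.0, "baseline": 0.5,
                      "width": 0.12, "peak_position": 0.45, "dispersion": 20.0},
        },
        "n_background_genes": 30,
        "background_gene": {"shape": "flat", "amplitude": 0.0,
                            "baseline": 8.0, "width": 1.0, "dispersion": 10.0},
        "cell_types": {
            "macrophage": {"shape": "decreasing", "amplitude": 0.85,
                           "baseline": 0.05, "width": None,  # solved
                           "dispersion": 1.0},
            "mpc": {"shape": "peaked", "amplitude": 0.85, "baseline": 0.05,
                    "width": 0.25, "peak_position": 0.55, "dispersion": 1.0},
        },
    }


def build_scene(scenario: Mapping | None = None, seed: int | None = None) -> Scene:
    """Materialize a scenario dict (see :func:`default_scenario`) into data."""
    sc = dict(default_scenario() if scenario is None else scenario)
    if seed is not None:
        sc["seed"] = int(seed)
    seed = int(sc.get("seed", 0))
    signed = bool(sc.get("signed", True))
    layout = LayoutSpec(**sc["layout"], seed=seed)
    table, mask = generate_layout(layout)
    st, border = true_spatialtime(layout, signed=signed)

    ct_specs: dict[str, GradientSpec] = {}
    for name, d in sc["cell_types"].items():
        d = dict(d)
        if d.get("width") is None:
            # solved so the scaled score profiles cross at the border
            outside = next(
                GradientSpec.from_dict(v) for k, v in sc["cell_types"].items()
                if v.get("shape") == "peaked"
            )
            d["width"] = _solve_inside_width(border, outside)
        ct_specs[name] = GradientSpec.from_dict(d)
    scores = generate_prediction_scores(
        layout, ct_specs, noise_sd=float(sc.get("score_noise_sd", 0.05)),
        seed=seed, signed=signed,
    )

    gene_specs = {n: GradientSpec.from_dict(d) for n, d in sc["genes"].items()}
    bg = sc.get("background_gene")
    for k in range(int(sc.get("n_background_genes", 0))):
        gene_specs[f"Bg{k + 1:02d}"] = GradientSpec.from_dict(bg)
    counts, genes = generate_counts(layout, st, gene_specs, seed=seed)

    full = SpotTable(
        spots=table.spots, counts=counts, genes=genes, scores=scores
    )
    truth = {
        "border_spatialtime": border,
        "signed": signed,
        "gene_shapes": {n: s.shape for n, s in gene_specs.items()},
        "gene_peaks": {
            n: s.peak_position for n, s in gene_specs.items()
            if s.shape == "peaked"
        },
        "score_crossing_spatialtime": border,
        "celltype_shapes": {n: s.shape for n, s in ct_specs.items()},
    }
    return Scene(
        table=full, mask=mask, layout=layout, gene_specs=gene_specs,
        celltype_specs=ct_specs, ground_truth=truth, scenario=sc,
    )


def write_scene(scene: Scene, out_dir: str | Path) -> dict[str, Path]:
    """Write a scene's artifacts: CSV/MTX/GeoJSON/PNG/YAML/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spots_csv": out / "spots.csv",
        "counts_mtx": out / "counts.mtx",
        "genes_txt": out / "genes.txt",
        "scores_csv": out / "scores.csv",
        "region_png": out / "region_mask.png",
        "region_geojson": out / "region.geojson",
        "scenario_yaml": out / "scenario.yaml",
        "ground_truth_json": out / "ground_truth.json",
    }
    write_spot_table(
        scene.table, paths["spots_csv"], paths["counts_mtx"],
        paths["genes_txt"], paths["scores_csv"],
    )
    write_region_mask(scene.mask, paths["region_png"])
    cx, cy = scene.layout.center
    r = max(scene.layout.region_radius, 0.5)
    ang = np.linspace(0, 2 * np.pi, 65)[:-1]
    polygon_to_geojson(
        [(cx + r * np.cos(a), cy + r * np.sin(a)) for a in ang],
        paths["region_geojson"],
    )
    paths["scenario_yaml"].write_text(yaml.safe_dump(scene.scenario, sort_keys=True))
    paths["ground_truth_json"].write_text(
        json.dumps(scene.ground_truth, indent=1, sort_keys=True)
    )
    return paths


def write_fibril_image(sample: FibrilSample, path: str | Path) -> None:
    """Write a fibril image as 16-bit grayscale TIFF."""
    tifffile.imwrite(
        str(path), (sample.image * 65535).astype(np.uint16)
    )
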