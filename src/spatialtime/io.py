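"""Reading and writing the on-disk artifacts of a spatial analysis.

Coordinate convention
---------------------
All coordinates are 0-based pixel indices in the full-resolution image
frame: ``x`` indexes columns, ``y`` indexes rows, and y increases downward
(image convention). The pixel at array position ``[i, j]`` has its center at
``(x, y) = (j, i)``. Spot centers live in the same frame and may be
fractional. Boundary pixels — centers lying exactly on a polygon edge —
count as inside.

Counts are stored in Matrix Market coordinate format (genes x spots) with a
plain-text gene-name sidecar; spot metadata and prediction scores are CSV.
Region masks travel either as a single-channel PNG (0/255) or as a GeoJSON
polygon rasterized onto the pixel frame.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
from scipy import io as spio
from scipy import sparse
from shapely.geometry import Polygon, shape as geojson_shape

from .exceptions import EmptyRegionError, FormatError, ValidationError

__all__ = [
    "SpotTable",
    "RegionMask",
    "read_spot_table",
    "write_spot_table",
    "read_region",
    "write_region_mask",
    "rasterize_polygon",
    "polygon_to_geojson",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class SpotTable:
    """A table of spatial spots: coordinates, counts and optional scores.

    Parameters
    ----------
    spots : pandas.DataFrame
        Columns ``spot_id`` (unique strings), ``x``, ``y`` (pixel units).
    counts : numpy.ndarray
        Dense gene-by-spot matrix of non-negative integers; column order
        matches the row order of ``spots``.
    genes : list of str
        Gene names, one per counts row.
    scores : pandas.DataFrame, optional
        Per-spot cell-type prediction scores in [0, 1]; one row per spot in
        spot order, one column per cell type.
    """

    spots: pd.DataFrame
    counts: np.ndarray
    genes: list[str]
    scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.genes = list(self.genes)
        self.validate()

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        for col in ("spot_id", "x", "y"):
            if col not in self.spots.columns:
                raise FormatError(f"spot table lacks required column {col!r}")
        ids = self.spots["spot_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValidationError(f"duplicate spot_id values: {dupes[:5]}")
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D gene-by-spot matrix")
        if self.counts.shape != (len(self.genes), len(self.spots)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.array_equal(self.counts, np.round(self.counts)):
                    raise ValidationError("counts must be integers")
                self.counts = self.counts.astype(np.int64)
            neg = np.argwhere(self.counts < 0)
            if len(neg):
                g, s = neg[0]
                raise ValidationError(
                    f"negative count {self.counts[g, s]} at gene "
                    f"{self.genes[g]!r}, spot {ids.iloc[s]!r}"
                )
        if self.scores is not None:
            if len(self.scores) != len(self.spots):
                raise ValidationError(
                    f"scores cover {len(self.scores)} spots but the table "
                    f"has {len(self.spots)}"
                )
            vals = self.scores.to_numpy(dtype=float)
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise ValidationError("prediction scores must lie in [0, 1]")


@dataclass
class RegionMask:
    """Binary raster of a marked region, aligned to the pixel frame."""

    raster: np.ndarray
    origin: tuple[int, int] = (0, 0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster).astype(bool)
        if self.raster.ndim != 2:
            raise FormatError("region raster must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    @property
    def n_positive(self) -> int:
        return int(self.raster.sum())

    def require_nonempty(self) -> None:
        if not self.raster.any():
            raise EmptyRegionError("region mask has no positive pixels")


# ---------------------------------------------------------------------------
# Spot table I/O
# ---------------------------------------------------------------------------

def write_spot_table(
    table: SpotTable,
    csv_path: str | Path,
    mtx_path: str | Path,
    genes_path: str | Path,
    scores_path: str | Path | None = None,
) -> None:
    """Write a SpotTable as CSV + Matrix Market triplet + gene sidecar."""
    table.validate()
    table.spots[["spot_id", "x", "y"]].to_csv(csv_path, index=False)
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(table.counts.astype(np.int64)))
    Path(genes_path).write_text("\n".join(table.genes) + "\n")
    if scores_path is not None:
        if table.scores is None:
            raise ValidationError("scores_path given but table has no scores")
        out = table.scores.copy()
        out.insert(0, "spot_id", table.spots["spot_id"].to_numpy())
        out.to_csv(scores_path, index=False)


def read_spot_table(
    csv_path: str | Path,
    mtx_path: str | Path,
    genes_path: str | Path,
    scores_path: str | Path | None = None,
) -> SpotTable:
    """Read a SpotTable written by :func:`write_spot_table`.

    Raises
    ------
    FormatError
        If the CSV spot count and the MTX column count disagree.
    ValidationError
        If the matrix contains a negative entry.
    """
    spots = pd.read_csv(csv_path, dtype={"spot_id": str})
    mat = spio.mmread(str(mtx_path))
    counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    if counts.shape[1] != len(spots):
        raise FormatError(
            f"counts matrix has {counts.shape[1]} spot columns but the spot "
            f"CSV lists {len(spots)} spots"
        )
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"counts matrix has {counts.shape[0]} gene rows but the gene "
            f"list has {len(genes)} entries"
        )
    scores = None
    if scores_path is not None:
        sdf = pd.read_csv(scores_path, dtype={"spot_id": str})
        if "spot_id" in sdf.columns:
            order = {sid: i for i, sid in enumerate(spots["spot_id"])}
            missing = set(spots["spot_id"]) - set(sdf["spot_id"])
            if missing:
                raise ValidationError(
                    f"scores missing for {len(missing)} spots, e.g. "
                    f"{sorted(missing)[:3]}"
                )
            sdf = sdf.sort_values("spot_id", key=lambda s: s.map(order))
            sdf = sdf.drop(columns="spot_id").reset_index(drop=True)
        scores = sdf
    return SpotTable(spots=spots, counts=counts, genes=genes, scores=scores)


# ---------------------------------------------------------------------------
# Region I/O and rasterization
# ---------------------------------------------------------------------------

def _as_polygon(polygon: Polygon | Sequence[tuple[float, float]]) -> Polygon:
    if isinstance(polygon, Polygon):
        poly = polygon
    else:
        pts = list(polygon)
        if len({tuple(p) for p in pts}) < 3:
            raise FormatError(
                f"polygon needs at least 3 distinct vertices, got {len(pts)}"
            )
        poly = Polygon(pts)
    if poly.is_empty or len(poly.exterior.coords) < 4:
        raise FormatError("degenerate polygon: fewer than 3 distinct vertices")
    if not poly.is_valid:
        raise FormatError("polygon is self-intersecting or otherwise invalid")
    if poly.area == 0:
        raise EmptyRegionError("polygon has zero area")
    return poly


def rasterize_polygon(
    polygon: Polygon | Sequence[tuple[float, float]],
    frame_shape: tuple[int, int],
) -> RegionMask:
    """Rasterize a polygon onto a pixel frame.

    A pixel is positive iff its center ``(x, y) = (col, row)`` lies inside
    or on the boundary of the polygon. Portions of the polygon outside the
    frame are clipped with a warning.
    """
    poly = _as_polygon(polygon)
    ny, nx = int(frame_shape[0]), int(frame_shape[1])
    if ny <= 0 or nx <= 0:
        raise FormatError(f"invalid frame shape {frame_shape}")
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > nx - 0.5 or maxy > ny - 0.5:
        warnings.warn(
            "polygon extends outside the pixel frame; clipping to the frame",
            stacklevel=2,
        )
    # Only scan the bounding box; everything else is negative.
    j0 = max(0, int(np.floor(minx)))
    j1 = min(nx - 1, int(np.ceil(maxx)))
    i0 = max(0, int(np.floor(miny)))
    i1 = min(ny - 1, int(np.ceil(maxy)))
    raster = np.zeros((ny, nx), dtype=bool)
    if j1 >= j0 and i1 >= i0:
        jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
        pts = shapely.points(jj.ravel().astype(float), ii.ravel().astype(float))
        inside = shapely.intersects(poly, pts)  # covers interior + boundary
        raster[ii.ravel()[inside], jj.ravel()[inside]] = True
    mask = RegionMask(raster=raster, meta={"source": "polygon"})
    mask.require_nonempty()
    return mask


def polygon_to_geojson(
    polygon: Polygon | Sequence[tuple[float, float]], path: str | Path
) -> None:
    """Write a polygon as a single-feature GeoJSON file."""
    poly = _as_polygon(polygon)
    feature = {
        "type": "Feature",
        "properties": {"name": "region"},
        "geometry": json.loads(shapely.to_geojson(poly)),
    }
    doc = {"type": "FeatureCollection", "features": [feature]}
    Path(path).write_text(json.dumps(doc, indent=1))


def _polygon_from_geojson(path: Path) -> Polygon:
    doc = json.loads(path.read_text())
    geom = doc
    if doc.get("type") == "FeatureCollection":
        feats = doc.get("features") or []
        if not feats:
            raise FormatError(f"{path}: GeoJSON has no features")
        geom = feats[0]["geometry"]
    elif doc.get("type") == "Feature":
        geom = doc["geometry"]
    g = geojson_shape(geom)
    if g.geom_type != "Polygon":
        raise FormatError(f"{path}: expected a Polygon, got {g.geom_type}")
    return _as_polygon(g)


def read_region(
    path: str | Path, frame_shape: tuple[int, int] | None = None
) -> RegionMask:
    """Read a marked region from GeoJSON or a label image.

    GeoJSON polygons are rasterized onto ``frame_shape`` (required).
    Images must be single-channel; pixels > 0 are positive.
    """
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        if frame_shape is None:
            raise FormatError("frame_shape is required to rasterize a polygon")
        return rasterize_polygon(_polygon_from_geojson(path), frame_shape)
    img = np.asarray(iio.imread(path))
    if img.ndim != 2:
        raise FormatError(
            f"{path}: region image must be single-channel, got shape {img.shape}"
        )
    raster = img > 0
    if not raster.any():
        raise EmptyRegionError(f"{path}: label image has no positive pixels")
    if frame_shape is not None and tuple(raster.shape) != tuple(frame_shape):
        raise FormatError(
            f"{path}: image shape {raster.shape} != frame shape {tuple(frame_shape)}"
        )
    return RegionMask(raster=raster, meta={"source": str(path)})


def write_region_mask(mask: RegionMask, path: str | Path) -> None:
    """Write a region mask as a single-channel 0/255 PNG."""
    iio.imwrite(path, (mask.raster.astype(np.uint8)) * 255)
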