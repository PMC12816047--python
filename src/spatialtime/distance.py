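"""The SpatialTime axis: per-spot distance to a marked region, scaled to [0, 1].

Each spot's raw distance is the minimum Euclidean distance from its center
to the center of any positive mask pixel; a spot whose own pixel is positive
scores exactly 0. Raw distances are then min-max scaled so the analyzed spot
set spans [0, 1], with 0 nearest the region. Optionally, interior spots can
receive *signed* (negative) distances — the distance to the region's
complement — so that the axis resolves structure inside the region border
as well as outside it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import EmptyRegionError, ValidationError
from .io import RegionMask, SpotTable

__all__ = [
    "SpatialTimeScores",
    "spot_region_distances",
    "scale_distances",
    "compute_spatialtime",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialTimeScores:
    """Raw and scaled per-spot distances to the reference region."""

    spot_id: np.ndarray
    raw_distance: np.ndarray
    spatialtime: np.ndarray
    signed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": self.spot_id,
                "raw_distance": self.raw_distance,
                "spatialtime": self.spatialtime,
            }
        )


def _pixel_centers(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.column_stack([cols.astype(float), rows.astype(float)])


def _containing_pixel_positive(xy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """True where a spot center falls on (rounds to) a positive mask pixel."""
    ny, nx = mask.shape
    j = np.rint(xy[:, 0]).astype(int)
    i = np.rint(xy[:, 1]).astype(int)
    ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
    out = np.zeros(len(xy), dtype=bool)
    out[ok] = mask[i[ok], j[ok]]
    return out


def spot_region_distances(
    spots: SpotTable, region: RegionMask, signed: bool = False
) -> np.ndarray:
    """Minimum Euclidean distance from each spot center to the region.

    Parameters
    ----------
    spots : SpotTable
    region : RegionMask
        Must contain at least one positive pixel.
    signed : bool
        If True, spots sitting on positive pixels receive the *negative*
        distance to the nearest background pixel instead of 0, so the axis
        continues into the region interior.

    Returns
    -------
    numpy.ndarray
        One distance per spot, in pixel units.
    """
    region.require_nonempty()
    xy = spots.spots[["x", "y"]].to_numpy(dtype=float)
    if not len(xy):
        raise ValidationError("spot table is empty")
    pos = _pixel_centers(region.raster)
    dist, _ = cKDTree(pos).query(xy)
    interior = _containing_pixel_positive(xy, region.raster)
    dist[interior] = 0.0
    if signed:
        bg = _pixel_centers(~region.raster)
        if len(bg) == 0:
            raise EmptyRegionError(
                "mask has no background pixels; signed distances undefined"
            )
        if interior.any():
            din, _ = cKDTree(bg).query(xy[interior])
            dist[interior] = -din
    return dist


def scale_distances(raw: np.ndarray) -> np.ndarray:
    """Min-max scale raw distances onto [0, 1] (0 = nearest the region).

    The affine map sends the minimum raw distance to 0 and the maximum to 1
    and preserves rank order. If all raw distances are equal the scaled
    values are all 0 and a warning is emitted.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValidationError("need at least one spot to scale distances")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        msg = "all raw distances are equal; SpatialTime set to 0 everywhere"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def compute_spatialtime(
    spots: SpotTable, region: RegionMask, signed: bool = False
) -> SpatialTimeScores:
    """Distance-score a spot table against a region: raw + scaled values."""
    raw = spot_region_distances(spots, region, signed=signed)
    return SpatialTimeScores(
        spot_id=spots.spots["spot_id"].to_numpy(),
        raw_distance=raw,
        spatialtime=scale_distances(raw),
        signed=signed,
    )
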