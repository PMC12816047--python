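"""Binned, smoothed profiles along the SpatialTime axis and their features.

A profile bins per-spot values (expression or prediction scores) into
fixed-width SpatialTime intervals (default 0.01, i.e. 100 bins on [0, 1]),
recording per-bin n, mean and standard error, then overlays a smoothed
curve (centered moving average across non-empty bins). Feature extraction
classifies the profile as increasing / decreasing / peaked / flat from the
spot-level Spearman trend and the prominence of any interior smoothed peak,
and locates where two profiles cross after per-profile min-max scaling —
the analysis behind gradient panels such as a macrophage/progenitor
crossover at a region border.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "BinnedProfile",
    "ProfileFeatures",
    "bin_profile",
    "smooth_profile",
    "profile_features",
    "crossing_points",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.01
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_PROMINENCE = 0.1


@dataclass
class BinnedProfile:
    """Per-bin summary of a value along SpatialTime.

    Bins are left-closed intervals of equal width on [0, 1]; the last bin is
    closed on both sides so SpatialTime exactly 1 is included. ``mean`` is
    NaN for empty bins and ``se`` (sample sd / sqrt(n), n-1 denominator) is
    NaN for bins with fewer than two observations.
    """

    bin_edges: np.ndarray
    n: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    smoothed: np.ndarray | None = None
    values: np.ndarray = field(default=None, repr=False)
    spatialtime: np.ndarray = field(default=None, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.n)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def nonempty(self) -> np.ndarray:
        return self.n > 0


@dataclass
class ProfileFeatures:
    """Gradient features of one profile: trend, peak and classification."""

    peak_spatialtime: float
    trend_rho: float
    trend_p: float
    direction: str  # increasing | decreasing | peaked | flat

    def to_dict(self) -> dict:
        return {
            "peak_spatialtime": self.peak_spatialtime,
            "trend_rho": self.trend_rho,
            "trend_p": self.trend_p,
            "direction": self.direction,
        }


def bin_profile(
    values: np.ndarray,
    spatialtime: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BinnedProfile:
    """Bin values by SpatialTime at fixed intervals; per-bin n, mean, SE."""
    values = np.asarray(values, dtype=float)
    st = np.asarray(spatialtime, dtype=float)
    if values.shape != st.shape or values.ndim != 1:
        raise ValidationError(
            f"values ({values.shape}) and spatialtime ({st.shape}) must be "
            "aligned 1-D arrays"
        )
    if st.size and (st.min() < 0 or st.max() > 1):
        raise ValidationError("spatialtime values must lie in [0, 1]")
    if not 0 < bin_width <= 1:
        raise ConfigurationError(f"bin_width must be in (0, 1], got {bin_width}")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # Left-closed bins; the final bin also takes spatialtime == 1.
    idx = np.minimum((st / bin_width).astype(int), n_bins - 1)
    n = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    np.divide(sums, n, out=mean, where=n > 0)
    sq = np.bincount(idx, weights=values**2, minlength=n_bins)
    se = np.full(n_bins, np.nan)
    multi = n > 1
    with np.errstate(invalid="ignore"):
        var = (sq[multi] - n[multi] * mean[multi] ** 2) / (n[multi] - 1)
    se[multi] = np.sqrt(np.maximum(var, 0.0) / n[multi])
    return BinnedProfile(
        bin_edges=edges, n=n, mean=mean, se=se, values=values, spatialtime=st
    )


def smooth_profile(
    binned: BinnedProfile, window: int = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Centered moving average of bin means across non-empty bins.

    Empty bins are skipped entirely: the window slides over the sequence of
    non-empty bins, and near the ends it shrinks to the available one-sided
    neighborhood. ``window = 1`` reproduces the raw bin means. The result is
    stored on ``binned.smoothed`` (NaN at empty bins) and returned.
    """
    if window < 1:
        raise ConfigurationError(f"smoothing window must be >= 1, got {window}")
    occupied = np.flatnonzero(binned.nonempty)
    if len(occupied) == 0:
        raise InsufficientDataError("profile has no non-empty bins")
    means = binned.mean[occupied]
    half = window // 2
    out = np.full(binned.n_bins, np.nan)
    for k, b in enumerate(occupied):
        lo = max(0, k - half)
        hi = min(len(occupied), k + half + 1)
        out[b] = means[lo:hi].mean()
    binned.smoothed = out
    return out


def _ensure_smoothed(binned: BinnedProfile) -> np.ndarray:
    if binned.smoothed is None:
        smooth_profile(binned)
    return binned.smoothed


def profile_features(
    binned: BinnedProfile,
    smoothed: np.ndarray | None = None,
    alpha: float = 0.05,
    prominence: float = DEFAULT_PROMINENCE,
) -> ProfileFeatures:
    """Extract trend, peak location and direction class from a profile.

    The trend is the Spearman correlation of the raw spot-level
    (value, spatialtime) pairs — not the binned means — so the p-value
    reflects the true number of observations. The peak is the bin center of
    the smoothed maximum. Direction is ``peaked`` when an interior smoothed
    maximum exceeds both profile ends by ``prominence`` times the smoothed
    range; otherwise ``increasing``/``decreasing`` per a significant trend,
    else ``flat``.
    """
    if smoothed is None:
        smoothed = _ensure_smoothed(binned)
    occupied = np.flatnonzero(binned.nonempty)
    if len(occupied) < 3:
        raise InsufficientDataError(
            f"need >= 3 non-empty bins, got {len(occupied)}"
        )
    centers = binned.bin_centers
    sm = smoothed[occupied]
    k_max = int(np.nanargmax(sm))
    peak = float(centers[occupied[k_max]])

    if binned.values is None or binned.spatialtime is None:
        raise ValidationError("profile lacks raw spot-level values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> NaN rho
        rho, p = stats.spearmanr(binned.spatialtime, binned.values)
    if np.isnan(rho):
        rho, p = 0.0, 1.0

    rng = float(np.nanmax(sm) - np.nanmin(sm))
    interior = 0 < k_max < len(occupied) - 1
    prominent = (
        interior
        and rng > 0
        and sm[k_max] - max(sm[0], sm[-1]) >= prominence * rng
    )
    # A genuine peak must rise significantly before it and fall
    # significantly after it at the spot level; this separates "peaked"
    # from a monotone profile whose sparse end bins wobble.
    if prominent:
        before = binned.spatialtime < peak
        after = ~before
        prominent = _flank_significant(
            binned.values[before], binned.spatialtime[before], +1, alpha
        ) and _flank_significant(
            binned.values[after], binned.spatialtime[after], -1, alpha
        )
    if prominent:
        direction = "peaked"
    elif p < alpha and rho > 0:
        direction = "increasing"
    elif p < alpha and rho < 0:
        direction = "decreasing"
    else:
        direction = "flat"
    return ProfileFeatures(
        peak_spatialtime=peak, trend_rho=float(rho), trend_p=float(p),
        direction=direction,
    )


def _flank_significant(
    values: np.ndarray, st: np.ndarray, sign: int, alpha: float
) -> bool:
    """Significant spot-level monotone trend of the requested sign."""
    if len(values) < 3:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(st, values)
    return bool(np.isfinite(rho) and np.sign(rho) == sign and p < alpha)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def crossing_points(
    profile_a: BinnedProfile, profile_b: BinnedProfile
) -> list[float]:
    """SpatialTime locations where two smoothed profiles cross.

    Each smoothed curve is first min-max scaled to [0, 1] so profiles on
    different natural scales (e.g. a prediction score vs an expression
    level) are comparable. A crossing is a sign change of (A - B) between
    consecutive bins that are non-empty in both profiles, located by linear
    interpolation between bin centers; tangential touches that do not change
    sign are not crossings.
    """
    if profile_a.n_bins != profile_b.n_bins:
        raise ValidationError("profiles use different binnings")
    sa = _minmax(_ensure_smoothed(profile_a))
    sb = _minmax(_ensure_smoothed(profile_b))
    both = np.flatnonzero(profile_a.nonempty & profile_b.nonempty)
    if len(both) < 2:
        raise InsufficientDataError("fewer than 2 bins shared by both profiles")
    centers = profile_a.bin_centers[both]
    d = sa[both] - sb[both]
    if np.all(d == 0):
        msg = "profiles are identical everywhere; no crossings"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        return []
    crossings: list[float] = []
    last_sign = 0
    last_x = last_d = None
    for x, di in zip(centers, d):
        s = int(np.sign(di))
        if s != 0:
            if last_sign != 0 and s != last_sign:
                # interpolate between the last non-zero point and this one
                t = last_d / (last_d - di)
                crossings.append(float(last_x + t * (x - last_x)))
            last_sign = s
            last_x, last_d = x, di
        elif last_sign != 0:
            last_x, last_d = x, di  # keep the zero point for interpolation
    return crossings
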