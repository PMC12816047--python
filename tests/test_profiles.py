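"""Binning, smoothing, gradient features and profile crossings."""

import numpy as np
import pytest

from spatialtime import (
    ConfigurationError,
    GradientSpec,
    InsufficientDataError,
    ValidationError,
    bin_profile,
    crossing_points,
    profile_features,
    smooth_profile,
)
from spatialtime.synthetic import generate_counts, LayoutSpec


def test_default_binning_gives_100_bins():
    prof = bin_profile(np.array([1.0]), np.array([0.5]))
    assert prof.n_bins == 100
    assert prof.bin_edges[0] == 0.0 and prof.bin_edges[-1] == 1.0


def test_hand_computed_se():
    prof = bin_profile(np.array([1.0, 2.0, 3.0]), np.array([0.5, 0.501, 0.509]))
    b = 50
    assert prof.n[b] == 3
    assert prof.mean[b] == pytest.approx(2.0)
    assert prof.se[b] == pytest.approx(0.5774, abs=1e-4)  # sd 1, 1/sqrt(3)


def test_last_bin_closed_on_the_right():
    prof = bin_profile(np.array([7.0]), np.array([1.0]))
    assert prof.n[99] == 1


def test_constant_values_have_zero_se():
    st = np.linspace(0, 1, 300)
    prof = bin_profile(np.full(300, 4.2), st)
    nz = prof.n > 1
    np.testing.assert_allclose(prof.mean[prof.n > 0], 4.2)
    np.testing.assert_allclose(prof.se[nz], 0.0, atol=1e-12)


def test_single_observation_bin_has_undefined_se():
    prof = bin_profile(np.array([1.0]), np.array([0.205]))
    assert prof.n[20] == 1 and np.isnan(prof.se[20])


def test_mismatched_lengths_rejected():
    with pytest.raises(ValidationError):
        bin_profile(np.zeros(3), np.zeros(4))
    with pytest.raises(ValidationError):
        bin_profile(np.zeros(2), np.array([0.5, 1.2]))


@pytest.mark.parametrize("seed", range(20))
def test_weighted_bin_means_recombine_to_global_mean(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(50, 500))
    values = rng.normal(3, 2, n)
    st = rng.uniform(0, 1, n)
    prof = bin_profile(values, st)
    assert prof.n.sum() == n
    nz = prof.n > 0
    recombined = float(np.sum(prof.n[nz] * prof.mean[nz]) / n)
    assert recombined == pytest.approx(values.mean(), rel=1e-9)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def _uniform_profile(means):
    """One value per bin so bin means equal `means` exactly."""
    st = (np.arange(len(means)) + 0.5) / 100
    return bin_profile(np.asarray(means, float), st)


def test_smoother_preserves_constants():
    prof = _uniform_profile([5.0] * 30)
    sm = smooth_profile(prof, window=5)
    np.testing.assert_allclose(sm[:30], 5.0)


def test_window_one_is_identity():
    rng = np.random.default_rng(0)
    means = rng.normal(size=15)
    prof = _uniform_profile(means)
    sm = smooth_profile(prof, window=1)
    np.testing.assert_allclose(sm[:15], means)


def test_moving_average_preserves_linear_trend_in_interior():
    means = np.arange(10, dtype=float)
    prof = _uniform_profile(means)
    sm = smooth_profile(prof, window=5)
    np.testing.assert_allclose(sm[2:8], means[2:8], atol=1e-12)


def test_smoothing_skips_empty_bins():
    values = np.array([1.0, 2.0, 3.0])
    st = np.array([0.005, 0.505, 0.995])  # far-apart occupied bins
    prof = bin_profile(values, st)
    sm = smooth_profile(prof, window=3)
    # window spans the non-empty neighbors, not the empty gap
    assert sm[50] == pytest.approx(2.0)
    assert np.isnan(sm[10])


def test_smoothing_stays_in_envelope():
    rng = np.random.default_rng(8)
    means = rng.normal(size=40)
    prof = _uniform_profile(means)
    sm = smooth_profile(prof, window=7)
    assert np.nanmin(sm) >= means.min() - 1e-12
    assert np.nanmax(sm) <= means.max() + 1e-12


def test_invalid_window_rejected():
    prof = _uniform_profile([1.0, 2.0])
    with pytest.raises(ConfigurationError):
        smooth_profile(prof, window=0)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def test_strictly_increasing_profile():
    n = 200
    st = np.linspace(0, 1, n)
    values = 2 * st + 1
    prof = bin_profile(values, st)
    feats = profile_features(prof)
    assert feats.direction == "increasing"
    assert feats.trend_rho == pytest.approx(1.0)
    last = np.flatnonzero(prof.nonempty)[-1]
    assert feats.peak_spatialtime == pytest.approx(prof.bin_centers[last])


def test_flat_profile():
    rng = np.random.default_rng(1)
    st = rng.uniform(0, 1, 400)
    values = np.full(400, 3.0) + rng.normal(0, 1e-3, 400)
    feats = profile_features(bin_profile(values, st))
    assert feats.direction == "flat"


def test_constant_profile_is_flat():
    st = np.linspace(0, 1, 50)
    feats = profile_features(bin_profile(np.full(50, 2.0), st))
    assert feats.direction == "flat"


def test_peak_recovery_on_synthetic_gradient():
    """A peaked count gradient (true peak 0.30, generator defaults,
    2000 spots) is recovered within the binning tolerance."""
    rng = np.random.default_rng(123)
    st = rng.uniform(0, 1, 2000)
    spec = GradientSpec(shape="peaked", peak_position=0.30)
    counts, _ = generate_counts(
        LayoutSpec(grid_nx=2, grid_ny=2, region_radius=0), st, {"g": spec},
        seed=123,
    )
    prof = bin_profile(counts[0].astype(float), st)
    feats = profile_features(prof)
    assert feats.direction == "peaked"
    assert feats.peak_spatialtime == pytest.approx(0.30, abs=0.05)


def test_too_few_bins_rejected():
    prof = bin_profile(np.array([1.0, 2.0]), np.array([0.1, 0.6]))
    with pytest.raises(InsufficientDataError):
        profile_features(prof)


# ---------------------------------------------------------------------------
# Crossings
# ---------------------------------------------------------------------------

def _profiles_from_arrays(a, b):
    st = (np.arange(len(a)) + 0.5) / 100
    pa = bin_profile(np.asarray(a, float), st)
    pb = bin_profile(np.asarray(b, float), st)
    smooth_profile(pa, window=1)
    smooth_profile(pb, window=1)
    return pa, pb


def test_symmetric_linear_profiles_cross_at_half():
    n = 100
    up = np.linspace(0, 1, n)
    down = np.linspace(1, 0, n)
    pa, pb = _profiles_from_arrays(up, down)
    crossings = crossing_points(pa, pb)
    assert len(crossings) == 1
    assert crossings[0] == pytest.approx(0.5, abs=1e-6)


def test_dominating_profile_never_crosses():
    # after per-profile scaling A = x and B = x^2 touch at both ends but
    # A stays above B in between: no sign change, no crossing
    x = np.linspace(0, 1, 80)
    pa, pb = _profiles_from_arrays(x, x**2)
    assert crossing_points(pa, pb) == []


def test_identical_profiles_warn_and_return_nothing():
    x = np.linspace(0, 1, 50)
    pa, pb = _profiles_from_arrays(x, x)
    with pytest.warns(UserWarning, match="identical"):
        assert crossing_points(pa, pb) == []


def test_tangential_touch_is_not_a_crossing():
    x = np.linspace(0, 1, 99)
    a = (x - 0.5) ** 2  # dips to 0 at x=0.5, positive elsewhere
    b = np.zeros(99)
    pa, pb = _profiles_from_arrays(a + 0.1, b)
    assert crossing_points(pa, pb) == []


def test_scale_equivariance():
    rng = np.random.default_rng(5)
    st = rng.uniform(0, 1, 800)
    va = np.exp(-st / 0.3) + rng.normal(0, 0.01, 800)
    vb = np.exp(-((st - 0.4) ** 2) / 0.02) + rng.normal(0, 0.01, 800)
    c = 7.3

    pa1 = bin_profile(va, st)
    pb1 = bin_profile(vb, st)
    pa2 = bin_profile(c * va, st)
    pb2 = bin_profile(c * vb, st)
    for p in (pa1, pb1, pa2, pb2):
        smooth_profile(p)

    nz = pa1.n > 0
    np.testing.assert_allclose(pa2.mean[nz], c * pa1.mean[nz], rtol=1e-9)
    multi = pa1.n > 1
    np.testing.assert_allclose(pa2.se[multi], c * pa1.se[multi], rtol=1e-9)

    f1, f2 = profile_features(pa1), profile_features(pa2)
    assert f1.trend_rho == pytest.approx(f2.trend_rho, abs=1e-12)
    assert f1.peak_spatialtime == f2.peak_spatialtime

    np.testing.assert_allclose(
        crossing_points(pa1, pb1), crossing_points(pa2, pb2), atol=1e-9
    )


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st_


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st_.integers(min_value=0, max_value=2**31 - 1))
def test_bin_counts_partition_spots_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 300))
    prof = bin_profile(rng.normal(size=n), rng.uniform(0, 1, n))
    assert prof.n.sum() == n
    nz = prof.n > 0
    recombined = float((prof.n[nz] * prof.mean[nz]).sum() / n)
    assert recombined == pytest.approx(float(np.mean(prof.values)), rel=1e-9)
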