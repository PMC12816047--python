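"""Generators: layouts, score fields, counts, fibril images, determinism."""

import numpy as np
import pytest

from spatialtime import (
    ConfigurationError,
    GradientSpec,
    LayoutSpec,
    build_scene,
    generate_counts,
    generate_fibril_image,
    generate_layout,
    generate_prediction_scores,
    true_spatialtime,
)
from spatialtime.synthetic import _nematic_order, default_scenario


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def test_degenerate_radius_marks_single_center_pixel():
    spec = LayoutSpec(grid_nx=10, grid_ny=10, pixel_pitch=10, region_radius=0)
    table, mask = generate_layout(spec)
    assert table.n_spots == 100
    assert mask.n_positive == 1
    assert mask.raster[45, 45]  # frame center of a 91x91 frame


def test_disk_pixel_count_matches_bruteforce_scan():
    spec = LayoutSpec(grid_nx=20, grid_ny=20, pixel_pitch=5, region_radius=15)
    _, mask = generate_layout(spec)
    h, w = mask.shape
    cx, cy = spec.center
    count = sum(
        (j - cx) ** 2 + (i - cy) ** 2 <= 15**2
        for i in range(h)
        for j in range(w)
    )
    assert mask.n_positive == count


def test_layout_deterministic():
    spec = LayoutSpec(grid_nx=8, grid_ny=6, pixel_pitch=7, region_radius=10)
    t1, m1 = generate_layout(spec)
    t2, m2 = generate_layout(spec)
    assert t1.spots.equals(t2.spots)
    np.testing.assert_array_equal(m1.raster, m2.raster)


def test_region_outside_lattice_rejected():
    with pytest.raises(ConfigurationError):
        LayoutSpec(grid_nx=5, grid_ny=5, pixel_pitch=10,
                   region_center=(5, 5), region_radius=20)


def test_true_spatialtime_border_position():
    spec = LayoutSpec(grid_nx=45, grid_ny=45, pixel_pitch=10, region_radius=60)
    st, border = true_spatialtime(spec, signed=True)
    assert st.min() == 0.0 and st.max() == 1.0
    # analytically: radius / (radius + corner distance - radius)
    corner = np.hypot(220, 220)
    assert border == pytest.approx(60 / (60 + corner - 60), abs=1e-9)
    st_u, border_u = true_spatialtime(spec, signed=False)
    assert border_u == 0.0
    assert (st_u >= 0).all()


# ---------------------------------------------------------------------------
# Gradient specs
# ---------------------------------------------------------------------------

def test_gradient_spec_validation():
    with pytest.raises(ConfigurationError):
        GradientSpec(shape="wiggly")
    with pytest.raises(ConfigurationError):
        GradientSpec(shape="peaked")  # missing peak_position
    with pytest.raises(ConfigurationError):
        GradientSpec(shape="decreasing", peak_position=0.3)
    with pytest.raises(ConfigurationError):
        GradientSpec(shape="flat", dispersion=0)


def test_zero_amplitude_forces_constant_mean():
    spec = GradientSpec(shape="decreasing", amplitude=0, baseline=4.0)
    st = np.linspace(0, 1, 11)
    np.testing.assert_array_equal(spec.mean_at(st), np.full(11, 4.0))


# ---------------------------------------------------------------------------
# Prediction scores
# ---------------------------------------------------------------------------

def test_noiseless_inside_high_ordering():
    layout = LayoutSpec(grid_nx=21, grid_ny=21, pixel_pitch=10, region_radius=40)
    spec = GradientSpec(shape="decreasing", amplitude=0.8, baseline=0.1,
                        width=0.3, dispersion=1)
    scores = generate_prediction_scores(layout, {"m": spec}, noise_sd=0.0,
                                        seed=0, signed=False)
    st, _ = true_spatialtime(layout, signed=False)
    near = scores["m"][st == 0.0]
    far = scores["m"][st == st.max()]
    assert near.min() > far.max()


def test_noiseless_flat_profile_is_exact():
    layout = LayoutSpec(grid_nx=10, grid_ny=10, pixel_pitch=10, region_radius=20)
    spec = GradientSpec(shape="flat", amplitude=0, baseline=0.7, dispersion=1)
    scores = generate_prediction_scores(layout, {"m": spec}, noise_sd=0.0)
    np.testing.assert_array_equal(scores["m"].to_numpy(), np.full(100, 0.7))


def test_score_noise_matches_stated_model():
    """Empirical stratum means stay within 3 SE of the noiseless profile."""
    layout = LayoutSpec(grid_nx=20, grid_ny=20, pixel_pitch=10, region_radius=40)
    spec = GradientSpec(shape="decreasing", amplitude=0.6, baseline=0.2,
                        width=0.4, dispersion=1)
    noiseless = generate_prediction_scores(layout, {"m": spec}, noise_sd=0.0)
    noisy = generate_prediction_scores(layout, {"m": spec}, noise_sd=0.05,
                                       seed=11)
    st, _ = true_spatialtime(layout, signed=True)
    strata = np.digitize(st, np.linspace(0, 1, 6)[1:-1])
    for s in np.unique(strata):
        idx = strata == s
        n = idx.sum()
        delta = abs(noisy["m"][idx].mean() - noiseless["m"][idx].mean())
        assert delta <= 3 * 0.05 / np.sqrt(n)


def test_scores_always_clipped_to_unit_interval():
    layout = LayoutSpec(grid_nx=15, grid_ny=15, pixel_pitch=10, region_radius=30)
    spec = GradientSpec(shape="decreasing", amplitude=0.9, baseline=0.1,
                        width=0.2, dispersion=1)
    scores = generate_prediction_scores(layout, {"m": spec}, noise_sd=0.5,
                                        seed=2)
    assert scores["m"].between(0, 1).all()


def test_negative_noise_sd_rejected():
    layout = LayoutSpec(grid_nx=5, grid_ny=5, pixel_pitch=10, region_radius=5)
    spec = GradientSpec(shape="flat", amplitude=0, baseline=0.5, dispersion=1)
    with pytest.raises(ConfigurationError):
        generate_prediction_scores(layout, {"m": spec}, noise_sd=-0.1)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def test_flat_nb_mean_recovered():
    layout = LayoutSpec(grid_nx=100, grid_ny=100, pixel_pitch=5,
                        region_radius=50)
    st = np.random.default_rng(0).uniform(0, 1, 10_000)
    spec = GradientSpec(shape="flat", amplitude=0, baseline=5.0, dispersion=4.0)
    counts, genes = generate_counts(layout, st, {"g": spec}, seed=4)
    assert genes == ["g"]
    se = np.sqrt((5 + 25 / 4) / 10_000)
    assert counts[0].mean() == pytest.approx(5.0, abs=3 * se)


def test_gradient_extremes_match_analytic_mean():
    layout = LayoutSpec(grid_nx=4, grid_ny=4, pixel_pitch=10, region_radius=5)
    st = np.concatenate([np.zeros(2500), np.ones(2500)])
    spec = GradientSpec(shape="decreasing", amplitude=20, baseline=2,
                        width=0.25, dispersion=6)
    counts, _ = generate_counts(layout, st, {"g": spec}, seed=9)
    for sel, mu in ((st == 0, 22.0), (st == 1, 2 + 20 * np.exp(-4))):
        se = np.sqrt((mu + mu**2 / 6) / sel.sum())
        assert counts[0][sel].mean() == pytest.approx(mu, abs=3 * se)


def test_zero_mean_gives_zero_counts():
    layout = LayoutSpec(grid_nx=4, grid_ny=4, pixel_pitch=10, region_radius=5)
    spec = GradientSpec(shape="flat", amplitude=0, baseline=0, dispersion=2)
    counts, _ = generate_counts(layout, np.linspace(0, 1, 50), {"g": spec})
    assert (counts == 0).all()


def test_counts_deterministic_and_gene_streams_independent():
    layout = LayoutSpec(grid_nx=6, grid_ny=6, pixel_pitch=10, region_radius=10)
    st = np.linspace(0, 1, 36)
    g1 = GradientSpec(shape="flat", amplitude=0, baseline=3, dispersion=2)
    g2 = GradientSpec(shape="decreasing", amplitude=5, baseline=1,
                      width=0.3, dispersion=2)
    c12, _ = generate_counts(layout, st, {"a": g1, "b": g2}, seed=7)
    c12_again, _ = generate_counts(layout, st, {"a": g1, "b": g2}, seed=7)
    np.testing.assert_array_equal(c12, c12_again)
    # adding a gene must not perturb existing genes
    c1, _ = generate_counts(layout, st, {"a": g1}, seed=7)
    np.testing.assert_array_equal(c1[0], c12[0])


# ---------------------------------------------------------------------------
# Fibril images
# ---------------------------------------------------------------------------

def test_perfectly_concentrated_fibers():
    s = generate_fibril_image(64, 64, 25.0, np.inf, n_fibers=10, seed=0)
    assert s.truth_anisotropy == pytest.approx(1.0, abs=1e-12)
    assert s.image.min() >= 0 and s.image.max() <= 1


def test_uniform_orientations_are_nearly_isotropic():
    rng_angles = generate_fibril_image(
        16, 16, 0.0, 0.0, n_fibers=10_000, seed=3
    ).angles
    assert _nematic_order(rng_angles) < 0.05


def test_fibril_image_deterministic():
    a = generate_fibril_image(96, 96, 10.0, 4.0, seed=5)
    b = generate_fibril_image(96, 96, 10.0, 4.0, seed=5)
    np.testing.assert_array_equal(a.image, b.image)
    assert a.truth_anisotropy == b.truth_anisotropy


def test_truth_monotone_in_concentration():
    prev = -1.0
    for conc in [0.0, 2.0, 8.0, 32.0, 128.0]:
        vals = [
            generate_fibril_image(32, 32, 0.0, conc, seed=100 + k).truth_anisotropy
            for k in range(3)
        ]
        cur = float(np.mean(vals))
        assert cur >= prev
        prev = cur


def test_fibril_parameter_validation():
    with pytest.raises(ConfigurationError):
        generate_fibril_image(0, 64, 0, 1)
    with pytest.raises(ConfigurationError):
        generate_fibril_image(64, 64, 0, -1)
    with pytest.raises(ConfigurationError):
        generate_fibril_image(64, 64, 0, 1, n_fibers=0)


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------

def test_scene_build_is_deterministic():
    s1 = build_scene(seed=6)
    s2 = build_scene(seed=6)
    np.testing.assert_array_equal(s1.table.counts, s2.table.counts)
    np.testing.assert_array_equal(
        s1.table.scores.to_numpy(), s2.table.scores.to_numpy()
    )
    assert s1.ground_truth == s2.ground_truth


def test_scene_ground_truth_is_consistent(default_scene):
    gt = default_scene.ground_truth
    assert gt["gene_shapes"]["Thbs1"] == "decreasing"
    assert gt["gene_shapes"]["Thbs2"] == "peaked"
    assert 0 < gt["border_spatialtime"] < gt["gene_peaks"]["Thbs2"]
    assert default_scene.table.scores.to_numpy().min() >= 0
    assert default_scene.table.scores.to_numpy().max() <= 1


def test_scenario_roundtrip_through_dict():
    sc = default_scenario(seed=2)
    sc["n_background_genes"] = 3
    scene = build_scene(sc)
    assert scene.table.n_genes == 5  # Thbs1, Thbs2 + 3 background
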