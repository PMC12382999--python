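"""Motion decoupling tests: polynomial fit oracles, known-shift recovery,
polar transform, adaptive thresholds and the trinary mask."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtrack import motion as M

from conftest import subpixel_shift, textured_image


# ----------------------------------------------------------------------
# fit_polynomial
# ----------------------------------------------------------------------

def test_constant_image_fit():
    img = np.full((9, 9), 0.5)
    fit = M.fit_polynomial(img, 5)
    for arr in (fit.a_xx, fit.a_yy, fit.a_xy, fit.b_x, fit.b_y):
        np.testing.assert_allclose(arr, 0.0, atol=1e-12)
    np.testing.assert_allclose(fit.c, 0.5, atol=1e-12)


def test_linear_ramp_fit():
    w = 16
    xs = np.tile(np.arange(w, dtype=float) / w, (12, 1))
    fit = M.fit_polynomial(xs, 5)
    inner = (slice(3, -3), slice(3, -3))
    np.testing.assert_allclose(fit.b_x[inner], 1.0 / w, atol=1e-12)
    np.testing.assert_allclose(fit.b_y[inner], 0.0, atol=1e-12)
    np.testing.assert_allclose(fit.a_xx[inner], 0.0, atol=1e-12)
    np.testing.assert_allclose(fit.c[inner], xs[inner], atol=1e-12)


def brute_force_quadratic_fit(img, y, x, window, sigma):
    """Independent normal-equations solve of the windowed weighted LSQ."""
    r = window // 2
    rows = []
    vals = []
    wts = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            rows.append([1.0, dx, dy, dx * dx, dy * dy, dx * dy])
            vals.append(img[y + dy, x + dx])
            wts.append(np.exp(-(dx * dx + dy * dy) / (2 * sigma * sigma)))
    B = np.array(rows)
    Wm = np.diag(wts)
    coef = np.linalg.solve(B.T @ Wm @ B, B.T @ Wm @ np.array(vals))
    c, bx, by, axx, ayy, axy = coef
    return dict(a_xx=2 * axx, a_yy=2 * ayy, a_xy=axy, b_x=bx, b_y=by, c=c)


def test_quadratic_fit_matches_bruteforce_oracle():
    xs = np.arange(7, dtype=float)
    img = np.tile(xs**2, (7, 1))
    sigma = 0.15 * 5 + 0.35
    fit = M.fit_polynomial(img, 5)
    want = brute_force_quadratic_fit(img, 3, 3, 5, sigma)
    assert abs(fit.a_xx[3, 3] - 2.0) < 1e-9
    for key, val in want.items():
        np.testing.assert_allclose(getattr(fit, key)[3, 3], val, atol=1e-9)


def test_random_image_fit_matches_bruteforce(rng):
    img = rng.random((11, 11))
    sigma = 0.15 * 5 + 0.35
    fit = M.fit_polynomial(img, 5)
    want = brute_force_quadratic_fit(img, 5, 5, 5, sigma)
    for key, val in want.items():
        np.testing.assert_allclose(getattr(fit, key)[5, 5], val, atol=1e-9)


@pytest.mark.parametrize("window", [2, 4, 1])
def test_fit_rejects_bad_window(window):
    with pytest.raises(ValueError):
        M.fit_polynomial(np.zeros((8, 8)), window)


def test_fit_rejects_oversized_window():
    with pytest.raises(ValueError):
        M.fit_polynomial(np.zeros((8, 8)), 9)


# ----------------------------------------------------------------------
# estimate_displacement
# ----------------------------------------------------------------------

def test_zero_motion(rng):
    img = textured_image(rng)
    fld = M.estimate_displacement(img, img)
    np.testing.assert_allclose(fld.dx, 0.0, atol=1e-9)
    np.testing.assert_allclose(fld.dy, 0.0, atol=1e-9)


def test_integer_shift_recovery(rng):
    img = textured_image(rng)
    fld = M.estimate_displacement(img, subpixel_shift(img, 1, 0))
    inner = (slice(8, -8),) * 2
    assert abs(np.median(fld.dx[inner]) - 1.0) < 0.25
    assert abs(np.median(fld.dy[inner])) < 0.25


def test_subpixel_shift_on_gaussian_blob():
    ys, xs = np.mgrid[0:64, 0:64].astype(float)
    blob = np.exp(-((xs - 32) ** 2 + (ys - 30) ** 2) / (2 * 36.0))
    fld = M.estimate_displacement(blob, subpixel_shift(blob, 0.5, -0.5))
    core = blob > 0.3
    assert abs(np.median(fld.dx[core]) - 0.5) < 0.25
    assert abs(np.median(fld.dy[core]) + 0.5) < 0.25


def test_displacement_shape_mismatch():
    with pytest.raises(ValueError):
        M.estimate_displacement(np.zeros((16, 16)), np.zeros((16, 18)))


# ----------------------------------------------------------------------
# to_polar
# ----------------------------------------------------------------------

def test_polar_345_triangle():
    p = M.to_polar(M.DisplacementField(np.full((1, 1), 3.0), np.full((1, 1), 4.0)))
    assert abs(p.rho[0, 0] - 5.0) < 1e-12
    assert abs(p.theta[0, 0] - 0.9272952180016122) < 1e-9


def test_polar_zero_and_negative_axis():
    p = M.to_polar(M.DisplacementField(np.array([[0.0, -1.0]]),
                                       np.array([[0.0, 0.0]])))
    assert p.rho[0, 0] == 0.0 and p.theta[0, 0] == 0.0
    assert abs(p.rho[0, 1] - 1.0) < 1e-15
    assert abs(p.theta[0, 1] - np.pi) < 1e-15


@settings(max_examples=50, deadline=None)
@given(st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False))
def test_polar_roundtrip_property(dx, dy):
    p = M.to_polar(M.DisplacementField(np.array([[dx]]), np.array([[dy]])))
    assert abs(p.rho[0, 0] * np.cos(p.theta[0, 0]) - dx) < 1e-12
    assert abs(p.rho[0, 0] * np.sin(p.theta[0, 0]) - dy) < 1e-12


def test_polar_rejects_nonfinite():
    with pytest.raises(ValueError):
        M.to_polar(M.DisplacementField(np.array([[np.nan]]), np.array([[0.0]])))


# ----------------------------------------------------------------------
# local statistics + thresholds
# ----------------------------------------------------------------------

def test_uniform_rho_statistics():
    polar = M.PolarMotionField(np.full((20, 20), 2.0), np.zeros((20, 20)))
    maps = M.local_statistics(polar, 5)
    np.testing.assert_allclose(maps.mu, 2.0, atol=1e-12)
    np.testing.assert_allclose(maps.sigma, 0.0, atol=1e-6)


def test_checkerboard_statistics():
    rho = np.indices((21, 21)).sum(axis=0) % 2 * 2.0
    maps = M.local_statistics(M.PolarMotionField(rho, np.zeros_like(rho)), 5)
    # window of 25 cells centred on a 0-cell: 12 twos -> mu = 24/25
    y = x = 10
    cells = rho[y - 2:y + 3, x - 2:x + 3]
    np.testing.assert_allclose(maps.mu[y, x], cells.mean(), atol=1e-12)
    np.testing.assert_allclose(maps.sigma[y, x], cells.std(), atol=1e-9)


def test_single_bright_pixel_statistics():
    rho = np.zeros((15, 15))
    rho[7, 7] = 5.0
    maps = M.local_statistics(M.PolarMotionField(rho, np.zeros_like(rho)), 5)
    np.testing.assert_allclose(maps.mu[7, 7], 5.0 / 25.0, atol=1e-12)


def test_statistics_window_validation():
    polar = M.PolarMotionField(np.zeros((10, 10)), np.zeros((10, 10)))
    with pytest.raises(ValueError):
        M.local_statistics(polar, 4)
    with pytest.raises(ValueError):
        M.local_statistics(polar, 11)


def test_threshold_arithmetic_reference_constants():
    maps = M.ThresholdMaps(mu=np.array([[1.0]]), sigma=np.array([[0.4]]))
    out = M.adaptive_thresholds(maps, 1.0, 2.5)
    np.testing.assert_allclose(out.tau_low, 1.4, atol=1e-12)
    np.testing.assert_allclose(out.tau_high, 2.0, atol=1e-12)


def test_threshold_degenerate_cases():
    maps = M.ThresholdMaps(mu=np.array([[3.0]]), sigma=np.array([[0.0]]))
    out = M.adaptive_thresholds(maps)
    assert out.tau_low[0, 0] == out.tau_high[0, 0] == 3.0
    maps = M.ThresholdMaps(mu=np.array([[0.0]]), sigma=np.array([[1.0]]))
    out = M.adaptive_thresholds(maps)
    assert out.tau_low[0, 0] == 1.0 and out.tau_high[0, 0] == 2.5


def test_threshold_rejects_k2_below_k1():
    maps = M.ThresholdMaps(mu=np.zeros((2, 2)), sigma=np.zeros((2, 2)))
    with pytest.raises(ValueError):
        M.adaptive_thresholds(maps, 2.0, 1.0)


# ----------------------------------------------------------------------
# classify_motion
# ----------------------------------------------------------------------

def _maps(tau_low, tau_high, shape=(1, 1)):
    return M.ThresholdMaps(mu=np.zeros(shape), sigma=np.zeros(shape),
                           tau_low=np.full(shape, tau_low),
                           tau_high=np.full(shape, tau_high))


@pytest.mark.parametrize("rho,lo,hi,label", [
    (1.0, 1.4, 2.0, 0),
    (1.4, 1.4, 2.0, 1),   # boundary inclusive to class 1
    (2.0, 1.4, 2.0, 1),
    (2.1, 1.4, 2.0, 2),
])
def test_classification_boundaries(rho, lo, hi, label):
    polar = M.PolarMotionField(np.full((1, 1), rho), np.zeros((1, 1)))
    mask = M.classify_motion(polar, _maps(lo, hi))
    assert mask.labels[0, 0] == label


def test_partition_property_random_fields(rng):
    for _ in range(100):
        rho = rng.random((12, 12)) * 3
        polar = M.PolarMotionField(rho, np.zeros_like(rho))
        maps = M.adaptive_thresholds(M.local_statistics(polar, 5))
        mask = M.classify_motion(polar, maps)
        counts = [(mask.labels == v).sum() for v in (0, 1, 2)]
        assert sum(counts) == rho.size
        assert set(np.unique(mask.labels)) <= {0, 1, 2}


def test_k1_monotonicity(rng):
    rho = rng.random((16, 16)) * 2
    polar = M.PolarMotionField(rho, np.zeros_like(rho))
    stats = M.local_statistics(polar, 5)
    lo = M.classify_motion(polar, M.adaptive_thresholds(stats, 0.5, 2.5))
    hi = M.classify_motion(polar, M.adaptive_thresholds(stats, 1.5, 2.5))
    # raising k1 never moves a pixel from class 0 to class >= 1
    assert not np.any((lo.labels == 0) & (hi.labels > 0))


def test_static_frames_yield_empty_motion(rng):
    img = textured_image(rng, size=48)
    fld = M.estimate_displacement(img, img)
    polar = M.to_polar(fld)
    maps = M.adaptive_thresholds(M.local_statistics(polar, 15))
    mask = M.classify_motion(polar, maps)
    assert (mask.labels == 2).sum() == 0


# ----------------------------------------------------------------------
# sparse features + raster
# ----------------------------------------------------------------------

def test_sparse_empty_and_selection():
    polar = M.PolarMotionField(np.ones((4, 4)), np.zeros((4, 4)))
    empty = M.sparse_features(polar, M.MotionMask(np.zeros((4, 4), dtype=int)))
    assert len(empty) == 0
    labels = np.zeros((4, 4), dtype=int)
    labels[0, 1] = 1
    labels[2, 3] = 2
    labels[3, 0] = 1
    feats = M.sparse_features(polar, M.MotionMask(labels))
    assert len(feats) == 3
    coords = {(int(x), int(y)) for x, y, _, _ in feats.entries}
    assert coords == {(1, 0), (3, 2), (0, 3)}


def test_sparse_count_matches_pixelwise_oracle(rng):
    img1 = textured_image(rng, 48)
    ys, xs = np.mgrid[0:48, 0:48].astype(float)
    img2 = np.clip(img1 + 0.4 * np.exp(-((xs - 16) ** 2 + (ys - 20) ** 2) / 18)
                   - 0.4 * np.exp(-((xs - 30) ** 2 + (ys - 28) ** 2) / 18), 0, 1)
    fld = M.estimate_displacement(img1, img2)
    polar = M.to_polar(fld)
    maps = M.adaptive_thresholds(M.local_statistics(polar, 15))
    mask = M.classify_motion(polar, maps)
    feats = M.sparse_features(polar, mask)
    assert len(feats) == int((mask.labels > 0).sum())


def test_raster_roundtrip():
    entries = np.array([[2.0, 3.0, 1.5, 0.5], [0.0, 0.0, 2.0, -1.0]])
    feats = M.SparseMotionFeatures(entries)
    img = M.rasterize_motion(feats, (5, 5))
    assert img.shape == (2, 5, 5)
    assert np.count_nonzero(img[0]) == 2
    assert img[0, 3, 2] == 1.5 and img[1, 3, 2] == 0.5
    # round trip through a mask reconstructed from nonzero rho
    labels = (img[0] > 0).astype(int)
    polar = M.PolarMotionField(img[0], img[1])
    back = M.sparse_features(polar, M.MotionMask(labels))
    np.testing.assert_allclose(
        sorted(map(tuple, back.entries)), sorted(map(tuple, entries)))


def test_raster_empty_and_out_of_bounds():
    assert M.rasterize_motion(M.SparseMotionFeatures(), (4, 4)).sum() == 0
    bad = M.SparseMotionFeatures(np.array([[9.0, 0.0, 1.0, 0.0]]))
    with pytest.raises(ValueError):
        M.rasterize_motion(bad, (4, 4))


def test_debug_dump_roundtrip(tmp_path, rng):
    rho = rng.random((12, 12))
    theta = rng.uniform(-np.pi, np.pi, (12, 12))
    polar = M.PolarMotionField(rho, theta)
    maps = M.adaptive_thresholds(M.local_statistics(polar, 5))
    mask = M.classify_motion(polar, maps)
    feats = M.sparse_features(polar, mask)
    out = M.dump_debug(polar, mask, feats, tmp_path)
    assert (out / "motion_mask.png").exists()
    assert (out / "motion_rho.png").exists()
    lines = (out / "motion_features.csv").read_text().strip().splitlines()
    assert len(lines) == len(feats) + 1
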