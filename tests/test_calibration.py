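"""Calibration: grid detection, homography estimation, lookup, reprojection."""

import json

import numpy as np
import pytest

from activelight import calibration as cal
from activelight.calibration import (
    CalibrationError,
    CircleGridSpec,
    TexelPixelMap,
    build_lookup,
    detect_grid_centroids,
    estimate_homography,
    project,
    project_points,
    render_circle_grid,
    reprojection_error,
)

SPEC = CircleGridSpec(rows=4, cols=11, spacing=1.0, radius=0.2)
H_TRUE = np.array(
    [[14.0, 0.4, 30.0], [-0.3, 15.0, 40.0], [1e-4, -2e-5, 1.0]]
)


def project_bruteforce(H, pt):
    """Independent homogeneous-algebra oracle for a single point."""
    v = np.array([pt[0], pt[1], 1.0])
    out = [sum(H[i][j] * v[j] for j in range(3)) for i in range(3)]
    return out[0] / out[2], out[1] / out[2]


# ---------------------------------------------------------------------------
# Grid detection


@pytest.mark.parametrize("noise_sigma,tol", [(0.0, 0.1), (2.0, 0.5)])
def test_detected_centroids_match_analytic_centers(noise_sigma, tol):
    rng = np.random.default_rng(7)
    img, centers = render_circle_grid(
        SPEC, H_TRUE, (160, 220), noise_sigma=noise_sigma, rng=rng
    )
    cents = detect_grid_centroids(img, SPEC)
    assert cents.shape == centers.shape
    err = np.linalg.norm(cents - centers, axis=1)
    assert err.max() < tol


def test_blank_image_raises_grid_not_found():
    blank = np.full((64, 64), 255, dtype=np.uint8)
    with pytest.raises(CalibrationError, match="grid not found"):
        detect_grid_centroids(blank, SPEC)


def test_incomplete_grid_reports_count():
    img, _ = render_circle_grid(SPEC, H_TRUE, (160, 220))
    # crop away part of the grid: fewer circles than the pattern needs
    with pytest.raises(CalibrationError, match="detected"):
        detect_grid_centroids(img[:, :80], SPEC)


# ---------------------------------------------------------------------------
# Homography estimation


def test_identity_recovered_from_exact_corners():
    src = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
    H = estimate_homography(src, src)
    assert np.allclose(H, np.eye(3), atol=1e-9)


def test_known_homography_recovered_to_1e8():
    rng = np.random.default_rng(2)
    src = rng.uniform(0, 10, (20, 2))
    dst = project_points(H_TRUE, src)
    H = estimate_homography(src, dst)
    assert np.abs(H - H_TRUE).max() < 1e-8


@pytest.mark.parametrize(
    "src",
    [
        np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),  # too few
        np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]),  # collinear
    ],
)
def test_degenerate_configurations_raise(src):
    with pytest.raises(CalibrationError, match="degenerate"):
        estimate_homography(src, src.copy())


def test_random_homography_roundtrip_property():
    """Estimation inverts generation for 100 well-conditioned random maps."""
    rng = np.random.default_rng(42)
    n_ok = 0
    while n_ok < 100:
        H = np.eye(3) + rng.normal(0, 0.2, (3, 3)) * np.array(
            [[1, 1, 10], [1, 1, 10], [0.01, 0.01, 0]]
        )
        H[2, 2] = 1.0
        if abs(np.linalg.det(H)) < 1e-3 or np.linalg.cond(H) > 1e3:
            continue
        src = rng.uniform(0, 20, (12, 2))
        dst = project_points(H, src)
        Hest = estimate_homography(src, dst)
        assert np.abs(Hest - H).max() < 1e-8
        # forward then inverse projection is the identity
        back = project_points(np.linalg.inv(Hest), dst)
        assert np.abs(back - src).max() < 1e-9
        n_ok += 1


# ---------------------------------------------------------------------------
# Projection


def test_identity_projection_swaps_rowcol_to_xy():
    assert project(np.eye(3), (5, 7)) == (7.0, 5.0)


def test_scaling_projection():
    assert project(np.diag([2.0, 2.0, 1.0]), (3, 4)) == (8.0, 6.0)


def test_projection_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        t = (int(rng.integers(0, 40)), int(rng.integers(0, 40)))
        got = project(H_TRUE, t)
        want = project_bruteforce(H_TRUE, (t[1], t[0]))
        assert np.allclose(got, want, atol=1e-12)


def test_projection_at_infinity_raises():
    H = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0.0]])  # w = -row
    with pytest.raises(CalibrationError, match="infinity"):
        project(H, (0, 5))


# ---------------------------------------------------------------------------
# Lookup table


def test_identity_lookup_fully_sampled():
    tmap = build_lookup(np.eye(3), (10, 10), (20, 20))
    assert tmap.n_sampled == 100
    assert not tmap.unsampled.any()


def test_translation_unsampled_count_matches_enumeration():
    # shift so that columns >= 10 of a 20-col grid leave a 20-px image
    H = np.array([[1.0, 0, 10.0], [0, 1.0, 0], [0, 0, 1.0]])
    tmap = build_lookup(H, (5, 20), (20, 20))
    expected = sum(
        1
        for r in range(5)
        for c in range(20)
        if not (0 <= c + 10 <= 19 and 0 <= r <= 19)
    )
    assert int(tmap.unsampled.sum()) == expected


def test_lookup_equals_rounded_projection():
    rng = np.random.default_rng(5)
    tmap = build_lookup(H_TRUE, (40, 40), (800, 800))
    for _ in range(1000):
        r, c = int(rng.integers(0, 40)), int(rng.integers(0, 40))
        x, y = project(H_TRUE, (r, c))
        want = (
            int(np.sign(x) * np.floor(abs(x) + 0.5)),
            int(np.sign(y) * np.floor(abs(y) + 0.5)),
        )
        assert tuple(tmap.lookup[r, c]) == want


def test_lookup_json_roundtrip():
    tmap = build_lookup(H_TRUE, (6, 7), (100, 100))
    loaded = TexelPixelMap.from_json(tmap.to_json())
    assert np.array_equal(loaded.lookup, tmap.lookup)
    assert np.array_equal(loaded.unsampled, tmap.unsampled)
    assert np.allclose(loaded.homography, tmap.homography)


# ---------------------------------------------------------------------------
# Reprojection error


def test_exact_correspondences_have_zero_error():
    src = np.random.default_rng(0).uniform(0, 10, (15, 2))
    dst = project_points(H_TRUE, src)
    rep = reprojection_error(H_TRUE, src, dst)
    assert rep.mean < 1e-12 and rep.std < 1e-12


def test_constant_displacement_gives_mean_std():
    src = np.random.default_rng(1).uniform(0, 10, (10, 2))
    proj = project_points(H_TRUE, src)
    disp = np.array([2.5, 0.0])
    rep = reprojection_error(H_TRUE, src, proj + disp)
    assert rep.mean == pytest.approx(2.5, abs=1e-12)
    assert rep.std == pytest.approx(0.0, abs=1e-12)


def test_random_perturbations_match_bruteforce_distances():
    rng = np.random.default_rng(9)
    src = rng.uniform(0, 10, (25, 2))
    dst = project_points(H_TRUE, src) + rng.normal(0, 1.0, (25, 2))
    rep = reprojection_error(H_TRUE, src, dst)
    dists = []
    for s, d in zip(src, dst):
        px, py = project_bruteforce(H_TRUE, s)
        dists.append(((px - d[0]) ** 2 + (py - d[1]) ** 2) ** 0.5)
    dists = np.array(dists)
    assert rep.mean == pytest.approx(dists.mean(), abs=1e-12)
    assert rep.std == pytest.approx(dists.std(), abs=1e-12)


def test_estimated_homography_is_locally_optimal():
    rng = np.random.default_rng(21)
    src = rng.uniform(0, 10, (30, 2))
    dst = project_points(H_TRUE, src) + rng.normal(0, 0.05, (30, 2))
    H = estimate_homography(src, dst)
    base = reprojection_error(H, src, dst).mean
    # perturbations large enough to dominate the (algebraic vs geometric)
    # least-squares gap: this is a smoke test of local optimality
    for _ in range(5):
        Hp = H + rng.normal(0, 1e-2, (3, 3)) * np.array(
            [[1, 1, 5], [1, 1, 5], [1e-4, 1e-4, 0]]
        )
        assert reprojection_error(Hp, src, dst).mean >= base


def test_empty_correspondences_raise():
    with pytest.raises(CalibrationError, match="empty"):
        reprojection_error(H_TRUE, np.empty((0, 2)), np.empty((0, 2)))


def test_full_calibration_pipeline_accuracy():
    img, _ = render_circle_grid(SPEC, H_TRUE, (160, 220))
    tmap, rep = cal.calibrate(img, SPEC, (4, 11))
    assert rep.mean < 0.2
    assert np.abs(tmap.homography - H_TRUE).max() / np.abs(H_TRUE).max() < 0.01
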