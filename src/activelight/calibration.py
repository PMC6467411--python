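"""Texel-to-pixel geometric calibration.

The illumination matrix is addressed in *texel* coordinates (row, col of the
light-dot grid) while the camera senses *pixel* coordinates.  The two frames
are related by a 3x3 homography ``H`` in homogeneous coordinates::

    [x, y, w]^T = H @ [col, row, 1]^T ,   pixel = (x/w, y/w)

Calibration estimates ``H`` from centroids of a rendered asymmetric circle
grid, builds the integer lookup table used by the feedback loop to sample one
camera pixel per texel, and scores the fit with the per-point reprojection
error.

Conventions: 0-based indices, origin top-left, pixel centers at integer
coordinates, ``x`` = column and ``y`` = row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform


class CalibrationError(ValueError):
    """Raised for degenerate inputs (grid not found, collinear points, ...)."""


# ---------------------------------------------------------------------------
# Asymmetric circle grid geometry


@dataclass(frozen=True)
class CircleGridSpec:
    """Geometry of an asymmetric circle calibration grid.

    ``rows`` x ``cols`` circles; odd rows are shifted by half the column
    ``spacing`` (diagonal interleave), the standard asymmetric layout.
    Canonical pattern points are returned in row-major order in *pattern
    units* of ``spacing``.
    """

    rows: int = 4
    cols: int = 11
    spacing: float = 1.0
    radius: float = 0.2  # circle radius, in spacing units

    def pattern_points(self) -> np.ndarray:
        """Canonical (x, y) pattern points, row-major, shape (rows*cols, 2)."""
        pts = []
        for r in range(self.rows):
            for c in range(self.cols):
                x = (2 * c + (r % 2)) * self.spacing / 2.0
                y = r * self.spacing
                pts.append((x, y))
        return np.asarray(pts, dtype=float)


def render_circle_grid(
    spec: CircleGridSpec,
    homography: np.ndarray,
    image_shape: tuple[int, int],
    *,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    supersample: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic calibration image of dark circles on white.

    The pattern points are pushed through ``homography`` and drawn as filled
    dark discs with ``supersample`` antialiasing, so detected centroids can be
    compared against the analytic projected centers.

    Returns ``(image, centers)`` where ``image`` is uint8 and ``centers`` the
    projected (x, y) circle centers, row-major.
    """
    h, w = image_shape
    centers = project_points(homography, spec.pattern_points())
    # projected radius: use the mean local scale of the map at each center
    ss = supersample
    yy, xx = np.mgrid[0:h * ss, 0:w * ss]
    # subsamples centered on pixel centers (pixel i spans i-0.5 .. i+0.5)
    xx = (xx + 0.5) / ss - 0.5
    yy = (yy + 0.5) / ss - 0.5
    img = np.ones((h * ss, w * ss), dtype=float)
    # local radius from the Jacobian scale of the homography at each center
    for (cx, cy), (px, py) in zip(spec.pattern_points(), centers):
        eps = 1e-3
        j = (
            project_points(homography, np.array([[cx + eps, cy], [cx, cy + eps]]))
            - np.array([px, py])
        ) / eps
        scale = float(np.sqrt(abs(np.linalg.det(j.T))))
        rad = spec.radius * scale
        mask = (xx - px) ** 2 + (yy - py) ** 2 <= rad**2
        img[mask] = 0.0
    img = img.reshape(h, ss, w, ss).mean(axis=(1, 3))
    img = img * 255.0
    if noise_sigma > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), centers


# ---------------------------------------------------------------------------
# Blob detection


def detect_grid_centroids(
    image: np.ndarray,
    spec: CircleGridSpec,
    *,
    threshold: float | None = None,
    min_area: int = 9,
    min_circularity: float = 0.7,
) -> np.ndarray:
    """Detect the circle-grid centroids in an 8-bit greyscale image.

    Dark blobs are extracted by thresholding (midpoint of the intensity range
    unless ``threshold`` is given), labelled with 8-connectivity, filtered by
    ``min_area`` (px) and ``min_circularity`` (4*pi*area/perimeter^2), and
    their intensity-weighted centroids returned with sub-pixel precision,
    ordered consistently with :meth:`CircleGridSpec.pattern_points`
    (row-major along the grid).

    Raises :class:`CalibrationError` if fewer blobs than grid points remain.
    """
    img = np.asarray(image, dtype=float)
    if threshold is None:
        lo, hi = float(img.min()), float(img.max())
        if hi - lo < 16:  # essentially flat image: no dark blobs
            raise CalibrationError(
                f"grid not found: image has no contrast (range {hi - lo:.1f})"
            )
        threshold = (lo + hi) / 2.0
    dark = img < threshold
    labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    cents: list[tuple[float, float]] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area < min_area:
            continue
        # perimeter via count of edge pixels' exposed faces (cheap, adequate
        # for the circularity screen)
        er = ndimage.binary_erosion(mask)
        boundary = int(mask.sum() - er.sum())
        perimeter = max(boundary, 1)
        circ = 4.0 * np.pi * area / (perimeter**2)
        if circ < min_circularity:
            continue
        # darkness-weighted centroid over the blob plus its antialiased rim
        rim = ndimage.binary_dilation(mask, iterations=2)
        bright = img[rim].max()
        wts = np.clip(bright - img[rim], 0, None)
        ys, xs = np.nonzero(rim)
        tot = wts.sum()
        if tot <= 0:
            continue
        cents.append((float((xs * wts).sum() / tot), float((ys * wts).sum() / tot)))
    npts = spec.rows * spec.cols
    if len(cents) < npts:
        raise CalibrationError(
            f"grid not found: expected {npts} circles, detected {len(cents)}"
        )
    pts = np.asarray(cents)
    return _order_like_pattern(pts, spec)


def _order_like_pattern(pts: np.ndarray, spec: CircleGridSpec) -> np.ndarray:
    """Order detected centroids to match the canonical pattern ordering.

    Estimates a homography from the convex-ordering-free correspondence by
    matching the point cloud to the pattern through an affine fit on extreme
    points is fragile; instead we exploit that the fixtures are rendered with
    modest perspective: sort into ``rows`` bands by the dominant direction of
    variation, then by position along each band.
    """
    npts = spec.rows * spec.cols
    if len(pts) > npts:
        # keep the npts blobs closest to the cloud median (spurious blobs are
        # usually peripheral noise)
        med = np.median(pts, axis=0)
        d = np.linalg.norm(pts - med, axis=1)
        pts = pts[np.argsort(d)[:npts]]
    centered = pts - pts.mean(axis=0)
    # principal axes of the cloud: rows vary along the minor axis
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    along = centered @ vt[0]
    across = centered @ vt[1]
    order = np.lexsort((along, np.rint(
        (across - across.min()) / (np.ptp(across) / (spec.rows - 1) + 1e-12)
    )))
    ordered = pts[order]
    # canonical pattern rows advance with y; flip if detected bands run opposite
    first_band = ordered[: spec.cols]
    last_band = ordered[-spec.cols:]
    if first_band[:, 1].mean() > last_band[:, 1].mean():
        ordered = ordered[::-1].copy()
        ordered = np.concatenate(
            [ordered[i * spec.cols:(i + 1) * spec.cols][::-1] for i in range(spec.rows)]
        )
    else:
        ordered = np.concatenate(
            [
                band[np.argsort(band[:, 0])]
                for band in np.split(ordered, spec.rows)
            ]
        )
    return ordered


# ---------------------------------------------------------------------------
# Homography estimation and use


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Estimate the 3x3 homography mapping ``src`` (x, y) to ``dst`` (x, y).

    Normalized DLT (least-squares on the algebraic error with isotropic point
    normalization); deterministic.  The result is scaled so ``H[2, 2] == 1``.

    Raises :class:`CalibrationError` for fewer than 4 points or a degenerate
    (collinear) configuration.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise CalibrationError("correspondence arrays must both be (n, 2)")
    if len(src) < 4:
        raise CalibrationError(
            f"degenerate configuration: need >= 4 correspondences, got {len(src)}"
        )
    if _collinear(src) or _collinear(dst):
        raise CalibrationError("degenerate configuration: points are collinear")
    tf = ProjectiveTransform.from_estimate(src, dst)
    if not tf:
        raise CalibrationError("degenerate configuration: estimation failed")
    H = tf.params
    if abs(H[2, 2]) > 1e-12:
        H = H / H[2, 2]
    return H


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def project_points(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply homography ``H`` to an (n, 2) array of (x, y) points."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    hom = np.column_stack([pts, np.ones(len(pts))]) @ np.asarray(H, dtype=float).T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-15):
        raise CalibrationError("projection at infinity: homogeneous w is 0")
    return hom[:, :2] / w[:, None]


def project(H: np.ndarray, texel: tuple[int, int]) -> tuple[float, float]:
    """Project a texel ``(row, col)`` to a pixel ``(x, y)`` through ``H``."""
    row, col = texel
    out = project_points(H, np.array([[float(col), float(row)]]))[0]
    return float(out[0]), float(out[1])


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class TexelPixelMap:
    """Calibrated homography plus the texel -> integer-pixel lookup table.

    ``lookup`` has shape (grid_rows, grid_cols, 2) holding (x, y); texels
    whose projection falls outside the image are flagged in ``unsampled``
    (boolean mask, same grid shape) and excluded from feedback.
    """

    homography: np.ndarray
    grid_shape: tuple[int, int]
    image_shape: tuple[int, int]
    lookup: np.ndarray = field(repr=False)
    unsampled: np.ndarray = field(repr=False)

    @property
    def n_sampled(self) -> int:
        return int((~self.unsampled).sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "homography": np.asarray(self.homography).tolist(),
                "grid_shape": list(self.grid_shape),
                "image_shape": list(self.image_shape),
                "lookup": self.lookup.tolist(),
                "unsampled_texels": [
                    [int(r), int(c)] for r, c in zip(*np.nonzero(self.unsampled))
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TexelPixelMap":
        d = json.loads(text)
        grid = tuple(d["grid_shape"])
        unsampled = np.zeros(grid, dtype=bool)
        for r, c in d["unsampled_texels"]:
            unsampled[r, c] = True
        return cls(
            homography=np.asarray(d["homography"], dtype=float),
            grid_shape=grid,  # type: ignore[arg-type]
            image_shape=tuple(d["image_shape"]),  # type: ignore[arg-type]
            lookup=np.asarray(d["lookup"], dtype=int),
            unsampled=unsampled,
        )


def build_lookup(
    H: np.ndarray, grid_shape: tuple[int, int], image_shape: tuple[int, int]
) -> TexelPixelMap:
    """Build the per-texel integer pixel lookup table for feedback sampling.

    Each in-grid texel (row, col) is projected through ``H`` and rounded
    (half away from zero); projections landing outside the image are flagged
    unsampled rather than raising.
    """
    rows, cols = grid_shape
    h, w = image_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([cc.ravel().astype(float), rr.ravel().astype(float)])
    proj = project_points(H, pts)
    ipix = _round_half_away(proj).astype(int).reshape(rows, cols, 2)
    x, y = ipix[..., 0], ipix[..., 1]
    unsampled = (x < 0) | (x >= w) | (y < 0) | (y >= h)
    return TexelPixelMap(
        homography=np.asarray(H, dtype=float),
        grid_shape=grid_shape,
        image_shape=image_shape,
        lookup=ipix,
        unsampled=unsampled,
    )


@dataclass(frozen=True)
class ReprojectionReport:
    """Per-point reprojection errors (px) with summary statistics."""

    errors: np.ndarray
    mean: float
    std: float

    @property
    def max(self) -> float:
        return float(self.errors.max())


def reprojection_error(
    H: np.ndarray, src: np.ndarray, dst: np.ndarray
) -> ReprojectionReport:
    """Euclidean distance between measured pixels and projected pattern points.

    ``mean`` is the statistic quoted as the reprojection error of a
    calibration; ``std`` is its spread over points.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) == 0:
        raise CalibrationError("empty correspondence set")
    proj = project_points(H, src)
    errs = np.linalg.norm(proj - dst, axis=1)
    return ReprojectionReport(
        errors=errs, mean=float(errs.mean()), std=float(errs.std())
    )


def calibrate(
    image: np.ndarray,
    spec: CircleGridSpec,
    grid_shape: tuple[int, int],
    *,
    pattern_to_texel: np.ndarray | None = None,
    detect_kwargs: dict | None = None,
) -> tuple[TexelPixelMap, ReprojectionReport]:
    """Full calibration: detect grid, estimate H, build lookup, score fit.

    ``pattern_to_texel`` optionally maps pattern units to texel coordinates
    (defaults to identity: pattern points are texel (col, row) positions).
    """
    cents = detect_grid_centroids(image, spec, **(detect_kwargs or {}))
    src = spec.pattern_points()
    if pattern_to_texel is not None:
        src = project_points(pattern_to_texel, src)
    H = estimate_homography(src, cents)
    report = reprojection_error(H, src, cents)
    tmap = build_lookup(H, grid_shape, image.shape[:2])
    return tmap, report
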