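"""Image-quality and segmentation metrics for backlight images.

The central score is the Fisher separability index between background
(positive class) and worm (negative class) grey levels,

    F = |mu_pos - mu_neg| / (sigma_pos^2 + sigma_neg^2),

with population standard deviations and the *sum of variances* in the
denominator (not its square root).  A larger F means the two intensity
populations are easier to split with a single fixed threshold.

Also provided: fixed-threshold connected-component segmentation of dark
worms and region-restricted image statistics (mean, std, 256-bin histogram,
line profiles) for compensated-vs-uncontrolled comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class MetricsError(ValueError):
    pass


def fisher_index(pos: np.ndarray, neg: np.ndarray) -> float:
    """Fisher separability of two intensity samples.

    ``pos`` and ``neg`` are 1-D grey-level samples (background and worm
    pixels).  Raises :class:`MetricsError` when either class is empty or both
    classes have zero variance (degenerate denominator).
    """
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise MetricsError("both classes must be non-empty")
    var = pos.var() + neg.var()  # population variances
    if var == 0:
        raise MetricsError("degenerate variance: both classes are constant")
    return float(abs(pos.mean() - neg.mean()) / var)


@dataclass(frozen=True)
class SegmentationResult:
    """Binary worm mask with per-object bookkeeping."""

    mask: np.ndarray
    threshold: float
    object_count: int
    areas: np.ndarray
    labels: np.ndarray = field(repr=False)


def threshold_segment(
    image: np.ndarray,
    threshold: float = 24.0,
    min_area: int = 20,
    *,
    region: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment dark objects by a fixed threshold.

    Pixels strictly below ``threshold`` (optionally restricted to ``region``)
    are foreground; 8-connected components smaller than ``min_area`` px are
    discarded.
    """
    if not 0 <= threshold <= 255:
        raise MetricsError("threshold must be a grey level in [0, 255]")
    img = np.asarray(image, dtype=float)
    fg = img < threshold
    if region is not None:
        fg &= np.asarray(region, dtype=bool)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_area) + 1
        relabel = np.zeros(n + 1, dtype=int)
        relabel[keep] = np.arange(1, len(keep) + 1)
        labels = relabel[labels]
        areas = areas[keep - 1].astype(int)
    else:
        areas = np.array([], dtype=int)
    return SegmentationResult(
        mask=labels > 0,
        threshold=float(threshold),
        object_count=int(len(areas)),
        areas=np.asarray(areas),
        labels=labels,
    )


@dataclass(frozen=True)
class RegionStats:
    mean: float
    std: float
    histogram: np.ndarray  # 256 bins
    profile: np.ndarray | None = None


def image_statistics(
    image: np.ndarray,
    region: np.ndarray | None = None,
    *,
    profile_row: int | None = None,
) -> RegionStats:
    """Mean, population std and 256-bin histogram restricted to ``region``.

    ``profile_row`` optionally extracts that image row's grey levels (within
    the region) as a line profile.
    """
    img = np.asarray(image, dtype=float)
    mask = np.ones(img.shape, bool) if region is None else np.asarray(region, bool)
    vals = img[mask]
    if vals.size == 0:
        raise MetricsError("empty region")
    hist, _ = np.histogram(vals, bins=256, range=(0, 256))
    profile = None
    if profile_row is not None:
        profile = np.where(mask[profile_row], img[profile_row], np.nan)
    return RegionStats(
        mean=float(vals.mean()), std=float(vals.std()), histogram=hist, profile=profile
    )


@dataclass(frozen=True)
class QualityReport:
    """Fisher index plus per-class statistics for one image."""

    fisher: float
    background_mean: float
    background_std: float
    worm_mean: float
    worm_std: float
    histogram: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "fisher": self.fisher,
            "background_mean": self.background_mean,
            "background_std": self.background_std,
            "worm_mean": self.worm_mean,
            "worm_std": self.worm_std,
        }


def quality_report(
    image: np.ndarray, background_mask: np.ndarray, worm_mask: np.ndarray
) -> QualityReport:
    """Score an image's worm/background separability from ground-truth masks."""
    img = np.asarray(image, dtype=float)
    pos = img[np.asarray(background_mask, bool)]
    neg = img[np.asarray(worm_mask, bool)]
    hist, _ = np.histogram(
        img[np.asarray(background_mask, bool) | np.asarray(worm_mask, bool)],
        bins=256,
        range=(0, 256),
    )
    return QualityReport(
        fisher=fisher_index(pos, neg),
        background_mean=float(pos.mean()),
        background_std=float(pos.std()),
        worm_mean=float(neg.mean()),
        worm_std=float(neg.std()),
        histogram=hist,
    )


def match_objects(result: SegmentationResult, truth_mask: np.ndarray, iou_min: float = 0.7) -> int:
    """Count ground-truth objects matched by a segmented object with IoU >= iou_min."""
    t_labels, t_n = ndimage.label(np.asarray(truth_mask, bool), structure=np.ones((3, 3), int))
    matched = 0
    for t in range(1, t_n + 1):
        tmask = t_labels == t
        cand = np.unique(result.labels[tmask])
        cand = cand[cand > 0]
        for c in cand:
            cmask = result.labels == c
            inter = float((tmask & cmask).sum())
            union = float((tmask | cmask).sum())
            if union and inter / union >= iou_min:
                matched += 1
                break
    return matched
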