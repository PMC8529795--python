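"""Evaluation metrics: pairwise-averaged Dice, maximum perpendicular
distance between myocardial contours, ROI statistics, and the 2-SD
positivity rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .signal_model import ParameterMap

__all__ = [
    "MaskSeries",
    "RoiStat",
    "dice_pair",
    "dice_series",
    "mpd",
    "roi_stats",
    "two_sd_positive",
]


@dataclass
class MaskSeries:
    """Per-image myocardium segmentations on one grid."""

    masks: np.ndarray  # (N, H, W) bool
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be an (N, H, W) stack")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))

    @property
    def n(self) -> int:
        return self.masks.shape[0]


@dataclass
class RoiStat:
    mean: float
    sd: float
    n_pixels: int


def dice_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|a & b| / (|a| + |b|)`` as a fraction in [0, 1]."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one shape")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_series(masks: MaskSeries) -> float:
    """Average Dice over all ordered pairs ``(i, j), i != j``, in percent.
    100% means all segmentations coincide."""
    n = masks.n
    if n < 2:
        raise ValueError("need at least 2 masks")
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += dice_pair(masks.masks[i], masks.masks[j])
    return 100.0 * total / (n * (n - 1))


# ---------------------------------------------------------------------------
# contours and MPD

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _contours(mask: np.ndarray):
    """Endo (inner) and epi (outer) boundary pixel coordinates of a filled
    myocardium mask, by 8-connectivity adjacency to holes resp. the outside.

    Returns (endo_pts, epi_pts) as (k, 2) arrays of (row, col). ``endo_pts``
    is empty when the mask has no interior hole.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no contour")
    bg = ~mask
    # 4-connectivity on the background complements 8-connectivity boundaries
    labels, _ = ndimage.label(bg, structure=ndimage.generate_binary_structure(2, 1))
    border_labels = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :]))
    border_labels |= set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    border_labels.discard(0)
    outside = np.isin(labels, sorted(border_labels))
    holes = bg & ~outside

    epi = mask & ndimage.binary_dilation(outside, structure=_STRUCT8)
    endo = mask & ndimage.binary_dilation(holes, structure=_STRUCT8)
    if not mask.all() and not epi.any():
        # mask touches every border pixel: fall back to plain boundary
        epi = mask & ~ndimage.binary_erosion(mask, structure=_STRUCT8)
    return np.argwhere(endo), np.argwhere(epi)


def _hausdorff(pts_a: np.ndarray, pts_b: np.ndarray, spacing) -> float:
    """Symmetric Hausdorff distance between two point sets, in mm."""
    sa = pts_a * np.asarray(spacing)[None, :]
    sb = pts_b * np.asarray(spacing)[None, :]
    d_ab = cKDTree(sb).query(sa)[0].max()
    d_ba = cKDTree(sa).query(sb)[0].max()
    return float(max(d_ab, d_ba))


def mpd(masks: MaskSeries) -> float:
    """Maximum perpendicular distance across the series, in mm.

    For every image pair, the symmetric Hausdorff distance is computed
    between endocardial contours and between epicardial contours (pair value
    = max of the two); the maximum over all pairs is returned.
    """
    if masks.n < 2:
        raise ValueError("need at least 2 masks")
    contours = [_contours(m) for m in masks.masks]
    worst = 0.0
    for i in range(masks.n):
        for j in range(i + 1, masks.n):
            endo_i, epi_i = contours[i]
            endo_j, epi_j = contours[j]
            d = _hausdorff(epi_i, epi_j, masks.spacing)
            if len(endo_i) or len(endo_j):
                if not (len(endo_i) and len(endo_j)):
                    raise ValueError(
                        f"degenerate endocardial contour in image pair ({i}, {j})"
                    )
                d = max(d, _hausdorff(endo_i, endo_j, masks.spacing))
            worst = max(worst, d)
    return worst


def roi_stats(param_map: ParameterMap, roi: np.ndarray) -> RoiStat:
    """Mean and sample SD of T1rho over a region of interest (ms)."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != param_map.shape:
        raise ValueError("roi and map shapes must match")
    roi = roi & param_map.mask
    n = int(roi.sum())
    if n == 0:
        raise ValueError("empty ROI")
    vals = param_map.t1rho[roi]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return RoiStat(mean=float(vals.mean()), sd=sd, n_pixels=n)


def two_sd_positive(
    param_map: ParameterMap, remote_roi: np.ndarray, segment_roi: np.ndarray
) -> bool:
    """Positivity rule: segment mean reaches at least the remote mean plus
    two remote standard deviations (an actual increase is required when the
    remote SD is zero)."""
    remote = roi_stats(param_map, remote_roi)
    segment = roi_stats(param_map, segment_roi)
    if remote.sd == 0.0:
        return segment.mean > remote.mean
    return segment.mean >= remote.mean + 2.0 * remote.sd
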