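"""ROI selection from whole-slide images via superpixel over-segmentation.

A WSI is reduced to a thumbnail, over-segmented into superpixels (SLIC),
and the superpixels are ranked by mean grayscale intensity: dense cellular
tissue absorbs more light, so dark regions mark high cellularity.  The
candidates at the lowest-intensity decile are kept, their centroids mapped
back to full resolution, and fixed-size ROIs cropped around them.

Pen-marker ink is darker than any tissue and therefore wins this ranking —
a known failure mode.  No automatic ink detection is attempted; callers may
supply an exclusion mask instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic
from skimage.transform import resize

log = logging.getLogger(__name__)

# Rec. 709 luma coefficients (as used by skimage.color.rgb2gray)
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class ROISelectionConfig:
    thumbnail_max_dim: int = 1024
    n_superpixels: int = 400
    compactness: float = 10.0
    percentile: float = 0.10
    roi_size: int = 1000
    background_threshold: float = 240.0  # mean above this = glass, excluded

    def __post_init__(self):
        if not 0.0 < self.percentile <= 1.0:
            raise ValueError("percentile must be in (0, 1]")
        if self.roi_size <= 0:
            raise ValueError("roi_size must be positive")
        if self.n_superpixels < 2:
            raise ValueError("n_superpixels must be >= 2")
        if self.thumbnail_max_dim < 64:
            raise ValueError("thumbnail_max_dim must be >= 64")


@dataclass
class ROICandidate:
    superpixel_id: int
    mean_intensity: float
    centroid_thumbnail: tuple[float, float]
    centroid_wsi: tuple[int, int]
    area: int


def _load_image(source) -> np.ndarray:
    if isinstance(source, np.ndarray):
        return source
    import imageio.v3 as iio

    try:
        return np.asarray(iio.imread(source))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read WSI source {source!r}: {exc}") from exc


def make_thumbnail(wsi, config: ROISelectionConfig | None = None):
    """Downscale to at most ``thumbnail_max_dim`` on the longest side.

    Returns ``(thumbnail_uint8, scale_factor)`` with
    ``scale_factor = full_dim / thumb_dim``.
    """
    config = config or ROISelectionConfig()
    img = _load_image(wsi)
    h, w = img.shape[:2]
    longest = max(h, w)
    if longest <= config.thumbnail_max_dim:
        return img.astype(np.uint8, copy=False), 1.0
    scale = longest / config.thumbnail_max_dim
    th, tw = max(1, round(h / scale)), max(1, round(w / scale))
    thumb = resize(img, (th, tw), anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(thumb), 0, 255).astype(np.uint8), longest / max(th, tw)


def oversegment(thumbnail: np.ndarray, config: ROISelectionConfig | None = None
                ) -> np.ndarray:
    """SLIC over-segmentation; every pixel receives exactly one label."""
    config = config or ROISelectionConfig()
    if thumbnail.size == 0:
        raise ValueError("thumbnail is empty")
    if np.ptp(thumbnail) == 0:
        log.warning("constant-color image: over-segmentation degenerates "
                    "to a single superpixel")
        return np.zeros(thumbnail.shape[:2], dtype=int)
    labels = slic(
        thumbnail,
        n_segments=config.n_superpixels,
        compactness=config.compactness,
        start_label=0,
        channel_axis=-1 if thumbnail.ndim == 3 else None,
        enforce_connectivity=True,
    )
    return labels


def _grayscale(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        return image.astype(float)
    return image[..., :3].astype(float) @ _LUMA


def rank_and_select(label_map: np.ndarray, thumbnail: np.ndarray,
                    config: ROISelectionConfig | None = None,
                    *, scale_factor: float = 1.0,
                    exclusion_mask: np.ndarray | None = None
                    ) -> list[ROICandidate]:
    """Rank superpixels by mean intensity; keep the darkest decile.

    Candidates are superpixels whose mean grayscale intensity is at or below
    the ``percentile`` quantile of all (non-glass) superpixel means, sorted
    ascending; ties broken by larger area, then lower label id.  Superpixels
    brighter than ``background_threshold`` are dropped as glass before
    ranking; nothing is ever excluded for being dark.  An optional exclusion
    mask removes superpixels that are mostly inside it (e.g. known ink).
    """
    config = config or ROISelectionConfig()
    if label_map.shape != thumbnail.shape[:2]:
        raise ValueError("label_map and thumbnail shapes differ")
    labels = np.unique(label_map)
    if labels.size == 0:
        raise ValueError("label map has no labels")

    gray = _grayscale(thumbnail)
    flat_labels = label_map.ravel()
    # densify ids for bincount
    dense = np.searchsorted(labels, flat_labels)
    areas = np.bincount(dense, minlength=labels.size)
    sums = np.bincount(dense, weights=gray.ravel(), minlength=labels.size)
    means = sums / np.maximum(areas, 1)
    rr, cc = np.mgrid[0 : label_map.shape[0], 0 : label_map.shape[1]]
    crow = np.bincount(dense, weights=rr.ravel(), minlength=labels.size) / np.maximum(areas, 1)
    ccol = np.bincount(dense, weights=cc.ravel(), minlength=labels.size) / np.maximum(areas, 1)

    keep = means <= config.background_threshold
    if exclusion_mask is not None:
        frac_excluded = (
            np.bincount(dense, weights=exclusion_mask.ravel().astype(float),
                        minlength=labels.size)
            / np.maximum(areas, 1)
        )
        keep &= frac_excluded < 0.5
    if not keep.any():
        log.warning("all superpixels excluded as background; keeping all")
        keep = np.ones_like(keep)

    idx = np.nonzero(keep)[0]
    q = np.quantile(means[idx], config.percentile)
    selected = idx[means[idx] <= q]
    # ascending mean, ties: larger area first, then lower label id
    order = sorted(selected, key=lambda i: (means[i], -areas[i], labels[i]))
    return [
        ROICandidate(
            superpixel_id=int(labels[i]),
            mean_intensity=float(means[i]),
            centroid_thumbnail=(float(crow[i]), float(ccol[i])),
            centroid_wsi=(int(round(crow[i] * scale_factor)),
                          int(round(ccol[i] * scale_factor))),
            area=int(areas[i]),
        )
        for i in order
    ]


def crop_roi(wsi_source, candidate: ROICandidate,
             config: ROISelectionConfig | None = None) -> np.ndarray:
    """Crop a ``roi_size`` square centered on the candidate's WSI centroid.

    Windows that would overrun the image are shifted (not padded) to fit.
    """
    config = config or ROISelectionConfig()
    img = _load_image(wsi_source)
    h, w = img.shape[:2]
    s = config.roi_size
    if h < s or w < s:
        raise ValueError(
            f"WSI of size {h}x{w} is smaller than roi_size {s}x{s}"
        )
    cy, cx = candidate.centroid_wsi
    r0 = int(np.clip(cy - s // 2, 0, h - s))
    c0 = int(np.clip(cx - s // 2, 0, w - s))
    return img[r0 : r0 + s, c0 : c0 + s]


def select_rois(wsi, config: ROISelectionConfig | None = None,
                exclusion_mask: np.ndarray | None = None):
    """Full ROI pipeline: thumbnail -> oversegment -> rank -> candidates.

    Returns ``(candidates, thumbnail, scale_factor)``; crop the top
    candidate with :func:`crop_roi`.
    """
    config = config or ROISelectionConfig()
    thumb, scale = make_thumbnail(wsi, config)
    labels = oversegment(thumb, config)
    if exclusion_mask is not None and exclusion_mask.shape != thumb.shape[:2]:
        exclusion_mask = (
            resize(exclusion_mask.astype(float), thumb.shape[:2], order=0,
                   preserve_range=True) > 0.5
        )
    candidates = rank_and_select(labels, thumb, config, scale_factor=scale,
                                 exclusion_mask=exclusion_mask)
    return candidates, thumb, scale
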