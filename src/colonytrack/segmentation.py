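"""Colony detection in phase-contrast frames.

Phase contrast produces bright halos around dense objects and slowly
varying illumination; the pipeline therefore runs

    retinex gray-value adaptation -> total-variation denoising ->
    region-based active contours -> hole filling -> connected labeling.

Individual cells inside a colony cannot be visually separated, so the unit
of segmentation is the connected colony region; separating touching
colonies is the tracker's job, not the segmenter's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, restoration, segmentation as sk_seg

__all__ = [
    "SegmentationParams",
    "retinex_correct",
    "tv_denoise",
    "active_contour_segment",
    "fill_holes",
    "segment_colonies",
    "relabel_raster_order",
]

_EPS = 1e-3


@dataclass
class SegmentationParams:
    retinex_sigma: float = 30.0
    tv_weight: float = 0.1
    tv_iterations: int = 100
    ac_iterations: int = 200
    ac_smoothing: int = 2
    min_object_px: int = 30

    def __post_init__(self) -> None:
        if self.retinex_sigma <= 0 or self.tv_weight <= 0:
            raise ValueError("retinex_sigma and tv_weight must be positive")
        if self.tv_iterations < 1 or self.ac_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.ac_smoothing < 0 or self.min_object_px < 0:
            raise ValueError("ac_smoothing and min_object_px must be >= 0")


def retinex_correct(image: np.ndarray, retinex_sigma: float = 30.0) -> np.ndarray:
    """Single-scale retinex: subtract the log of a Gaussian illumination
    estimate from the log image, then rescale to [0, 1].

    Flattens smooth illumination gradients and compresses halo artifacts
    while preserving local texture contrast.  A constant image has no
    retinex response and maps to the neutral value 0.5.
    """
    if retinex_sigma <= 0:
        raise ValueError("retinex_sigma must be positive")
    image = np.asarray(image, dtype=np.float64)
    illum = ndimage.gaussian_filter(image, retinex_sigma)
    r = np.log(image + _EPS) - np.log(illum + _EPS)
    lo, hi = float(r.min()), float(r.max())
    if hi - lo < 1e-12:
        return np.full_like(image, 0.5)
    return (r - lo) / (hi - lo)


def tv_denoise(image: np.ndarray, tv_weight: float = 0.1, tv_iterations: int = 100) -> np.ndarray:
    """Rudin–Osher–Fatemi denoising via Chambolle's projection algorithm."""
    if tv_weight <= 0:
        raise ValueError("tv_weight must be positive")
    if tv_iterations < 1:
        raise ValueError("tv_iterations must be >= 1")
    out = restoration.denoise_tv_chambolle(
        np.asarray(image, dtype=np.float64), weight=tv_weight, max_num_iter=tv_iterations
    )
    return np.clip(out, 0.0, 1.0)


def active_contour_segment(
    image: np.ndarray,
    init_mask: np.ndarray | None = None,
    ac_iterations: int = 200,
    ac_smoothing: int = 2,
) -> np.ndarray:
    """Two-phase region-based (piecewise-constant) active contour.

    Evolves a level set from ``init_mask`` (or a checkerboard when absent)
    for ``ac_iterations`` steps; the returned foreground is the phase with
    the higher mean gray value.  A constant image, where the two-phase
    energy cannot distinguish any partition, yields an empty mask.
    """
    image = np.asarray(image, dtype=np.float64)
    if init_mask is not None:
        init_mask = np.asarray(init_mask)
        if init_mask.shape != image.shape:
            raise ValueError("init_mask shape does not match image")
        if not init_mask.any():
            init_mask = None
    if float(image.max() - image.min()) < 1e-9:
        return np.zeros(image.shape, dtype=bool)
    init = init_mask.astype(np.int8) if init_mask is not None else "checkerboard"
    ls = sk_seg.morphological_chan_vese(
        image, num_iter=ac_iterations, init_level_set=init, smoothing=ac_smoothing
    ).astype(bool)
    if not ls.any() or ls.all():
        return np.zeros(image.shape, dtype=bool)
    # orient the phases: foreground = brighter phase
    if image[ls].mean() < image[~ls].mean():
        ls = ~ls
    return ls


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set every background component not connected to the border to
    foreground; the foreground never shrinks."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by raster-scan order of each component's first pixel."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return np.zeros_like(labels, dtype=np.int32)
    # first occurrence of each label in raster order
    _, first_idx = np.unique(flat[nz], return_index=True)
    order = flat[nz[np.sort(first_idx)]]
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, order.size + 1)
    return lut[labels]


def segment_colonies(frame, params: SegmentationParams | None = None) -> np.ndarray:
    """Full detection pipeline on one frame; returns an integer label mask.

    Components are 8-connected; objects below ``min_object_px`` pixels are
    discarded; labels run 1..K in raster-scan order of first pixel.
    """
    p = params or SegmentationParams()
    pixels = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame, dtype=np.float64)
    pre = retinex_correct(pixels, p.retinex_sigma)
    pre = tv_denoise(pre, p.tv_weight, p.tv_iterations)
    fg = active_contour_segment(pre, None, p.ac_iterations, p.ac_smoothing)
    fg = fill_holes(fg)
    if p.min_object_px > 0:
        fg = _remove_small(fg, p.min_object_px)
    labels = measure.label(fg, connectivity=2)
    return relabel_raster_order(labels)


def _remove_small(fg: np.ndarray, min_object_px: int) -> np.ndarray:
    """Drop 8-connected components with area < min_object_px."""
    labels, n = ndimage.label(fg, structure=np.ones((3, 3)))
    if n == 0:
        return fg
    areas = np.bincount(labels.ravel())
    keep = areas >= min_object_px
    keep[0] = False
    return keep[labels]
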