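"""Conventional post-image filters: Gaussian smoothing and non-local means.

These are the two comparators against which the learned denoiser is judged,
and the Gaussian filter also produces the reference image set (applied to the
full-count volume).  The Gaussian filter is parameterised by its full width
at half maximum (FWHM) in millimetres, the convention of PET post-smoothing;
the NLM filter operates slice-by-slice in 2D with a 3x3 patch and a 5x5
search window, with filtering strength h set from the standard deviation of
background fibroglandular tissue in the low-count images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import PETVolume

__all__ = [
    "GaussianFilterParams",
    "NlmParams",
    "fwhm_to_sigma",
    "gaussian_post_filter",
    "estimate_background_sigma",
    "nlm_filter",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.35482


@dataclass(frozen=True)
class GaussianFilterParams:
    """FWHM of the Gaussian post-filter, in mm.  ``axes="3d"`` smooths
    isotropically along all three axes; ``"2d"`` smooths in-plane only."""

    fwhm_mm: float = 1.17
    axes: str = "3d"

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be non-negative")
        if self.axes not in ("3d", "2d"):
            raise ValueError("axes must be '3d' or '2d'")


@dataclass(frozen=True)
class NlmParams:
    """Non-local-means parameters.

    patch / search: odd side lengths in pixels (3x3 patches compared over a
    5x5 search window by default).
    h: filtering strength in SUV, entering the weights as exp(-D^2/h^2);
    set it from ``estimate_background_sigma`` on the low-count image.
    self_weight_rule: "self" gives the centre pixel its literal distance-zero
    weight of 1; "max" gives it the maximum weight among its neighbours
    (the Buades convention).
    distance_weighting: "uniform" averages squared differences over the
    patch; "gaussian" weights them with a Gaussian kernel over the patch.
    """

    patch: int = 3
    search: int = 5
    h: float = 1.0
    self_weight_rule: str = "self"
    distance_weighting: str = "uniform"

    def __post_init__(self) -> None:
        for name, v in (("patch", self.patch), ("search", self.search)):
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be a positive odd integer")
        if self.patch > self.search:
            raise ValueError("patch size must not exceed the search window")
        if self.h <= 0:
            raise ValueError("filtering strength h must be positive")
        if self.self_weight_rule not in ("self", "max"):
            raise ValueError("self_weight_rule must be 'self' or 'max'")
        if self.distance_weighting not in ("uniform", "gaussian"):
            raise ValueError("distance_weighting must be 'uniform' or 'gaussian'")


def fwhm_to_sigma(fwhm_mm: float, voxel_mm: float) -> float:
    """Convert a FWHM in mm to a Gaussian sigma in voxel units:
    sigma = FWHM / (2 sqrt(2 ln 2) * voxel)."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    return fwhm_mm / (_FWHM_PER_SIGMA * voxel_mm)


def gaussian_post_filter(
    vol: PETVolume, params: GaussianFilterParams = GaussianFilterParams()
) -> PETVolume:
    """Separable Gaussian smoothing with unit-sum kernel and reflective
    boundaries; FWHM 0 returns the volume unchanged."""
    sigma = fwhm_to_sigma(params.fwhm_mm, vol.spacing)
    if sigma == 0:
        return vol.with_values(vol.values.copy(), meta=vol.meta + "+Gaussian")
    sigmas = (sigma, sigma, sigma) if params.axes == "3d" else (0.0, sigma, sigma)
    out = ndimage.gaussian_filter(vol.values, sigma=sigmas, mode="reflect")
    return vol.with_values(out, meta=vol.meta + "+Gaussian")


def estimate_background_sigma(vol: PETVolume, rois) -> float:
    """Pooled sample standard deviation (n-1) of all pixels in the union of
    the given background ROIs — the NLM filtering strength h."""
    rois = list(rois)
    if not rois:
        raise ValueError("at least one background ROI is required")
    pixels = np.concatenate([roi.extract(vol) for roi in rois])
    if pixels.size < 2:
        raise ValueError("background ROIs must contain at least 2 pixels")
    return float(np.std(pixels, ddof=1))


def _patch_kernel(params: NlmParams) -> np.ndarray:
    p = params.patch
    if params.distance_weighting == "uniform":
        k = np.full((p, p), 1.0 / (p * p))
    else:
        half = p // 2
        sig = max(half / 2.0, 0.5)
        y, x = np.mgrid[-half : half + 1, -half : half + 1]
        k = np.exp(-(y**2 + x**2) / (2 * sig**2))
        k /= k.sum()
    return k


def nlm_filter(vol: PETVolume, params: NlmParams) -> PETVolume:
    """Slice-wise 2D non-local means.

    Each output pixel is a convex combination of its search-window pixels
    with weights exp(-D^2/h^2), D^2 the patch-averaged squared difference
    between the centre patch and the neighbour patch; boundaries are padded
    reflectively.
    """
    out = np.empty_like(vol.values)
    for i in range(vol.n_slices):
        out[i] = _nlm_filter_slice(vol.values[i], params)
    return vol.with_values(out, meta=vol.meta + "+NLM")


def _nlm_filter_slice(img: np.ndarray, params: NlmParams) -> np.ndarray:
    h2 = params.h**2
    s_half = params.search // 2
    p_half = params.patch // 2
    kern = _patch_kernel(params)
    H, W = img.shape
    pad = s_half + p_half
    padded = np.pad(img, pad, mode="reflect")

    # centre patches: padded[pad-p_half : pad+p_half+H, ...] windowed
    centre = padded[s_half : s_half + H + 2 * p_half, s_half : s_half + W + 2 * p_half]

    num = np.zeros((H, W), dtype=np.float64)
    den = np.zeros((H, W), dtype=np.float64)
    max_other = np.zeros((H, W), dtype=np.float64)
    self_vals = img.astype(np.float64)

    for dy in range(-s_half, s_half + 1):
        for dx in range(-s_half, s_half + 1):
            if dy == 0 and dx == 0:
                continue
            shifted = padded[
                s_half + dy : s_half + dy + H + 2 * p_half,
                s_half + dx : s_half + dx + W + 2 * p_half,
            ]
            diff2 = (centre - shifted) ** 2
            # patch-kernel-weighted sum of squared differences around each pixel
            d2 = ndimage.correlate(diff2, kern, mode="constant")[
                p_half : p_half + H, p_half : p_half + W
            ]
            w = np.exp(-d2 / h2)
            vals = padded[pad + dy : pad + dy + H, pad + dx : pad + dx + W]
            num += w * vals
            den += w
            np.maximum(max_other, w, out=max_other)

    if params.self_weight_rule == "self":
        w_self = np.ones((H, W), dtype=np.float64)
    else:
        w_self = max_other
    num += w_self * self_vals
    den += w_self
    return num / den
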