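"""Quantitative evaluation: ROIs, SUV statistics, agreement and projections.

Implements the clinical evaluation protocol for denoised dbPET image sets:

* circular 8 mm background ROIs on fibroglandular tissue and 10x30-pixel
  rectangular ROIs near the FOV edge, five each, on slices at least five
  apart (placement is automated and seeded; clinically it is manual);
* SUVmean, SD and coefficient of variation CV = sigma / SUVmean x 100 (%)
  per ROI; SUVmax over a 3D volume of interest and SUVpeak (mean of a fixed
  10 mm diameter 2D-ROI centred at the maximum) per lesion;
* relative differences d = (SUVtgt - SUVref) / SUVref x 100 (%) and
  Bland-Altman agreement (bias = mean of d, limits = 1.96 x SD of d);
* paired t / Wilcoxon signed-rank comparisons with Bonferroni correction;
* maximum intensity projections with the standard 0-4 SUV display window.

Sample standard deviations (n-1) are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volume import PETVolume

__all__ = [
    "Roi",
    "RoiStats",
    "LesionMeasurement",
    "AgreementReport",
    "ComparisonResult",
    "place_background_rois",
    "place_edge_rois",
    "roi_stats",
    "measure_lesion",
    "relative_difference",
    "bland_altman",
    "paired_compare",
    "mip",
    "render_mip",
]


@dataclass(frozen=True)
class Roi:
    """A 2D region bound to one slice: a circle (centre + diameter in mm,
    pixels whose centres fall within the radius belong) or a pixel-aligned
    rectangle (origin + height x width in pixels)."""

    slice_index: int
    kind: str  # "circle" | "rectangle"
    center_rc: tuple[float, float] | None = None
    diameter_mm: float | None = None
    origin_rc: tuple[int, int] | None = None
    height_px: int | None = None
    width_px: int | None = None

    @staticmethod
    def circle(slice_index: int, center_rc, diameter_mm: float) -> "Roi":
        return Roi(slice_index=slice_index, kind="circle",
                   center_rc=tuple(center_rc), diameter_mm=diameter_mm)

    @staticmethod
    def rectangle(slice_index: int, origin_rc, height_px: int, width_px: int) -> "Roi":
        return Roi(slice_index=slice_index, kind="rectangle",
                   origin_rc=tuple(origin_rc), height_px=height_px,
                   width_px=width_px)

    def member_indices(self, shape_rc: tuple[int, int], voxel_mm: float):
        """(rows, cols) index arrays of member pixels; errors if the ROI is
        empty or leaves the grid."""
        nr, nc = shape_rc
        if self.kind == "circle":
            r0, c0 = self.center_rc
            rad_px = self.diameter_mm / 2.0 / voxel_mm
            rr, cc = np.mgrid[0:nr, 0:nc]
            inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad_px**2
            # reject if the circle's bounding box pokes outside the grid
            if (r0 - rad_px < -0.5 or r0 + rad_px > nr - 0.5
                    or c0 - rad_px < -0.5 or c0 + rad_px > nc - 0.5):
                raise ValueError("circular ROI extends outside the image grid")
            rows, cols = np.nonzero(inside)
        else:
            r0, c0 = self.origin_rc
            if r0 < 0 or c0 < 0 or r0 + self.height_px > nr or c0 + self.width_px > nc:
                raise ValueError("rectangular ROI extends outside the image grid")
            rr, cc = np.mgrid[r0:r0 + self.height_px, c0:c0 + self.width_px]
            rows, cols = rr.ravel(), cc.ravel()
        if rows.size == 0:
            raise ValueError("ROI contains no pixels")
        return rows, cols

    def extract(self, vol: PETVolume) -> np.ndarray:
        """Member pixel values from the bound slice, as a flat array."""
        rows, cols = self.member_indices(vol.shape[1:], vol.spacing)
        return vol.values[self.slice_index, rows, cols]


@dataclass(frozen=True)
class RoiStats:
    suv_mean: float
    sd: float
    cv: float | None  # percent; None when SUVmean is 0


@dataclass(frozen=True)
class LesionMeasurement:
    suv_max: float
    suv_peak: float
    max_location: tuple[int, int, int]


@dataclass
class AgreementReport:
    """Bland-Altman agreement of one target image set against the reference."""

    d_values: list
    bias: float = field(init=False)
    limits: float = field(init=False)

    def __post_init__(self) -> None:
        ds = np.asarray(self.d_values, dtype=np.float64)
        if ds.size < 2:
            raise ValueError("Bland-Altman analysis needs at least 2 differences")
        self.bias = float(np.mean(ds))
        self.limits = float(1.96 * np.std(ds, ddof=1))


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    raw_p: float
    adjusted_p: float
    significant: bool
    degenerate: bool = False


def roi_stats(vol: PETVolume, roi: Roi) -> RoiStats:
    """SUVmean, sample SD and CV (%) of one ROI."""
    pixels = roi.extract(vol)
    if pixels.size < 2:
        raise ValueError("ROI statistics need at least 2 pixels")
    mean = float(np.mean(pixels))
    sd = float(np.std(pixels, ddof=1))
    cv = None if mean == 0 else sd / mean * 100.0
    return RoiStats(suv_mean=mean, sd=sd, cv=cv)


def _disk_footprint(diameter_mm: float, voxel_mm: float) -> np.ndarray:
    rad_px = diameter_mm / 2.0 / voxel_mm
    n = int(math.floor(rad_px)) * 2 + 1
    half = n // 2
    rr, cc = np.mgrid[-half:half + 1, -half:half + 1]
    return rr**2 + cc**2 <= rad_px**2


def _select_slices(eligible: np.ndarray, n: int, gap: int,
                   rng: np.random.Generator, tries: int = 200) -> list[int]:
    """Pick n slice indices from ``eligible`` with pairwise distance >= gap.

    Random greedy with a deterministic ascending-greedy fallback; errors if
    even the fallback cannot satisfy the constraint.
    """
    eligible = np.asarray(sorted(set(int(s) for s in eligible)))
    if eligible.size == 0:
        raise ValueError("no eligible slices for ROI placement")

    def greedy(order):
        chosen: list[int] = []
        for s in order:
            if all(abs(s - c) >= gap for c in chosen):
                chosen.append(int(s))
                if len(chosen) == n:
                    return chosen
        return None

    for _ in range(tries):
        got = greedy(rng.permutation(eligible))
        if got is not None:
            return sorted(got)
    got = greedy(eligible)
    if got is None:
        raise ValueError(
            f"cannot place {n} ROIs on slices >= {gap} apart: only "
            f"{len(eligible)} eligible slices at indices {eligible.tolist()}")
    return sorted(got)


def place_background_rois(vol: PETVolume, gland_mask: np.ndarray, n: int = 5,
                          diameter_mm: float = 8.0, min_slice_gap: int = 5,
                          seed: int = 0, lesion_mask: np.ndarray | None = None,
                          ) -> list[Roi]:
    """Seeded automatic placement of circular background ROIs.

    Each ROI lies entirely within gland tissue (and outside any lesion), on
    ``n`` distinct slices whose pairwise index distance is at least
    ``min_slice_gap``.
    """
    if gland_mask.shape != vol.shape:
        raise ValueError("gland mask shape must match the volume")
    allowed = gland_mask.copy()
    if lesion_mask is not None:
        allowed &= ~lesion_mask
    footprint = _disk_footprint(diameter_mm, vol.spacing)
    rng = np.random.default_rng(seed)
    # centres whose full disk fits in the allowed tissue
    feasible = np.zeros_like(allowed)
    for z in range(vol.n_slices):
        if allowed[z].any():
            feasible[z] = ndimage.binary_erosion(allowed[z], structure=footprint)
    eligible = np.nonzero(feasible.any(axis=(1, 2)))[0]
    slices = _select_slices(eligible, n, min_slice_gap, rng)
    rois = []
    for z in slices:
        centres = np.argwhere(feasible[z])
        r, c = centres[rng.integers(len(centres))]
        rois.append(Roi.circle(z, (float(r), float(c)), diameter_mm))
    return rois


def place_edge_rois(vol: PETVolume, breast_mask: np.ndarray, n: int = 5,
                    rect_px: tuple[int, int] = (10, 30), edge_offset: int = 5,
                    min_slice_gap: int = 5, seed: int = 0,
                    edge_slice_fraction: float = 0.2) -> list[Roi]:
    """Seeded placement of rectangular ROIs in the noisy FOV-edge region.

    Rectangles are anchored with their near edge exactly ``edge_offset``
    pixels from the chest-wall (row 0) image edge, confined to tissue, and
    restricted to slices in the first/last ``edge_slice_fraction`` of the
    axial range, where detector sensitivity — and therefore noise — is worst.
    """
    if breast_mask.shape != vol.shape:
        raise ValueError("breast mask shape must match the volume")
    h, w = rect_px
    nz, nr, nc = vol.shape
    rng = np.random.default_rng(seed)
    n_edge = max(int(round(edge_slice_fraction * nz)), 1)
    edge_band = list(range(n_edge)) + list(range(nz - n_edge, nz))
    r0 = edge_offset
    eligible, origins = [], {}
    for z in sorted(set(edge_band)):
        cands = [c0 for c0 in range(0, nc - w + 1)
                 if breast_mask[z, r0:r0 + h, c0:c0 + w].all()]
        if cands:
            eligible.append(z)
            origins[z] = cands
    slices = _select_slices(eligible, n, min_slice_gap, rng)
    return [Roi.rectangle(z, (r0, origins[z][rng.integers(len(origins[z]))]), h, w)
            for z in slices]


def measure_lesion(vol: PETVolume, voi: np.ndarray,
                   peak_diameter_mm: float = 10.0) -> LesionMeasurement:
    """SUVmax over a 3D volume of interest and SUVpeak around it.

    SUVmax is the maximum over the VOI (ties broken toward the lowest
    (slice, row, col)); SUVpeak is the mean of a fixed-diameter circular
    2D-ROI centred at the maximum pixel on its slice.  A peak ROI that would
    leave the image grid is an error.
    """
    if voi.shape != vol.shape:
        raise ValueError("VOI mask shape must match the volume")
    if not voi.any():
        raise ValueError("VOI is empty")
    vals = vol.values[voi]
    suv_max = float(vals.max())
    coords = np.argwhere(voi)
    at_max = coords[vol.values[voi] == suv_max]
    # lexicographic lowest (slice, row, col)
    loc = tuple(int(v) for v in min(map(tuple, at_max)))
    peak_roi = Roi.circle(loc[0], (float(loc[1]), float(loc[2])), peak_diameter_mm)
    suv_peak = float(np.mean(peak_roi.extract(vol)))
    return LesionMeasurement(suv_max=suv_max, suv_peak=suv_peak, max_location=loc)


def relative_difference(suv_tgt: float, suv_ref: float) -> float:
    """d = (SUVtgt - SUVref) / SUVref x 100 (%)."""
    if suv_ref <= 0:
        raise ValueError("reference SUV must be positive")
    return (suv_tgt - suv_ref) / suv_ref * 100.0


def bland_altman(ds) -> tuple[float, float]:
    """(bias, limits) = (mean of d, 1.96 x sample SD of d)."""
    report = AgreementReport(d_values=list(ds))
    return report.bias, report.limits


def paired_compare(a, b, test: str = "t", n_comparisons: int = 1,
                   alpha: float = 0.05) -> ComparisonResult:
    """Two-sided paired comparison with Bonferroni correction.

    test: "t" (paired t-test) or "wilcoxon" (signed-rank).  All-zero paired
    differences are reported as non-significant with a degenerate flag.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    if test not in ("t", "wilcoxon"):
        raise ValueError("test must be 't' or 'wilcoxon'")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if np.all(a == b):
        return ComparisonResult(test=test, raw_p=1.0, adjusted_p=1.0,
                                significant=False, degenerate=True)
    if test == "t":
        raw = float(stats.ttest_rel(a, b).pvalue)
    else:
        raw = float(stats.wilcoxon(a, b).pvalue)
    adj = min(1.0, n_comparisons * raw)
    return ComparisonResult(test=test, raw_p=raw, adjusted_p=adj,
                            significant=adj < alpha)


_VIEW_AXES = {"craniocaudal": 0, "mediolateral": 2}


def mip(vol: PETVolume, view: str = "craniocaudal") -> np.ndarray:
    """Maximum intensity projection along the named view axis."""
    if view not in _VIEW_AXES:
        raise ValueError(f"view must be one of {sorted(_VIEW_AXES)}")
    return vol.values.max(axis=_VIEW_AXES[view])


def render_mip(projection: np.ndarray, suv_window: tuple[float, float] = (0.0, 4.0)
               ) -> np.ndarray:
    """Map a projection to inverse grayscale in the standard 0-4 SUV window
    (1 = no uptake, 0 = SUV >= window top)."""
    lo, hi = suv_window
    if hi <= lo:
        raise ValueError("invalid display window")
    clipped = np.clip(projection, lo, hi)
    return 1.0 - (clipped - lo) / (hi - lo)
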