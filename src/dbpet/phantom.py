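"""Synthetic breast phantom and paired low-count/full-count scan simulation.

Dedicated breast PET (dbPET) images a single prone breast inside a detector
ring.  The real scanner's sensitivity is maximal at the axial centre of the
field of view (FOV) and drops toward the axial edges, so short acquisitions
are noisy everywhere and noisiest near the edge slices.  This module emulates
exactly those two noise behaviours — variance scaling with acquisition
duration and elevated noise near the axial FOV edge — with a voxelwise
scaled-Poisson count model on top of a parametric breast activity map.  No
sinogram, reconstruction or scatter/attenuation physics is modelled.

The activity map is a half-ellipsoidal breast attached to the chest-wall
(row 0) edge of the in-plane grid, a smooth seeded fibroglandular/fat tissue
pattern, and spherical FDG-avid lesions of the focus / mass / non-mass kinds
used clinically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import ActivityVolume, PETVolume

__all__ = [
    "Lesion",
    "SensitivityModel",
    "PhantomSpec",
    "breast_mask",
    "generate_activity_map",
    "axial_sensitivity",
    "simulate_scan",
    "make_paired_dataset",
    "sample_lesions",
]


@dataclass(frozen=True)
class Lesion:
    """A spherical FDG-avid lesion with a uniform SUV plateau.

    kind: "focus" (small hot spot, diameter <= 10 mm), "mass" or "non_mass".
    center: (slice, row, col) voxel coordinate of the sphere centre.
    edge_blur_mm: optional Gaussian blur of the lesion edge; 0 keeps a hard
    plateau (no partial-volume modelling by default).
    """

    kind: str
    center: tuple[int, int, int]
    diameter_mm: float
    suv: float
    edge_blur_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("focus", "mass", "non_mass"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.kind == "focus" and self.diameter_mm > 10:
            raise ValueError("focus lesions must have diameter <= 10 mm")
        if self.suv <= 0:
            raise ValueError("lesion SUV must be positive")


@dataclass(frozen=True)
class SensitivityModel:
    """Relative axial detector sensitivity: 1 at the centre slice, ``edge_min``
    at the first/last slice, monotone in between.

    profile_shape: "cosine" (half-sine arch, default) or "linear" (tent).
    """

    edge_min: float = 0.3
    profile_shape: str = "cosine"

    def __post_init__(self) -> None:
        if not (0 < self.edge_min <= 1):
            raise ValueError("edge_min must lie in (0, 1]")
        if self.profile_shape not in ("cosine", "linear"):
            raise ValueError(f"unknown sensitivity profile {self.profile_shape!r}")


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic dbPET phantom acquisition.

    Grid defaults match the scanner protocol this package emulates: 236x132
    trans-axial matrix with 0.78 mm isotropic voxels, paired 3-minute
    (low-count, LC) and 7-minute (full-count, FC) acquisitions.  suv_gland
    defaults to the typical background fibroglandular SUVmean of 1.18.

    counts_per_suv_min calibrates expected Poisson counts per voxel:
    lambda = SUV x minutes x sensitivity x counts_per_suv_min.  The default
    15.0 puts the per-voxel CV of a 7-minute gland acquisition near 9%
    (1/sqrt(1.18 * 7 * 15) ~= 0.090), the noise scale of a clinical
    full-count reference image.

    breast_mask_params: half-ellipsoid semi-axes as fractions of the grid —
    ``extent_row`` (fraction of rows, from the chest wall at row 0),
    ``semi_col`` (fraction of half the columns), ``semi_z`` (fraction of half
    the slice count).

    noise_smoothing_mm: optional Gaussian smoothing of the simulated noise
    field, emulating the spatial correlation of reconstructed PET noise;
    0 (default) keeps voxel noise independent.
    """

    n_slices: int = 96
    slice_shape: tuple[int, int] = (236, 132)
    voxel_mm: float = 0.78
    breast_mask_params: dict = field(
        default_factory=lambda: {"extent_row": 0.75, "semi_col": 0.80, "semi_z": 0.90}
    )
    suv_fat: float = 0.40
    suv_gland: float = 1.18
    gland_fraction: float = 0.5
    gland_texture_sigma_mm: float = 3.0
    lesions: list[Lesion] = field(default_factory=list)
    sensitivity: SensitivityModel = field(default_factory=SensitivityModel)
    duration_lc_min: float = 3.0
    duration_fc_min: float = 7.0
    counts_per_suv_min: float = 15.0
    noise_smoothing_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.suv_fat < 0 or self.suv_gland < 0:
            raise ValueError("tissue SUVs must be non-negative")
        if self.suv_fat >= self.suv_gland:
            raise ValueError("suv_fat must be below suv_gland")
        if not (0 <= self.gland_fraction <= 1):
            raise ValueError("gland_fraction must lie in [0, 1]")
        if self.duration_lc_min >= self.duration_fc_min:
            raise ValueError("LC duration must be shorter than FC duration")
        if self.duration_lc_min <= 0:
            raise ValueError("durations must be positive")
        if self.counts_per_suv_min <= 0:
            raise ValueError("counts_per_suv_min must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, *self.slice_shape)

    def with_lesions(self, lesions: list[Lesion]) -> "PhantomSpec":
        return replace(self, lesions=list(lesions))


def breast_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean breast mask: a half-ellipsoid attached to the chest-wall
    (row 0) in-plane edge, centred axially.

    An ``extent_row`` of 0 (degenerate ellipsoid) yields an empty mask.
    """
    nz, nr, nc = spec.shape
    p = spec.breast_mask_params
    a_r = p["extent_row"] * nr
    a_c = p["semi_col"] * nc / 2.0
    a_z = p["semi_z"] * nz / 2.0
    if min(a_r, a_c, a_z) <= 0:
        return np.zeros(spec.shape, dtype=bool)
    z, r, c = np.ogrid[:nz, :nr, :nc]
    zc = (nz - 1) / 2.0
    cc = (nc - 1) / 2.0
    # row term measured from the chest wall (row 0); only rows < a_r inside
    d2 = (r / a_r) ** 2 + ((c - cc) / a_c) ** 2 + ((z - zc) / a_z) ** 2
    return d2 <= 1.0


def _ball(spec: PhantomSpec, center, diameter_mm: float) -> np.ndarray:
    nz, nr, nc = spec.shape
    z, r, c = np.ogrid[:nz, :nr, :nc]
    cz, cr, cc = center
    rad_vox = diameter_mm / 2.0 / spec.voxel_mm
    d2 = (z - cz) ** 2 + (r - cr) ** 2 + (c - cc) ** 2
    return d2 <= rad_vox**2


def _lesion_ball(spec: PhantomSpec, lesion: Lesion) -> np.ndarray:
    return _ball(spec, lesion.center, lesion.diameter_mm)


def generate_activity_map(spec: PhantomSpec, seed: int) -> ActivityVolume:
    """Build the noise-free SUV map for one phantom.

    Breast voxels carry ``suv_fat`` or ``suv_gland`` according to a seeded
    smooth random field thresholded so that ``gland_fraction`` of the breast
    is fibroglandular; lesion spheres carry their plateau SUV; air is 0.
    The same (spec, seed) always yields the identical map.
    """
    rng = np.random.default_rng(seed)
    mask = breast_mask(spec)
    values = np.zeros(spec.shape, dtype=np.float64)

    if mask.any():
        noise = rng.standard_normal(spec.shape)
        sigma_vox = spec.gland_texture_sigma_mm / spec.voxel_mm
        field_ = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
        inside = field_[mask]
        if spec.gland_fraction >= 1.0:
            gland = mask
        elif spec.gland_fraction <= 0.0:
            gland = np.zeros_like(mask)
        else:
            thr = np.quantile(inside, 1.0 - spec.gland_fraction)
            gland = mask & (field_ >= thr)
        values[mask] = spec.suv_fat
        values[gland] = spec.suv_gland

    for lesion in spec.lesions:
        ball = _lesion_ball(spec, lesion)
        if not ball.any():
            raise ValueError(f"lesion at {lesion.center} covers no voxel")
        if not mask[ball].all():
            raise ValueError(
                f"lesion at {lesion.center} (diameter {lesion.diameter_mm} mm) "
                "extends outside the breast mask"
            )
        if lesion.suv <= spec.suv_gland:
            raise ValueError("lesion SUV must exceed the gland background SUV")
        if lesion.edge_blur_mm > 0:
            prof = ball.astype(np.float64)
            prof = ndimage.gaussian_filter(
                prof, sigma=lesion.edge_blur_mm / spec.voxel_mm, mode="constant"
            )
            # blend: keep plateau at full suv where profile ~ 1
            values = np.maximum(values, lesion.suv * prof)
        else:
            values[ball] = lesion.suv

    return ActivityVolume(values=values, spacing=spec.voxel_mm)


def axial_sensitivity(z, n_slices: int, model: SensitivityModel):
    """Relative sensitivity of slice ``z`` in an ``n_slices`` stack.

    1.0 at the axial centre, ``model.edge_min`` at either end, symmetric and
    monotone from edge to centre.  Accepts scalar or array ``z``.
    """
    z_arr = np.asarray(z)
    if np.any(z_arr < 0) or np.any(z_arr >= n_slices):
        raise ValueError(f"slice index {z} outside [0, {n_slices})")
    if n_slices == 1:
        out = np.ones_like(z_arr, dtype=np.float64)
        return float(out) if np.isscalar(z) else out
    t = z_arr / (n_slices - 1)  # 0 at first slice, 1 at last
    if model.profile_shape == "cosine":
        base = np.sin(np.pi * t)
    else:  # linear tent
        base = 1.0 - np.abs(2.0 * t - 1.0)
    out = model.edge_min + (1.0 - model.edge_min) * base
    return float(out) if np.isscalar(z) else out


def simulate_scan(
    activity: ActivityVolume, duration_min: float, spec: PhantomSpec, seed: int
) -> PETVolume:
    """Simulate one acquisition of ``duration_min`` minutes from an activity map.

    Per voxel the expected count is
    ``lambda = activity * duration * sensitivity(z) * counts_per_suv_min``;
    a Poisson draw is rescaled back to SUV, so the simulated volume is
    unbiased for the activity and its voxel variance is
    ``activity / (duration * sensitivity(z) * counts_per_suv_min)`` —
    noise shrinks with longer scans and grows toward the axial FOV edges.
    """
    if duration_min <= 0:
        raise ValueError("acquisition duration must be positive")
    rng = np.random.default_rng(seed)
    nz = activity.shape[0]
    sens = axial_sensitivity(np.arange(nz), nz, spec.sensitivity)
    scale = duration_min * spec.counts_per_suv_min * sens[:, None, None]
    lam = activity.values * scale
    counts = rng.poisson(lam).astype(np.float64)
    values = counts / scale
    if spec.noise_smoothing_mm > 0:
        resid = values - activity.values
        resid = ndimage.gaussian_filter(
            resid, sigma=spec.noise_smoothing_mm / spec.voxel_mm, mode="reflect"
        )
        values = activity.values + resid
    tag = "LC" if duration_min == spec.duration_lc_min else (
        "FC" if duration_min == spec.duration_fc_min else f"{duration_min:g}min"
    )
    return PETVolume(
        values=values, spacing=activity.spacing, duration_min=duration_min, meta=tag
    )


def make_paired_dataset(
    spec: PhantomSpec, n_phantoms: int, seed: int
) -> list[tuple[PETVolume, PETVolume, ActivityVolume, list[Lesion]]]:
    """Simulate ``n_phantoms`` paired LC/FC acquisitions.

    Each phantom gets its own seeded gland texture; its LC and FC volumes are
    drawn from the same activity map with independent Poisson noise, standing
    in for reconstructing two durations from one list-mode acquisition.
    Returns ``(lc, fc, activity, lesions)`` tuples; fully determined by
    (spec, seed).
    """
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_phantoms):
        s_act, s_lc, s_fc = child.generate_state(3) % (2**31)
        activity = generate_activity_map(spec, int(s_act))
        lc = simulate_scan(activity, spec.duration_lc_min, spec, int(s_lc))
        fc = simulate_scan(activity, spec.duration_fc_min, spec, int(s_fc))
        out.append((lc, fc, activity, list(spec.lesions)))
    return out


# SUVmax statistics of the two lesion kinds seen clinically in the breast:
# focus lesions are small and moderately avid, mass lesions larger and hotter.
_LESION_STATS = {
    "focus": {"suv_mean": 2.84, "suv_sd": 0.85, "diam_mm": (4.0, 9.0)},
    "mass": {"suv_mean": 12.61, "suv_sd": 8.05, "diam_mm": (8.0, 16.0)},
}
_FOCUS_PROB = 6 / 22  # observed focus / mass mix in the emulated cohort


def sample_lesions(
    spec: PhantomSpec,
    rng: np.random.Generator,
    n_lesions: int,
    max_tries: int = 200,
    peak_margin_mm: float = 5.0,
) -> list[Lesion]:
    """Draw random lesions inside the breast mask of ``spec``.

    Kind and SUV follow the clinical focus/mass mix and SUVmax distributions;
    positions are rejection-sampled so every lesion sphere fits inside the
    mask and so a SUVpeak measurement circle of radius ``peak_margin_mm``
    around any voxel of the lesion stays inside the in-plane grid.  Raises if
    a placement cannot be found.
    """
    mask = breast_mask(spec)
    if not mask.any():
        raise ValueError("cannot place lesions: empty breast mask")
    # voxelwise clearance to the mask boundary: a sphere of radius r fits at
    # a centre iff clearance > r
    clearance = ndimage.distance_transform_edt(mask)
    nr, nc = spec.slice_shape
    lesions: list[Lesion] = []

    def eligible_centres(diam_mm: float) -> np.ndarray:
        radius_vox = diam_mm / 2.0 / spec.voxel_mm
        # in-plane margin keeping the peak circle of any lesion voxel inside
        # the grid (the hottest voxel can sit anywhere on the ball)
        margin = int(math.ceil(
            (peak_margin_mm + diam_mm / 2.0) / spec.voxel_mm)) + 2
        ok = clearance > radius_vox + 0.5
        ok[:, :margin, :] = ok[:, nr - margin:, :] = False
        ok[:, :, :margin] = ok[:, :, nc - margin:] = False
        return np.argwhere(ok)

    for _ in range(n_lesions):
        kind = "focus" if rng.random() < _FOCUS_PROB else "mass"
        stats = _LESION_STATS[kind]
        lo, hi = stats["diam_mm"]
        # clamp the upper diameter to what this grid and mask can host
        while hi > lo and len(eligible_centres(hi)) == 0:
            hi = max(lo, hi - 1.0)
        if len(eligible_centres(lo)) == 0:
            raise ValueError(
                f"cannot place a {kind} lesion of {lo:g} mm: no centre has "
                "enough clearance inside the breast mask")
        for attempt in range(max_tries):
            suv = rng.normal(stats["suv_mean"], stats["suv_sd"])
            suv = max(suv, spec.suv_gland + 0.5)
            if kind == "focus":
                suv = min(suv, 10.0)
            diam = rng.uniform(lo, hi)
            cand = eligible_centres(diam)
            if len(cand) == 0:
                continue
            center = tuple(int(v) for v in cand[rng.integers(len(cand))])
            lesion = Lesion(kind=kind, center=center, diameter_mm=diam, suv=float(suv))
            # keep lesions well separated (>= ~3 voxels surface-to-surface)
            # so their measurement volumes of interest stay disjoint
            pad_mm = 6.0 * spec.voxel_mm
            grown = _ball(spec, center, diam + pad_mm)
            if all(not (grown & _lesion_ball(spec, other)).any()
                   for other in lesions):
                lesions.append(lesion)
                break
        else:
            raise ValueError(
                f"could not place a {kind} lesion inside the mask "
                f"after {max_tries} tries"
            )
    return lesions
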