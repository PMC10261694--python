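"""Core volume containers.

All volumes are 3D numpy arrays indexed ``(slice, row, col)``: axis 0 is the
axial (slice) direction, each slice is a trans-axial ``rows x cols`` image.
Intensities are in SUV (standardized uptake value) units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ActivityVolume", "PETVolume"]


@dataclass
class ActivityVolume:
    """Noise-free SUV map: the ground truth a scan is simulated from.

    Values are zero outside the breast (air) and non-negative everywhere.
    """

    values: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("activity values must be a 3D array (slice, row, col)")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class PETVolume:
    """A (simulated) PET acquisition or a processed image set derived from one.

    ``meta`` carries the provenance tag of the image set, e.g. ``"LC"``,
    ``"FC"``, ``"LC+DL"``, ``"LC+Gaussian"``, ``"LC+NLM"``, ``"FC+Gaussian"``.
    """

    values: np.ndarray
    spacing: float
    duration_min: float
    meta: str = field(default="")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("PET values must be a 3D array (slice, row, col)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PET values must be finite")
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.duration_min <= 0:
            raise ValueError("acquisition duration must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, meta: str | None = None) -> "PETVolume":
        """Copy of this volume with new voxel values (and optionally a new tag)."""
        return PETVolume(
            values=values,
            spacing=self.spacing,
            duration_min=self.duration_min,
            meta=self.meta if meta is None else meta,
        )
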