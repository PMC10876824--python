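"""Shared in-memory containers for dynamic ¹⁷O-MRI analysis.

All images live on a single rectangular voxel grid; no resampling is ever
performed — grids must match exactly (registration is upstream of this
package). Frames of a dynamic series are indexed 0-based and frame ``i``
represents the bin-center time ``(i + 0.5) * frame_min`` minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "TimeSeries4D",
    "MaskSet",
    "SignalCurve",
    "apply_psf",
    "fwhm_to_sigma",
    "GridMismatchError",
]

#: conversion factor between Gaussian FWHM and standard deviation
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: tissue-class and ROI label codes used in label volumes
TISSUE_CODES = {"GM": 1, "WM": 2, "CSF": 3}
ROI_CODES = {"S_left": 11, "C_right": 12, "N_left": 13, "N_right": 14}
LABEL_CODES = {**TISSUE_CODES, **ROI_CODES}

TISSUE_NAMES = tuple(TISSUE_CODES)
ROI_NAMES = tuple(ROI_CODES)


class GridMismatchError(ValueError):
    """Raised when two images do not share the same grid (shape or voxel size)."""


def _check_triple(name: str, value: Sequence[float]) -> Tuple[float, float, float]:
    triple = tuple(float(v) for v in value)
    if len(triple) != 3 or any(v <= 0 for v in triple):
        raise ValueError(f"{name} must be a positive triple, got {value!r}")
    return triple


def fwhm_to_sigma(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given full width at half maximum."""
    return float(fwhm) / FWHM_PER_SIGMA


def apply_psf(
    data: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: Sequence[float],
) -> np.ndarray:
    """Blur a 3D array with the isotropic Gaussian point-spread function.

    This single primitive defines the PSF model everywhere: the phantom uses
    it to emulate the image-domain broadening of the Hamming-filtered radial
    acquisition, and the geometric-transfer-matrix construction uses the very
    same operator on mask indicators. Outside the field of view the signal is
    taken to be zero (``mode='constant'``), matching a zero-concentration
    background compartment.
    """
    if fwhm_mm < 0:
        raise ValueError(f"psf_fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return np.asarray(data, dtype=float).copy()
    sigmas = [fwhm_to_sigma(fwhm_mm) / v for v in _check_triple("voxel_size_mm", voxel_size_mm)]
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=sigmas, mode="constant", cval=0.0)


@dataclass(frozen=True)
class Volume:
    """A 3D scalar lattice with voxel geometry (sizes in mm)."""

    data: np.ndarray
    voxel_size_mm: Tuple[float, float, float] = (7.5, 7.5, 7.5)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {arr.shape}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size_mm", _check_triple("voxel_size_mm", self.voxel_size_mm))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume | TimeSeries4D | MaskSet") -> bool:
        return self.shape == other.shape_3d and np.allclose(self.voxel_size_mm, other.voxel_size_mm)

    @property
    def shape_3d(self) -> Tuple[int, int, int]:
        return self.shape


@dataclass(frozen=True)
class TimeSeries4D:
    """A dynamic image series: frames stacked along the last axis.

    ``t_a_min`` marks the start of gas inhalation and ``t_b_min`` the switch
    back to room air; both are in minutes from acquisition start.
    """

    data: np.ndarray  # (nx, ny, nz, n_frames)
    voxel_size_mm: Tuple[float, float, float] = (7.5, 7.5, 7.5)
    frame_min: float = 1.0
    t_a_min: Optional[float] = None
    t_b_min: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 4:
            raise ValueError(f"TimeSeries4D data must be 4D, got shape {arr.shape}")
        if self.frame_min <= 0:
            raise ValueError("frame_min must be positive")
        if self.t_a_min is not None and self.t_b_min is not None and not self.t_a_min < self.t_b_min:
            raise ValueError("t_a_min must precede t_b_min")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size_mm", _check_triple("voxel_size_mm", self.voxel_size_mm))

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape_3d(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def times_min(self) -> np.ndarray:
        """Bin-center frame times in minutes."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_min

    def frame(self, i: int) -> Volume:
        return Volume(self.data[..., i], self.voxel_size_mm)

    def with_data(self, data: np.ndarray) -> "TimeSeries4D":
        return replace(self, data=data)


@dataclass
class MaskSet:
    """Named, co-registered binary masks (tissue classes and/or ROIs)."""

    masks: Dict[str, np.ndarray]
    voxel_size_mm: Tuple[float, float, float] = (7.5, 7.5, 7.5)

    def __post_init__(self) -> None:
        self.voxel_size_mm = _check_triple("voxel_size_mm", self.voxel_size_mm)
        shapes = {np.asarray(m).shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GridMismatchError(f"masks live on different grids: {sorted(shapes)}")
        self.masks = {k: np.asarray(m, dtype=bool) for k, m in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def names(self) -> Tuple[str, ...]:
        return tuple(self.masks)

    @property
    def shape_3d(self) -> Tuple[int, int, int]:
        return next(iter(self.masks.values())).shape  # type: ignore[return-value]

    def subset(self, names: Sequence[str]) -> "MaskSet":
        return MaskSet({n: self.masks[n] for n in names}, self.voxel_size_mm)


@dataclass
class SignalCurve:
    """Per-frame scalar values for one region or compartment."""

    times: np.ndarray  # minutes, strictly increasing
    values: np.ndarray
    t_a: Optional[float] = None
    t_b: Optional[float] = None
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1D array")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.t_a is not None and self.t_b is not None and not self.t_a < self.t_b:
            raise ValueError("t_a must precede t_b")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def frame_min(self) -> float:
        """Frame spacing inferred from the time axis (single-frame curves -> 1)."""
        if len(self) < 2:
            return 1.0
        return float(np.median(np.diff(self.times)))

    def replace_values(self, values: np.ndarray, units: Optional[str] = None) -> "SignalCurve":
        return SignalCurve(
            self.times.copy(), np.asarray(values, dtype=float),
            t_a=self.t_a, t_b=self.t_b, label=self.label,
            units=self.units if units is None else units,
        )


def check_same_grid(a, b, what: str = "images") -> None:
    """Reject grid mismatches loudly; silent resampling is never performed."""
    if a.shape_3d != b.shape_3d:
        raise GridMismatchError(f"{what}: shape mismatch {a.shape_3d} vs {b.shape_3d}")
    if not np.allclose(a.voxel_size_mm, b.voxel_size_mm):
        raise GridMismatchError(
            f"{what}: voxel size mismatch {a.voxel_size_mm} vs {b.voxel_size_mm}"
        )
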