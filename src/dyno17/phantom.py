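"""Digital phantom for the three-phase ¹⁷O inhalation experiment.

The phantom stands in for the (unshareable) scanner data: a brain-like
ellipsoid partitioned into CSF (outer shell + central ventricle), a GM
cortical shell and a WM core, split into left/right hemispheres with
mirror-symmetric stimulated (S_left) and control (C_right) cortical
patches. Each tissue×ROI region follows its own kinetic curve; the
rendered 4D series is blurred with the acquisition PSF, multiplied by a
smooth coil sensitivity field, and given per-frame Gaussian noise — the
three image-domain effects of the real acquisition that the downstream
analysis has to undo or tolerate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from . import io as d17io
from .core import (
    MaskSet,
    ROI_NAMES,
    SignalCurve,
    TISSUE_NAMES,
    TimeSeries4D,
    Volume,
    apply_psf,
)
from .curves import max_around_tb, normalize_baseline
from .kinetics import ATParams, at_forward

__all__ = [
    "PhantomSpec",
    "TruthRecord",
    "default_tissue_params",
    "calibrate_cmro2",
    "build_label_volume",
    "render_timeseries",
    "generate_dataset",
    "region_name",
]

#: minimum voxel count for every named mask; smaller regions cannot
#: support the regional statistics the analysis computes
MIN_REGION_VOXELS = 8

#: noiseless relative maxima the default tissue kinetics are calibrated to
#: (grey matter matches the ~1.35 relative maximum of cortical ROIs; white
#: matter and CSF rise less, reflecting their lower oxidative metabolism)
DEFAULT_REL_MAX = {"GM": 1.35, "WM": 1.20, "CSF": 1.05}

#: frozen washout/gain/baseline parameters per tissue class; cmro2 is
#: calibrated numerically against DEFAULT_REL_MAX (see default_tissue_params)
_TISSUE_BASE = {
    "GM": dict(k_l=0.12, k_g=0.020, c0=11.7),
    "WM": dict(k_l=0.10, k_g=0.010, c0=10.5),
    "CSF": dict(k_l=0.08, k_g=0.004, c0=13.0),
}


def region_name(tissue: str, roi: str) -> str:
    """Canonical name of a tissue×ROI intersection region, e.g. 'GM_S_left'."""
    return f"{tissue}_{roi}"


def calibrate_cmro2(
    template: ATParams,
    target_rel_max: float,
    times: np.ndarray,
    window: int = 5,
    n_baseline: int = 5,
) -> float:
    """Production rate that makes the noiseless relative maximum hit a target.

    The model is linear in cmro2 for fixed rates, so the baseline-normalised
    window mean around t_b is an affine function of cmro2; two forward
    evaluations determine it exactly.
    """
    def rel_max(cmro2: float) -> float:
        curve = at_forward(template.replace(cmro2=cmro2), times)
        return max_around_tb(normalize_baseline(curve, n_baseline), window)

    m0 = rel_max(0.0)
    m1 = rel_max(1.0)
    if m1 <= m0:
        raise ValueError("relative maximum does not respond to cmro2; check timing")
    cmro2 = (target_rel_max - m0) / (m1 - m0)
    if cmro2 < 0:
        raise ValueError(
            f"target {target_rel_max} already exceeded by the gain term alone ({m0:.4f})"
        )
    return float(cmro2)


def default_tissue_params(
    t_a: float = 10.0,
    t_b: float = 21.0,
    n_frames: int = 40,
    frame_min: float = 1.0,
) -> Dict[str, ATParams]:
    """Per-tissue kinetic parameters calibrated to the default relative maxima."""
    times = (np.arange(n_frames) + 0.5) * frame_min
    out = {}
    for tissue, base in _TISSUE_BASE.items():
        template = ATParams(cmro2=0.0, alpha=0.70, t_a=t_a, t_b=t_b, **base)
        cmro2 = calibrate_cmro2(template, DEFAULT_REL_MAX[tissue], times)
        out[tissue] = template.replace(cmro2=cmro2)
    return out


@dataclass
class PhantomSpec:
    """Full description of one synthetic inhalation-experiment dataset.

    Defaults reproduce the study protocol: (7.5 mm)³ nominal resolution,
    40 one-minute frames, 10 min of room-air baseline, ~11 min of gas
    inhalation ending at t_b = 21 min, 10% baseline noise in small ROIs,
    and a PSF FWHM of 1.5× the voxel size standing in for the broadening
    of the Hamming-filtered radial reconstruction.
    """

    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: Tuple[float, float, float] = (7.5, 7.5, 7.5)
    n_frames: int = 40
    frame_min: float = 1.0
    t_a_min: float = 10.0
    t_b_min: float = 21.0
    tissue_params: Optional[Dict[str, ATParams]] = None
    stim_factor: float = 1.0
    psf_fwhm_mm: Optional[float] = None
    bias_amplitude: float = 0.15
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.grid_shape) != 3 or any(v < 1 for v in self.grid_shape):
            raise ValueError("grid_shape must be a positive integer triple")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if self.n_frames < 1 or self.frame_min <= 0:
            raise ValueError("n_frames and frame_min must be positive")
        if not 0 <= self.t_a_min < self.t_b_min < self.n_frames * self.frame_min:
            raise ValueError("need 0 <= t_a < t_b < total acquisition time")
        if self.stim_factor < 0 or self.noise_cv < 0:
            raise ValueError("stim_factor and noise_cv must be non-negative")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if self.psf_fwhm_mm is None:
            self.psf_fwhm_mm = 1.5 * self.voxel_size_mm[0]
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")
        if self.tissue_params is None:
            self.tissue_params = default_tissue_params(
                self.t_a_min, self.t_b_min, self.n_frames, self.frame_min
            )
        missing = set(TISSUE_NAMES) - set(self.tissue_params)
        if missing:
            raise ValueError(f"tissue_params missing entries for {sorted(missing)}")

    @property
    def times_min(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) * self.frame_min

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissue_params"] = {k: dataclasses.asdict(v) for k, v in self.tissue_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        tp = d.get("tissue_params")
        if tp is not None:
            d["tissue_params"] = {k: ATParams(**v) for k, v in tp.items()}
        return cls(**d)


@dataclass
class TruthRecord:
    """Noiseless ground truth of a rendered phantom dataset."""

    region_curves: Dict[str, SignalCurve]
    region_params: Dict[str, ATParams]
    sensitivity: Volume
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "regions": {
                name: {
                    "params": dataclasses.asdict(self.region_params[name]),
                    "times": self.region_curves[name].times.tolist(),
                    "values": self.region_curves[name].values.tolist(),
                }
                for name in self.region_curves
            },
        }


def _ellipsoid_rho(shape: Tuple[int, int, int], semi_axes: Tuple[float, float, float]) -> np.ndarray:
    """Normalised elliptic radius per voxel, mirror-symmetric about mid-sagittal x."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    rho2 = np.zeros(shape)
    for g, n, a in zip(grids, shape, semi_axes):
        rho2 += ((g - (n - 1) / 2.0) / a) ** 2
    return np.sqrt(rho2)


def build_label_volume(spec: PhantomSpec) -> Tuple[Volume, MaskSet]:
    """Construct the tissue partition and ROI partition of the phantom brain.

    Returns the tissue label volume (codes 1=GM, 2=WM, 3=CSF) and a
    MaskSet holding the three tissue masks plus the four ROI masks. The
    tissue masks are mutually exclusive and cover the brain; S_left∪N_left
    and C_right∪N_right partition the left and right hemisphere. S_left
    and C_right are mirror images of each other, so their voxel counts are
    identical by construction.
    """
    nx, ny, nz = spec.grid_shape
    axes = (0.44 * nx, 0.44 * ny, 0.42 * nz)
    rho = _ellipsoid_rho(spec.grid_shape, axes)
    brain = rho <= 1.0

    vent = _ellipsoid_rho(spec.grid_shape, (0.12 * nx, 0.16 * ny, 0.10 * nz)) <= 1.0
    csf = ((rho > 0.88) & brain) | (vent & brain)
    gm = (rho > 0.70) & (rho <= 0.88)
    wm = (rho <= 0.70) & ~vent

    xs = np.arange(nx)[:, None, None]
    left = np.broadcast_to(xs <= (nx - 1) / 2.0, spec.grid_shape) & brain
    right = brain & ~left

    # mirror-symmetric posterior-lateral cortical patches
    cx, cy, cz = ((n - 1) / 2.0 for n in spec.grid_shape)
    p_left = np.array([cx - 0.55 * axes[0], cy + 0.55 * axes[1], cz + 0.15 * axes[2]])
    radius = 0.42 * axes[0]
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in spec.grid_shape], indexing="ij")
    dist_l = np.sqrt(sum((g - p) ** 2 for g, p in zip(grids, p_left)))
    ball_l = dist_l <= radius
    ball_r = ball_l[::-1, :, :]  # exact mirror about the mid-sagittal plane

    s_left = left & ball_l
    c_right = right & ball_r
    n_left = left & ~s_left
    n_right = right & ~c_right

    masks = {
        "GM": gm, "WM": wm, "CSF": csf,
        "S_left": s_left, "C_right": c_right, "N_left": n_left, "N_right": n_right,
    }
    for name, m in masks.items():
        if m.sum() < MIN_REGION_VOXELS:
            raise ValueError(
                f"grid {spec.grid_shape} too small: region {name!r} has "
                f"{int(m.sum())} voxels (< {MIN_REGION_VOXELS})"
            )
    for tissue in TISSUE_NAMES:
        for roi in ("S_left", "C_right"):
            if not (masks[tissue] & masks[roi]).any():
                raise ValueError(f"grid too small: {region_name(tissue, roi)} is empty")

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[gm], labels[wm], labels[csf] = 1, 2, 3
    return Volume(labels, spec.voxel_size_mm), MaskSet(masks, spec.voxel_size_mm)


def _sensitivity_field(spec: PhantomSpec, brain: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative coil profile, 1 + amplitude · (normalised polynomial).

    The polynomial uses only terms even in the left-right coordinate, making
    the field mirror-symmetric about the mid-sagittal plane (birdcage head
    coils are approximately symmetric in that sense); it is zero-mean over
    the brain and scaled so its extreme deviation equals the amplitude.
    """
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    grids = np.meshgrid(
        *[(np.arange(n, dtype=float) - (n - 1) / 2.0) / max(n / 2.0, 1.0) for n in spec.grid_shape],
        indexing="ij",
    )
    x, y, z = grids
    terms = [x**2, y, z, y * z, y**2, z**2, x**2 * y, x**2 * z]
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
    q = sum(c * t for c, t in zip(coeffs, terms))
    q = q - q[brain].mean()
    peak = np.abs(q[brain]).max()
    if peak == 0:  # pragma: no cover - measure-zero coefficient draw
        return np.ones(spec.grid_shape)
    return 1.0 + spec.bias_amplitude * q / peak


def render_timeseries(
    labels: Volume,
    masks: MaskSet,
    spec: PhantomSpec,
) -> Tuple[TimeSeries4D, TruthRecord]:
    """Render the noisy 4D series and its ground-truth record.

    Each voxel is painted with its region's kinetic curve (cmro2 scaled by
    ``stim_factor`` inside S_left), each frame is blurred with the
    isotropic Gaussian PSF, multiplied by the fixed sensitivity field, and
    finally independent zero-mean Gaussian noise with standard deviation
    ``noise_cv × (mean noiseless brain baseline value)`` is added.
    Everything is deterministic given ``spec.seed``.
    """
    if labels.shape != masks.shape_3d:
        raise ValueError("labels and masks must share one grid")
    times = spec.times_min
    rng = np.random.default_rng(spec.seed)

    region_curves: Dict[str, SignalCurve] = {}
    region_params: Dict[str, ATParams] = {}
    truth = np.zeros(spec.grid_shape + (spec.n_frames,))
    brain = np.zeros(spec.grid_shape, dtype=bool)
    for tissue in TISSUE_NAMES:
        for roi in ROI_NAMES:
            sel = masks[tissue] & masks[roi]
            name = region_name(tissue, roi)
            params = spec.tissue_params[tissue]
            if roi == "S_left":
                params = params.replace(cmro2=params.cmro2 * spec.stim_factor)
            curve = at_forward(params, times)
            curve.label = name
            region_curves[name] = curve
            region_params[name] = params
            if sel.any():
                truth[sel, :] = curve.values
                brain |= sel

    sens = _sensitivity_field(spec, brain, rng)

    data = np.empty_like(truth)
    for i in range(spec.n_frames):
        data[..., i] = apply_psf(truth[..., i], spec.psf_fwhm_mm, spec.voxel_size_mm) * sens

    if spec.noise_cv > 0:
        baseline_mean = float(truth[brain, 0].mean())
        sd = spec.noise_cv * baseline_mean
        data = data + rng.normal(0.0, sd, size=data.shape)

    series = TimeSeries4D(data, spec.voxel_size_mm, spec.frame_min,
                          t_a_min=spec.t_a_min, t_b_min=spec.t_b_min)
    record = TruthRecord(region_curves=region_curves, region_params=region_params,
                         sensitivity=Volume(sens, spec.voxel_size_mm), seed=spec.seed)
    return series, record


def generate_dataset(spec: PhantomSpec, out_dir: "str | Path") -> Dict[str, Path]:
    """Write a complete synthetic dataset to disk.

    Produces the 4D series, tissue and ROI label volumes, the realized
    sensitivity map (all NIfTI-1), the ground-truth record and a spec echo
    (JSON). Re-running with the same spec and seed reproduces identical
    voxel arrays.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tissue_labels, masks = build_label_volume(spec)
    series, record = render_timeseries(tissue_labels, masks, spec)

    roi_labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for roi, code in d17io.ROI_CODES.items():
        roi_labels[masks[roi]] = code

    paths = {
        "series": out / "series.nii.gz",
        "tissue_labels": out / "tissue_labels.nii.gz",
        "roi_labels": out / "roi_labels.nii.gz",
        "sensitivity": out / "sensitivity.nii.gz",
        "truth": out / "truth.json",
        "spec": out / "spec.json",
    }
    d17io.write_series(series, paths["series"])
    d17io.write_volume(tissue_labels, paths["tissue_labels"])
    d17io.write_volume(Volume(roi_labels, spec.voxel_size_mm), paths["roi_labels"])
    d17io.write_volume(record.sensitivity, paths["sensitivity"])
    paths["truth"].write_text(json.dumps(record.to_dict(), indent=1))
    paths["spec"].write_text(json.dumps(spec.to_dict(), indent=1))
    return paths
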