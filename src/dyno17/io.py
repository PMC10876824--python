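"""NIfTI, CSV and JSON file formats.

NIfTI-1 carries all image data; dynamic series store time along the 4th
dimension with the frame duration (minutes) in the header time step. Label
volumes use the integer codes 1=GM, 2=WM, 3=CSF for tissue classes and
11=S_left, 12=C_right, 13=N_left, 14=N_right for ROIs. Curves travel as
CSV with columns ``time_min,value,phase``.

Grids are never resampled: a shape or voxel-size mismatch between a series
and its masks is an error, since registration happens upstream.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np

from .core import (
    GridMismatchError,
    LABEL_CODES,
    MaskSet,
    ROI_CODES,
    SignalCurve,
    TISSUE_CODES,
    TimeSeries4D,
    Volume,
)

__all__ = [
    "read_volume", "write_volume",
    "read_series", "write_series",
    "read_maskset", "labels_to_maskset",
    "read_curve", "write_curve",
    "ROI_CODES", "TISSUE_CODES", "LABEL_CODES",
]

PHASES = ("baseline", "inhalation", "decay")


def _affine(voxel_size_mm: Tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def _voxel_size(img: nib.Nifti1Image) -> Tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def write_volume(volume: Volume, path: "str | Path") -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data), _affine(volume.voxel_size_mm))
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, path)
    return path


def read_volume(path: "str | Path") -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return Volume(data, _voxel_size(img))


def write_series(series: TimeSeries4D, path: "str | Path") -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(series.data), _affine(series.voxel_size_mm))
    img.header.set_zooms(series.voxel_size_mm + (series.frame_min,))
    nib.save(img, path)
    return path


def read_series(
    path: "str | Path",
    t_a_min: Optional[float] = None,
    t_b_min: Optional[float] = None,
    frame_min: Optional[float] = None,
) -> TimeSeries4D:
    """Load a 4D series; frame spacing comes from the header unless given."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    zooms = img.header.get_zooms()
    if frame_min is None:
        frame_min = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return TimeSeries4D(data, _voxel_size(img), frame_min,
                        t_a_min=t_a_min, t_b_min=t_b_min)


def labels_to_maskset(tissue: Volume, roi: Optional[Volume] = None) -> MaskSet:
    """Expand label volumes into named binary masks.

    The tissue volume must use codes {1: GM, 2: WM, 3: CSF}; the optional
    ROI volume uses {11: S_left, 12: C_right, 13: N_left, 14: N_right}.
    """
    masks: Dict[str, np.ndarray] = {}
    tdata = np.asarray(tissue.data)
    for name, code in TISSUE_CODES.items():
        masks[name] = tdata == code
    if roi is not None:
        if tissue.shape != roi.shape or not np.allclose(tissue.voxel_size_mm, roi.voxel_size_mm):
            raise GridMismatchError("tissue and ROI label volumes live on different grids")
        rdata = np.asarray(roi.data)
        for name, code in ROI_CODES.items():
            masks[name] = rdata == code
    return MaskSet(masks, tissue.voxel_size_mm)


def read_maskset(tissue_path: "str | Path", roi_path: "str | Path | None" = None) -> MaskSet:
    tissue = read_volume(tissue_path)
    roi = read_volume(roi_path) if roi_path is not None else None
    return labels_to_maskset(tissue, roi)


def _phase_of(time: float, t_a: float, t_b: float) -> str:
    if time < t_a:
        return "baseline"
    if time < t_b:
        return "inhalation"
    return "decay"


def write_curve(curve: SignalCurve, path: "str | Path") -> Path:
    """Write a curve as ``time_min,value,phase`` CSV (phases from the markers)."""
    if curve.t_a is None or curve.t_b is None:
        raise ValueError("curve needs t_a and t_b markers to assign phases")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_min", "value", "phase"])
        for t, v in zip(curve.times, curve.values):
            writer.writerow([repr(float(t)), repr(float(v)), _phase_of(t, curve.t_a, curve.t_b)])
    return path


def read_curve(path: "str | Path", label: str = "") -> SignalCurve:
    """Read a curve CSV; phases must be contiguous and in protocol order.

    The phase markers are reconstructed as the midpoints between the last
    frame of one phase and the first frame of the next, which is the exact
    inverse of :func:`write_curve` for marker times aligned with frame
    boundaries.
    """
    path = Path(path)
    times, values, phases = [], [], []
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["time_min", "value", "phase"]:
            raise ValueError(f"{path}:1: expected header 'time_min,value,phase', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                t, v = float(row[0]), float(row[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number: {exc}") from None
            phase = row[2].strip()
            if phase not in PHASES:
                raise ValueError(f"{path}:{lineno}: unknown phase token {phase!r}")
            if times and t <= times[-1]:
                raise ValueError(f"{path}:{lineno}: non-monotone time {t} after {times[-1]}")
            times.append(t)
            values.append(v)
            phases.append(phase)
    if not times:
        raise ValueError(f"{path}: empty curve")

    order = [PHASES.index(p) for p in phases]
    if any(b < a for a, b in zip(order, order[1:])):
        raise ValueError(f"{path}: phases must be contiguous in the order {PHASES}")

    def boundary(before: str, after: str) -> Optional[float]:
        idx = [i for i, p in enumerate(phases) if p == after]
        if not idx or idx[0] == 0:
            return None
        return 0.5 * (times[idx[0] - 1] + times[idx[0]])

    t_a = boundary("baseline", "inhalation")
    t_b = boundary("inhalation", "decay")
    return SignalCurve(np.array(times), np.array(values), t_a=t_a, t_b=t_b, label=label)
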