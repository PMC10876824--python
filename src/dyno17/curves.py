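"""Region-wise relative evaluation of signal curves.

Spatial averaging over a mask, division by the early-baseline mean (which
cancels coil transmit/receive profiles), the averaged maximum around the
end of gas inhalation, and the coefficient of variation of the baseline as
the noise-level metric.
"""

from __future__ import annotations

import numpy as np

from .core import MaskSet, SignalCurve, TimeSeries4D, Volume, check_same_grid

__all__ = [
    "region_mean_series",
    "normalize_baseline",
    "max_around_tb",
    "baseline_cv",
]


def region_mean_series(series: TimeSeries4D, mask: "np.ndarray | Volume") -> SignalCurve:
    """Per-frame arithmetic (unweighted) mean over the mask voxels.

    Voxels flagged invalid (NaN, e.g. by the sensitivity correction) are
    excluded from every frame's mean. Carries the series' phase markers.
    """
    if isinstance(mask, Volume):
        check_same_grid(series, mask, "series/mask")
        mask = mask.data
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape_3d:
        raise ValueError(f"mask shape {mask.shape} does not match series grid {series.shape_3d}")
    if not mask.any():
        raise ValueError("mask is empty")
    voxels = series.data[mask, :]  # (n_voxels, n_frames)
    if np.isnan(voxels).all(axis=0).any():
        raise ValueError("mask contains no valid voxels in at least one frame")
    with np.errstate(invalid="ignore"):
        values = np.nanmean(voxels, axis=0)
    return SignalCurve(series.times_min, values, t_a=series.t_a_min, t_b=series.t_b_min)


def normalize_baseline(curve: SignalCurve, n_baseline: int = 5) -> SignalCurve:
    """Divide every data point by the mean of the first ``n_baseline`` values.

    This is the relative evaluation: the output is dimensionless and its
    first-``n_baseline`` mean is exactly 1. All ``n_baseline`` points must
    precede the inhalation start t_a (when the marker is set), and their
    mean must be positive.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if len(curve) < n_baseline:
        raise ValueError(f"curve has {len(curve)} points, needs >= {n_baseline}")
    if curve.t_a is not None and curve.times[n_baseline - 1] >= curve.t_a:
        raise ValueError(f"fewer than {n_baseline} points before t_a={curve.t_a}")
    base = float(np.mean(curve.values[:n_baseline]))
    if base <= 0:
        raise ValueError(f"baseline mean must be positive, got {base}")
    return curve.replace_values(curve.values / base, units="relative")


def _frame_containing(curve: SignalCurve, t: float) -> int:
    """Index of the frame whose bin [center − Δ/2, center + Δ/2) contains t."""
    half = curve.frame_min / 2.0
    inside = (curve.times - half <= t) & (t < curve.times + half)
    idx = np.flatnonzero(inside)
    if idx.size:
        return int(idx[0])
    return int(np.argmin(np.abs(curve.times - t)))


def max_around_tb(curve: SignalCurve, window: int = 5) -> float:
    """Mean of ``window`` values centred on the frame containing t_b.

    Averaging a few points around the switch back to room air (where the
    signal peaks) reduces the influence of frame-to-frame noise on the
    reported maximum. The window must be odd (centring is undefined
    otherwise) and must fit inside the curve — no silent truncation.
    """
    if curve.t_b is None:
        raise ValueError("curve has no t_b marker")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    center = _frame_containing(curve, curve.t_b)
    half = window // 2
    lo, hi = center - half, center + half + 1
    if lo < 0 or hi > len(curve):
        raise ValueError(
            f"window of {window} frames around t_b (frames {lo}..{hi - 1}) "
            f"exceeds curve bounds 0..{len(curve) - 1}"
        )
    return float(np.mean(curve.values[lo:hi]))


def baseline_cv(curve: SignalCurve, n_baseline: int | None = None) -> float:
    """Coefficient of variation (std/mean) of the baseline values.

    The standard deviation uses the n−1 denominator. By default the
    baseline comprises every frame strictly before t_a (10 frames at the
    1-minute frame spacing of the 40-minute protocol); pass ``n_baseline``
    to use the first n points instead.
    """
    if n_baseline is None:
        if curve.t_a is None:
            raise ValueError("curve has no t_a marker; pass n_baseline explicitly")
        base = curve.values[curve.times < curve.t_a]
    else:
        base = curve.values[: int(n_baseline)]
    if base.size < 2:
        raise ValueError("need at least 2 baseline points for a CV")
    mean = float(np.mean(base))
    if mean <= 0:
        raise ValueError(f"baseline mean must be positive, got {mean}")
    return float(np.std(base, ddof=1) / mean)
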