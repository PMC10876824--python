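"""End-to-end driver: both analysis arms, summary statistics, output bundle.

Arm A (absolute, PV-corrected): sensitivity correction → concentration
calibration → geometric-transfer-matrix PV correction → baseline
normalisation → averaged maxima around t_b, plus kinetic-model fits of the
stimulated and control grey-matter curves.

Arm B (relative, no PV correction): plain regional means → baseline
normalisation → maxima. No sensitivity correction is needed here because
dividing by the region's own baseline cancels the coil profile.

The stimulated/control comparison pairs each left-hemisphere region with
its mirrored right-hemisphere control across tissue classes; with several
datasets (participants) the per-dataset maxima feed the cohort-level
paired t-test via :func:`dyno17.stats.summary_table`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .core import MaskSet, ROI_NAMES, SignalCurve, TISSUE_NAMES, TimeSeries4D, Volume
from .curves import baseline_cv, max_around_tb, normalize_baseline, region_mean_series
from .io import read_maskset, read_series, read_volume, write_curve
from .kinetics import at_fit
from .quantify import (
    NATURAL_ABUNDANCE_H2O17_MMOL_L,
    build_gtm,
    calibrate_concentration,
    pv_correct_series,
    sensitivity_correct,
)
from .stats import paired_t_test

__all__ = ["PipelineConfig", "run_pipeline", "roi_compartments"]

#: (stimulated, control) region pairs compared within one dataset
PAIRED_ROIS = ("S_left", "C_right")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end analysis run."""

    series_path: str
    tissue_labels_path: str
    roi_labels_path: str
    out_dir: str
    sensitivity_path: Optional[str] = None
    t_a_min: float = 10.0
    t_b_min: float = 21.0
    frame_min: Optional[float] = None
    pv: bool = True
    dilation_iterations: int = 2
    psf_fwhm_mm: Optional[float] = None
    sensitivity_mode: str = "map"
    ref_signal: Optional[float] = None
    ref_concentration_mmol_l: float = NATURAL_ABUNDANCE_H2O17_MMOL_L
    fit_kinetics: bool = True
    alpha: float = 0.05
    window: int = 5
    n_baseline: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_a_min < self.t_b_min:
            raise ValueError("t_a_min must precede t_b_min")
        if self.pv and self.psf_fwhm_mm is None:
            raise ValueError("PV correction requires psf_fwhm_mm")
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        flat: dict = {}
        for key, value in d.items():
            if isinstance(value, dict):
                flat.update(value)  # allow grouped sections (paths:, timing:, ...)
            else:
                flat[key] = value
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def roi_compartments(masks: MaskSet) -> MaskSet:
    """Partition the brain into tissue×ROI compartments (e.g. 'GM_S_left').

    The stimulated patch may follow different kinetics than the rest of a
    tissue class, so the PV-correction compartments must distinguish the
    ROIs; merging the ROI labels recovers the plain GM/WM/CSF compartments.
    Empty intersections are dropped.
    """
    comps = {}
    for tissue in TISSUE_NAMES:
        for roi in ROI_NAMES:
            if tissue in masks and roi in masks:
                sel = masks[tissue] & masks[roi]
                if sel.any():
                    comps[f"{tissue}_{roi}"] = sel
    if not comps:
        raise ValueError("mask set has no tissue×ROI intersections")
    return MaskSet(comps, masks.voxel_size_mm)


def _paired_rows(maxima: Dict[str, float]) -> List[Tuple[str, float, float]]:
    rows = []
    for name, value in maxima.items():
        if name.endswith("_" + PAIRED_ROIS[0]):
            partner = name[: -len(PAIRED_ROIS[0])] + PAIRED_ROIS[1]
            if partner in maxima:
                rows.append((name.rsplit("_", 2)[0], value, maxima[partner]))
    return rows


def _maxima_test(maxima: Dict[str, float]) -> dict:
    """Paired stimulated-vs-control test across tissue classes of one dataset."""
    rows = _paired_rows(maxima)
    out: dict = {"pairs": [
        {"region": r, "stimulated": s, "control": c} for r, s, c in rows
    ]}
    if len(rows) < 2:
        out["ttest"] = {"status": "not enough pairs"}
        return out
    stim = np.array([s for _, s, _ in rows])
    ctrl = np.array([c for _, _, c in rows])
    diffs = stim - ctrl
    scale = max(float(np.abs(np.concatenate([stim, ctrl])).max()), 1.0)
    if float(np.std(diffs, ddof=1)) <= 1e-9 * scale:
        # numerically symmetric data (e.g. an unstimulated noiseless phantom)
        out["ttest"] = {"status": "degenerate",
                        "reason": "stimulated/control differences have (numerically) "
                                  "zero variance; t statistic undefined"}
        return out
    try:
        res = paired_t_test(stim, ctrl)
        out["ttest"] = {"status": "ok", "t": res.t, "df": res.df,
                        "p_one_tailed": res.p_one_tailed,
                        "mean_diff": res.mean_diff, "sd_diff": res.sd_diff}
    except ValueError as exc:  # e.g. perfectly symmetric noiseless data
        out["ttest"] = {"status": "degenerate", "reason": str(exc)}
    return out


def _analyse_curves(curves: Dict[str, SignalCurve], window: int, n_baseline: int) -> dict:
    maxima, cvs, normalized = {}, {}, {}
    for name, curve in curves.items():
        rel = normalize_baseline(curve, n_baseline)
        normalized[name] = rel
        maxima[name] = max_around_tb(rel, window)
        cvs[name] = baseline_cv(rel)
    return {"maxima": maxima, "baseline_cv": cvs, "normalized": normalized}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute both analysis arms and write the result bundle.

    Writes per-region curve CSVs, a maxima table CSV, ``results.json`` and
    a log with package versions, the config echo and the seed. Returns the
    results dictionary. Any stage failure propagates with the stage named
    in the exception message.
    """
    out = Path(config.out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    series = stage("read series", read_series, config.series_path,
                   t_a_min=config.t_a_min, t_b_min=config.t_b_min,
                   frame_min=config.frame_min)
    masks = stage("read masks", read_maskset, config.tissue_labels_path,
                  config.roi_labels_path)
    if masks.shape_3d != series.shape_3d:
        raise RuntimeError("pipeline stage 'grid check' failed: series and masks "
                           f"have different grids {series.shape_3d} vs {masks.shape_3d}")
    comps = stage("compartments", roi_compartments, masks)

    results: dict = {"seed": config.seed, "version": __version__,
                     "config": dataclasses.asdict(config)}

    # --- arm A: absolute quantification with PV correction -----------------
    if config.pv:
        corrected = series
        if config.sensitivity_path:
            sens = stage("read sensitivity map", read_volume, config.sensitivity_path)
            corrected = stage("sensitivity correction", sensitivity_correct,
                              corrected, sens, config.sensitivity_mode)
        if config.ref_signal is not None:
            corrected = stage("concentration calibration", calibrate_concentration,
                              corrected, config.ref_signal,
                              config.ref_concentration_mmol_l)
        gtm = stage("GTM construction", build_gtm, comps, config.psf_fwhm_mm,
                    series.voxel_size_mm, dilate_iterations=config.dilation_iterations)
        pv_curves = stage("PV correction", pv_correct_series, corrected, comps, gtm)
        arm_a = stage("arm A evaluation", _analyse_curves, pv_curves,
                      config.window, config.n_baseline)
        arm_a_out = {"maxima": arm_a["maxima"], "baseline_cv": arm_a["baseline_cv"],
                     "gtm_condition_number": gtm.condition_number}
        arm_a_out.update(_maxima_test(arm_a["maxima"]))
        if config.fit_kinetics:
            fits = {}
            for name in ("GM_S_left", "GM_C_right"):
                if name in pv_curves:
                    fit = stage(f"kinetic fit {name}", at_fit, pv_curves[name],
                                seed=config.seed)
                    fits[name] = {"adjusted_r2": fit.adjusted_r2,
                                  "converged": fit.converged,
                                  "params": dataclasses.asdict(fit.params)}
            arm_a_out["kinetic_fits"] = fits
        results["arm_a"] = arm_a_out
        for name, curve in arm_a["normalized"].items():
            write_curve(curve, out / "curves" / f"armA_{name}.csv")

    # --- arm B: relative signal evolution, no PV correction ----------------
    plain = {name: stage(f"region mean {name}", region_mean_series, series, comps[name])
             for name in comps.names()}
    arm_b = stage("arm B evaluation", _analyse_curves, plain,
                  config.window, config.n_baseline)
    arm_b_out = {"maxima": arm_b["maxima"], "baseline_cv": arm_b["baseline_cv"]}
    arm_b_out.update(_maxima_test(arm_b["maxima"]))
    results["arm_b"] = arm_b_out
    for name, curve in arm_b["normalized"].items():
        write_curve(curve, out / "curves" / f"armB_{name}.csv")

    # --- output bundle ------------------------------------------------------
    rows = ["arm,region,max_around_tb,baseline_cv"]
    for arm_key in ("arm_a", "arm_b"):
        if arm_key in results:
            for name in sorted(results[arm_key]["maxima"]):
                rows.append(f"{arm_key},{name},{results[arm_key]['maxima'][name]!r},"
                            f"{results[arm_key]['baseline_cv'][name]!r}")
    (out / "maxima.csv").write_text("\n".join(rows) + "\n")
    (out / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))

    import nibabel, scipy
    log = [
        f"dyno17 {__version__} (numpy {np.__version__}, scipy {scipy.__version__}, "
        f"nibabel {nibabel.__version__})",
        f"seed: {config.seed}",
        "config: " + json.dumps(dataclasses.asdict(config), sort_keys=True),
    ]
    (out / "run.log").write_text("\n".join(log) + "\n")
    return results
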