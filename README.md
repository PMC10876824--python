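# dyno17 — dynamic ¹⁷O-MRI oxygen-metabolism analysis

Dynamic ¹⁷O MRI measures cerebral oxygen metabolism directly: inhaled
¹⁷O₂ gas is MR-invisible until mitochondria metabolise it to ¹⁷O-labelled
water, so the H₂¹⁷O signal rise during a three-phase inhalation
experiment (room-air baseline → enriched-gas inhalation → washout)
reflects the local cerebral metabolic rate of oxygen consumption
(CMRO₂). `dyno17` implements the complete quantitative analysis of such
experiments for researchers working with low-SNR X-nuclei imaging:

* a **digital brain phantom** (GM/WM/CSF compartments, mirror-symmetric
  stimulated and control cortical ROIs) that renders 4D inhalation
  series with PSF blur, smooth coil bias and calibrated noise;
* the **three-phase kinetic model** of the H₂¹⁷O concentration,

  $$\frac{dC}{dt} = 2\,\alpha\,u(t)\,\mathrm{CMRO_2} + k_g X(t)
    - k_l\,(C - C_0),$$

  with gas enrichment α, inhalation indicator *u(t)* on [T_A, T_B],
  recirculated-water excess *X(t)*, washout rate *k_l* and baseline
  concentration *C₀*, solved in closed form per phase and fitted by
  bounded multi-start nonlinear least squares with adjusted-R² scoring;
* **absolute quantification**: flip-angle/sensitivity correction,
  concentration calibration against natural-abundance reference bottles
  (20.48 mmol/L H₂¹⁷O), mask dilation, and partial-volume correction via
  a **geometric transfer matrix** (GTM) — solving g·c = m per frame for
  one PV-corrected concentration per compartment and time point;
* **relative evaluation**: regional mean curves divided by the mean of
  the first five baseline points (which cancels coil profiles), the
  5-frame averaged maximum around T_B, and baseline coefficient of
  variation as the noise metric;
* **statistics**: the one-tailed paired t-test built on the regularized
  incomplete beta function, group summary tables, Monte-Carlo power
  curves and the minimal detectable CMRO₂ change.

## Worked example

```python
from dyno17 import summary_table

# averaged relative maxima around T_B, (stimulated, control) per participant
pairs = list(zip((1.27, 1.36, 1.32, 1.35, 1.45),
                 (1.54, 1.40, 1.21, 1.49, 1.46)))
table = summary_table(pairs)
print(f"stimulated: {table.mean_stimulated:.2f} +/- {table.sd_stimulated:.2f}")
print(f"control:    {table.mean_control:.2f} +/- {table.sd_control:.2f}")
print(f"one-tailed paired p = {table.ttest.p_one_tailed:.3f}")
```

```
stimulated: 1.35 +/- 0.07
control:    1.42 +/- 0.13
one-tailed paired p = 0.168
```

The stimulated cortex rose to 1.35× its baseline on average, the control
side to 1.42×; the paired test finds no significant stimulated-vs-control
difference (p = 0.168 ≥ 0.05). A full phantom round trip — simulate a
noiseless experiment with a +30 % CMRO₂ stimulation of the left cortical
patch, then run both analysis arms:

```python
from dyno17 import PhantomSpec, PipelineConfig, generate_dataset, run_pipeline

spec = PhantomSpec(stim_factor=1.3, noise_cv=0.0, seed=0)
paths = generate_dataset(spec, "data")
res = run_pipeline(PipelineConfig(
    series_path=str(paths["series"]),
    tissue_labels_path=str(paths["tissue_labels"]),
    roi_labels_path=str(paths["roi_labels"]),
    sensitivity_path=str(paths["sensitivity"]),
    out_dir="out", psf_fwhm_mm=spec.psf_fwhm_mm, ref_signal=20.48, seed=0))
a = res["arm_a"]["maxima"]
print(f"PV-corrected GM maxima: stimulated {a['GM_S_left']:.3f}, "
      f"control {a['GM_C_right']:.3f}")
```

```
PV-corrected GM maxima: stimulated 1.433, control 1.350
```

The PV-corrected control grey matter recovers its calibrated 1.35
relative maximum exactly despite the 11.25 mm PSF and a 15 % coil bias;
the stimulated side rises higher (1.433; the recirculation term does not
scale with CMRO₂, so a +30 % CMRO₂ change lifts the maximum by less than
30 % of the rise). The same commands are available from the shell via
`dyno17 simulate|quantify|curves|fit|stats|power|run`.

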