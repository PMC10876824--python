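# Methods

## The measurement being modelled

A three-phase ¹⁷O₂ inhalation experiment: ~10 min of room-air baseline,
~11 min of 70 %-enriched ¹⁷O₂ gas (ending at T_B ≈ 21 min when the
reservoir empties), then washout, imaged continuously for 40 min at one
frame per minute with a nominal (7.5 mm)³ resolution. The H₂¹⁷O baseline
concentration is set by the 0.037 % natural abundance of ¹⁷O in body
water; metabolised gas raises it location-dependently with the local
CMRO₂. Frames are indexed 0-based and frame *i* represents the
bin-center time (i + 0.5)·Δt.

## Kinetic model

The tissue H₂¹⁷O concentration follows the linear ODE

    dC/dt = 2·α·u(t)·CMRO₂ + k_g·X(t) − k_l·(C − C₀)

with u(t) = 1 during inhalation, the recirculated-body-water excess X(t)
ramping linearly during inhalation and decaying as exp(−k_l·(t − T_B))
afterwards, gas enrichment α = 0.70, washout rate k_l (1/min), gain
coefficient k_g and baseline C₀ (mmol/L). The factor 2 counts the two
water molecules produced per O₂ molecule. This reconstruction keeps the
canonical three-phase structure (flat baseline, saturating rise,
washout) while remaining linear in (C₀, CMRO₂, k_g) for fixed k_l — a
property both the calibration and the test oracles exploit. The forward
interface is pluggable so alternative functional forms of the three-phase
family can be swapped into the same fitting machinery.

The ODE is solved in closed form per phase. For k_l < 1e−8 the
inhalation-phase responses switch to fourth-order series expansions in
k_l·τ to avoid catastrophic cancellation; the branch keeps the relative
error against high-accuracy numerical integration below ~1e−9 across the
tested parameter space. The decay phase uses the exact resonant solution
(y_b + k_g·D·τ)·e^(−k_l·τ), valid for all k_l ≥ 0 without branching.

Fitting: unweighted nonlinear least squares (no weighting scheme is
implied by the data model) over the free set {CMRO₂, k_l, k_g, C₀} with
non-negativity bounds scaled from the data, restarted from 5 scrambled
Halton points (seed 0 by default) to escape local minima; the
best-residual solution is scored with the adjusted R²,
1 − (1 − R²)(n − 1)/(n − p − 1). A constant curve with free CMRO₂ is
flagged non-identifiable rather than fitted.

## Quantification chain

1. **Sensitivity correction** divides each frame voxelwise by a
   sensitivity map, or by sin(θ_actual)/sin(θ_nominal) when a flip-angle
   map is supplied (nominal 60°). Non-positive map voxels become NaN and
   are excluded from every later regional mean.
2. **Concentration calibration** scales by ref_concentration/ref_signal.
   The default reference is 20.48 mmol/L — pure-water molarity
   (55.35 mol/L) times the 3.7e−4 natural abundance — the H₂¹⁷O
   concentration of the regular-water reference bottles.
3. **Partial-volume correction** uses a geometric transfer matrix:
   g[i, j] is the mean over measurement region i of the PSF-blurred
   indicator of compartment j, built with the *same* Gaussian-PSF
   primitive the phantom renders with. Measurement regions are the
   compartments dilated twice with the 6-connected structuring element,
   so PSF spill-over is captured rather than lost. Background outside all
   compartments is a known zero-concentration column and drops out of
   the per-frame solve g·c = m. Matrices with condition number above
   1e8 are rejected; the condition number is always reported because it
   is the lever arm of noise amplification in small compartments.

The pipeline partitions the brain into tissue × ROI compartments
(GM_S_left, …, CSF_N_right) rather than plain GM/WM/CSF: the stimulated
patch may follow different kinetics than the rest of the grey matter, so
a homogeneous-GM assumption would alias stimulation into the global GM
value. Merging the ROI labels recovers the conventional three-compartment
correction.

## Relative evaluation

Curves are divided by the mean of their first five baseline points,
making them dimensionless and cancelling any fixed multiplicative coil
profile — which is why the no-PV arm needs no sensitivity correction.
The reported maximum is the mean of the five frames centred on the frame
containing T_B (a centred odd window is the symmetric reading of
"around T_B"; even windows are rejected rather than truncated). The
noise metric is the coefficient of variation (sample sd / mean) of the
baseline; by default all frames strictly before T_A (10 at Δt = 1 min)
count as baseline.

## Statistics

The one-tailed paired t-test computes t = mean(d)/(sd(d)/√n) and, by
default, p = P(T_{n−1} ≥ |t|). This magnitude convention is what
spreadsheet one-tail tests report regardless of the sign of the mean
difference, and it is the convention under which both published p-values
(0.168 for the PV-corrected maxima, 0.382 for the relative maxima)
recompute exactly from the published per-participant values. Note the
published table of the relative evaluation prints p = 0.333, but its own
maxima yield 0.3824 — the value printed elsewhere in the same report;
this package targets the recomputable 0.382. A `directional=True` mode
gives the strict pre-specified-direction test P(T ≥ t); the power
analysis uses it, since power is defined against a directional
alternative. The tail probability itself comes from the regularized
incomplete beta function and matches the closed-form df = 4 CDF to
1e−9.

**Power analysis.** Each Monte-Carlo replicate draws n paired
(stimulated, control) maxima with independent Gaussian noise of sd
noise_cv·M₀ about M₀ = 1.35 and M₁ = 1 + (M₀ − 1)(1 + e): a relative
CMRO₂ change e scales the rise above baseline, because the production
term scales that rise in the kinetic model. The effect model is
pluggable (one could instead scale M₀ directly, or shrink the noise by
the √5 of the 5-frame maximum averaging — choices that materially change
the minimal detectable effect and that the available information does
not pin down). Common random numbers across effect sizes make the power
curve exactly monotone and the bisection for the minimal detectable
change well-posed; an unreachable power target is reported as an error
instead of searched past the effect bound. Under the default model the
minimal detectable CMRO₂ change at n = 5, 10 % noise and power 0.8 is
about 0.75 — a deliberately conservative figure, since the default
places the full per-maximum noise on each of the paired values.

## Phantom

Geometry: a brain-shaped ellipsoid (semi-axes 0.44/0.44/0.42 of the
grid) with a CSF outer shell (normalised radius > 0.88) plus a central
ventricle, a GM shell (0.70–0.88) and a WM core; hemispheres split at
the mid-sagittal plane; the stimulated patch S_left is the intersection
of the left hemisphere with a ball centred on the posterior-lateral
cortex, and C_right is its exact mirror image (equal voxel counts by
construction). Every named region must contain ≥ 8 voxels or the grid is
rejected. At the default 32³ grid the patches hold ~680 voxels each.

Rendering: each tissue × ROI region is painted with its kinetic curve
(CMRO₂ multiplied by `stim_factor` inside S_left), each frame is blurred
with an isotropic Gaussian PSF, multiplied by a fixed sensitivity field,
and given i.i.d. zero-mean Gaussian noise with sd = noise_cv × (mean
noiseless brain baseline). Defaults and what they emulate:

| parameter | default | rationale |
|---|---|---|
| grid, voxel | 32³ at (7.5 mm)³ | nominal resolution of the protocol |
| n_frames, Δt | 40 × 1 min | reconstruction frame rate |
| T_A, T_B | 10, 21 min | 10 min baseline, ~11 min inhalation |
| psf_fwhm_mm | 11.25 (1.5 × voxel) | stand-in for Hamming-filter broadening; no quantitative PSF is published for the radial protocol, so this is a tunable choice that reproduces the GM/WM spill that motivates dilation and PV correction |
| bias_amplitude | 0.15 | typical peak coil-profile deviation; the field is a smooth low-order polynomial, zero-mean over the brain, built only from terms even in the left-right coordinate (birdcage profiles are approximately mirror-symmetric), so it never fakes a lateralised effect |
| noise_cv | 0.10 | the baseline noise level of small PV-corrected ROIs |
| α, C₀ | 0.70; 11.7 / 10.5 / 13.0 mmol/L (GM/WM/CSF) | gas enrichment; baseline concentrations in the measured 11–13 mmol/L range |
| k_l, k_g | 0.12/0.10/0.08; 0.020/0.010/0.004 | plausible washout/recirculation rates ordered by perfusion |
| CMRO₂ | calibrated | solved (linearly, two forward evaluations) so the noiseless relative maximum hits 1.35 (GM), 1.20 (WM), 1.05 (CSF) |

Noise is additive symmetric Gaussian, not Rician: the CV is the only
noise statistic the analysis consumes, and magnitude-bias modelling is
out of scope. The sensitivity field is stored in the truth record so the
correction step can invert it exactly.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: k-space acquisition and reconstruction
(golden-angle trajectories, Hamming filtering appear only as their
assumed image-domain PSF), B₀/B₁ inhomogeneity beyond a smooth
multiplicative field, motion, physiological drift, registration and
segmentation error (masks are exact by construction), relaxation
weighting of the reference bottles, and anatomical realism. Exact PV
recovery on the phantom therefore demonstrates the correctness of the
GTM algebra under its own assumptions, not the accuracy of PV correction
under mask misregistration — which is precisely the regime where the
real data's fits degraded.

## Numerical choices

* Grids must match exactly everywhere; there is no resampling.
* Blur uses zero boundary conditions, consistent with a
  zero-concentration background compartment; GTM rows plus the
  background column sum to 1 for interior regions.
* The GTM solve uses a dense LU solve (compartment counts are ≤ ~13);
  singularity is caught by the condition-number gate, not by the solver.
* `normalize_baseline` requires all five baseline points to precede T_A
  and a positive baseline mean; `max_around_tb` refuses windows that do
  not fit (no silent truncation).
* All randomness (phantom bias/noise, fit restarts, power replicates)
  flows from explicit integer seeds; re-running any entry point with the
  same inputs and seed is bit-reproducible.

## Problem sizes used in the automated checks

The phantom checks run on the default 32³ grid with 40 frames; the
kinetic-model verification uses 100 random parameter draws against
numerical ODE integration; noisy parameter recovery uses 100 curves at
10 % noise against a 51-node profile grid search; the power calibration
uses 10 000 replicates. These sizes make the full verification suite run
in well under a minute while keeping Monte-Carlo standard errors small
against the tested tolerances.

## Known limitations

* The exact functional form of the original three-phase model is not
  reproducible from the available description; the ODE above is a
  faithful reconstruction of its structure, and the fitting layer is
  deliberately agnostic to the forward form.
* The published in-vivo adjusted R² range (0.5–0.8) and the supplementary
  ≥ 23 % minimal detectable CMRO₂ change depend on unavailable raw data
  and an unspecified effect-to-noise mapping; they are plausibility
  references, not reproduction targets (see the effect-model discussion
  above).
* The GTM treats each compartment as homogeneous at each time point;
  within-compartment gradients (e.g. perfusion gradients inside GM) bias
  it in ways the piecewise-constant phantom cannot reveal.
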