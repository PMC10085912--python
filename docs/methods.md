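# Methods

This note records the models implemented in `petkin`, the numerical choices
behind them, what the built-in simulator does and does not emulate, and the
known limitations. Time is in minutes throughout the model layer (file inputs
are in seconds and converted once, at TAC construction); all rate constants
are min⁻¹; activity values are assumed decay-corrected, so no half-life
correction is applied anywhere.

## Reference-tissue models

All quantification is reference-input based: a region assumed devoid of
specific binding supplies C_R(t) in place of the arterial input. The suite
comprises:

**SRTM (nonlinear).** `C_T = R1·C_R + (k2 − R1·k2a)·C_R ⊗ e^(−k2a·t)` with
free (R1, k2, k2a), fitted by bounded weighted least squares
(`scipy.optimize.least_squares`, bounds R1 ∈ (0, 5], k2, k2a ∈ (1e-4, 5]
min⁻¹, tight xtol/ftol/gtol = 1e-13). The start point is the basis-function
solution on the same data, so the nonlinear fit can only improve the weighted
RSS — a nesting property the tests assert. `BP_ND = k2/k2a − 1`.

**SRTM basis.** The linearisation `C_T = R1·C_R + θ·B_i` with
`B_i = C_R ⊗ e^(−k2a_i·t)` precomputed on a log-spaced k2a grid (default 64
points in [0.01, 1.0] min⁻¹). Each grid point costs one 2-parameter weighted
linear solve; the point with minimal weighted RSS wins, ties going to the
smaller k2a (the first index, since the grid is increasing). Then
`k2 = R1·k2a + θ`. The default grid suits amyloid-like kinetics; recovery of a
parameter to better than the grid's local spacing requires a denser or
re-centred grid, which the validation experiments use where they assert
1e-3-level agreement.

**SRTM2 / SRTM2 basis.** Same model with the reference efflux k2′ fixed by the
user: `C_T = R1·[C_R + (k2′ − k2a)·C_R ⊗ e^(−k2a·t)]`, so each basis candidate
is a one-parameter solve; `BP_ND = R1·k2′/k2a − 1`, `k2 = R1·k2′`.

**SRTM-ASL.** With R1 supplied externally (e.g. ASL-derived delivery), the
dummy signal `C_T − R1·C_R = θ·B_i` leaves only θ free, which allows fitting a
late acquisition window on its own (the basis convolution still runs from
t = 0, using the full-scan reference curve). k2 is recovered as
`R1·k2a + θ`, by analogy with the basis linearisation. Two caveats the
implementation makes explicit:

* If the dummy signal is identically ~0 the model is degenerate (any k2a fits
  perfectly); the result reports BP_ND = 0 with status
  `no_specific_binding` rather than the arbitrary algebraic value.
* Over a short late window the θ-only objective is nearly flat in k2a, and
  for k2a far above the tracer's kinetics the basis column degenerates to
  C_R/k2a, so an overly wide grid can select that quasi-proportional boundary
  on near-noiseless data. The late-window analyses in the tests and the
  validation script therefore restrict the grid to the physiological range
  (0.01–0.3 min⁻¹, 128 points; k2a = k2/(1+BP_ND) stays below ~0.2 min⁻¹ for
  the simulated kinetics). This is a modelling choice made a priori, not a
  fitted quantity.

**Logan / Logan2.** The reference Logan plot regresses
`∫₀ᵀ C_T / C_T(T)` on `∫₀ᵀ C_R / C_T(T)` (Logan2 adds `C_R(T)/k2′` to the
numerator) over frames with midtime ≥ t*; the slope is DVR and
`BP_ND = DVR − 1`. Frames with C_T(T) ≤ 0 are excluded with a warning; fewer
than three usable points is an error. t* is a required user setting — there
is no automatic t* search.

**MRTM / MRTM2.** The multilinear forms regress C_T(T) on
{∫C_R, ∫C_T, C_R(T)} (MRTM) or {∫C_R + C_R(T)/k2′, ∫C_T} (MRTM2);
`BP_ND = −(γ1/γ2 + 1)`. MRTM additionally exposes `k2′ = γ1/γ3` for chaining
into the fixed-k2′ models. Exact rank deficiency of the design (e.g.
C_T ∝ C_R, which makes the two integrals collinear) raises a collinearity
error naming the offending regressor pair; the rank test uses a 1e-12
relative singular-value threshold so the merely ill-conditioned (but usable)
late-window designs of real data are not rejected.

**SUVr.** Frame-duration-weighted mean of the target over a user window
divided by the same for the reference; frames must lie fully inside the
window.

## Reference input processing

Four methods turn the measured reference TAC into a continuous curve:
piecewise-linear and natural cubic-spline interpolation through the frame
midtimes, the exponential tail `a0 + a1·e^(−b1·t)` fitted on a user window
[t_s, t_e] (used for all t ≥ t_s, with linear interpolation of the measured
points before t_s), and the Feng-input + one-tissue-compartment model fitted
to the whole TAC. The model-based methods exist for dual-time-window scans:
an exponential or compartmental fit follows the kinetics across the gap,
which linear bridging does not; the validation quantifies this on simulated
1TC data (in-gap RMSE roughly 4× below linear for the exponential and two
orders of magnitude below for the Feng model, which is the generating class).

Numerical choices:

* Interpolation fits operate on frame midtimes. They are unweighted by
  default, with an optional per-frame weight vector.
* The Feng + 1TC model is linear in its three amplitudes once the four rates
  are fixed, so fitting is separable: bounded least squares over log-rates
  (positivity by construction) with an exact inner linear solve, from five
  deterministic log-spaced starts. The a3 ↔ amplitude scale degeneracy is
  resolved by fixing a3 = 1; only the fitted curve is meaningful, and
  individual parameters of this 8-parameter family are not identifiable from
  a single reference TAC.
* The exponential-tail rate is scanned on a deterministic log grid
  (25 points, 1e-3–2 min⁻¹) with exact inner solves, then polished by bounded
  least squares; the polish is kept only if it does not increase the RSS, so
  the result is never worse than the grid search.
* Extrapolation: all curves hold their first value constant before the first
  midtime. After the last midtime the interpolants hold the last value
  constant (activity is bounded; extending the last spline segment can
  diverge), while the exponential and Feng curves use their own model tail.
* For `method="exp"` on a gapped schedule, t_s must not lie after the gap
  start — otherwise the exponential cannot bridge the gap and the
  configuration is rejected.

## Convolution and frame sampling

The kernel underlying every `⊗ e^(−k·t)` term samples the reference curve on
a uniform grid (default 1 s) augmented with the curve's own breakpoints and
the frame boundaries/midtimes, then integrates the convolution analytically
segment by segment — exact for piecewise-linear curves on that node set. The
recurrence over segments is evaluated in numerically safe blocks (the scaled
cumulative-product form is re-normalised before `k·Δt` sums reach ~500), so
rates up to the optimiser bounds cannot overflow or underflow. Small `k·Δt`
uses series expansions to avoid cancellation. Against a 1e-4-min trapezoidal
quadrature oracle the kernel agrees to ~1e-9 relative.

Model predictions are **frame-averaged** over [start, end] by default,
because PET frames are time averages of activity; point evaluation at the
frame midtime is available (`sampling="midtime"`) for comparison with
software that samples. Cumulative integrals in the graphical/multilinear
models use the trapezoid rule on (0 ∪ midtimes) with C(0) = 0 assumed.

Weighted regressions apply the user weights to the residuals of the model's
own dependent variable. For the graphical models this ignores the noise
transformation onto both axes (the conventional implementation choice); the
known consequences — noise-dependent Logan bias — are not corrected, and no
iteratively reweighted fitting is provided. Estimates are invariant to global
rescaling of the weights.

## Frame weighting

Schemes: `uniform` (the default when no weights are given),
`frame_duration` (w ∝ Δt), `duration_over_activity` (w ∝ Δt/C, the usual
count-statistics variance approximation, with an ε = 1e-6·max(C) guard
against division by small values), and `user` (validated pass-through).
Duration-based weights are normalised to mean 1. A `halflife_min` field is
accepted for compatibility with decayed-count schemes, but on decay-corrected
data those reduce to `duration_over_activity` and the field is otherwise
unused.

## Parametric imaging

`fit_image` applies one model per voxel of a 4-D image. Basis matrices and
the reference samples are computed once per volume and shared; each voxel
then runs the identical ROI code path, so voxel maps equal ROI fits on the
same TAC exactly (asserted to 1e-6 on random phantoms, where the residual is
pure float-summation noise). The default mask keeps voxels whose time-mean
activity exceeds 2% of the image maximum. Voxel-level failures never abort
the volume; they are coded in a status map (0 fitted, 1 outside mask,
2 failed) and summarised in one warning. The nonlinear models are accepted
voxelwise but are off the fast path and intended for small volumes only.
Maps are written as one NIfTI file per parameter with the template's
geometry; background voxels are NaN.

## The simulator and what passing tests mean

The generator composes the same forward models the fitters invert: a Feng
arterial input drives a 1TC reference region, SRTM produces the targets, the
continuous curves are frame-averaged to the acquisition schedule, and
optional Gaussian noise with sd = scale·sqrt(max(C,0)/Δt) emulates
count-limited frames (short early frames noisier than long late ones, so the
weighting schemes are exercised).

Default conditions, chosen once as a realistic amyloid-like study and used by
the whole validation suite:

* Feng input a0 = 400, a1 = 10, a2 = 8 (kBq/mL scale), b0 = 4, b1 = 0.01,
  b2 = 0.12 min⁻¹; reference uptake a3 = 0.2, efflux b3 = 0.15 min⁻¹. This
  gives a plasma peak inside the first minute and a reference peak of
  ~15 kBq/mL around 8 min with a slow tail. The values are fixtures with a
  plausible shape, not calibrated to any specific tracer.
* 34-frame schedule over 0–110 min (4×15 s, 4×30 s, 4×60 s, 4×120 s, 3×300 s,
  9×400 s, 6×200 s); the dual-time-window variant drops the 30–90 min block,
  mirroring a 0–30 + 90–110 min protocol.
* Eleven regions with BP_ND from 0.02 to 2.0, R1 0.75–1.25 and k2
  0.11–0.20 min⁻¹ (no region sits on the R1 = 1 + BP_ND degeneracy where the
  SRTM-ASL dummy signal vanishes identically).
* Noise scale 0.25, i.e. ~2–4% standard deviation on late regional frames —
  representative of ROI-averaged clinical data. A seed is mandatory whenever
  noise is drawn.

The simulator's fine grid (0.01 min plus frame boundaries and midtimes) uses
the same node construction as the fitting grid, so frame averages of the
sampled curve are exact and validation experiments can separate estimator
error from discretisation error: tight recovery tests pass the analytic
reference curve and the matching grid step to the fitter, while
default-step behaviour is covered at realistic (percent-level) tolerances.

Because generator and fitters share model classes and numerical kernels by
construction, passing tests demonstrate correctness of the estimators and
internal consistency of the suite — not robustness to the things real data
add: motion, scatter/attenuation residuals, partial-volume effects,
reference-region specific binding, violations of the one- and two-compartment
assumptions, and non-Gaussian reconstruction noise. Phantoms are voxel-wise
resampled TACs, not scanner simulations.

## Other design choices and limitations

* ROI extraction is the unweighted arithmetic mean over voxels of a label;
  no volume weighting or partial-volume correction.
* File formats are NIfTI-1 and a three-column TAC CSV
  (`frame_start_s,frame_end_s,value`, written at 17 significant digits and
  parsed with round-trip float precision, so CSV round trips are lossless).
* Frame timing always comes from the user-supplied schedule, never from image
  headers.
* Plasma-input models (1TCM/2TCM with arterial input), automatic t* search,
  motion correction and map post-processing (smoothing, spatial priors) are
  out of scope.
* The CLI validates its JSON settings against a strict schema (unknown keys
  rejected), derives every random draw from the configured seed, and writes a
  provenance sidecar per output file.
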