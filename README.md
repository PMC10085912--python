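# petkin

Reference-tissue pharmacokinetic analysis of dynamic brain PET.

Quantitative PET studies of slowly binding tracers (amyloid ligands and
similar) estimate tracer binding without arterial blood sampling by using a
reference region devoid of specific binding in place of the plasma input.
`petkin` implements the standard reference-input method suite end to end:

* **Reference input processing** — turn a measured reference-region
  time-activity curve (TAC) into a continuous input C_R(t) by linear or cubic
  interpolation, a fitted exponential tail `a0 + a1·e^(−b1·t)` on a user
  window [t_s, t_e], or a one-tissue-compartment model driven by a Feng
  arterial input
  `C_p(t) = (a0·t − a1 − a2)·e^(−b0·t) + a1·e^(−b1·t) + a2·e^(−b2·t)`,
  `C_R(t) = a3·C_p(t) ⊗ e^(−b3·t)`.
  The model-based methods bridge the mid-scan break of **dual-time-window**
  protocols (e.g. 0–30 plus 90–110 min), where linear bridging does not follow
  the kinetics.
* **Kinetic models** — simplified reference tissue model
  `C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·C_R(t) ⊗ e^(−k2a·t)` fitted by bounded
  nonlinear least squares (SRTM) or by basis functions over a log-spaced k2a
  grid (SRTM basis); the fixed-k2′ variants SRTM2 / SRTM2 basis; **SRTM-ASL**,
  which fixes R1 from an external perfusion measurement so that only the basis
  coefficient remains and a late scan window suffices; the Logan and Logan2
  reference graphical plots (slope = DVR); Ichise's multilinear models MRTM /
  MRTM2 (`BP_ND = −(γ1/γ2 + 1)`); and SUVr. Outcomes follow the field's
  conventions: `BP_ND = k2/k2a − 1`, `DVR = BP_ND + 1`, rates in min⁻¹.
* **Frame weighting** — uniform, frame-duration, duration/activity, or
  user-supplied weights for all weighted least-squares fits.
* **Parametric imaging** — any linear model applied voxelwise to a 4-D NIfTI
  with shared precomputed basis matrices; per-voxel results are exactly the
  ROI computation on that voxel's TAC.
* **Forward simulator** — Feng input → 1TC reference → SRTM targets → frame
  averaging → optional dual-time-window gap and count-shaped noise → optional
  4-D phantom, providing ground truth for every model in the suite.

## Worked example

Simulate a noisy regional dataset, build the reference input, and fit two
models to a region whose ground truth is R1 = 1.00, k2 = 0.13 min⁻¹,
BP_ND = 1.25:

```python
import numpy as np
from petkin import SRTMBasis, LoganRef, SimulationSpec, simulate_tacs
from petkin.reference import interp_linear

spec = SimulationSpec(noise_scale=0.25, seed=7)
ds = simulate_tacs(spec)

ref_curve = interp_linear(ds.ref_tac)
tac = ds.targets[8]  # ground truth: R1=1.00, k2=0.13/min, BP_ND=1.25

res = SRTMBasis(tac, ref_curve).fit()
print(res.summary())
print(f"Logan BP_ND: {LoganRef(tac, ref_curve, t_star=60.0).fit().bp_nd:.4f}")
```

prints

```
Kinetic model fit: srtmb
  frames used: 34    weighted RSS: 17.9963    status: ok
  parameter       estimate       std err
  r1              0.981469       0.02264
  k2              0.134414            --
  k2a            0.0577969            --
  bp_nd            1.32563            --
  dvr              2.32563            --
Logan BP_ND: 1.3212
```

At this noise level the basis-SRTM estimates sit a few percent from the
generating values (R1 0.98 vs 1.00, k2 0.134 vs 0.130 min⁻¹, BP_ND 1.33 vs
1.25), and the Logan slope-derived BP_ND agrees with the SRTM estimate —
the consistency one expects between the two model families at a late t*.
`res.plot(tac)` overlays the fitted curve on the frame data.

The same analyses run from the shell:

```sh
petkin simulate --config sim.json --out-dir fixtures/
petkin interp-ref --tac fixtures/ref.csv --method feng_1tc --out ref_interp.csv
petkin fit-roi --tac fixtures/region_08.csv --ref fixtures/ref.csv \
       --model srtmb --out results.csv
petkin fit-image --pet dyn.nii.gz --timing frames.csv --ref ref.csv \
       --model logan --config settings.json --out-prefix subj01_
```

Every output file gets a `.meta.json` sidecar recording the package version
and a hash of the effective configuration; identical configuration and seed
give byte-identical outputs.

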