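"""Forward simulator: ground-truth TACs and phantoms for the kinetic models.

Pipeline: a Feng-style arterial plasma input drives a one-tissue-compartment
reference region (``C_R = a3 C_p (x) e^{-b3 t}``); target regions follow the
SRTM forward model (``C_T = R1 C_R + (k2 - R1 k2a) C_R (x) e^{-k2a t}`` with
``k2a = k2/(1+BP_ND)``).  Continuous curves are frame-averaged to a
34-frame, 0-110 min schedule (optionally with the 30-90 min break of a
dual-time-window protocol), and optionally perturbed with count-shaped
Gaussian noise so that weighting schemes are exercised.

The defaults are fixtures with a realistic amyloid-tracer shape (plasma peak
within the first minute, slow tail, reference efflux 0.15/min); they are not
calibrated to any specific tracer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .exceptions import ConfigurationError, DimensionError
from .models import conv_exp
from .reference import (
    FengRefParams,
    ReferenceCurve,
    feng_plasma_values,
    feng_reference_curve,
    feng_reference_values,
)
from .tac import TAC, FrameSchedule, RegionalTACSet, frame_average_values

__all__ = [
    "RegionParams",
    "SimulationSpec",
    "SimulatedDataset",
    "Phantom",
    "DEFAULT_FENG",
    "DEFAULT_REGIONS",
    "default_schedule",
    "simulate_plasma",
    "simulate_reference",
    "simulate_target",
    "frame_average",
    "add_noise",
    "blank_gap",
    "simulate_tacs",
    "make_phantom",
]

#: fine simulation grid step, minutes
FINE_STEP = 0.01

#: Feng-like input + 1TC reference defaults (kBq/mL scale, rates in 1/min)
DEFAULT_FENG = FengRefParams(a0=400.0, a1=10.0, a2=8.0, a3=0.2, b0=4.0, b1=0.01, b2=0.12, b3=0.15)


@dataclass(frozen=True)
class RegionParams:
    """Ground-truth SRTM parameters of one simulated region."""

    r1: float
    k2: float  # 1/min
    bp_nd: float

    def __post_init__(self):
        if not (self.r1 > 0 and self.k2 > 0):
            raise ConfigurationError("r1 and k2 must be > 0")
        if self.bp_nd < 0:
            raise ConfigurationError("bp_nd must be >= 0")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)


#: eleven regions spanning BP_ND in [0.02, 2.0] with mixed delivery/efflux,
#: loosely mirroring a whole-brain parcellation (white matter ... accumbens)
DEFAULT_REGIONS: Dict[int, RegionParams] = {
    1: RegionParams(0.85, 0.18, 0.02),
    2: RegionParams(1.12, 0.12, 0.10),
    3: RegionParams(0.90, 0.16, 0.25),
    4: RegionParams(1.05, 0.14, 0.40),
    5: RegionParams(0.95, 0.20, 0.60),
    6: RegionParams(1.20, 0.11, 0.80),
    7: RegionParams(0.80, 0.17, 1.00),
    8: RegionParams(1.00, 0.13, 1.25),
    9: RegionParams(1.15, 0.15, 1.50),
    10: RegionParams(0.75, 0.19, 1.75),
    11: RegionParams(1.25, 0.12, 2.00),
}


def default_schedule(gap: bool = False) -> FrameSchedule:
    """34-frame 0-110 min schedule; ``gap=True`` drops the 30-90 min block.

    Durations: 4x15 s, 4x30 s, 4x60 s, 4x120 s, 3x300 s (to 30 min),
    9x400 s (30-90 min), 6x200 s (90-110 min).
    """
    durations = [15.0] * 4 + [30.0] * 4 + [60.0] * 4 + [120.0] * 4 + [300.0] * 3 + [400.0] * 9 + [200.0] * 6
    end = np.cumsum(durations)
    start = end - durations
    sched = FrameSchedule(start, end)
    if gap:
        keep = (sched.end_s <= 1800.0 + 1e-9) | (sched.start_s >= 5400.0 - 1e-9)
        sched = sched.subset(keep)
    return sched


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the forward simulation."""

    feng: FengRefParams = DEFAULT_FENG
    regions: Dict[int, RegionParams] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    schedule: FrameSchedule = field(default_factory=default_schedule)
    noise_scale: float = 0.25
    seed: Optional[int] = 12345
    fine_step: float = FINE_STEP

    def __post_init__(self):
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        if self.noise_scale > 0 and self.seed is None:
            raise ConfigurationError("a seed is mandatory when noise_scale > 0")


# ---------------------------------------------------------------------------
# continuous-time pieces
# ---------------------------------------------------------------------------

def simulate_plasma(params: FengRefParams, t) -> np.ndarray:
    """Feng arterial input C_p(t); C_p(0) = 0 and C_p -> 0 as t -> inf."""
    return feng_plasma_values(params, t)


def simulate_reference(params: FengRefParams, t, step: float = FINE_STEP) -> np.ndarray:
    """Reference tissue curve ``a3 C_p (x) e^{-b3 t}`` via the numeric kernel.

    (The analytic closed form is available as
    :func:`petkin.reference.feng_reference_values`; the two agree to the
    discretisation accuracy of the fine grid.)
    """

    def plasma(tt):
        return feng_plasma_values(params, tt)

    return params.a3 * conv_exp(plasma, params.b3, t, step=step)


def true_reference_curve(spec_or_params) -> ReferenceCurve:
    """Analytic ground-truth reference curve for a spec or FengRefParams."""
    params = spec_or_params.feng if isinstance(spec_or_params, SimulationSpec) else spec_or_params
    return feng_reference_curve(params)


def simulate_target(ref_curve, r1: float, k2: float, bp_nd: float, t, step: float = FINE_STEP) -> np.ndarray:
    """SRTM forward model values at t, with k2a = k2/(1+BP_ND)."""
    k2a = k2 / (1.0 + bp_nd)
    conv = conv_exp(ref_curve, k2a, t, step=step)
    return r1 * np.asarray(ref_curve(t), dtype=float) + (k2 - r1 * k2a) * conv


def frame_average(t, values, schedule: FrameSchedule) -> TAC:
    """Average a fine-grid signal over each frame window; returns a TAC."""
    return TAC(schedule, frame_average_values(np.asarray(t, float), np.asarray(values, float), schedule))


def add_noise(tac: TAC, scale: float, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None) -> TAC:
    """Count-shaped Gaussian noise: sd_i = scale * sqrt(max(C_i, 0) / dt_i).

    dt_i is the frame duration in minutes, so short frames are noisier, as in
    reconstructed PET data.  ``scale=0`` returns the TAC unchanged.
    """
    if scale < 0:
        raise ConfigurationError("noise scale must be >= 0")
    if scale == 0:
        return tac
    if rng is None:
        if seed is None:
            raise ConfigurationError("a seed (or rng) is mandatory when scale > 0")
        rng = np.random.default_rng(seed)
    sd = scale * np.sqrt(np.maximum(tac.values, 0.0) / tac.schedule.duration_min)
    return TAC(tac.schedule, tac.values + rng.normal(0.0, 1.0, len(tac)) * sd)


def blank_gap(tac: TAC, gap_start_min: float = 30.0, gap_end_min: float = 90.0) -> TAC:
    """Drop the frames inside [gap_start, gap_end] (dual-time-window break)."""
    keep = (tac.schedule.end_min <= gap_start_min + 1e-9) | (
        tac.schedule.start_min >= gap_end_min - 1e-9
    )
    return tac.subset(keep)


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedDataset:
    """Reference + regional target TACs with their generating truth."""

    schedule: FrameSchedule
    ref_tac: TAC
    targets: RegionalTACSet
    truth: Dict[int, RegionParams]
    ref_curve: ReferenceCurve
    noiseless_ref: TAC
    noiseless_targets: RegionalTACSet


def _fine_grid(schedule: FrameSchedule, step: float) -> np.ndarray:
    # same node construction as the model-fitting grid: frame boundaries and
    # midtimes are exact nodes, so frame averages are exact for the sampled curve
    end = float(schedule.end_min[-1])
    return np.union1d(
        np.concatenate(
            [np.arange(0.0, end, step), schedule.start_min, schedule.end_min, schedule.midtimes_min]
        ),
        [0.0, end],
    )


def simulate_tacs(spec: SimulationSpec) -> SimulatedDataset:
    """Generate the reference TAC and one target TAC per region.

    Noise draws are deterministic given ``spec.seed``: the reference is drawn
    first, then regions in ascending label order.
    """
    curve = true_reference_curve(spec)
    t = _fine_grid(spec.schedule, spec.fine_step)
    ref_fine = feng_reference_values(spec.feng, t)
    ref_clean = frame_average(t, ref_fine, spec.schedule)
    clean = {}
    for label in sorted(spec.regions):
        p = spec.regions[label]
        clean[label] = frame_average(t, simulate_target(curve, p.r1, p.k2, p.bp_nd, t, spec.fine_step), spec.schedule)
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        ref_tac = add_noise(ref_clean, spec.noise_scale, rng=rng)
        noisy = {lab: add_noise(clean[lab], spec.noise_scale, rng=rng) for lab in sorted(clean)}
    else:
        ref_tac = ref_clean
        noisy = dict(clean)
    return SimulatedDataset(
        schedule=spec.schedule,
        ref_tac=ref_tac,
        targets=RegionalTACSet(noisy, spec.schedule),
        truth=dict(spec.regions),
        ref_curve=curve,
        noiseless_ref=ref_clean,
        noiseless_targets=RegionalTACSet(clean, spec.schedule),
    )


@dataclass(frozen=True)
class Phantom:
    """A synthetic 4-D dynamic image with its parcellation and truth maps."""

    image4d: np.ndarray
    parcellation: np.ndarray
    truth_maps: Dict[str, np.ndarray]
    dataset: SimulatedDataset


def make_phantom(
    spec: SimulationSpec,
    shape: Tuple[int, int, int] = (16, 16, 8),
    region_layout: Optional[np.ndarray] = None,
) -> Phantom:
    """Build a 4-D phantom where each region's voxels carry its TAC.

    ``region_layout`` is an optional integer (X, Y, Z) parcellation using the
    spec's region labels; by default the x-axis is split into contiguous
    slabs, one per region.  With ``noise_scale > 0`` every voxel receives an
    independent noise draw (reference noise drawn first, then voxels in raster
    order), so regional averages are less noisy than voxels, as in real data.
    """
    labels = sorted(spec.regions)
    if region_layout is None:
        nx = shape[0]
        if nx < len(labels):
            raise DimensionError("phantom x-extent smaller than number of regions")
        region_layout = np.zeros(shape, dtype=np.int32)
        edges = np.linspace(0, nx, len(labels) + 1).astype(int)
        for lab, lo, hi in zip(labels, edges[:-1], edges[1:]):
            region_layout[lo:hi, :, :] = lab
    else:
        region_layout = np.asarray(region_layout)
        if region_layout.shape != tuple(shape):
            raise DimensionError("region_layout shape does not match phantom shape")

    clean_spec = SimulationSpec(
        feng=spec.feng,
        regions=spec.regions,
        schedule=spec.schedule,
        noise_scale=0.0,
        seed=spec.seed,
        fine_step=spec.fine_step,
    )
    ds = simulate_tacs(clean_spec)
    nf = spec.schedule.n_frames
    img = np.zeros(tuple(shape) + (nf,), dtype=float)
    for lab in labels:
        img[region_layout == lab] = ds.noiseless_targets[lab].values
    rng = np.random.default_rng(spec.seed) if spec.noise_scale > 0 else None
    ref_tac = ds.noiseless_ref
    if rng is not None:
        ref_tac = add_noise(ds.noiseless_ref, spec.noise_scale, rng=rng)
        sd = spec.noise_scale * np.sqrt(
            np.maximum(img, 0.0) / spec.schedule.duration_min[None, None, None, :]
        )
        img = img + rng.normal(0.0, 1.0, img.shape) * sd
        img[region_layout == 0] = 0.0

    truth_maps = {}
    for name in ("r1", "k2", "bp_nd", "k2a"):
        vol = np.full(shape, np.nan)
        for lab in labels:
            p = spec.regions[lab]
            vol[region_layout == lab] = getattr(p, name)
        truth_maps[name] = vol

    ds_out = SimulatedDataset(
        schedule=ds.schedule,
        ref_tac=ref_tac,
        targets=ds.targets,
        truth=ds.truth,
        ref_curve=ds.ref_curve,
        noiseless_ref=ds.noiseless_ref,
        noiseless_targets=ds.noiseless_targets,
    )
    return Phantom(image4d=img, parcellation=region_layout, truth_maps=truth_maps, dataset=ds_out)
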