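"""Voxelwise parametric mapping.

Applies one of the linear kinetic models to every voxel of a 4-D dynamic
image, reusing the expensive shared quantities (basis matrices) across
voxels.  The module's core contract is that each voxel's result is exactly
the ROI operation applied to that voxel's TAC — the voxel path calls the same
functions with the same precomputed inputs, so the two are bit-identical.

Nonlinear SRTM/SRTM2 are also accepted but are orders of magnitude slower
voxelwise and intended only for small volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import nibabel as nib

from .exceptions import ConfigurationError, DimensionError, PetkinError
from .models import (
    BasisSet,
    make_basis,
    logan_ref,
    logan_ref_k2p,
    mrtm,
    mrtm2,
    srtm2_basis,
    srtm2_nls,
    srtm_asl,
    srtm_basis,
    srtm_nls,
    suvr,
)
from .reference import ReferenceCurve
from .tac import TAC, FrameSchedule, frame_average_values

__all__ = ["ParametricMaps", "fit_image", "write_maps", "default_mask", "LINEAR_MODELS"]

LINEAR_MODELS = ("srtmb", "srtm2b", "srtm_asl", "logan", "logan2", "mrtm", "mrtm2", "suvr")
_NONLINEAR_MODELS = ("srtm", "srtm2")

#: map names produced per model (plus "rss" and "status" where applicable)
_MAP_FIELDS = {
    "srtmb": ("r1", "k2", "k2a", "bp_nd", "dvr"),
    "srtm2b": ("r1", "k2", "k2a", "bp_nd", "dvr"),
    "srtm_asl": ("r1", "k2", "k2a", "bp_nd", "dvr"),
    "srtm": ("r1", "k2", "k2a", "bp_nd", "dvr"),
    "srtm2": ("r1", "k2", "k2a", "bp_nd", "dvr"),
    "logan": ("bp_nd", "dvr", "intercept"),
    "logan2": ("bp_nd", "dvr", "intercept"),
    "mrtm": ("bp_nd", "dvr", "gamma1", "gamma2", "gamma3"),
    "mrtm2": ("bp_nd", "dvr", "gamma1", "gamma2"),
}


@dataclass
class ParametricMaps:
    """Named parameter volumes on the input grid; non-mask voxels are NaN.

    ``maps["status"]`` codes voxel outcomes: 0 fitted, 1 outside mask,
    2 fit failed (details were warned once per volume).
    """

    model: str
    maps: Dict[str, np.ndarray]
    mask: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    @property
    def names(self):
        return tuple(self.maps)


def default_mask(image4d: np.ndarray) -> np.ndarray:
    """Voxels whose time-mean activity exceeds 2% of the image maximum."""
    tm = image4d.mean(axis=3)
    return tm > 0.02 * float(image4d.max())


def fit_image(
    image4d: np.ndarray,
    schedule: FrameSchedule,
    ref: ReferenceCurve,
    model: str,
    settings: Optional[dict] = None,
    mask: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> ParametricMaps:
    """Fit one kinetic model per voxel of a 4-D dynamic image.

    Parameters
    ----------
    image4d : (X, Y, Z, T) array
    schedule : frame timing (T frames)
    ref : continuous reference input
    model : one of srtmb, srtm2b, srtm_asl, logan, logan2, mrtm, mrtm2, suvr
        (nonlinear srtm/srtm2 accepted but slow voxelwise)
    settings : model settings: n_basis, k2a_min, k2a_max, k2p, t_star, r1
        (scalar or 3-D map, srtm_asl), suvr_window, sampling, grid_step
    mask : optional 3-D boolean mask; defaults to :func:`default_mask`
    weights : optional per-frame weights shared across voxels

    Voxel-level fit failures never abort the volume; they are coded in the
    status map.
    """
    image4d = np.asarray(image4d, dtype=float)
    if image4d.ndim != 4:
        raise DimensionError("image4d must be 4-dimensional")
    if image4d.shape[3] != schedule.n_frames:
        raise DimensionError("4th dimension must equal the number of frames")
    if model not in LINEAR_MODELS + _NONLINEAR_MODELS:
        raise ConfigurationError(f"unknown model {model!r}")
    s = dict(settings or {})
    shape = image4d.shape[:3]
    if mask is None:
        mask = default_mask(image4d)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise DimensionError("mask shape does not match image grid")

    sampling = s.get("sampling", "frame_average")
    step = s.get("grid_step", None)
    basis_kw = dict(
        n_basis=int(s.get("n_basis", 64)),
        k2a_range=(float(s.get("k2a_min", 0.01)), float(s.get("k2a_max", 1.0))),
        sampling=sampling,
    )
    if step is not None:
        basis_kw["step"] = float(step)
    k2p = s.get("k2p")
    t_star = s.get("t_star")
    r1 = s.get("r1")
    suvr_window = s.get("suvr_window")

    # shared precomputations
    basis: Optional[BasisSet] = None
    if model in ("srtmb", "srtm_asl", "srtm"):
        basis = make_basis(ref, schedule, **basis_kw)
    elif model in ("srtm2b", "srtm2"):
        if k2p is None:
            raise ConfigurationError(f"model {model} requires settings['k2p']")
        basis = make_basis(ref, schedule, k2p=float(k2p), **basis_kw)
    if model in ("logan", "logan2", "mrtm", "mrtm2") and t_star is None:
        raise ConfigurationError(f"model {model} requires settings['t_star']")
    if model in ("logan2", "mrtm2") and k2p is None:
        raise ConfigurationError(f"model {model} requires settings['k2p']")
    ref_tac = None
    if model == "suvr":
        if suvr_window is None:
            raise ConfigurationError("model suvr requires settings['suvr_window']")
        # reference TAC synthesised from the curve with the standard sampling rule
        from .models import _prepare_grid

        mg = _prepare_grid(ref, schedule, "frame_average",
                           float(step) if step is not None else 1.0 / 60.0)
        ref_tac = TAC(schedule, mg.sample(mg.f))
    r1_map = None
    if model == "srtm_asl":
        if r1 is None:
            raise ConfigurationError("model srtm_asl requires settings['r1'] (scalar or 3-D map)")
        r1_map = np.asarray(r1, dtype=float)
        if r1_map.ndim == 0:
            r1_map = np.full(shape, float(r1_map))
        elif r1_map.shape != shape:
            raise DimensionError("r1 map shape does not match image grid")

    names = ("suvr",) if model == "suvr" else _MAP_FIELDS[model] + ("rss",)
    maps = {name: np.full(shape, np.nan) for name in names}
    status = np.ones(shape, dtype=float)  # 1 = outside mask
    n_failed = 0
    first_failure = None

    flat = image4d.reshape(-1, schedule.n_frames)
    flat_mask = mask.ravel()
    flat_status = status.ravel()
    flat_maps = {name: maps[name].ravel() for name in names}
    flat_r1 = r1_map.ravel() if r1_map is not None else None

    for idx in np.flatnonzero(flat_mask):
        tac = TAC(schedule, flat[idx])
        try:
            if model == "suvr":
                flat_maps["suvr"][idx] = suvr(tac, ref_tac, suvr_window)
                flat_status[idx] = 0.0
                continue
            if model == "srtmb":
                res = srtm_basis(tac, basis, weights)
            elif model == "srtm2b":
                res = srtm2_basis(tac, basis, weights)
            elif model == "srtm_asl":
                res = srtm_asl(tac, ref, float(flat_r1[idx]), basis, weights)
            elif model == "srtm":
                res = srtm_nls(tac, ref, weights, basis=basis, sampling=sampling,
                               **({"step": float(step)} if step is not None else {}))
            elif model == "srtm2":
                r0 = srtm2_basis(tac, basis, weights)
                res = srtm2_nls(tac, ref, float(k2p), weights, init=(r0.r1, r0.k2a),
                                sampling=sampling,
                                **({"step": float(step)} if step is not None else {}))
            elif model == "logan":
                res = logan_ref(tac, ref, float(t_star), weights)
            elif model == "logan2":
                res = logan_ref_k2p(tac, ref, float(k2p), float(t_star), weights)
            elif model == "mrtm":
                res = mrtm(tac, ref, float(t_star), weights)
            else:  # mrtm2
                res = mrtm2(tac, ref, float(k2p), float(t_star), weights)
        except (PetkinError, ZeroDivisionError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            if first_failure is None:
                first_failure = exc
            flat_status[idx] = 2.0
            continue
        for name in names:
            if name == "rss":
                flat_maps[name][idx] = res.rss
            else:
                flat_maps[name][idx] = getattr(res, name)
        flat_status[idx] = 0.0

    if n_failed:
        warnings.warn(
            f"fit_image({model}): {n_failed} voxel fit(s) failed "
            f"(first: {first_failure}); coded 2 in the status map",
            stacklevel=2,
        )
    for name in names:
        maps[name] = flat_maps[name].reshape(shape)
    maps["status"] = flat_status.reshape(shape)
    return ParametricMaps(model=model, maps=maps, mask=mask)


def write_maps(maps: ParametricMaps, template, out_prefix: str) -> Dict[str, str]:
    """Write one NIfTI volume per map, geometry copied from the template.

    Parameters
    ----------
    maps : the fitted parametric maps
    template : a ``nibabel`` spatial image whose affine/header define the
        output geometry; its spatial shape must match the maps.
    out_prefix : path prefix; files are ``<prefix><name>.nii.gz``.

    Returns the mapping name -> written path.
    """
    if not isinstance(template, nib.spatialimages.SpatialImage):
        raise ConfigurationError("template must be a nibabel spatial image")
    shape = next(iter(maps.maps.values())).shape
    if tuple(template.shape[:3]) != shape:
        raise DimensionError(
            f"template grid {tuple(template.shape[:3])} does not match maps {shape}"
        )
    written = {}
    for name, vol in maps.maps.items():
        img = nib.Nifti1Image(vol.astype(np.float64), template.affine)
        path = f"{out_prefix}{name}.nii.gz"
        nib.save(img, path)
        written[name] = path
    return written
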