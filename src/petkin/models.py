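"""Reference-tissue kinetic models for dynamic PET.

Implemented methods
-------------------
* SRTM / SRTM2 by bounded nonlinear least squares:
  ``C_T = R1 C_R + (k2 - R1 k2a) C_R (x) e^{-k2a t}`` and the fixed-k2'
  variant ``C_T = R1 C_R + R1 (k2' - k2a) C_R (x) e^{-k2a t}``.
* SRTM / SRTM2 by basis functions: the convolution is precomputed on a
  log-spaced k2a grid, so every candidate fit is a small weighted linear
  solve and the grid point with minimal weighted RSS wins.
* SRTM-ASL: SRTM basis with R1 fixed from an external (e.g. ASL perfusion)
  measurement — only the basis coefficient theta is estimated, which allows
  fitting a late scan window only.
* Logan / Logan2 reference graphical analysis, MRTM / MRTM2 multilinear
  reference tissue models, and SUVr.

Outputs use the field's conventions: BP_ND = k2/k2a - 1 (SRTM),
R1 k2'/k2a - 1 (SRTM2), -(g1/g2 + 1) (MRTM family); DVR = BP_ND + 1; all
rates in 1/min, time in minutes.

Numerical conventions
---------------------
The reference curve is sampled on a uniform fine grid (default 1 s) plus its
own breakpoints and the frame boundaries; the convolution with a decaying
exponential is then computed analytically segment-by-segment, which is exact
for piecewise-linear curves.  Model predictions are frame-averaged over
[start, end] by default because frames are time averages of activity;
``sampling="midtime"`` switches to point evaluation at frame mid-times for
cross-software comparison.  Cumulative integrals for the graphical and
multilinear models use the trapezoid rule on (0, midtimes) with C(0) = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    DegenerateDesignError,
    FitError,
    InsufficientDataError,
)
from .reference import ReferenceCurve
from .tac import TAC, FrameSchedule, frame_average_values

__all__ = [
    "DEFAULT_GRID_STEP",
    "KineticResult",
    "BasisSet",
    "conv_exp",
    "make_basis",
    "srtm_basis",
    "srtm2_basis",
    "srtm_nls",
    "srtm2_nls",
    "srtm_asl",
    "logan_ref",
    "logan_ref_k2p",
    "mrtm",
    "mrtm2",
    "suvr",
    "SRTM",
    "SRTM2",
    "SRTMBasis",
    "SRTM2Basis",
    "SRTMASL",
    "LoganRef",
    "LoganRefK2p",
    "MRTM",
    "MRTM2",
    "MODEL_NAMES",
]

#: default reference-curve sampling step for convolution, minutes (1 second)
DEFAULT_GRID_STEP = 1.0 / 60.0

_NLS_BOUNDS_LO = np.array([1e-6, 1e-4, 1e-4])  # R1, k2, k2a
_NLS_BOUNDS_HI = np.array([5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class KineticResult:
    """Estimates and diagnostics from one kinetic-model fit.

    Fields not produced by a given model are NaN.  ``fitted_values`` are in
    the model's own fitting domain: per-frame activity for the SRTM family,
    the fitted dependent variable of the regression (on the frames actually
    used) for the graphical/multilinear models.  ``se`` holds approximate
    standard errors where cheaply available (linear-regression covariance,
    or the Gauss-Newton covariance at the NLS solution).
    """

    model: str
    r1: float = np.nan
    k2: float = np.nan
    k2a: float = np.nan
    k2p: float = np.nan
    bp_nd: float = np.nan
    dvr: float = np.nan
    intercept: float = np.nan
    gamma1: float = np.nan
    gamma2: float = np.nan
    gamma3: float = np.nan
    rss: float = np.nan
    fitted_values: Optional[np.ndarray] = None
    used: Optional[np.ndarray] = None  # boolean per-frame mask for subset fits
    status: str = "ok"
    se: Dict[str, float] = field(default_factory=dict)
    n_used: int = 0

    _FIELDS = ("r1", "k2", "k2a", "k2p", "bp_nd", "dvr", "intercept", "gamma1", "gamma2", "gamma3")

    def as_dict(self) -> Dict[str, float]:
        d = {name: getattr(self, name) for name in self._FIELDS}
        d["rss"] = self.rss
        d["model"] = self.model
        d["status"] = self.status
        return d

    def summary(self) -> str:
        """Human-readable parameter table."""
        lines = [
            f"Kinetic model fit: {self.model}",
            f"  frames used: {self.n_used}    weighted RSS: {self.rss:.6g}    status: {self.status}",
            f"  {'parameter':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name in self._FIELDS:
            val = getattr(self, name)
            if np.isnan(val):
                continue
            se = self.se.get(name)
            se_s = f"{se:>14.4g}" if se is not None and np.isfinite(se) else f"{'--':>14}"
            lines.append(f"  {name:<10}{val:>14.6g}{se_s}")
        return "\n".join(lines)

    def plot(self, tac: Optional[TAC] = None, ax=None):
        """Plot data and fitted values against frame mid-time (activity-domain models)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if tac is not None:
            ax.plot(tac.midtimes_min, tac.values, "o", ms=4, label="data")
            if self.fitted_values is not None and self.fitted_values.size == len(tac):
                ax.plot(tac.midtimes_min, self.fitted_values, "-", label=f"{self.model} fit")
        elif self.fitted_values is not None:
            ax.plot(self.fitted_values, "-", label=f"{self.model} fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity (kBq/mL)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# convolution kernel
# ---------------------------------------------------------------------------

def _exp_conv_nodes(t: np.ndarray, f: np.ndarray, k: float) -> np.ndarray:
    """(f (x) e^{-k s}) at the nodes of t, exact for piecewise-linear f.

    Uses the per-segment closed form and a numerically safe blocked scan of
    the recurrence g[j+1] = e^{-k dt} g[j] + c[j].
    """
    dt = np.diff(t)
    if k == 0.0:
        return cumulative_trapezoid(f, t, initial=0.0)
    kd = k * dt
    r = np.exp(-kd)
    m = np.diff(f) / dt
    # E = (1 - e^{-k dt})/k and H = (dt - E)/k, with series for small k*dt
    small = kd < 1e-4
    E = np.where(small, dt * (1.0 - kd / 2.0 + kd**2 / 6.0 - kd**3 / 24.0), (1.0 - r) / k)
    H = np.where(small, dt**2 * (0.5 - kd / 6.0 + kd**2 / 24.0), (dt - E) / k)
    c = f[:-1] * E + m * H

    g = np.zeros(t.size)
    n = c.size
    i = 0
    g0 = 0.0
    while i < n:
        stop = min(i + 4096, n)
        s = np.cumsum(kd[i:stop])
        # keep exp(s) well inside double range
        j = int(np.searchsorted(s, 500.0))
        j = max(j, 1)
        s = s[:j]
        p = np.exp(-s)  # cumulative products of r
        acc = np.cumsum(c[i : i + j] / p)
        g[i + 1 : i + j + 1] = p * (g0 + acc)
        g0 = g[i + j]
        i += j
    return g


def conv_exp(curve, rate: float, t, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Convolution ``(curve (x) e^{-rate s})(t)`` for a reference curve.

    The curve is sampled from 0 to max(t) on a uniform grid of ``step``
    minutes, augmented with the curve's breakpoints and the requested times,
    and convolved analytically segment-by-segment (exact for piecewise-linear
    curves on that node set).

    Parameters
    ----------
    curve : ReferenceCurve or callable t -> activity
    rate : decay rate of the exponential kernel, 1/min, >= 0
    t : increasing evaluation times, minutes
    """
    if rate < 0:
        raise ConfigurationError("rate must be >= 0")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tmax = float(t[-1])
    if tmax == 0.0:
        return np.zeros_like(t)
    pieces = [np.arange(0.0, tmax, step), t]
    knots = getattr(curve, "knots", None)
    if knots is not None:
        knots = np.asarray(knots, float)
        pieces.append(knots[(knots > 0.0) & (knots < tmax)])
    grid = np.union1d(np.concatenate(pieces), [0.0, tmax])
    f = np.asarray(curve(grid), dtype=float)
    g = _exp_conv_nodes(grid, f, float(rate))
    return np.interp(t, grid, g)


# ---------------------------------------------------------------------------
# shared sampling machinery
# ---------------------------------------------------------------------------

@dataclass
class _ModelGrid:
    """Fine time grid plus the rule mapping a continuous signal to frames."""

    tg: np.ndarray
    f: np.ndarray  # reference values on tg
    schedule: FrameSchedule
    sampling: str

    def sample(self, values_on_tg: np.ndarray) -> np.ndarray:
        if self.sampling == "midtime":
            return np.interp(self.schedule.midtimes_min, self.tg, values_on_tg)
        return frame_average_values(self.tg, values_on_tg, self.schedule)

    def conv(self, rate: float) -> np.ndarray:
        return _exp_conv_nodes(self.tg, self.f, rate)


def _prepare_grid(
    ref, schedule: FrameSchedule, sampling: str = "frame_average", step: float = DEFAULT_GRID_STEP
) -> _ModelGrid:
    if sampling not in ("frame_average", "midtime"):
        raise ConfigurationError(f"unknown sampling {sampling!r}")
    end = float(schedule.end_min[-1])
    pieces = [
        np.arange(0.0, end, step),
        schedule.start_min,
        schedule.end_min,
        schedule.midtimes_min,
    ]
    knots = getattr(ref, "knots", None)
    if knots is not None:
        knots = np.asarray(knots, float)
        pieces.append(knots[(knots > 0.0) & (knots < end)])
    tg = np.union1d(np.concatenate(pieces), [0.0, end])
    f = np.asarray(ref(tg), dtype=float)
    return _ModelGrid(tg, f, schedule, sampling)


def _weights(weights, n) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ConfigurationError(f"weights must have length {n}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ConfigurationError("weights must be finite and >= 0")
    if not np.any(w > 0):
        raise ConfigurationError("weights must not be all zero")
    return w


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (beta, rss, cov)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    resid = y - X @ beta
    rss = float(w @ resid**2)
    n, p = X.shape
    cov = None
    if n > p:
        try:
            cov = rss / (n - p) * np.linalg.inv(Xw.T @ Xw)
        except np.linalg.LinAlgError:
            cov = None
    return beta, rss, cov


# ---------------------------------------------------------------------------
# basis sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisSet:
    """Precomputed basis functions over a log-spaced k2a grid.

    ``B[:, i]`` is the per-frame sample (frame-averaged by default) of
    ``C_R (x) e^{-k2a_i t}`` when ``k2p`` is None, or of the fixed-k2' basis
    ``C_R + (k2' - k2a_i) C_R (x) e^{-k2a_i t}`` when ``k2p`` is given.
    ``cr`` is C_R itself sampled with the same rule.
    """

    k2a_grid: np.ndarray
    B: np.ndarray  # (n_frames, n_basis)
    cr: np.ndarray  # (n_frames,)
    schedule: FrameSchedule
    ref: ReferenceCurve
    k2p: Optional[float] = None
    sampling: str = "frame_average"
    step: float = DEFAULT_GRID_STEP


def make_basis(
    ref,
    schedule: FrameSchedule,
    n_basis: int = 64,
    k2a_range: tuple = (0.01, 1.0),
    k2p: Optional[float] = None,
    sampling: str = "frame_average",
    step: float = DEFAULT_GRID_STEP,
) -> BasisSet:
    """Precompute the basis matrix shared across ROIs/voxels."""
    if n_basis < 2:
        raise ConfigurationError("n_basis must be >= 2")
    lo, hi = float(k2a_range[0]), float(k2a_range[1])
    if not (0.0 < lo < hi):
        raise ConfigurationError("k2a_range must satisfy 0 < min < max")
    grid = np.geomspace(lo, hi, n_basis)
    mg = _prepare_grid(ref, schedule, sampling, step)
    cr = mg.sample(mg.f)
    cols = []
    for k2a in grid:
        conv = mg.sample(mg.conv(float(k2a)))
        if k2p is None:
            cols.append(conv)
        else:
            cols.append(cr + (k2p - k2a) * conv)
    B = np.column_stack(cols)
    if not np.all(np.isfinite(B)):
        raise FitError("basis matrix contains non-finite values")
    return BasisSet(grid, B, cr, schedule, ref if isinstance(ref, ReferenceCurve) else None,
                    k2p=k2p, sampling=sampling, step=step)


# ---------------------------------------------------------------------------
# SRTM family, basis-function versions
# ---------------------------------------------------------------------------

def srtm_basis(tac: TAC, basis: BasisSet, weights: Optional[np.ndarray] = None) -> KineticResult:
    """SRTM linearised with basis functions.

    For each grid point i, solve the weighted linear problem
    ``C_T = R1 C_R + theta B_i`` and keep the i with smallest weighted RSS
    (ties broken towards smaller k2a).  Then ``k2 = R1 k2a + theta`` and
    ``BP_ND = k2/k2a - 1``.
    """
    if basis.k2p is not None:
        raise ConfigurationError("srtm_basis needs a basis built without k2p")
    y = tac.values
    w = _weights(weights, len(tac))
    cr = basis.cr
    a11 = float(w @ cr**2)
    if a11 <= 1e-300 * max(1.0, float(w @ y**2)):
        raise DegenerateDesignError("reference curve is (numerically) zero")
    B = basis.B
    a12 = (w * cr) @ B
    a22 = w @ B**2
    b1 = float((w * cr) @ y)
    b2 = (w * y) @ B
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_i = (a22 * b1 - a12 * b2) / det
        th_i = (a11 * b2 - a12 * b1) / det
        rss_i = w @ y**2 - (r1_i * b1 + th_i * b2)
    rss_i = np.where((det > 0) & np.isfinite(rss_i), rss_i, np.inf)
    i = int(np.argmin(rss_i))  # argmin takes the first (smallest k2a) on ties
    if not np.isfinite(rss_i[i]):
        raise DegenerateDesignError("all basis designs are degenerate")
    X = np.column_stack([cr, B[:, i]])
    beta, rss, cov = _wls(X, y, w)
    r1, theta = float(beta[0]), float(beta[1])
    k2a = float(basis.k2a_grid[i])
    k2 = r1 * k2a + theta
    bp = k2 / k2a - 1.0
    se = {}
    if cov is not None:
        se = {"r1": float(np.sqrt(cov[0, 0]))}
    return KineticResult(
        model="srtmb",
        r1=r1,
        k2=k2,
        k2a=k2a,
        bp_nd=bp,
        dvr=bp + 1.0,
        rss=rss,
        fitted_values=X @ beta,
        status="ok",
        se=se,
        n_used=len(tac),
    )


def srtm2_basis(tac: TAC, basis: BasisSet, weights: Optional[np.ndarray] = None) -> KineticResult:
    """SRTM2 (fixed k2') linearised with basis functions: one-parameter fits."""
    if basis.k2p is None:
        raise ConfigurationError("srtm2_basis needs a basis built with k2p")
    y = tac.values
    w = _weights(weights, len(tac))
    B = basis.B
    a = w @ B**2
    if np.all(a <= 0):
        raise DegenerateDesignError("reference curve is (numerically) zero")
    b = (w * y) @ B
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_i = b / a
        rss_i = w @ y**2 - r1_i * b
    rss_i = np.where((a > 0) & np.isfinite(rss_i), rss_i, np.inf)
    i = int(np.argmin(rss_i))
    X = B[:, i : i + 1]
    beta, rss, cov = _wls(X, y, w)
    r1 = float(beta[0])
    k2a = float(basis.k2a_grid[i])
    k2p = float(basis.k2p)
    k2 = r1 * k2p
    bp = r1 * k2p / k2a - 1.0
    se = {"r1": float(np.sqrt(cov[0, 0]))} if cov is not None else {}
    return KineticResult(
        model="srtm2b",
        r1=r1,
        k2=k2,
        k2a=k2a,
        k2p=k2p,
        bp_nd=bp,
        dvr=bp + 1.0,
        rss=rss,
        fitted_values=X @ beta,
        status="ok",
        se=se,
        n_used=len(tac),
    )


def srtm_asl(
    tac: TAC,
    ref,
    r1: float,
    basis: Optional[BasisSet] = None,
    weights: Optional[np.ndarray] = None,
    **basis_kwargs,
) -> KineticResult:
    """SRTM with externally fixed R1 (e.g. ASL-derived delivery).

    The dummy signal ``C_T - R1 C_R`` is regressed on each basis function
    (theta only); ``k2 = R1 k2a + theta`` and ``BP_ND = k2/k2a - 1``.  Because
    theta is the only free parameter, the fit works on a late scan window
    alone (build the basis on the late-frame schedule; the convolution still
    runs from t = 0).
    """
    if not r1 > 0:
        raise ConfigurationError("r1 must be > 0")
    if basis is None:
        basis = make_basis(ref, tac.schedule, **basis_kwargs)
    if basis.k2p is not None:
        raise ConfigurationError("srtm_asl needs a basis built without k2p")
    y = tac.values
    w = _weights(weights, len(tac))
    yd = y - r1 * basis.cr
    scale = max(1.0, float(np.max(np.abs(y))))
    if np.max(np.abs(yd)) <= 1e-12 * scale:
        # C_T == R1 C_R exactly: no specific-binding signal, k2a unidentified
        k2a = float(basis.k2a_grid[0])
        return KineticResult(
            model="srtm_asl",
            r1=float(r1),
            k2=r1 * k2a,
            k2a=k2a,
            bp_nd=0.0,
            dvr=1.0,
            rss=0.0,
            fitted_values=r1 * basis.cr,
            status="no_specific_binding",
            se={},
            n_used=len(tac),
        )
    B = basis.B
    a = w @ B**2
    b = (w * yd) @ B
    with np.errstate(divide="ignore", invalid="ignore"):
        th_i = b / a
        rss_i = w @ yd**2 - th_i * b
    rss_i = np.where((a > 0) & np.isfinite(rss_i), rss_i, np.inf)
    i = int(np.argmin(rss_i))
    beta, rss, cov = _wls(B[:, i : i + 1], yd, w)
    theta = float(beta[0])
    k2a = float(basis.k2a_grid[i])
    k2 = r1 * k2a + theta
    bp = k2 / k2a - 1.0
    se = {"k2": float(np.sqrt(cov[0, 0]))} if cov is not None else {}
    return KineticResult(
        model="srtm_asl",
        r1=float(r1),
        k2=k2,
        k2a=k2a,
        bp_nd=bp,
        dvr=bp + 1.0,
        rss=rss,
        fitted_values=r1 * basis.cr + theta * B[:, i],
        status="ok",
        se=se,
        n_used=len(tac),
    )


# ---------------------------------------------------------------------------
# SRTM family, nonlinear versions
# ---------------------------------------------------------------------------

def _nls_se(res, n, p, names):
    """Gauss-Newton standard errors from a least_squares result."""
    if n <= p:
        return {}
    rss = float(np.sum(res.fun**2))
    try:
        cov = rss / (n - p) * np.linalg.inv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return {}
    return {nm: float(np.sqrt(cov[i, i])) for i, nm in enumerate(names)}


def srtm_nls(
    tac: TAC,
    ref,
    weights: Optional[np.ndarray] = None,
    init: Optional[tuple] = None,
    sampling: str = "frame_average",
    step: float = DEFAULT_GRID_STEP,
    basis: Optional[BasisSet] = None,
) -> KineticResult:
    """SRTM by bounded nonlinear weighted least squares over (R1, k2, k2a).

    Bounds: R1 in (0, 5], k2 and k2a in (1e-4, 5] 1/min.  The default start is
    the basis-function solution on the same data.
    """
    y = tac.values
    w = _weights(weights, len(tac))
    sw = np.sqrt(w)
    mg = _prepare_grid(ref, tac.schedule, sampling, step)
    cr = mg.sample(mg.f)
    if init is None:
        if basis is None:
            basis = make_basis(ref, tac.schedule, sampling=sampling, step=step)
        r0 = srtm_basis(tac, basis, weights)
        init = (r0.r1, r0.k2, r0.k2a)
    x0 = np.clip(np.asarray(init, float), _NLS_BOUNDS_LO, _NLS_BOUNDS_HI)

    def model(p):
        conv = mg.sample(mg.conv(float(p[2])))
        return p[0] * cr + (p[1] - p[0] * p[2]) * conv

    def resid(p):
        return sw * (y - model(p))

    res = least_squares(
        resid, x0=x0, bounds=(_NLS_BOUNDS_LO, _NLS_BOUNDS_HI), xtol=1e-13, ftol=1e-13, gtol=1e-13
    )
    if res.status <= 0:
        raise FitError("SRTM nonlinear fit did not converge", status=res.status)
    r1, k2, k2a = (float(v) for v in res.x)
    bp = k2 / k2a - 1.0
    return KineticResult(
        model="srtm",
        r1=r1,
        k2=k2,
        k2a=k2a,
        bp_nd=bp,
        dvr=bp + 1.0,
        rss=float(np.sum(res.fun**2)),
        fitted_values=model(res.x),
        status=f"converged({res.status})",
        se=_nls_se(res, len(tac), 3, ("r1", "k2", "k2a")),
        n_used=len(tac),
    )


def srtm2_nls(
    tac: TAC,
    ref,
    k2p: float,
    weights: Optional[np.ndarray] = None,
    init: Optional[tuple] = None,
    sampling: str = "frame_average",
    step: float = DEFAULT_GRID_STEP,
) -> KineticResult:
    """SRTM2 (fixed k2') by bounded nonlinear least squares over (R1, k2a)."""
    if not k2p > 0:
        raise ConfigurationError("k2p must be > 0")
    y = tac.values
    w = _weights(weights, len(tac))
    sw = np.sqrt(w)
    mg = _prepare_grid(ref, tac.schedule, sampling, step)
    cr = mg.sample(mg.f)
    if init is None:
        b = make_basis(ref, tac.schedule, k2p=k2p, sampling=sampling, step=step)
        r0 = srtm2_basis(tac, b, weights)
        init = (r0.r1, r0.k2a)
    x0 = np.clip(np.asarray(init, float), _NLS_BOUNDS_LO[[0, 2]], _NLS_BOUNDS_HI[[0, 2]])

    def model(p):
        conv = mg.sample(mg.conv(float(p[1])))
        return p[0] * cr + p[0] * (k2p - p[1]) * conv

    def resid(p):
        return sw * (y - model(p))

    res = least_squares(
        resid,
        x0=x0,
        bounds=(_NLS_BOUNDS_LO[[0, 2]], _NLS_BOUNDS_HI[[0, 2]]),
        xtol=1e-13,
        ftol=1e-13,
        gtol=1e-13,
    )
    if res.status <= 0:
        raise FitError("SRTM2 nonlinear fit did not converge", status=res.status)
    r1, k2a = (float(v) for v in res.x)
    bp = r1 * k2p / k2a - 1.0
    return KineticResult(
        model="srtm2",
        r1=r1,
        k2=r1 * k2p,
        k2a=k2a,
        k2p=float(k2p),
        bp_nd=bp,
        dvr=bp + 1.0,
        rss=float(np.sum(res.fun**2)),
        fitted_values=model(res.x),
        status=f"converged({res.status})",
        se=_nls_se(res, len(tac), 2, ("r1", "k2a")),
        n_used=len(tac),
    )


# ---------------------------------------------------------------------------
# graphical and multilinear models
# ---------------------------------------------------------------------------

def _cum_from_zero(mid: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Trapezoid cumulative integral on (0, midtimes) assuming v(0) = 0."""
    t = np.concatenate([[0.0], mid])
    y = np.concatenate([[0.0], v])
    return cumulative_trapezoid(y, t)


def _graphical_inputs(tac: TAC, ref, t_star: float):
    mid = tac.midtimes_min
    ct = tac.values
    crm = np.asarray(ref(mid), dtype=float)
    return mid, ct, crm, _cum_from_zero(mid, ct), _cum_from_zero(mid, crm)


def _logan_common(tac, ref, t_star, weights, k2p, model_name):
    mid, ct, crm, ict, icr = _graphical_inputs(tac, ref, t_star)
    late = mid >= t_star - 1e-9
    bad = late & (ct <= 0)
    if np.any(bad):
        warnings.warn(
            f"{model_name}: excluded {int(bad.sum())} frame(s) with C_T <= 0", stacklevel=3
        )
    use = late & (ct > 0)
    if use.sum() < 3:
        raise InsufficientDataError(f"{model_name} needs >= 3 usable frames with midtime >= t_star")
    num = icr if k2p is None else icr + crm / k2p
    x = num[use] / ct[use]
    yv = ict[use] / ct[use]
    w = _weights(weights, len(tac))[use]
    X = np.column_stack([x, np.ones_like(x)])
    beta, rss, cov = _wls(X, yv, w)
    dvr, intercept = float(beta[0]), float(beta[1])
    se = {}
    if cov is not None:
        se = {"dvr": float(np.sqrt(cov[0, 0])), "bp_nd": float(np.sqrt(cov[0, 0])),
              "intercept": float(np.sqrt(cov[1, 1]))}
    return KineticResult(
        model=model_name,
        k2p=np.nan if k2p is None else float(k2p),
        bp_nd=dvr - 1.0,
        dvr=dvr,
        intercept=intercept,
        rss=rss,
        fitted_values=X @ beta,
        used=use,
        status="ok",
        se=se,
        n_used=int(use.sum()),
    )


def logan_ref(tac: TAC, ref, t_star: float, weights: Optional[np.ndarray] = None) -> KineticResult:
    """Logan reference graphical analysis; the late-time slope is DVR.

    ``fitted_values`` are in the transformed (normalised-integral) domain and
    aligned with ``result.used``.
    """
    return _logan_common(tac, ref, t_star, weights, None, "logan")


def logan_ref_k2p(
    tac: TAC, ref, k2p: float, t_star: float, weights: Optional[np.ndarray] = None
) -> KineticResult:
    """Logan reference analysis with the k2' correction term on the abscissa."""
    if not k2p > 0:
        raise ConfigurationError("k2p must be > 0")
    return _logan_common(tac, ref, t_star, weights, k2p, "logan2")


_MRTM_COLS = ("int_CR", "int_CT", "CR")


def _check_collinear(X: np.ndarray, names):
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        i = int(np.argmin(norms))
        raise CollinearityError(f"regressor {names[i]} is identically zero")
    Xn = X / norms
    sv = np.linalg.svd(Xn, compute_uv=False)
    if sv[-1] / sv[0] < 1e-12:
        corr = np.abs(Xn.T @ Xn)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(int(np.argmax(corr)), corr.shape)
        raise CollinearityError(
            f"design matrix is rank deficient: regressors {names[i]} and {names[j]} "
            "are collinear"
        )


def mrtm(tac: TAC, ref, t_star: float, weights: Optional[np.ndarray] = None) -> KineticResult:
    """Ichise's multilinear reference tissue model (MRTM).

    Regresses C_T(T) on {int C_R, int C_T, C_R(T)} for frames past t_star;
    BP_ND = -(g1/g2 + 1).  The reference efflux estimate k2' = g1/g3 is stored
    in ``result.k2p`` for chaining into the fixed-k2' models.
    """
    mid, ct, crm, ict, icr = _graphical_inputs(tac, ref, t_star)
    use = mid >= t_star - 1e-9
    if use.sum() < 4:
        raise InsufficientDataError("mrtm needs >= 4 frames with midtime >= t_star")
    X = np.column_stack([icr[use], ict[use], crm[use]])
    _check_collinear(X, _MRTM_COLS)
    w = _weights(weights, len(tac))[use]
    beta, rss, cov = _wls(X, ct[use], w)
    g1, g2, g3 = (float(b) for b in beta)
    bp = -(g1 / g2 + 1.0)
    se = {}
    if cov is not None:
        se = {f"gamma{i + 1}": float(np.sqrt(cov[i, i])) for i in range(3)}
    return KineticResult(
        model="mrtm",
        k2p=g1 / g3,
        bp_nd=bp,
        dvr=bp + 1.0,
        gamma1=g1,
        gamma2=g2,
        gamma3=g3,
        rss=rss,
        fitted_values=X @ beta,
        used=use,
        status="ok",
        se=se,
        n_used=int(use.sum()),
    )


def mrtm2(
    tac: TAC, ref, k2p: float, t_star: float, weights: Optional[np.ndarray] = None
) -> KineticResult:
    """MRTM2: two-regressor multilinear model with pre-defined k2'."""
    if not k2p > 0:
        raise ConfigurationError("k2p must be > 0")
    mid, ct, crm, ict, icr = _graphical_inputs(tac, ref, t_star)
    use = mid >= t_star - 1e-9
    if use.sum() < 3:
        raise InsufficientDataError("mrtm2 needs >= 3 frames with midtime >= t_star")
    X = np.column_stack([icr[use] + crm[use] / k2p, ict[use]])
    _check_collinear(X, ("int_CR + CR/k2p", "int_CT"))
    w = _weights(weights, len(tac))[use]
    beta, rss, cov = _wls(X, ct[use], w)
    g1, g2 = (float(b) for b in beta)
    bp = -(g1 / g2 + 1.0)
    se = {}
    if cov is not None:
        se = {"gamma1": float(np.sqrt(cov[0, 0])), "gamma2": float(np.sqrt(cov[1, 1]))}
    return KineticResult(
        model="mrtm2",
        k2p=float(k2p),
        bp_nd=bp,
        dvr=bp + 1.0,
        gamma1=g1,
        gamma2=g2,
        rss=rss,
        fitted_values=X @ beta,
        used=use,
        status="ok",
        se=se,
        n_used=int(use.sum()),
    )


# ---------------------------------------------------------------------------
# SUVr
# ---------------------------------------------------------------------------

def suvr(tac: TAC, ref_tac: TAC, window: tuple) -> float:
    """Standardised uptake value ratio over a late time window (minutes).

    Uses the frame-duration-weighted mean over frames lying fully inside the
    window, for target and reference independently (their schedules need not
    match).
    """
    w0, w1 = float(window[0]), float(window[1])
    if not w0 < w1:
        raise ConfigurationError("suvr window must satisfy start < end")

    def window_mean(t: TAC) -> float:
        inside = (t.schedule.start_min >= w0 - 1e-9) & (t.schedule.end_min <= w1 + 1e-9)
        if not np.any(inside):
            raise InsufficientDataError(
                f"no frame fully inside SUVr window [{w0}, {w1}] min"
            )
        d = t.schedule.duration_min[inside]
        return float((t.values[inside] * d).sum() / d.sum())

    target = window_mean(tac)
    refv = window_mean(ref_tac)
    if refv == 0.0:
        raise ZeroDivisionError("reference window mean is zero; SUVr undefined")
    return target / refv


# ---------------------------------------------------------------------------
# statsmodels-style model classes
# ---------------------------------------------------------------------------

class KineticModel:
    """Base class: bind data (target TAC, reference input, weights) to a model.

    ``fit()`` returns a :class:`KineticResult`; subclasses add their own
    settings at construction.
    """

    name = "base"

    def __init__(self, tac: TAC, ref, weights: Optional[np.ndarray] = None, **options):
        self.tac = tac
        self.ref = ref
        self.weights = weights
        self.options = options

    def fit(self) -> KineticResult:  # pragma: no cover - abstract
        raise NotImplementedError


class SRTM(KineticModel):
    """Simplified reference tissue model, nonlinear fit of (R1, k2, k2a)."""

    name = "srtm"

    def fit(self) -> KineticResult:
        return srtm_nls(self.tac, self.ref, self.weights, **self.options)


class SRTM2(KineticModel):
    """SRTM with pre-defined reference efflux k2', nonlinear fit of (R1, k2a)."""

    name = "srtm2"

    def __init__(self, tac, ref, k2p, weights=None, **options):
        super().__init__(tac, ref, weights, **options)
        self.k2p = k2p

    def fit(self) -> KineticResult:
        return srtm2_nls(self.tac, self.ref, self.k2p, self.weights, **self.options)


class SRTMBasis(KineticModel):
    """SRTM linearised with basis functions over a k2a grid."""

    name = "srtmb"

    def __init__(self, tac, ref, weights=None, basis: Optional[BasisSet] = None, **basis_options):
        super().__init__(tac, ref, weights)
        self.basis = basis if basis is not None else make_basis(ref, tac.schedule, **basis_options)

    def fit(self) -> KineticResult:
        return srtm_basis(self.tac, self.basis, self.weights)


class SRTM2Basis(KineticModel):
    """SRTM2 (fixed k2') linearised with basis functions."""

    name = "srtm2b"

    def __init__(self, tac, ref, k2p, weights=None, basis: Optional[BasisSet] = None, **basis_options):
        super().__init__(tac, ref, weights)
        self.basis = (
            basis if basis is not None else make_basis(ref, tac.schedule, k2p=k2p, **basis_options)
        )

    def fit(self) -> KineticResult:
        return srtm2_basis(self.tac, self.basis, self.weights)


class SRTMASL(KineticModel):
    """SRTM basis with externally supplied R1 (ASL-derived delivery)."""

    name = "srtm_asl"

    def __init__(self, tac, ref, r1, weights=None, basis: Optional[BasisSet] = None, **basis_options):
        super().__init__(tac, ref, weights)
        self.r1 = r1
        self.basis = basis if basis is not None else make_basis(ref, tac.schedule, **basis_options)

    def fit(self) -> KineticResult:
        return srtm_asl(self.tac, self.ref, self.r1, self.basis, self.weights)


class LoganRef(KineticModel):
    """Logan reference graphical analysis."""

    name = "logan"

    def __init__(self, tac, ref, t_star, weights=None):
        super().__init__(tac, ref, weights)
        self.t_star = t_star

    def fit(self) -> KineticResult:
        return logan_ref(self.tac, self.ref, self.t_star, self.weights)


class LoganRefK2p(KineticModel):
    """Logan reference analysis with pre-defined k2'."""

    name = "logan2"

    def __init__(self, tac, ref, k2p, t_star, weights=None):
        super().__init__(tac, ref, weights)
        self.k2p = k2p
        self.t_star = t_star

    def fit(self) -> KineticResult:
        return logan_ref_k2p(self.tac, self.ref, self.k2p, self.t_star, self.weights)


class MRTM(KineticModel):
    """Ichise multilinear reference tissue model."""

    name = "mrtm"

    def __init__(self, tac, ref, t_star, weights=None):
        super().__init__(tac, ref, weights)
        self.t_star = t_star

    def fit(self) -> KineticResult:
        return mrtm(self.tac, self.ref, self.t_star, self.weights)


class MRTM2(KineticModel):
    """MRTM with pre-defined k2'."""

    name = "mrtm2"

    def __init__(self, tac, ref, k2p, t_star, weights=None):
        super().__init__(tac, ref, weights)
        self.k2p = k2p
        self.t_star = t_star

    def fit(self) -> KineticResult:
        return mrtm2(self.tac, self.ref, self.k2p, self.t_star, self.weights)


MODEL_NAMES = (
    "srtm",
    "srtm2",
    "srtmb",
    "srtm2b",
    "srtm_asl",
    "logan",
    "logan2",
    "mrtm",
    "mrtm2",
    "suvr",
)
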