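"""Frame weighting schemes for kinetic model fitting.

Weights enter every fit as multipliers of the squared residual per frame.
Schemes follow the standard count-statistics variance-model family:

* ``uniform`` — all frames weighted 1 (the default when no weights are given);
* ``frame_duration`` — w_i proportional to the frame duration dt_i;
* ``duration_over_activity`` — w_i proportional to dt_i / C_i, the usual
  approximation to inverse variance for count data (decay-corrected);
* ``user`` — a pre-determined weight vector passed through unchanged.

Duration-based weights are normalised to mean 1 so the RSS magnitude stays
comparable across schemes; model estimates are invariant to any global
rescaling of the weights.  A ``halflife_min`` field is accepted for
compatibility with decayed-count schemes, but on decay-corrected data these
reduce to ``duration_over_activity`` and the field is not otherwise used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .tac import TAC

__all__ = ["WeightSpec", "compute_weights", "SCHEMES"]

SCHEMES = ("uniform", "frame_duration", "duration_over_activity", "user")


@dataclass(frozen=True)
class WeightSpec:
    """Choice of weighting scheme plus its optional inputs."""

    scheme: str = "uniform"
    halflife_min: Optional[float] = None
    values: Optional[Sequence[float]] = None

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"unknown weighting scheme {self.scheme!r}; expected one of {SCHEMES}")
        if self.scheme == "user" and self.values is None:
            raise ConfigurationError("scheme 'user' requires a weight vector")


def compute_weights(spec: WeightSpec, tac: TAC) -> np.ndarray:
    """Per-frame weights (>= 0, finite, not all zero) for the given TAC."""
    n = len(tac)
    if spec.scheme == "uniform":
        return np.ones(n)
    if spec.scheme == "user":
        w = np.asarray(spec.values, dtype=float)
        if w.shape != (n,):
            raise ConfigurationError(f"user weights must have length {n}, got {w.shape}")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ConfigurationError("user weights must be finite and >= 0")
        if not np.any(w > 0):
            raise ConfigurationError("user weights must not be all zero")
        return w
    dt = tac.schedule.duration_min
    if spec.scheme == "frame_duration":
        w = dt.copy()
    else:  # duration_over_activity
        cmax = float(np.max(tac.values))
        eps = 1e-6 * cmax if cmax > 0 else 1e-6
        w = dt / np.maximum(tac.values, eps)
    return w / w.mean()
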