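"""Air-velocity response of the two velocity-aware indices (ET, ETIS).

ET and ETIS are evaluated over a velocity sweep at fixed dry-bulb
temperature and humidity and compared against a still-air winter baseline
(10 °C, 60 % RH, 0 m/s).  A warm-season curve crossing the winter baseline
means the index assigns the same value to two conditions a pig plainly
feels differently — the diagnostic the sweep exists for.

Below 38 °C (the sow surface temperature in ETIS) both indices fall as
velocity rises; above it the ETIS convection term changes sign and the
curve rises instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

from .indices import IndexId, evaluate

__all__ = [
    "WINTER_STATE",
    "VelocityCurve",
    "winter_reference",
    "velocity_curve",
    "find_crossing_velocity",
]

#: Winter baseline condition: (T °C, RH %, v m/s).
WINTER_STATE = (10.0, 60.0, 0.0)

#: Velocity sweep bounds, m/s.
V_RANGE = (0.0, 4.0)

_VELOCITY_IDS = (IndexId.ET, IndexId.ETIS)


def _require_velocity_index(id: IndexId) -> IndexId:
    id = IndexId(id)
    if id not in _VELOCITY_IDS:
        raise ValueError(f"velocity analysis applies to ET/ETIS only, got {id.value}")
    return id


@dataclass(frozen=True)
class VelocityCurve:
    """An index sampled on a strictly increasing velocity grid."""

    id: IndexId
    T: float
    RH: float
    v: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.v) > 0):
            raise ValueError("velocity grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve contains non-finite values")


def winter_reference(id: IndexId) -> float:
    """Index value at the winter baseline (10 °C, 60 %, still air).

    Recomputed from the formula, never hard-coded: ET ≈ 21.21 °C,
    ETIS ≈ 18.56 °C.
    """
    id = _require_velocity_index(id)
    T, RH, v = WINTER_STATE
    return evaluate(id, T, RH, v)


def velocity_curve(
    id: IndexId,
    T: float,
    RH: float,
    v_grid: np.ndarray | None = None,
) -> VelocityCurve:
    """Sample the index over a velocity grid (default 0 to 4 m/s, step 0.01)."""
    id = _require_velocity_index(id)
    if v_grid is None:
        v_grid = np.arange(V_RANGE[0], V_RANGE[1] + 1e-12, 0.01)
    v_grid = np.asarray(v_grid, dtype=float)
    values = np.array([evaluate(id, T, RH, v) for v in v_grid])
    return VelocityCurve(id, T, RH, v_grid, values)


def find_crossing_velocity(
    id: IndexId,
    T: float,
    RH: float,
    reference: float | None = None,
) -> float | None:
    """Velocity at which the curve meets a reference value, or None.

    Bisection on [0, 4] m/s to |Δv| < 1e-6; ``None`` (a valid result, not
    an error) when the curve never reaches the reference — e.g. warm-season
    ETIS curves never descending to the winter baseline.  ``reference``
    defaults to the index's own winter baseline.
    """
    id = _require_velocity_index(id)
    if reference is None:
        reference = winter_reference(id)

    def f(v: float) -> float:
        return evaluate(id, T, RH, v) - reference

    lo, hi = V_RANGE
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        return None
    return float(bisect(f, lo, hi, xtol=1e-8))
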