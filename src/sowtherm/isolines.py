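"""Iso-index lines on the psychrometric plane.

Every index is anchored at the reference state 22 °C / 70 % RH (still air,
standard pressure).  For each relative humidity on a grid the dry-bulb
temperature giving the anchored index value is solved, tracing the locus of
conditions the index declares "equally stressful".  How far that locus
strays from the 22 °C isotherm is the point of the comparison: the
enthalpy, THI8 and BGHI lines climb past 37 °C at dry air (a difference any
animal feels), while the ETIS line stays within about 2 °C.

A slope sign worth knowing: the THI6 line *rises* with humidity — its RH
term is a decreasing function of RH, so temperature must increase to hold
the index constant, the inverse of what heat-stress physiology expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .indices import ETIS_MONOTONE_CAP, IndexId, evaluate
from .psychrometrics import STANDARD_PRESSURE_MMHG, VALID_T_RANGE

__all__ = [
    "REFERENCE_STATE",
    "IsoLine",
    "reference_value",
    "iso_temperature_at",
    "trace_iso_line",
]

#: Anchor condition (T °C, RH %) shared by all twelve iso-lines.
REFERENCE_STATE = (22.0, 70.0)

#: Dry-bulb search bracket, °C.
T_BRACKET = (0.0, 50.0)

#: Residual tolerance on the index value, index units.
INDEX_TOL = 1e-9

#: Pre-scan step for bracketing the root, °C.
_SCAN_STEP = 0.5


def _t_cap(id: IndexId) -> float:
    # ETIS is non-monotone in T at still air above ~36 degC (quartic
    # radiation term); capping plus lowest-root bracketing keeps the
    # physically relevant branch.
    return ETIS_MONOTONE_CAP if IndexId(id) is IndexId.ETIS else T_BRACKET[1]


def reference_value(id: IndexId, Pm: float = STANDARD_PRESSURE_MMHG) -> float:
    """Index value at the 22 °C / 70 % anchor (v = 0 for ET/ETIS)."""
    T, RH = REFERENCE_STATE
    return evaluate(IndexId(id), T, RH, v=0.0, Pm=Pm)


def iso_temperature_at(
    id: IndexId,
    RH: float,
    Pm: float = STANDARD_PRESSURE_MMHG,
) -> float | None:
    """Dry-bulb temperature at which index(T, RH) equals the anchor value.

    The bracket [0, 50] °C (capped at 42 °C for ETIS) is pre-scanned in
    0.5 °C steps and the lowest sign change is refined by bisection, so a
    non-monotone index still yields its physically relevant (coolest) root.
    Returns ``None`` when no root exists in the bracket (a gap in the line).
    """
    id = IndexId(id)
    if not 0.0 <= RH <= 100.0:
        raise ValueError(f"RH must be in [0, 100] %, got {RH!r}")
    target = reference_value(id, Pm)

    def f(T: float) -> float:
        return evaluate(id, T, RH, v=0.0, Pm=Pm) - target

    lo, hi = T_BRACKET[0], _t_cap(id)
    grid = np.arange(lo, hi + 1e-12, _SCAN_STEP)
    prev_T, prev_f = grid[0], f(grid[0])
    if prev_f == 0.0:
        return float(prev_T)
    for T in grid[1:]:
        cur = f(T)
        if cur == 0.0:
            return float(T)
        if prev_f * cur < 0.0:
            root = bisect(f, prev_T, T, xtol=1e-12, rtol=8.9e-16)
            assert abs(f(root)) < max(INDEX_TOL, 1e-9 * abs(target))
            return float(root)
        prev_T, prev_f = T, cur
    return None


@dataclass(frozen=True)
class IsoLine:
    """One traced constant-index line.

    ``points`` has columns ``rh_pct``, ``temp_c`` (NaN where no solution
    exists in the bracket) and ``in_validity`` flagging points where the
    solved temperature leaves the calibration window of the psychrometric
    fits.
    """

    id: IndexId
    reference_value: float
    points: pd.DataFrame

    @property
    def temperature_spread(self) -> float:
        """max − min solved temperature over the grid, °C."""
        t = self.points["temp_c"].dropna()
        return float(t.max() - t.min())


def trace_iso_line(
    id: IndexId,
    rh_grid: np.ndarray | None = None,
    Pm: float = STANDARD_PRESSURE_MMHG,
) -> IsoLine:
    """Trace one iso-index line over an RH grid (default 0–100 %, step 1)."""
    id = IndexId(id)
    if rh_grid is None:
        rh_grid = np.arange(0.0, 101.0, 1.0)
    ref = reference_value(id, Pm)
    lo, hi = VALID_T_RANGE
    rows = []
    for RH in np.asarray(rh_grid, dtype=float):
        T = iso_temperature_at(id, RH, Pm)
        rows.append(
            {
                "rh_pct": RH,
                "temp_c": float("nan") if T is None else T,
                "in_validity": T is not None and lo <= T <= hi,
            }
        )
    return IsoLine(id, ref, pd.DataFrame(rows))
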