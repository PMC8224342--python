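"""Equivalent-temperature-change analysis.

A humidity change can be expressed as the dry-bulb temperature change that
would have the same effect on a given index: hold the index constant,

    index(T1, RH1) = index(T2, RH2),

solve for T2, and report T_equ = T1 − T2.  A positive T_equ means the
humidity rise acts like a temperature rise (the compensating dry-bulb
temperature had to drop).  ET and ETIS carry an air-velocity argument; when
they are compared against the pure temperature–humidity indices the
velocity is fixed at 1 m/s.

The default experiment sweeps T1 ∈ {25, 30, 35, 40} °C with RH rising from
50 % to 60 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.optimize import bisect

from .indices import ETIS_MONOTONE_CAP, IndexId, evaluate
from .psychrometrics import STANDARD_PRESSURE_MMHG

__all__ = [
    "EquivalenceResult",
    "solve_matched_temperature",
    "equivalent_temperature_change",
    "equivalence_table",
    "DEFAULT_TEMPS",
]

DEFAULT_TEMPS = (25.0, 30.0, 35.0, 40.0)

#: Residual tolerance on the held-constant index, in index units.
INDEX_TOL = 1e-9

#: Half-width of the temperature bracket around T1, °C.
BRACKET_HALFWIDTH = 15.0


@dataclass(frozen=True)
class EquivalenceResult:
    """One matched pair: (T1, RH1) and the solved (T2, RH2) at equal index."""

    id: IndexId
    T1: float
    RH1: float
    RH2: float
    v: float
    T2: float
    T_equ: float
    index_value: float


def _bracket(id: IndexId, T1: float) -> tuple[float, float]:
    hi = T1 + BRACKET_HALFWIDTH
    if IndexId(id) is IndexId.ETIS:
        # dETIS/dT turns negative above the cap; keep the bracket monotone
        hi = min(hi, ETIS_MONOTONE_CAP)
    return T1 - BRACKET_HALFWIDTH, hi


def solve_matched_temperature(
    id: IndexId,
    T1: float,
    RH1: float,
    RH2: float,
    v: float = 1.0,
    Pm: float = STANDARD_PRESSURE_MMHG,
) -> float:
    """Dry-bulb temperature T2 with index(T2, RH2) = index(T1, RH1).

    Solved by bisection on [T1 − 15, min(T1 + 15, 42)] °C to an index
    residual below ``INDEX_TOL``; requires the index to be monotone in T on
    the bracket (true for all twelve inside their validity windows).

    Raises
    ------
    ValueError
        If the target index value is not bracketed ("no compensating
        temperature in range").
    """
    id = IndexId(id)
    target = evaluate(id, T1, RH1, v, Pm)
    if RH1 == RH2:
        return float(T1)

    def f(T: float) -> float:
        return evaluate(id, T, RH2, v, Pm) - target

    lo, hi = _bracket(id, T1)
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        raise ValueError(
            f"no compensating temperature in [{lo:g}, {hi:g}] degC for "
            f"{id.value} at T1={T1:g}, RH {RH1:g}->{RH2:g}"
        )
    T2 = bisect(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(f(T2)) < max(INDEX_TOL, 1e-9 * abs(target))
    return float(T2)


def equivalent_temperature_change(
    id: IndexId,
    T1: float,
    RH1: float,
    RH2: float,
    v: float = 1.0,
    Pm: float = STANDARD_PRESSURE_MMHG,
) -> float:
    """T_equ = T1 − T2: the temperature rise equivalent to the RH change."""
    return T1 - solve_matched_temperature(id, T1, RH1, RH2, v, Pm)


def equivalence_table(
    ids: list[IndexId] | None = None,
    temps: list[float] | None = None,
    RH1: float = 50.0,
    RH2: float = 60.0,
    v: float = 1.0,
    Pm: float = STANDARD_PRESSURE_MMHG,
) -> pd.DataFrame:
    """Run the full equivalent-temperature experiment.

    One row per (index, T1); solver failures are flagged in the ``status``
    column rather than dropped.  Defaults reproduce the standard sweep
    (all 12 indices, 25–40 °C, RH 50→60 %, v = 1 m/s).
    """
    ids = list(IndexId) if ids is None else [IndexId(i) for i in ids]
    temps = list(DEFAULT_TEMPS) if temps is None else list(temps)
    rows = []
    for id in ids:
        for T1 in temps:
            ref = evaluate(id, T1, RH1, v, Pm)
            try:
                T2 = solve_matched_temperature(id, T1, RH1, RH2, v, Pm)
                rows.append(
                    {
                        "index": id.value,
                        "T1_c": T1,
                        "rh1_pct": RH1,
                        "rh2_pct": RH2,
                        "vel_ms": v,
                        "T2_c": T2,
                        "T_equ_c": T1 - T2,
                        "index_value": ref,
                        "status": "ok",
                    }
                )
            except ValueError as err:
                rows.append(
                    {
                        "index": id.value,
                        "T1_c": T1,
                        "rh1_pct": RH1,
                        "rh2_pct": RH2,
                        "vel_ms": v,
                        "T2_c": float("nan"),
                        "T_equ_c": float("nan"),
                        "index_value": ref,
                        "status": f"failed: {err}",
                    }
                )
    return pd.DataFrame(rows)
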