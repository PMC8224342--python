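"""The twelve thermal-comfort indices and their heat-stress threshold zones.

Eight temperature–humidity indices (THI1–THI8), the black-globe humidity
index (BGHI), effective temperature (ET), the equivalent temperature index
of sows (ETIS) and moist-air enthalpy (H).  THI1–THI8 and BGHI are
dimensionless, ET and ETIS are in °C, H in kJ/kg.

Two of the indices fold in air velocity (ET, ETIS) and one needs barometric
pressure (H); the rest are pure temperature–humidity functions.  THI4 and
THI6 are Fahrenheit-native: the API always accepts °C and converts
internally.

Formula readings that need stating once:

* ET = T + 0.0015·(RH−50)·T − 1.0·(42 − T)·(v^0.66 − 0.2^0.66).  The
  velocity term is a wind-cooling correction that vanishes at v = 0.2 m/s
  and changes sign at T = 42 °C (air hotter than that heats the animal as
  velocity rises).
* ETIS = T + 0.0006·(RH−50)·T − 0.3132·u^0.6827·(38 − T)
  − 4.79·(1.0086·38 − T) + 4.8957e−8·((38+273.15)⁴ − (T+273.15)⁴),
  i.e. convection around a 38 °C sow body (u^0.6827 power law), a linear
  latent term (1.0086·38 is a product, not an exponent) and a quartic
  grey-body radiation term.
* H = 1.006·T + (RH/Pm)·10^(7.5·T/(273.3+T))·(71.28 + 0.052·T).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

from .psychrometrics import (
    AirState,
    STANDARD_PRESSURE_MMHG,
    black_globe_temperature,
    celsius_to_fahrenheit,
    dew_point_temperature,
    wet_bulb_temperature,
)

__all__ = [
    "IndexId",
    "IndexValue",
    "ThresholdTable",
    "Zone",
    "THRESHOLDS",
    "UNCLASSIFIED",
    "evaluate",
    "compute_index",
    "compute_all",
    "classify",
]

logger = logging.getLogger(__name__)

#: Sow body-surface temperature (°C) baked into the ETIS formula.
SOW_SURFACE_T = 38.0

#: Dry-bulb cap (°C) below which ETIS is monotone increasing in T at the
#: cross-index comparison velocity of 1 m/s; root brackets must stay below it.
ETIS_MONOTONE_CAP = 42.0


class IndexId(str, Enum):
    """Enumeration of the twelve indices."""

    THI1 = "THI1"
    THI2 = "THI2"
    THI3 = "THI3"
    THI4 = "THI4"
    THI5 = "THI5"
    THI6 = "THI6"
    THI7 = "THI7"
    THI8 = "THI8"
    BGHI = "BGHI"
    ET = "ET"
    ETIS = "ETIS"
    H = "H"

    @property
    def uses_velocity(self) -> bool:
        return self in (IndexId.ET, IndexId.ETIS)

    @property
    def uses_pressure(self) -> bool:
        return self is IndexId.H

    @property
    def units(self) -> str:
        if self in (IndexId.ET, IndexId.ETIS):
            return "degC"
        if self is IndexId.H:
            return "kJ/kg"
        return "1"


def _thi1(T: float, RH: float) -> float:
    return T + 0.36 * wet_bulb_temperature(T, RH) + 41.5


def _thi2(T: float, RH: float) -> float:
    return 0.8 * T + RH * (T - 14.4) / 100.0 + 46.4


def _thi3(T: float, RH: float) -> float:
    return 0.65 * T + 0.35 * wet_bulb_temperature(T, RH)


def _thi4(T: float, RH: float) -> float:
    Tf = celsius_to_fahrenheit(T)
    return Tf - (0.55 - 0.0055 * RH) * (Tf - 58.0)


def _thi5(T: float, RH: float) -> float:
    return 0.72 * T + 0.72 * wet_bulb_temperature(T, RH) + 40.6


def _thi6(T: float, RH: float) -> float:
    Tf = celsius_to_fahrenheit(T)
    return Tf - (0.55 * RH / 100.0) * (Tf - 58.0)


def _thi7(T: float, RH: float) -> float:
    return T - (0.55 - 0.0055 * RH) * (T - 14.5)


def _thi8(T: float, RH: float) -> float:
    return 0.27 * T + 1.35 * wet_bulb_temperature(T, RH) + 34.07


def _bghi(T: float, RH: float) -> float:
    return (
        black_globe_temperature(T, RH)
        + 0.36 * dew_point_temperature(T, RH)
        + 41.5
    )


def _et(T: float, RH: float, v: float) -> float:
    return T + 0.0015 * (RH - 50.0) * T - 1.0 * (42.0 - T) * (v**0.66 - 0.2**0.66)


def _etis(T: float, RH: float, u: float) -> float:
    Ts = SOW_SURFACE_T
    return (
        T
        + 0.0006 * (RH - 50.0) * T
        - 0.3132 * u**0.6827 * (Ts - T)
        - 4.79 * (1.0086 * Ts - T)
        + 4.8957e-8 * ((Ts + 273.15) ** 4 - (T + 273.15) ** 4)
    )


def _enthalpy(T: float, RH: float, Pm: float) -> float:
    return 1.006 * T + (RH / Pm) * 10.0 ** (7.5 * T / (273.3 + T)) * (
        71.28 + 0.052 * T
    )


def evaluate(
    id: IndexId,
    T: float,
    RH: float,
    v: float | None = None,
    Pm: float = STANDARD_PRESSURE_MMHG,
) -> float:
    """Evaluate index ``id`` at a raw (T, RH, v, Pm) condition.

    Low-level scalar entry point; :func:`compute_index` is the
    :class:`~sowtherm.psychrometrics.AirState`-based wrapper.

    Raises
    ------
    ValueError
        If the index needs air velocity (ET, ETIS) and ``v`` is None.
    """
    id = IndexId(id)
    if id.uses_velocity:
        if v is None:
            raise ValueError(f"{id.value} requires air velocity v")
        return _et(T, RH, v) if id is IndexId.ET else _etis(T, RH, v)
    if id is IndexId.H:
        return _enthalpy(T, RH, Pm)
    fn = {
        IndexId.THI1: _thi1,
        IndexId.THI2: _thi2,
        IndexId.THI3: _thi3,
        IndexId.THI4: _thi4,
        IndexId.THI5: _thi5,
        IndexId.THI6: _thi6,
        IndexId.THI7: _thi7,
        IndexId.THI8: _thi8,
        IndexId.BGHI: _bghi,
    }[id]
    return fn(T, RH)


@dataclass(frozen=True)
class IndexValue:
    """One evaluated index: identity, value (in ``id.units``) and the state."""

    id: IndexId
    value: float
    state: AirState

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite {self.id.value} value: {self.value!r}")


def compute_index(id: IndexId, state: AirState) -> IndexValue:
    """Evaluate one index at an :class:`AirState`."""
    value = evaluate(IndexId(id), state.T, state.RH, state.v, state.Pm)
    return IndexValue(IndexId(id), value, state)


def compute_all(state: AirState) -> dict[IndexId, IndexValue]:
    """Evaluate every index the state supports.

    ET and ETIS are omitted (with a logged reason) when the state carries
    no air velocity; pressure always has its standard-atmosphere default.
    """
    out: dict[IndexId, IndexValue] = {}
    for id in IndexId:
        if id.uses_velocity and not state.has_velocity:
            logger.info("skipping %s: state has no air velocity", id.value)
            continue
        out[id] = compute_index(id, state)
    return out


# --------------------------------------------------------------------------
# heat-stress threshold zones


UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Zone:
    """Half-open-or-closed interval [lower, upper] with a stress label.

    ``None`` bounds mean unbounded.  ``lower_closed``/``upper_closed`` give
    the printed boundary openness exactly.
    """

    label: str
    lower: float | None
    upper: float | None
    lower_closed: bool = True
    upper_closed: bool = False

    def contains(self, x: float) -> bool:
        if self.lower is not None:
            if x < self.lower or (x == self.lower and not self.lower_closed):
                return False
        if self.upper is not None:
            if x > self.upper or (x == self.upper and not self.upper_closed):
                return False
        return True


ThresholdTable = tuple[Zone, ...]

# Encoded exactly as printed, gaps included (they classify as "unclassified").
THRESHOLDS: dict[IndexId, ThresholdTable] = {
    IndexId.THI1: (
        Zone("thermal comfort", 61, 65, lower_closed=False, upper_closed=True),
        Zone("intermediate", 65, 69, lower_closed=False, upper_closed=True),
        Zone("heat stress", 69, 73, lower_closed=False, upper_closed=True),
    ),
    IndexId.THI2: (
        Zone("suitable", None, 74),
        Zone("mild", 74, 78),
        Zone("moderate", 78, 82),
        Zone("severe", 82, None),
    ),
    # the printed row says "THI2 >= 28" but sits in the THI3 row: a typo.
    IndexId.THI3: (Zone("heat stress", 28, None),),
    IndexId.THI5: (
        Zone("moderate", 75, 78),
        Zone("severe", 83, None),
    ),
    IndexId.THI6: (
        Zone("suitable", None, 74, upper_closed=True),
        Zone("mild", 74, 78, lower_closed=False, upper_closed=True),
        Zone("moderate", 78, 84, lower_closed=False, upper_closed=True),
        Zone("severe", 84, None, lower_closed=False),
    ),
    IndexId.ETIS: (
        Zone("suitable", None, 33.1),
        Zone("mild", 33.1, 34.5),
        Zone("moderate", 34.5, 35.9),
        Zone("severe", 35.9, None),
    ),
}


def classify(id: IndexId, value: float) -> str:
    """Heat-stress zone label for an index value.

    Only THI1, THI2, THI3, THI5, THI6 and ETIS carry published threshold
    tables; the rest raise.  Values falling into a printed gap (e.g. THI5
    between 78 and 83) return ``"unclassified"``.
    """
    id = IndexId(id)
    try:
        table = THRESHOLDS[id]
    except KeyError:
        raise ValueError(f"no thresholds defined for {id.value}") from None
    for zone in table:
        if zone.contains(value):
            return zone.label
    return UNCLASSIFIED
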