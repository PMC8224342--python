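"""Empirical psychrometric conversions used by the thermal-comfort indices.

All four conversions are regression fits against dry-bulb temperature (°C)
and relative humidity (% on a 0–100 scale), not thermodynamic solutions of
the moist-air state equations.  They are calibrated for barn conditions
(roughly 10–46 °C); outside a declared validity window of [-10, 50] °C a
``ValidityWarning`` is emitted and the fit is evaluated anyway.

Notable quirks of the fits, kept deliberately:

* the dew-point fit is linear in RH and returns a finite value at RH = 0
  (0.84·T − 19.2) although the physical dew point diverges to −∞;
* the wet-bulb fit is a single rational expression (degree-3 polynomial
  numerator and denominator) and may exceed the dry-bulb temperature by a
  few tenths of a degree near saturation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "AirState",
    "ValidityWarning",
    "VALID_T_RANGE",
    "STANDARD_PRESSURE_MMHG",
    "dew_point_temperature",
    "wet_bulb_temperature",
    "black_globe_temperature",
    "celsius_to_fahrenheit",
    "fahrenheit_to_celsius",
    "saturation_vapor_pressure",
]

#: Dry-bulb window (°C) inside which the empirical fits are calibrated.
VALID_T_RANGE = (-10.0, 50.0)

#: Standard atmosphere in millimetres of mercury.
STANDARD_PRESSURE_MMHG = 760.0


class ValidityWarning(UserWarning):
    """Raised (as a warning) when a fit is evaluated outside calibration."""


def _check_validity(T: float, RH: float | None = None) -> None:
    lo, hi = VALID_T_RANGE
    if not lo <= T <= hi:
        warnings.warn(
            f"dry-bulb temperature {T:.2f} degC outside the [{lo:g}, {hi:g}] degC "
            "validity window of the empirical psychrometric fits",
            ValidityWarning,
            stacklevel=3,
        )
    if RH is not None and not 0.0 <= RH <= 100.0:
        raise ValueError(f"relative humidity must be in [0, 100] %, got {RH!r}")


def dew_point_temperature(T: float, RH: float) -> float:
    """Dew-point temperature (°C) from the linear empirical fit.

    Tdp = (0.198 + 0.0017·T)·RH + 0.84·T − 19.2
    """
    _check_validity(T, RH)
    return (0.198 + 0.0017 * T) * RH + 0.84 * T - 19.2


def wet_bulb_temperature(T: float, RH: float) -> float:
    """Wet-bulb temperature (°C) from the rational empirical fit.

    The whole 5-term numerator is divided by the whole 6-term denominator.

    Raises
    ------
    ValueError
        If the denominator is not positive (signals input far outside the
        calibration range).
    """
    _check_validity(T, RH)
    num = (
        -5.86154
        + 0.58174 * T
        + 0.1485 * RH
        - 0.00191 * RH**2
        + 1.01768e-5 * RH**3
    )
    den = (
        1.0
        + 0.0036 * T
        - 9.79822e-5 * T**2
        + 9.26824e-7 * T**3
        - 0.00899 * RH
        + 4.38111e-5 * RH**2
    )
    if den <= 0.0:
        raise ValueError(
            f"wet-bulb fit denominator non-positive at T={T!r} degC, RH={RH!r} %"
        )
    return num / den


def saturation_vapor_pressure(T: float) -> float:
    """Saturation vapor pressure (hPa), Magnus-type form used by the globe fit."""
    return 6.105 * math.exp(17.27 * T / (237.7 + T))


def black_globe_temperature(T: float, RH: float) -> float:
    """Black-globe temperature (°C): 0.567·T + 0.393·e + 3.94.

    e is the ambient vapor pressure (RH/100)·6.105·exp(17.27·T/(237.7+T)).
    """
    _check_validity(T, RH)
    e = (RH / 100.0) * saturation_vapor_pressure(T)
    return 0.567 * T + 0.393 * e + 3.94


def celsius_to_fahrenheit(T: float) -> float:
    """°C → °F."""
    return 1.8 * T + 32.0


def fahrenheit_to_celsius(Tf: float) -> float:
    """°F → °C, exact inverse of :func:`celsius_to_fahrenheit`."""
    return (Tf - 32.0) / 1.8


@dataclass(frozen=True)
class AirState:
    """One environmental condition — the argument of every thermal index.

    Parameters
    ----------
    T : float
        Dry-bulb air temperature, °C.
    RH : float
        Relative humidity, % (0–100 scale).
    v : float or None
        Air velocity, m/s (``u`` in the ETIS literature).  ``None`` means
        "not measured"; indices that need it are then unavailable.
    Pm : float
        Barometric pressure, mmHg.  Defaults to the standard atmosphere.
    """

    T: float
    RH: float
    v: float | None = None
    Pm: float = field(default=STANDARD_PRESSURE_MMHG)

    def __post_init__(self) -> None:
        if not 0.0 <= self.RH <= 100.0:
            raise ValueError(f"RH must be in [0, 100] %, got {self.RH!r}")
        if self.v is not None and self.v < 0.0:
            raise ValueError(f"air velocity must be >= 0 m/s, got {self.v!r}")
        if self.Pm <= 0.0:
            raise ValueError(f"barometric pressure must be > 0 mmHg, got {self.Pm!r}")
        _check_validity(self.T)

    @property
    def has_velocity(self) -> bool:
        return self.v is not None
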