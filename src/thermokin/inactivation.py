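"""First-order irreversible thermal-inactivation kinetics.

An enzyme held at a denaturing temperature loses activity following
first-order kinetics,

    ln([Act]_t / [Act]_0) = -k_in * t,

so the inactivation rate constant k_in (min^-1) is the negated slope of
the log residual fraction against time.  Derived stability metrics:

* half-life        t_1/2 = ln 2 / k_in
* decimal reduction time (time to 10% residual activity)
    standard convention:  D = ln 10 / k_in
    compat convention:    D = (R*T in kJ/mol) / k_in — a dimensionally
      irregular form that matches some published stability tables; kept
      as an explicit opt-in, never the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import COMPAT, PhysicalConstants
from .units import Temperature

LN2 = math.log(2.0)
LN10 = math.log(10.0)


class DegenerateFitWarning(UserWarning):
    """A zero-slope (no-decay) series: k_in = 0, derived metrics undefined."""


@dataclass(frozen=True)
class InactivationSeries:
    """Residual-activity fractions over time at one temperature.

    ``fractions[0]`` must be exactly 1 (the t=0 reference); non-positive
    fractions at later times are dropped with a warning before the log
    transform rather than failing the analysis.
    """

    temperature: Temperature
    times: tuple[float, ...]  # minutes, ascending from 0
    fractions: tuple[float, ...]
    ph: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fracs = np.asarray(self.fractions, dtype=float)
        if times.size != fracs.size:
            raise ValueError("times and fractions lengths differ")
        if times.size < 1 or times[0] != 0.0:
            raise ValueError("series must start at t = 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not math.isclose(fracs[0], 1.0, rel_tol=0, abs_tol=1e-12):
            raise ValueError("fraction at t = 0 must be 1")
        if np.any(fracs[1:] <= 0):
            keep = np.concatenate(([True], fracs[1:] > 0))
            warnings.warn(
                "dropping non-positive residual fractions before log transform",
                UserWarning,
                stacklevel=2,
            )
            object.__setattr__(self, "times", tuple(times[keep]))
            object.__setattr__(self, "fractions", tuple(fracs[keep]))
        else:
            object.__setattr__(self, "times", tuple(times))
            object.__setattr__(self, "fractions", tuple(fracs))


@dataclass(frozen=True)
class InactivationFit:
    """Fitted first-order inactivation at one temperature."""

    temperature: Temperature
    kin: float  # min^-1
    kin_stderr: float
    r_squared: float
    t_half: float  # min
    d_value: float  # min
    d_mode: str  # "standard" or "compat"
    intercept: float = 0.0  # of the ln-fraction fit (0 when through origin)


def half_life(kin: float) -> float:
    """t_1/2 = ln 2 / k_in, minutes for k_in in min^-1."""
    if kin <= 0:
        raise ValueError(f"k_in must be positive, got {kin}")
    return LN2 / kin


def d_value(
    kin: float,
    T: Temperature | None = None,
    mode: str = "standard",
    constants: PhysicalConstants = COMPAT,
) -> float:
    """Decimal reduction time.

    ``standard``: ln 10 / k_in (time to 10% residual activity under
    first-order decay).  ``compat``: (R*T in kJ/mol) / k_in, the
    convention found in some printed stability tables; requires ``T``.
    """
    if kin <= 0:
        raise ValueError(f"k_in must be positive, got {kin}")
    if mode == "standard":
        return LN10 / kin
    if mode == "compat":
        if T is None:
            raise ValueError("compat D value requires a temperature")
        return constants.R_kJ * T.kelvin / kin
    raise ValueError(f"unknown D-value mode {mode!r}")


def fit_first_order(
    series: InactivationSeries,
    intercept_mode: str = "through_origin",
    d_mode: str = "standard",
    constants: PhysicalConstants = COMPAT,
) -> InactivationFit:
    """Fit ln(fraction) = -k_in * t by ordinary least squares.

    ``through_origin`` (default) forces the intercept to 0, as the
    first-order law implies; ``free`` estimates the intercept too (a
    diagnostic for mis-specified [Act]_0).  r^2 is computed on the
    transformed (log) data — uncentred for the through-origin fit.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.log(np.asarray(series.fractions, dtype=float))

    if intercept_mode == "through_origin":
        if t.size < 2:
            raise ValueError("need at least two time points")
        sxx = float(np.sum(t * t))
        if sxx == 0:
            raise ValueError("time grid has no spread")
        slope = float(np.sum(t * y)) / sxx
        resid = y - slope * t
        dof = max(t.size - 1, 1)
        stderr = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
        sst = float(np.sum(y**2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        intercept = 0.0
    elif intercept_mode == "free":
        if t.size < 3:
            raise ValueError("free-intercept fit needs at least three points")
        (slope, intercept), cov = np.polyfit(t, y, 1, cov=True)
        slope = float(slope)
        intercept = float(intercept)
        stderr = math.sqrt(float(cov[0, 0]))
        resid = y - (slope * t + intercept)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    else:
        raise ValueError(f"unknown intercept mode {intercept_mode!r}")

    kin = -slope
    if kin <= 0:
        warnings.warn(
            "non-positive inactivation rate (no measurable decay); "
            "half-life and D value are undefined",
            DegenerateFitWarning,
            stacklevel=2,
        )
        return InactivationFit(
            temperature=series.temperature,
            kin=max(kin, 0.0),
            kin_stderr=stderr,
            r_squared=r2,
            t_half=math.nan,
            d_value=math.nan,
            d_mode=d_mode,
            intercept=intercept,
        )
    return InactivationFit(
        temperature=series.temperature,
        kin=kin,
        kin_stderr=stderr,
        r_squared=r2,
        t_half=half_life(kin),
        d_value=d_value(kin, series.temperature, d_mode, constants),
        d_mode=d_mode,
        intercept=intercept,
    )


def inactivation_table(
    series_by_temperature: Sequence[InactivationSeries],
    intercept_mode: str = "through_origin",
    d_mode: str = "standard",
    constants: PhysicalConstants = COMPAT,
) -> list[InactivationFit]:
    """Fit every temperature series; one fit per temperature, sorted by T."""
    if not series_by_temperature:
        raise ValueError("no inactivation series supplied")
    temps = [s.temperature.celsius for s in series_by_temperature]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures in inactivation panel")
    fits = [
        fit_first_order(s, intercept_mode, d_mode, constants)
        for s in sorted(series_by_temperature, key=lambda s: s.temperature.celsius)
    ]
    return fits


def fits_to_frame(fits: Sequence[InactivationFit]) -> pd.DataFrame:
    """Tabulate per-temperature fits (k_in, t_1/2, D)."""
    return pd.DataFrame(
        {
            "temperature_C": [f.temperature.celsius for f in fits],
            "kin_per_min": [f.kin for f in fits],
            "kin_stderr": [f.kin_stderr for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "t_half_min": [f.t_half for f in fits],
            "d_value_min": [f.d_value for f in fits],
            "d_mode": [f.d_mode for f in fits],
        }
    )
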