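"""Arrhenius and Eyring analyses for catalysis and thermal inactivation.

Rate constants measured across temperature are converted into activation
energies and transition-state thermodynamic parameters:

* Arrhenius:  ln k = ln A - Ea/(R*T); Ea from the slope of ln k vs 1/T.
* Eyring:     k = (kB*T/h) * exp(-dG/(R*T)), giving
              dG = -R*T*ln(k*h/(kB*T));
              dH and dS from the slope/intercept of ln(k/T) vs 1/T.
* dH = Ea - R*T;  dS = (dH - dG)/T;  dG = dH - T*dS (Gibbs-Helmholtz
  identities used to cross-derive whichever member is missing).

Rate-constant units are explicit tags and are used as-is: the Eyring
expression is unit-sensitive, and converting k from min^-1 to s^-1
shifts dG by exactly R*T*ln(60).  Catalytic quantities are conventionally
analysed with kcat in s^-1; inactivation tables in this package follow
the min^-1 convention of residual-activity time courses measured in
minutes (the ``compat`` table convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import CODATA, COMPAT, PhysicalConstants
from .inactivation import InactivationFit
from .mm_kinetics import MMResult, binding_free_energies
from .units import Temperature

RATE_UNITS = ("1/s", "1/min")


@dataclass(frozen=True)
class ArrheniusFit:
    """Result of an Arrhenius regression of ln k on 1/T."""

    Ea: float  # kJ/mol
    lnA: float  # intercept
    slope: float  # K
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ThermoRecord:
    """Transition-state parameters at one temperature."""

    T: Temperature
    dH: float  # kJ/mol
    dG: float  # kJ/mol
    dS: float  # J/(mol K), signed
    rate_constant: float
    rate_unit: str
    kind: str  # "activation" or "inactivation"


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst if sst > 0 else 1.0
    return float(slope), float(intercept), r2


def arrhenius_fit(
    temperatures: Sequence[Temperature],
    rate_constants: Sequence[float],
    unit: str = "1/min",
    constants: PhysicalConstants = CODATA,
) -> ArrheniusFit:
    """Activation energy from OLS of ln k against 1/T; Ea = -slope*R."""
    if unit not in RATE_UNITS:
        raise ValueError(f"rate unit must be one of {RATE_UNITS}")
    k = np.asarray(rate_constants, dtype=float)
    tk = np.asarray([t.kelvin for t in temperatures], dtype=float)
    if k.size != tk.size:
        raise ValueError("temperatures and rate constants lengths differ")
    if k.size < 2 or len(set(tk)) < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any(k <= 0):
        raise ValueError("rate constants must be positive")
    slope, intercept, r2 = _ols(1.0 / tk, np.log(k))
    return ArrheniusFit(
        Ea=-slope * constants.R / 1000.0,
        lnA=intercept,
        slope=slope,
        r_squared=r2,
        n_points=int(k.size),
    )


def enthalpy_of_activation(
    Ea: float, T: Temperature, constants: PhysicalConstants = CODATA
) -> float:
    """dH = Ea - R*T (kJ/mol)."""
    return Ea - constants.R_kJ * T.kelvin


def gibbs_from_rate(
    k: float,
    unit: str,
    T: Temperature,
    constants: PhysicalConstants = CODATA,
) -> float:
    """Eyring free energy of activation, dG = -R*T*ln(k*h/(kB*T)) in kJ/mol.

    The rate constant is used in its declared unit with no silent
    conversion — the unit tag is mandatory precisely because the result
    depends on it (by R*T*ln 60 between min^-1 and s^-1).
    """
    if unit not in RATE_UNITS:
        raise ValueError(f"rate unit must be one of {RATE_UNITS}, got {unit!r}")
    if k <= 0:
        raise ValueError("rate constant must be positive")
    ratio = k * constants.h / (constants.kB * T.kelvin)
    return -constants.R_kJ * T.kelvin * math.log(ratio)


def entropy_from_HG(dH: float, dG: float, T: Temperature) -> float:
    """dS = (dH - dG)/T in J/(mol K); the sign is preserved."""
    return 1000.0 * (dH - dG) / T.kelvin


def gibbs_from_HS(dH: float, dS: float, T: Temperature) -> float:
    """dG = dH - T*dS (dS in J/(mol K), result kJ/mol)."""
    return dH - T.kelvin * dS / 1000.0


def eyring_fit(
    temperatures: Sequence[Temperature],
    rate_constants: Sequence[float],
    unit: str = "1/s",
    constants: PhysicalConstants = CODATA,
) -> dict[str, float]:
    """dH and dS from OLS of ln(k/T) on 1/T.

    dH = -slope*R (kJ/mol); dS = R*(intercept - ln(kB/h)) in J/(mol K).
    """
    if unit not in RATE_UNITS:
        raise ValueError(f"rate unit must be one of {RATE_UNITS}")
    k = np.asarray(rate_constants, dtype=float)
    tk = np.asarray([t.kelvin for t in temperatures], dtype=float)
    if k.size < 2 or len(set(tk)) < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any(k <= 0):
        raise ValueError("rate constants must be positive")
    slope, intercept, r2 = _ols(1.0 / tk, np.log(k / tk))
    dh = -slope * constants.R / 1000.0
    ds = constants.R * (intercept - math.log(constants.kB / constants.h))
    return {"dH": dh, "dS": ds, "r_squared": r2}


def _tag(value: float, unit: str, method: str, mode: str) -> dict:
    return {"value": value, "unit": unit, "method": method, "mode": mode}


def activation_summary(
    mm: MMResult,
    T_opt: Temperature,
    mode: str = "strict",
    *,
    Ea: float | None = None,
    rate_by_temperature: tuple[Sequence[Temperature], Sequence[float]] | None = None,
    dH_override: float | None = None,
    dS_override: float | None = None,
    kcat_override: float | None = None,
    efficiency_override: float | None = None,
    constants: PhysicalConstants | None = None,
) -> dict[str, dict]:
    """Assemble a catalytic-activation summary table.

    Ea comes from an Arrhenius fit of ``rate_by_temperature`` or is
    supplied directly.  In ``strict`` mode dH = Ea - R*T, dG is the
    Eyring free energy of kcat (s^-1) and dS = (dH - dG)/T.  In
    ``compat`` mode the route is reversed to match published tables that
    report via the Gibbs-Helmholtz identity: dG = dH - T*dS with a
    signed dS, using any supplied overrides for dH/dS/kcat/efficiency
    (printed table values that are not internally derivable are treated
    as inputs).  Every field carries unit and derivation tags.
    """
    if mode not in ("strict", "compat"):
        raise ValueError(f"unknown mode {mode!r}")
    consts = constants if constants is not None else (COMPAT if mode == "compat" else CODATA)
    if Ea is None:
        if rate_by_temperature is None:
            raise ValueError("supply Ea or rate_by_temperature for the Arrhenius fit")
        temps, rates = rate_by_temperature
        Ea = arrhenius_fit(temps, rates, "1/s", consts).Ea
        ea_method = "arrhenius: Ea = -slope(ln k vs 1/T) * R"
    else:
        ea_method = "supplied"
    kcat = kcat_override if kcat_override is not None else mm.kcat
    efficiency = (
        efficiency_override if efficiency_override is not None else mm.efficiency
    )
    out: dict[str, dict] = {
        "Vmax": _tag(mm.Vmax, "U/mg", "nonlinear MM fit", mode),
        "Km": _tag(mm.Km, "mM", "nonlinear MM fit", mode),
        "Ka": _tag(mm.Ka, "1/mM", "Ka = 1/Km", mode),
        "Ea": _tag(Ea, "kJ/mol", ea_method, mode),
    }
    if kcat is not None:
        out["kcat"] = _tag(kcat, "1/s", "kcat = Vmax*1e-6*MW/60", mode)
    if efficiency is not None:
        out["efficiency"] = _tag(efficiency, "1/(M*s)", "kcat/Km, Km in M", mode)

    dh = dH_override if dH_override is not None else enthalpy_of_activation(Ea, T_opt, consts)
    dh_method = "supplied" if dH_override is not None else "dH = Ea - R*T"
    out["dH"] = _tag(dh, "kJ/mol", dh_method, mode)

    if mode == "strict":
        if kcat is None:
            raise ValueError("strict mode needs kcat (supply a molecular weight)")
        dg = gibbs_from_rate(kcat, "1/s", T_opt, consts)
        ds = entropy_from_HG(dh, dg, T_opt)
        out["dG"] = _tag(dg, "kJ/mol", "eyring: dG = -R*T*ln(k*h/(kB*T))", mode)
        out["dS"] = _tag(ds, "J/(mol*K)", "dS = (dH - dG)/T", mode)
    else:
        if dS_override is None:
            raise ValueError("compat mode needs a signed dS")
        dg = gibbs_from_HS(dh, dS_override, T_opt)
        out["dS"] = _tag(dS_override, "J/(mol*K)", "supplied (signed)", mode)
        out["dG"] = _tag(dg, "kJ/mol", "dG = dH - T*dS", mode)

    if kcat is not None:
        bfe = binding_free_energies(
            kcat, mm.Km, T_opt, mode=mode,
            efficiency_M_s=efficiency, constants=consts,
        )
        sign = "-" if mode == "strict" else "+"
        out["dG_ES"] = _tag(bfe["dG_ES"], "kJ/mol", "dG_ES = -R*T*ln(1/Km), Km in M", mode)
        out["dG_ET"] = _tag(bfe["dG_ET"], "kJ/mol", f"dG_ET = {sign}R*T*ln(kcat/Km)", mode)
    return out


def inactivation_thermo_table(
    fits: Sequence[InactivationFit],
    Ea_in: float | None = None,
    constants: PhysicalConstants = COMPAT,
) -> pd.DataFrame:
    """Per-temperature inactivation thermodynamics.

    For each fitted temperature: k_in, t_1/2, D, dH = Ea - R*T, the
    Eyring dG of k_in (in min^-1, the unit of the underlying time
    course) and dS = (dH - dG)/T.  ``Ea_in`` may be supplied (e.g. read
    off an external Arrhenius plot) or is fitted from the k_in values.
    """
    if not fits:
        raise ValueError("no inactivation fits supplied")
    fits = sorted(fits, key=lambda f: f.temperature.celsius)
    if Ea_in is None:
        if len(fits) < 2:
            raise ValueError("need >=2 temperatures to fit Ea")
        Ea_in = arrhenius_fit(
            [f.temperature for f in fits], [f.kin for f in fits], "1/min", constants
        ).Ea
    rows = []
    for f in fits:
        if f.kin <= 0:
            raise ValueError(
                f"degenerate fit at {f.temperature.celsius} degC (kin <= 0)"
            )
        dh = enthalpy_of_activation(Ea_in, f.temperature, constants)
        dg = gibbs_from_rate(f.kin, "1/min", f.temperature, constants)
        ds = entropy_from_HG(dh, dg, f.temperature)
        rows.append(
            {
                "temperature_C": f.temperature.celsius,
                "kin_per_min": f.kin,
                "t_half_min": f.t_half,
                "d_value_min": f.d_value,
                "d_mode": f.d_mode,
                "Ea_kJ_mol": Ea_in,
                "dH_kJ_mol": dh,
                "dG_kJ_mol": dg,
                "dS_J_mol_K": ds,
            }
        )
    return pd.DataFrame(rows)


def thermo_records_from_table(table: pd.DataFrame, kind: str = "inactivation") -> list[ThermoRecord]:
    """Convert a thermodynamics table into typed records."""
    return [
        ThermoRecord(
            T=Temperature(row["temperature_C"]),
            dH=row["dH_kJ_mol"],
            dG=row["dG_kJ_mol"],
            dS=row["dS_J_mol_K"],
            rate_constant=row["kin_per_min"],
            rate_unit="1/min",
            kind=kind,
        )
        for _, row in table.iterrows()
    ]
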