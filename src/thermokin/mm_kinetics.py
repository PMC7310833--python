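"""Michaelis-Menten estimation and catalytic-efficiency derivations.

The hyperbolic rate law v = Vmax*S/(Km+S) is fitted by nonlinear least
squares on the raw replicate points (no Lineweaver-Burk linearisation).
From the fitted parameters the module derives the turnover number kcat,
the catalytic efficiency kcat/Km, the association constant Ka = 1/Km and
the transition-state binding free energies

    dG_ES = -R*T*ln(Ki),        Ki = 1/Km (Km in molar)   [strict]
    dG_ET = -R*T*ln(kcat/Km)                              [strict]

``compat`` mode evaluates dG_ET with the opposite sign, +R*T*ln(kcat/Km)
with the efficiency supplied in M^-1 s^-1 — the sign convention under
which some published tables report a negative value for an efficiency
below 1 M^-1 s^-1.  The two modes are exact negations of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import CODATA, PhysicalConstants
from .units import Temperature


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries solver diagnostics."""


@dataclass(frozen=True)
class RateCurve:
    """Initial rates against substrate concentration, replicates preserved.

    ``substrate_mM`` and ``rate`` are aligned point-by-point; replicate
    measurements simply repeat the concentration.  ``replicate`` is an
    optional parallel index used only for bookkeeping.
    """

    substrate_mM: tuple[float, ...]
    rate: tuple[float, ...]  # U/mg
    replicate: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_mM, dtype=float)
        v = np.asarray(self.rate, dtype=float)
        if s.size != v.size:
            raise ValueError("substrate and rate lengths differ")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be positive")
        if self.replicate is not None and len(self.replicate) != s.size:
            raise ValueError("replicate index length differs")
        object.__setattr__(self, "substrate_mM", tuple(s))
        object.__setattr__(self, "rate", tuple(v))

    def means(self) -> "RateCurve":
        """Collapse replicates to per-concentration mean rates."""
        df = pd.DataFrame({"s": self.substrate_mM, "v": self.rate})
        agg = df.groupby("s", sort=True)["v"].mean()
        return RateCurve(tuple(agg.index), tuple(agg.values))

    @property
    def n_distinct(self) -> int:
        return len(set(self.substrate_mM))


@dataclass(frozen=True)
class MMResult:
    """Fitted Michaelis-Menten parameters and derived quantities."""

    Km: float  # mM
    Vmax: float  # U/mg
    Km_stderr: float
    Vmax_stderr: float
    ssr: float
    kcat: float | None = None  # s^-1, requires a molecular weight
    efficiency: float | None = None  # M^-1 s^-1
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.Vmax <= 0:
            raise ValueError("Km and Vmax must be positive")

    @property
    def Ka(self) -> float:
        """Association constant 1/Km (mM^-1)."""
        return 1.0 / self.Km

    def rate_at(self, s_mM: float) -> float:
        return self.Vmax * s_mM / (self.Km + s_mM)


def michaelis_menten(s, Vmax, Km):
    """v = Vmax*S/(Km+S); vectorised model function."""
    return Vmax * np.asarray(s, dtype=float) / (Km + np.asarray(s, dtype=float))


def _initial_guess(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Vmax0 = max observed rate; Km0 = S interpolated at half Vmax0."""
    vmax0 = float(v.max())
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    half = vmax0 / 2.0
    km0 = float(np.interp(half, v_sorted, s_sorted)) if v_sorted.size > 1 else s_sorted[0]
    if km0 <= 0:
        km0 = float(np.median(s))
    return vmax0, km0


def fit_mm(
    curve: RateCurve,
    use_means: bool = False,
    mw_g_mol: float | None = None,
) -> MMResult:
    """Fit v = Vmax*S/(Km+S) by nonlinear least squares.

    By default the fit runs on all replicate points, preserving the
    implicit weighting by replication; ``use_means`` fits per-
    concentration means instead.  If a molecular weight is given, kcat
    and kcat/Km are derived from the fitted Vmax.
    """
    if curve.n_distinct < 3:
        raise ValueError("need at least three distinct substrate concentrations")
    data = curve.means() if use_means else curve
    s = np.asarray(data.substrate_mM, dtype=float)
    v = np.asarray(data.rate, dtype=float)
    vmax0, km0 = _initial_guess(s, v)
    try:
        popt, pcov = curve_fit(
            michaelis_menten,
            s,
            v,
            p0=(vmax0, km0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=500 * (s.size + 2),
        )
    except RuntimeError as exc:  # pragma: no cover - solver pathologies
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    resid = v - michaelis_menten(s, vmax, km)
    ssr = float(np.sum(resid**2))
    perr = np.sqrt(np.diag(pcov))
    kcat = efficiency = None
    if mw_g_mol is not None:
        kcat = kcat_from_vmax(vmax, mw_g_mol)
        efficiency = catalytic_efficiency(kcat, km)
    return MMResult(
        Km=km,
        Vmax=vmax,
        Km_stderr=float(perr[1]),
        Vmax_stderr=float(perr[0]),
        ssr=ssr,
        kcat=kcat,
        efficiency=efficiency,
        n_points=int(s.size),
    )


def kcat_from_vmax(Vmax: float, mw_g_mol: float) -> float:
    """Turnover number (s^-1) from Vmax in umol min^-1 mg^-1.

    Convention: kcat = Vmax * 1e-6 * MW / 60 (micromoles of product to
    moles, minutes to seconds, enzyme amount normalised through its
    molar mass).  The enzyme-mass basis of the printed unit is the
    package's fixed convention; see the methods note.
    """
    if Vmax <= 0 or mw_g_mol <= 0:
        raise ValueError("Vmax and molecular weight must be positive")
    return Vmax * 1e-6 * mw_g_mol / 60.0


def catalytic_efficiency(kcat: float, Km_mM: float) -> float:
    """kcat/Km in M^-1 s^-1 (Km converted from mM to molar)."""
    if kcat <= 0 or Km_mM <= 0:
        raise ValueError("kcat and Km must be positive")
    return kcat / (Km_mM * 1e-3)


def binding_free_energies(
    kcat: float,
    Km_mM: float,
    T: Temperature,
    mode: str = "strict",
    efficiency_M_s: float | None = None,
    constants: PhysicalConstants = CODATA,
) -> dict[str, float]:
    """Free energies of substrate binding and transition-state formation.

    strict:
        dG_ES = -R*T*ln(1/Km) with Km in molar;
        dG_ET = -R*T*ln(kcat/Km) with the efficiency in M^-1 s^-1.
    compat:
        dG_ET = +R*T*ln(kcat/Km) — the sign convention of some published
        tables; dG_ES as in strict.  dG_ET(strict) = -dG_ET(compat).

    ``efficiency_M_s`` overrides the internally derived kcat/Km (useful
    when reproducing a table whose printed efficiency is not consistent
    with its printed kcat and Km).  Returns kJ/mol values plus
    Ka = 1/Km in mM^-1.
    """
    if mode not in ("strict", "compat"):
        raise ValueError(f"unknown mode {mode!r}")
    if kcat <= 0 or Km_mM <= 0:
        raise ValueError("kcat and Km must be positive")
    rt_kj = constants.R_kJ * T.kelvin
    km_M = Km_mM * 1e-3
    ki = 1.0 / km_M
    eff = efficiency_M_s if efficiency_M_s is not None else kcat / km_M
    if eff <= 0:
        raise ValueError("efficiency must be positive")
    dg_es = -rt_kj * math.log(ki)
    dg_et = -rt_kj * math.log(eff)
    if mode == "compat":
        dg_et = -dg_et
    return {"dG_ES": dg_es, "dG_ET": dg_et, "Ka": 1.0 / Km_mM}


def read_rate_curve(path) -> RateCurve:
    """Read a rate-curve CSV: substrate_mM, rate, replicate."""
    df = pd.read_csv(path)
    rep = (
        tuple(int(r) for r in df["replicate"]) if "replicate" in df.columns else None
    )
    return RateCurve(
        substrate_mM=tuple(float(s) for s in df["substrate_mM"]),
        rate=tuple(float(v) for v in df["rate"]),
        replicate=rep,
    )
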