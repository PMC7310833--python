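"""Seeded synthetic assay data with stored ground truth.

Generates every input class the analysis consumes, with the statistical
structure the methods assume:

* hyperbolic Michaelis-Menten rate curves with additive Gaussian noise
  (SD a fixed fraction of Vmax, truncated at zero);
* exponential first-order residual-activity decays whose rate constant
  follows an Arrhenius law across a 60-100 degC panel, with
  multiplicative lognormal (default) or additive Gaussian noise;
* replicate effector panels drawn around stated relative activities;
* a purification step table (deterministic accounting, no noise).

Defaults mirror the bench design of a thermostable protease
characterisation: casein substrate from 10 to 70 mM in triplicate,
120 min time courses sampled every 10 min, and a reference inactivation
rate of 2.10e-3 min^-1 at the 60 degC activity optimum.

A single integer seed drives one deterministic stream per dataset
(fixed sub-seed offsets), and every generated bundle ships a
:class:`TruthBundle` whose derived quantities (t_1/2, D, dH, dG, dS per
temperature) are computed in closed form from the generating parameters.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import inactivation as _inact
from . import thermodynamics as _thermo
from .constants import COMPAT, PhysicalConstants
from .mm_kinetics import RateCurve
from .inactivation import InactivationSeries
from .units import Temperature

# Sub-seed offsets: one independent stream per dataset class.
_MM_STREAM = 1
_INACT_STREAM = 2
_EFFECTOR_STREAM = 3


class MMConfig(BaseModel):
    Km: float = 13.72  # mM
    Vmax: float = 2.657  # U/mg
    s_grid: list[float] = Field(default=[10, 20, 30, 40, 50, 60, 70])  # mM
    replicates: int = 3
    noise_sd: float = 0.02  # fraction of Vmax

    @model_validator(mode="after")
    def _check(self):
        if self.Km <= 0 or self.Vmax <= 0:
            raise ValueError("Km and Vmax must be positive")
        if any(s <= 0 for s in self.s_grid) or len(self.s_grid) < 3:
            raise ValueError("substrate grid must be positive with >=3 points")
        if self.replicates < 1 or self.noise_sd < 0:
            raise ValueError("replicates >= 1 and noise_sd >= 0 required")
        return self


class InactivationConfig(BaseModel):
    Ea: float = 50.31  # kJ/mol
    kin_ref: float = 2.10e-3  # min^-1 at T_ref
    T_ref_K: float = 333.15
    temperatures_C: list[float] = Field(default=[60, 70, 80, 90, 100])
    time_grid: list[float] = Field(default=list(range(0, 130, 10)))  # min
    replicates: int = 3  # assays run in triplicate at each time point
    noise_model: Literal["lognormal", "gaussian"] = "lognormal"
    noise_sd: float = 0.02

    @model_validator(mode="after")
    def _check(self):
        if self.kin_ref <= 0 or self.T_ref_K <= 0:
            raise ValueError("kin_ref and T_ref must be positive")
        if not self.temperatures_C:
            raise ValueError("at least one temperature required")
        if self.time_grid[0] != 0 or any(
            b <= a for a, b in zip(self.time_grid, self.time_grid[1:])
        ):
            raise ValueError("time grid must start at 0 and increase")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        return self

    def kin_at(self, T_K: float, constants: PhysicalConstants = COMPAT) -> float:
        """Arrhenius law: kin(T) = kin_ref * exp(-Ea/R * (1/T - 1/T_ref))."""
        return self.kin_ref * math.exp(
            -self.Ea * 1000.0 / constants.R * (1.0 / T_K - 1.0 / self.T_ref_K)
        )


class EffectorTruth(BaseModel):
    name: str
    effector_class: Literal["metal_ion", "organic_solvent", "inhibitor", "surfactant"]
    concentration: float = 1.0
    concentration_unit: str = "% v/v"
    true_relative: float  # percent of control
    sd: float  # percent of control


class EffectorConfig(BaseModel):
    control_activity: float = 1.0  # arbitrary U/mg
    replicates: int = 3
    truths: list[EffectorTruth] = Field(
        default=[
            EffectorTruth(name="Tween 20", effector_class="surfactant",
                          true_relative=415.7, sd=5.0),
            EffectorTruth(name="Tween 80", effector_class="surfactant",
                          true_relative=488.7, sd=7.8),
            EffectorTruth(name="SDS", effector_class="surfactant",
                          true_relative=100.0, sd=1.7),
            EffectorTruth(name="beta-mercaptoethanol", effector_class="organic_solvent",
                          true_relative=150.6, sd=2.3),
            EffectorTruth(name="methanol", effector_class="organic_solvent",
                          true_relative=120.0, sd=1.8),
            EffectorTruth(name="PMSF", effector_class="inhibitor",
                          true_relative=79.3, sd=3.4),
            EffectorTruth(name="EDTA", effector_class="inhibitor",
                          true_relative=97.8, sd=2.2),
        ]
    )


class PurificationStepConfig(BaseModel):
    step: str
    volume_ml: float
    total_activity_U: float
    total_protein_mg: float


class PurificationConfig(BaseModel):
    steps: list[PurificationStepConfig] = Field(
        default=[
            PurificationStepConfig(step="Crude extract", volume_ml=50,
                                   total_activity_U=14.1, total_protein_mg=49.2),
            PurificationStepConfig(step="Ni-NTA", volume_ml=4,
                                   total_activity_U=12.4, total_protein_mg=0.7),
            PurificationStepConfig(step="Thermal shock", volume_ml=4,
                                   total_activity_U=10.3, total_protein_mg=0.8),
        ]
    )


class GeneratorConfig(BaseModel):
    seed: int
    mm: MMConfig = Field(default_factory=MMConfig)
    inactivation: InactivationConfig = Field(default_factory=InactivationConfig)
    effectors: EffectorConfig = Field(default_factory=EffectorConfig)
    purification: PurificationConfig = Field(default_factory=PurificationConfig)


class TruthBundle(BaseModel):
    """Generating parameters plus their closed-form derived quantities."""

    config: GeneratorConfig
    kin_by_temperature: dict[str, float]
    t_half_by_temperature: dict[str, float]
    d_value_by_temperature: dict[str, float]  # standard convention ln10/kin
    dH_by_temperature: dict[str, float]
    dG_by_temperature: dict[str, float]
    dS_by_temperature: dict[str, float]

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def make_truth(config: GeneratorConfig, constants: PhysicalConstants = COMPAT) -> TruthBundle:
    """Closed-form truths for the inactivation panel of ``config``."""
    kin, th, dv, dh, dg, ds = {}, {}, {}, {}, {}, {}
    for tc in config.inactivation.temperatures_C:
        T = Temperature(tc)
        key = f"{tc:g}"
        k = config.inactivation.kin_at(T.kelvin, constants)
        kin[key] = k
        th[key] = _inact.half_life(k)
        dv[key] = _inact.d_value(k, T, "standard")
        dh[key] = _thermo.enthalpy_of_activation(config.inactivation.Ea, T, constants)
        dg[key] = _thermo.gibbs_from_rate(k, "1/min", T, constants)
        ds[key] = _thermo.entropy_from_HG(dh[key], dg[key], T)
    return TruthBundle(
        config=config,
        kin_by_temperature=kin,
        t_half_by_temperature=th,
        d_value_by_temperature=dv,
        dH_by_temperature=dh,
        dG_by_temperature=dg,
        dS_by_temperature=ds,
    )


def simulate_mm(config: GeneratorConfig) -> tuple[RateCurve, TruthBundle]:
    """Hyperbolic rate curve with additive Gaussian noise, truncated at 0."""
    c = config.mm
    rng = _rng(config.seed, _MM_STREAM)
    s_all, v_all, rep_all = [], [], []
    for rep in range(c.replicates):
        for s in c.s_grid:
            v = c.Vmax * s / (c.Km + s)
            if c.noise_sd > 0:
                v += rng.normal(0.0, c.noise_sd * c.Vmax)
            s_all.append(float(s))
            v_all.append(max(v, 0.0))
            rep_all.append(rep + 1)
    curve = RateCurve(tuple(s_all), tuple(v_all), tuple(rep_all))
    return curve, make_truth(config)


def _inactivation_replicates(
    config: GeneratorConfig,
) -> list[tuple[Temperature, np.ndarray, np.ndarray]]:
    """Per-temperature (T, times, replicate-activity matrix) draws.

    The replicate matrix has shape (replicates, n_times): each assay
    replicate carries its own noise draw, mirroring a triplicate bench
    design.  The t=0 readings are noise-free (they define [Act]_0).
    """
    c = config.inactivation
    rng = _rng(config.seed, _INACT_STREAM)
    out = []
    for tc in c.temperatures_C:
        T = Temperature(tc)
        k = c.kin_at(T.kelvin)
        t = np.asarray(c.time_grid, dtype=float)
        clean = np.exp(-k * t)
        reps = np.tile(clean, (c.replicates, 1))
        if c.noise_sd > 0:
            if c.noise_model == "lognormal":
                reps = reps * rng.lognormal(0.0, c.noise_sd, size=reps.shape)
            else:
                reps = reps + rng.normal(0.0, c.noise_sd, size=reps.shape)
        reps[:, 0] = 1.0
        reps = np.clip(reps, 1e-12, None)
        out.append((T, t, reps))
    return out


def simulate_inactivation(
    config: GeneratorConfig,
) -> tuple[list[InactivationSeries], TruthBundle]:
    """Arrhenius-linked first-order decays; fraction at t=0 is fixed at 1.

    Replicate readings at each time point are averaged into the series
    fractions, as the analysis does for bench triplicates.
    """
    truth = make_truth(config)
    series = []
    for T, t, reps in _inactivation_replicates(config):
        frac = reps.mean(axis=0)
        frac[0] = 1.0
        series.append(
            InactivationSeries(temperature=T, times=tuple(t), fractions=tuple(frac))
        )
    return series, truth


def simulate_effector_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Replicate effector activities ~ Normal(true% x control, sd% x control).

    Returns the effector-panel CSV schema (effector, class, concentration,
    unit, rep1..repN) with the control row included.
    """
    c = config.effectors
    rng = _rng(config.seed, _EFFECTOR_STREAM)
    rows = []
    rep_cols = [f"rep{i + 1}" for i in range(c.replicates)]
    control_reps = np.full(c.replicates, c.control_activity)
    rows.append(
        {"effector": "control", "class": "metal_ion", "concentration": 1.0,
         "unit": "mM", **dict(zip(rep_cols, control_reps))}
    )
    for t in c.truths:
        mu = t.true_relative / 100.0 * c.control_activity
        sd = t.sd / 100.0 * c.control_activity
        reps = rng.normal(mu, sd, size=c.replicates) if sd > 0 else np.full(c.replicates, mu)
        reps = np.clip(reps, 0.0, None)
        rows.append(
            {"effector": t.name, "class": t.effector_class,
             "concentration": t.concentration, "unit": t.concentration_unit,
             **dict(zip(rep_cols, reps))}
        )
    return pd.DataFrame(rows)


def purification_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Purification CSV schema (deterministic; accounting has no noise model)."""
    return pd.DataFrame([s.model_dump() for s in config.purification.steps])


def write_datasets(config: GeneratorConfig, outdir) -> dict[str, Path]:
    """Write every dataset class as CSV plus the truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    curve, truth = simulate_mm(config)
    mm_df = pd.DataFrame(
        {"substrate_mM": curve.substrate_mM, "rate": curve.rate,
         "replicate": curve.replicate}
    )
    paths["rate_curve"] = outdir / "rate_curve.csv"
    mm_df.to_csv(paths["rate_curve"], index=False)

    rows = []
    for T, t, reps in _inactivation_replicates(config):
        for j, tj in enumerate(t):
            row = {"temperature_C": T.celsius, "pH": 7.0, "time_min": tj}
            row.update({f"rep{i + 1}": reps[i, j] for i in range(reps.shape[0])})
            rows.append(row)
    paths["time_course"] = outdir / "time_course.csv"
    pd.DataFrame(rows).to_csv(paths["time_course"], index=False)

    paths["effectors"] = outdir / "effectors.csv"
    simulate_effector_panel(config).to_csv(paths["effectors"], index=False)

    paths["purification"] = outdir / "purification.csv"
    purification_frame(config).to_csv(paths["purification"], index=False)

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
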