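"""Core data model and normalisation for enzyme activity assays.

Covers replicate activity measurements, effector panels (metal ions,
solvents, inhibitors, surfactants), temperature/pH activity profiles,
purification-step accounting, relative/residual activity normalisation
and substrate-specificity ranking.

Replicates are aggregated with the arithmetic mean; spread is the sample
standard deviation (n-1 denominator).  Activity units are opaque tags:
the package only requires that the quantities entering a single
comparison carry the same tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .units import Temperature

EFFECTOR_CLASSES = frozenset(
    {"metal_ion", "organic_solvent", "inhibitor", "surfactant"}
)


class InvalidControlError(ValueError):
    """Raised when a control measurement cannot serve as 100% reference."""


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


@dataclass(frozen=True)
class ActivityMeasurement:
    """Replicate activity readings under one assay condition."""

    condition_label: str
    replicates: tuple[float, ...]
    unit: str
    temperature: Temperature | None = None
    ph: float | None = None

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate is required")
        if any(v < 0 for v in self.replicates):
            raise ValueError("replicate activities must be non-negative")
        if self.ph is not None and not (0.0 <= self.ph <= 14.0):
            raise ValueError(f"pH {self.ph} outside [0, 14]")
        object.__setattr__(self, "replicates", tuple(float(v) for v in self.replicates))

    @property
    def mean(self) -> float:
        return _mean_sd(self.replicates)[0]

    @property
    def sd(self) -> float:
        return _mean_sd(self.replicates)[1]


@dataclass(frozen=True)
class EffectorRecord:
    """One effector condition (compound, class, concentration, replicates)."""

    effector_name: str
    effector_class: str
    concentration: float
    concentration_unit: str  # e.g. "% v/v" or "mM"
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.effector_class not in EFFECTOR_CLASSES:
            raise ValueError(
                f"effector_class {self.effector_class!r} not in {sorted(EFFECTOR_CLASSES)}"
            )
        if self.concentration <= 0:
            raise ValueError("effector concentration must be positive")
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate is required")
        object.__setattr__(self, "replicates", tuple(float(v) for v in self.replicates))

    @property
    def mean(self) -> float:
        return _mean_sd(self.replicates)[0]

    @property
    def sd(self) -> float:
        return _mean_sd(self.replicates)[1]


@dataclass(frozen=True)
class PurificationStep:
    """One purification step with derived specific activity."""

    step_name: str
    volume_ml: float
    total_activity: float  # U
    total_protein: float  # mg

    def __post_init__(self) -> None:
        if self.total_protein <= 0:
            raise ValueError("total protein must be positive")

    @property
    def specific_activity(self) -> float:
        """Total activity per mg protein (U/mg)."""
        return self.total_activity / self.total_protein


@dataclass(frozen=True)
class ActivityProfile:
    """Mean activity on an ordered temperature or pH grid."""

    axis: str  # "temperature" or "pH"
    grid: tuple[float, ...]
    mean_activity: tuple[float, ...]
    sd: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.axis not in ("temperature", "pH"):
            raise ValueError("axis must be 'temperature' or 'pH'")
        if len(self.grid) != len(self.mean_activity):
            raise ValueError("grid and mean_activity lengths differ")
        if not self.sd:
            object.__setattr__(self, "sd", (0.0,) * len(self.grid))
        if len(self.sd) != len(self.grid):
            raise ValueError("sd length differs from grid")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid must be strictly increasing")

    @property
    def normalized(self) -> tuple[float, ...]:
        """Activity as percent of the profile maximum (max is exactly 100)."""
        top = max(self.mean_activity)
        if top <= 0:
            raise ValueError("profile maximum must be positive to normalise")
        return tuple(100.0 * v / top for v in self.mean_activity)


@dataclass(frozen=True)
class RelativeActivity:
    percent: float
    sd: float


def relative_activity(
    test: ActivityMeasurement, control: ActivityMeasurement
) -> RelativeActivity:
    """Express ``test`` as a percentage of ``control`` (control = 100%).

    The SD is the replicate SD of the test scaled by the same factor as
    the mean (the control is treated as the fixed reference).
    """
    if control.mean <= 0:
        raise InvalidControlError(
            f"control mean {control.mean} is not positive; cannot normalise"
        )
    if test.unit != control.unit:
        raise ValueError(f"unit mismatch: {test.unit!r} vs {control.unit!r}")
    scale = 100.0 / control.mean
    return RelativeActivity(percent=test.mean * scale, sd=test.sd * scale)


def residual_fractions(
    series: Sequence[tuple[float, float]],
    temperature: Temperature | None = None,
    ph: float | None = None,
):
    """Convert a (time, activity) course into residual-activity fractions.

    Fractions are activity(t) / activity(0); the t=0 point must exist with
    positive activity, and the fraction there is exactly 1.  Returns an
    :class:`thermokin.inactivation.InactivationSeries` ready for
    first-order fitting.
    """
    from .inactivation import InactivationSeries  # avoid import cycle

    if not series:
        raise ValueError("empty time course")
    times = np.asarray([t for t, _ in series], dtype=float)
    acts = np.asarray([a for _, a in series], dtype=float)
    if times[0] != 0.0:
        raise ValueError("time course must start at t = 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if acts[0] <= 0:
        raise ValueError("activity at t = 0 must be positive")
    fractions = acts / acts[0]
    if temperature is None:
        temperature = Temperature(25.0)
    return InactivationSeries(
        temperature=temperature,
        times=tuple(times),
        fractions=tuple(fractions),
        ph=ph,
    )


def purification_summary(steps: Sequence[PurificationStep]) -> pd.DataFrame:
    """Purification table with specific activity, yield and fold.

    The first step is the reference (crude extract): its yield is 100%
    and its fold is 1.  Full-precision values are returned; round for
    display with :func:`format_purification_table`.
    """
    if not steps:
        raise ValueError("empty purification table")
    ref = steps[0]
    if ref.total_activity <= 0:
        raise ValueError("reference step must have positive total activity")
    rows = []
    for s in steps:
        rows.append(
            {
                "step": s.step_name,
                "volume_ml": s.volume_ml,
                "total_activity_U": s.total_activity,
                "total_protein_mg": s.total_protein,
                "specific_activity_U_mg": s.specific_activity,
                "yield_percent": 100.0 * s.total_activity / ref.total_activity,
                "fold": s.specific_activity / ref.specific_activity,
            }
        )
    return pd.DataFrame(rows)


def format_purification_table(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Round a purification summary for display (default 1 decimal)."""
    out = table.copy()
    for col in ("specific_activity_U_mg", "yield_percent", "fold"):
        out[col] = out[col].round(decimals)
    return out


def substrate_specificity(
    panel: dict[str, ActivityMeasurement | float],
) -> list[tuple[str, float]]:
    """Rank substrates relative to the most-hydrolysed one (set to 100%).

    Returns (substrate, percent) pairs in descending percentage order;
    ties are broken alphabetically.
    """
    if not panel:
        raise ValueError("empty substrate panel")
    means = {
        name: (m.mean if isinstance(m, ActivityMeasurement) else float(m))
        for name, m in panel.items()
    }
    top = max(means.values())
    if top <= 0:
        raise ValueError("all substrate activities are zero")
    scaled = [(name, 100.0 * v / top) for name, v in means.items()]
    return sorted(scaled, key=lambda kv: (-kv[1], kv[0]))


def profile_optimum(profile: ActivityProfile) -> float:
    """Grid value (temperature or pH) of maximal mean activity.

    Ties resolve to the lower axis value (the grid is increasing, so the
    first maximum wins).
    """
    if len(profile.grid) < 2:
        raise ValueError("profile needs at least two grid points")
    idx = int(np.argmax(profile.mean_activity))
    return profile.grid[idx]


# ---------------------------------------------------------------------------
# Delimited-text readers (one schema per record type; header row mandatory)
# ---------------------------------------------------------------------------


def _rep_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.lower().startswith("rep")]
    if not cols:
        raise ValueError("no replicate columns (rep1..repN) found")
    return cols


def read_effector_panel(path) -> list[EffectorRecord]:
    """Read an effector panel CSV: effector, class, concentration, unit, rep1..repN."""
    df = pd.read_csv(path)
    reps = _rep_columns(df)
    records = []
    for _, row in df.iterrows():
        records.append(
            EffectorRecord(
                effector_name=str(row["effector"]),
                effector_class=str(row["class"]),
                concentration=float(row["concentration"]),
                concentration_unit=str(row["unit"]),
                replicates=tuple(float(row[c]) for c in reps if pd.notna(row[c])),
            )
        )
    return records


def read_profile(path) -> ActivityProfile:
    """Read a profile CSV: axis, value, rep1..repN (one axis per file)."""
    df = pd.read_csv(path)
    reps = _rep_columns(df)
    axes = df["axis"].unique()
    if len(axes) != 1:
        raise ValueError("profile file must contain exactly one axis")
    df = df.sort_values("value")
    means, sds = [], []
    for _, row in df.iterrows():
        vals = [float(row[c]) for c in reps if pd.notna(row[c])]
        m, s = _mean_sd(vals)
        means.append(m)
        sds.append(s)
    return ActivityProfile(
        axis=str(axes[0]),
        grid=tuple(float(v) for v in df["value"]),
        mean_activity=tuple(means),
        sd=tuple(sds),
    )


def read_purification(path) -> list[PurificationStep]:
    """Read a purification CSV: step, volume_ml, total_activity_U, total_protein_mg."""
    df = pd.read_csv(path)
    return [
        PurificationStep(
            step_name=str(row["step"]),
            volume_ml=float(row["volume_ml"]),
            total_activity=float(row["total_activity_U"]),
            total_protein=float(row["total_protein_mg"]),
        )
        for _, row in df.iterrows()
    ]


def read_time_course(path) -> list:
    """Read a residual-activity time-course CSV into inactivation series.

    Schema: temperature_C, pH, time_min, rep1..repN.  One series is built
    per (temperature, pH) group; replicate readings at each time point are
    averaged before the fraction transform.
    """
    df = pd.read_csv(path)
    reps = _rep_columns(df)
    out = []
    for (temp_c, ph), grp in df.groupby(["temperature_C", "pH"], dropna=False):
        grp = grp.sort_values("time_min")
        course = []
        for _, row in grp.iterrows():
            vals = [float(row[c]) for c in reps if pd.notna(row[c])]
            course.append((float(row["time_min"]), _mean_sd(vals)[0]))
        out.append(
            residual_fractions(
                course,
                temperature=Temperature(float(temp_c)),
                ph=None if pd.isna(ph) else float(ph),
            )
        )
    out.sort(key=lambda s: s.temperature.celsius)
    return out
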