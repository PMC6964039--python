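"""Scenario inputs: feed and milk schedules, lactation curves, file IO.

A :class:`Schedule` maps simulation time (days) to an input value (DMI
in g/d or milk yield in kg/d) and knows its discontinuities so the
integrator can restart there.  Lactation inputs are generated as Wood
gamma curves anchored to the printed peak values (41 kg/d milk and
22 kg/d DMI around week 8 postpartum), emulating the interpolated
study data used as model input; measured series can be loaded from CSV
(canonical interchange: columns ``day, dmi_g_per_d, milk_kg_per_d``) or
MATLAB ``.mat`` files (variables ``DM`` and ``ML``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Schedule",
    "PulseSchedule",
    "Scenario",
    "TimeseriesFormatError",
    "make_lactation_curves",
    "lactation_schedules",
    "load_timeseries",
    "make_restriction_schedule",
]

MAINTENANCE_DMI = 11700.0  # g/d, 600-kg cow


class TimeseriesFormatError(ValueError):
    """An input time series violates the expected format."""


class Schedule:
    """Time-dependent scalar input on ``[0, horizon]``.

    Either piecewise-constant (from ``breakpoints`` = [(t0, v0), (t1, v1),
    ...], value vi holding on [ti, t(i+1))) or linearly interpolated
    (from ``times``/``values`` samples).
    """

    def __init__(self, breakpoints=None, times=None, values=None,
                 name: str = ""):
        self.name = name
        if breakpoints is not None:
            bp = sorted(breakpoints)
            if bp[0][0] > 0:
                raise ValueError("piecewise schedule must start at t <= 0")
            self._t = np.array([t for t, _ in bp], dtype=float)
            self._v = np.array([v for _, v in bp], dtype=float)
            self._mode = "step"
        elif times is not None and values is not None:
            t = np.asarray(times, dtype=float)
            v = np.asarray(values, dtype=float)
            if t.size < 2 or np.any(np.diff(t) <= 0):
                raise ValueError("interpolated schedule needs increasing times")
            self._t, self._v = t, v
            self._mode = "interp"
        else:
            raise ValueError("provide breakpoints or times/values")

    @classmethod
    def constant(cls, value: float, name: str = "") -> "Schedule":
        return cls(breakpoints=[(0.0, value)], name=name)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self._mode == "step":
            idx = np.clip(np.searchsorted(self._t, t, side="right") - 1, 0, None)
            out = self._v[idx]
        else:
            out = np.interp(t, self._t, self._v)
        return float(out) if out.ndim == 0 else out

    @property
    def discontinuities(self) -> np.ndarray:
        """Times where the integrator should restart."""
        if self._mode == "step":
            return self._t[self._t > 0]
        return np.array([])

    def anchored(self, t0: float, pre_value: float) -> "Schedule":
        """Translate a piecewise-constant schedule so its origin is at
        ``t0``, holding ``pre_value`` before that (used to start a
        restriction protocol at a detected ovulation)."""
        if self._mode != "step":
            raise ValueError("only piecewise-constant schedules can be anchored")
        bp = [(0.0, pre_value)] + [(t + t0, v)
                                   for t, v in zip(self._t, self._v)]
        return Schedule(breakpoints=bp, name=self.name)


@dataclass(frozen=True)
class PulseSchedule:
    """Repeated square pulses, e.g. daily exogenous oxytocin injections.

    A pulse of ``amplitude`` (rate units, [Oxy]/d) and ``duration`` days
    starts every ``interval`` days from ``start`` until ``stop``.
    """

    amplitude: float = 20.0
    duration: float = 0.25
    start: float = 2.0
    interval: float = 1.0
    stop: float = 30.0

    def __call__(self, t: float) -> float:
        if t < self.start or t >= self.stop:
            return 0.0
        phase = (t - self.start) % self.interval
        return self.amplitude if phase < self.duration else 0.0

    @property
    def discontinuities(self) -> np.ndarray:
        edges = []
        t = self.start
        while t < self.stop:
            edges += [t, t + self.duration]
            t += self.interval
        return np.array(edges)


@dataclass
class Scenario:
    """A complete simulation setup: time-varying inputs plus flags."""

    name: str
    horizon_d: float
    dmi: Schedule
    milk: Schedule
    lactating: bool = False
    c0: Optional[float] = None           # overrides the parameter default
    exogenous_oxytocin: Optional[PulseSchedule] = None
    anchor_dmi_to_first_ovulation: bool = False
    burn_in_d: float = 20.0

    def __post_init__(self):
        if self.horizon_d <= 0:
            raise ValueError("horizon must be positive")
        if not self.lactating:
            if self.milk(0.0) != 0.0 or self.milk(self.horizon_d / 2) != 0.0:
                raise ValueError("non-lactating scenarios require Milk == 0")
        ts = np.linspace(0, self.horizon_d, 101)
        if np.any(np.asarray(self.dmi(ts)) <= 0):
            raise ValueError("DMI(t) must be positive over the horizon")
        if np.any(np.asarray(self.milk(ts)) < 0):
            raise ValueError("Milk(t) must be non-negative over the horizon")

    @classmethod
    def maintenance(cls, horizon_d: float = 100.0, c0: Optional[float] = None,
                    dmi: float = MAINTENANCE_DMI) -> "Scenario":
        return cls(name="maintenance", horizon_d=horizon_d,
                   dmi=Schedule.constant(dmi, "dmi"),
                   milk=Schedule.constant(0.0, "milk"), c0=c0)

    @classmethod
    def acute_restriction(cls, horizon_d: float = 100.0,
                          anchor: bool = True) -> "Scenario":
        """15-day reduction to 33% of maintenance intake.

        By default the restriction is applied immediately after a
        detected ovulation (the experimental protocol); with
        ``anchor=False`` it runs at the absolute days 43-58 instead.
        """
        if anchor:
            dmi = Schedule(breakpoints=[(0.0, MAINTENANCE_DMI),
                                        (0.5, 3840.0),
                                        (15.5, MAINTENANCE_DMI)], name="dmi")
            return cls(name="acute-restriction", horizon_d=horizon_d,
                       dmi=dmi, milk=Schedule.constant(0.0, "milk"),
                       anchor_dmi_to_first_ovulation=True, burn_in_d=20.0)
        return cls(name="acute-restriction", horizon_d=horizon_d,
                   dmi=make_restriction_schedule("acute"),
                   milk=Schedule.constant(0.0, "milk"))

    @classmethod
    def chronic_restriction(cls, horizon_d: float = 260.0,
                            burn_in_d: float = 20.0) -> "Scenario":
        return cls(name="chronic-restriction", horizon_d=horizon_d,
                   dmi=make_restriction_schedule("chronic"),
                   milk=Schedule.constant(0.0, "milk"),
                   anchor_dmi_to_first_ovulation=True, burn_in_d=burn_in_d)

    @classmethod
    def lactation(cls, horizon_d: float = 305.0, c0: float = 0.25,
                  curves: Optional[pd.DataFrame] = None) -> "Scenario":
        if curves is None:
            curves = make_lactation_curves(horizon_d=horizon_d)
        dmi, milk = lactation_schedules(curves)
        return cls(name="lactation", horizon_d=horizon_d, dmi=dmi, milk=milk,
                   lactating=True, c0=c0)

    @classmethod
    def oxytocin_challenge(cls, horizon_d: float = 40.0,
                           pulses: Optional[PulseSchedule] = None) -> "Scenario":
        return cls(name="oxytocin-challenge", horizon_d=horizon_d,
                   dmi=Schedule.constant(MAINTENANCE_DMI, "dmi"),
                   milk=Schedule.constant(0.0, "milk"),
                   exogenous_oxytocin=pulses or PulseSchedule(),
                   anchor_dmi_to_first_ovulation=True, burn_in_d=20.0)


def _wood(t, peak_value, peak_day, shape_b):
    """Wood gamma curve ``a*t^b*exp(-c*t)`` scaled so its maximum equals
    ``peak_value`` at ``peak_day`` (time shifted by one day so the curve
    is positive at t=0)."""
    tt = np.asarray(t, dtype=float) + 1.0
    tpk = peak_day + 1.0
    c = shape_b / tpk
    with np.errstate(divide="ignore"):
        raw = tt ** shape_b * np.exp(-c * tt)
    peak_raw = tpk ** shape_b * np.exp(-shape_b)
    return peak_value * raw / peak_raw


def make_lactation_curves(peak_milk: float = 41.0, peak_dmi: float = 22.0,
                          peak_week: float = 8.0, horizon_d: float = 305.0,
                          milk_shape: float = 0.18,
                          dmi_shape: float = 0.10) -> pd.DataFrame:
    """Synthetic lactation input: daily milk yield and DMI.

    Wood-type gamma curves constrained to hit the given peaks exactly at
    ``peak_week`` (default: 41 kg/d milk and 22 kg/d DMI at week 8
    postpartum).  The shape exponents are in the range typically fitted
    for Holstein lactations and give a realistic fresh-cow start (milk
    ~58% and DMI ~74% of peak at calving).  ``peak_milk=0`` degenerates
    to a non-lactating (dry) input.
    """
    if peak_milk < 0 or peak_dmi <= 0:
        raise ValueError("peaks must be positive (peak_milk may be 0)")
    peak_day = peak_week * 7.0
    if not (0 < peak_day < horizon_d):
        raise ValueError("peak_week must fall inside the horizon")
    day = np.arange(0, int(horizon_d) + 1)
    milk = _wood(day, peak_milk, peak_day, milk_shape) if peak_milk > 0 \
        else np.zeros_like(day, dtype=float)
    dmi = _wood(day, peak_dmi * 1000.0, peak_day, dmi_shape)
    df = pd.DataFrame({"day": day, "dmi_g_per_d": dmi, "milk_kg_per_d": milk})
    # sanity band on the implied full-lactation yield, independent of the
    # simulated horizon
    day305 = np.arange(0, 306)
    total = float(np.trapezoid(_wood(day305, peak_milk, peak_day, milk_shape),
                               day305)) if peak_milk > 0 else 0.0
    if peak_milk > 0 and total < 8000.0:
        warnings.warn(f"implied 305-d milk yield {total:.0f} kg below "
                      "the plausible 8000 kg")
    return df


def lactation_schedules(curves: pd.DataFrame) -> tuple[Schedule, Schedule]:
    """Turn a lactation input table into (dmi, milk) schedules with
    linear interpolation between daily samples."""
    _validate_curves(curves)
    t = curves["day"].to_numpy(dtype=float)
    dmi = Schedule(times=t, values=curves["dmi_g_per_d"].to_numpy(dtype=float),
                   name="dmi")
    milk = Schedule(times=t, values=curves["milk_kg_per_d"].to_numpy(dtype=float),
                    name="milk")
    return dmi, milk


_REQUIRED_COLUMNS = ("day", "dmi_g_per_d", "milk_kg_per_d")


def _validate_curves(df: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TimeseriesFormatError(f"missing columns: {missing}")
    if len(df) == 0:
        raise TimeseriesFormatError("empty time series")
    t = df["day"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0)) + 1
        raise TimeseriesFormatError(f"non-monotone time at row {i}")
    for col in ("dmi_g_per_d", "milk_kg_per_d"):
        v = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            i = int(np.argmax(~np.isfinite(v) | (v < 0)))
            raise TimeseriesFormatError(f"invalid {col} at row {i}")


def load_timeseries(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read a lactation input series from CSV (canonical) or ``.mat``.

    CSV must carry the columns ``day, dmi_g_per_d, milk_kg_per_d``.  A
    ``.mat`` file is expected to contain two-column arrays ``DM`` (day,
    DMI kg/d) and ``ML`` (day, milk kg/d) as in the published input
    files; DMI is converted to g/d.
    """
    path = str(path)
    if fmt is None:
        fmt = "mat" if path.endswith(".mat") else "csv"
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as e:
            raise TimeseriesFormatError(f"empty file: {path}") from e
        _validate_curves(df)
        return df[list(_REQUIRED_COLUMNS)].astype(float)
    if fmt == "mat":
        from scipy.io import loadmat

        raw = loadmat(path)
        if "DM" not in raw or "ML" not in raw:
            raise TimeseriesFormatError(
                f"{path}: expected variables 'DM' and 'ML', found "
                f"{[k for k in raw if not k.startswith('_')]}"
            )
        dm = np.atleast_2d(raw["DM"]).astype(float)
        ml = np.atleast_2d(raw["ML"]).astype(float)
        day = dm[:, 0]
        df = pd.DataFrame({
            "day": day,
            "dmi_g_per_d": dm[:, 1] * 1000.0,
            "milk_kg_per_d": np.interp(day, ml[:, 0], ml[:, 1]),
        })
        _validate_curves(df)
        return df
    raise ValueError(f"unknown format {fmt!r}")


def make_restriction_schedule(kind: str,
                              maintenance: float = MAINTENANCE_DMI) -> Schedule:
    """Feed-restriction DMI schedules.

    ``acute``: maintenance, reduced to 33% (3840 g/d) on day 43 for 15
    days, then back to maintenance.  ``chronic``: 58% (6790 g/d) for 30
    weeks from the schedule origin, then 160% (18720 g/d); the origin is
    anchored to the first post-burn-in ovulation by the simulator.
    """
    if kind == "acute":
        return Schedule(breakpoints=[(0.0, maintenance), (43.0, 3840.0),
                                     (58.0, maintenance)], name="dmi")
    if kind == "chronic":
        return Schedule(breakpoints=[(0.0, 6790.0), (30 * 7.0, 18720.0)],
                        name="dmi")
    raise ValueError(f"unknown restriction kind {kind!r}")
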