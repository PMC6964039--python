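"""Event detection and scenario post-processing.

Observables derived from trajectories: onset of luteal activity (first
time P4 exceeds a threshold), ovulations (LH surges followed by a P4
rise), cycle lengths, cessation/re-initiation of cyclicity, the
energy-balance indicator, and the exponential response curve of the
postpartum anestrus length to dietary glucose content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "EventLog",
    "NO_EVENT",
    "detect_luteal_onset",
    "detect_ovulations",
    "detect_first_ovulation",
    "cycle_lengths",
    "detect_cessation",
    "energy_balance",
    "fit_anestrus_response",
    "analyze",
]

#: sentinel for "the event never occurred within the horizon"
NO_EVENT = float("nan")


@dataclass
class EventLog:
    """Detected reproductive events of one scenario run (days)."""

    luteal_onset_d: float = NO_EVENT
    ovulation_times_d: list = field(default_factory=list)
    cycle_lengths_d: list = field(default_factory=list)
    first_ovulation_d: float = NO_EVENT
    cessation_d: float = NO_EVENT
    reinitiation_d: float = NO_EVENT

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def detect_luteal_onset(time, p4, threshold: float = 1.0) -> float:
    """First time at which P4 reaches ``threshold`` (relative units),
    linearly interpolated between samples; ``NO_EVENT`` if never."""
    time = np.asarray(time, float)
    p4 = np.asarray(p4, float)
    above = p4 >= threshold
    if not above.any():
        return NO_EVENT
    i = int(np.argmax(above))
    if i == 0:
        return float(time[0])
    t0, t1 = time[i - 1], time[i]
    v0, v1 = p4[i - 1], p4[i]
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def detect_ovulations(time, lh, p4,
                      surge_prominence: Optional[float] = None,
                      p4_rise_window: float = 7.0,
                      p4_margin_frac: float = 0.1) -> list[float]:
    """Ovulation times: local LH maxima of sufficient prominence that
    are followed within ``p4_rise_window`` days by P4 rising above its
    baseline plus a margin.

    The surge prominence defaults to 50% of the largest LH surge in the
    trajectory (auto-calibration), so that sub-surge pulses are ignored;
    the P4 baseline is the trajectory minimum plus ``p4_margin_frac`` of
    the P4 amplitude.
    """
    time = np.asarray(time, float)
    lh = np.asarray(lh, float)
    p4 = np.asarray(p4, float)
    lh_base = float(np.median(lh))
    lh_amp = float(lh.max() - lh_base)
    if lh_amp <= 1e-6:
        return []
    if surge_prominence is None:
        surge_prominence = 0.5 * lh_amp
    dt = float(np.median(np.diff(time)))
    peaks, _ = find_peaks(lh, prominence=surge_prominence,
                          distance=max(int(5.0 / dt), 1))
    p4_floor = float(p4.min())
    p4_baseline = p4_floor + p4_margin_frac * float(p4.max() - p4_floor)
    out = []
    for i in peaks:
        t_peak = time[i]
        win = (time > t_peak) & (time <= t_peak + p4_rise_window)
        if win.any() and float(p4[win].max()) > p4_baseline:
            out.append(float(t_peak))
    return out


def detect_first_ovulation(time, lh, p4, **kw) -> float:
    ov = detect_ovulations(time, lh, p4, **kw)
    return float(ov[0]) if ov else NO_EVENT


def cycle_lengths(ovulation_times: Sequence[float]) -> list[float]:
    """Inter-ovulatory intervals (days)."""
    ov = np.asarray(ovulation_times, float)
    return list(np.diff(ov)) if ov.size >= 2 else []


def detect_cessation(ovulation_times: Sequence[float], horizon_d: float,
                     gap_d: float = 35.0) -> float:
    """Day of the last ovulation before a gap of at least ``gap_d`` days
    with no further ovulation (~1.5 cycles); ``NO_EVENT`` if cyclicity
    never ceases."""
    ov = list(ovulation_times)
    if not ov:
        return NO_EVENT
    times = ov + [horizon_d]
    for a, b in zip(times[:-1], times[1:]):
        if b - a >= gap_d:
            return float(a)
    return NO_EVENT


def energy_balance(fluxes) -> np.ndarray:
    """Energy-balance indicator: lipogenesis minus fat mobilization,
    ``delta_fat = glu_lv_fat - glu_fat_lv`` in g/d (negative = NEB)."""
    return (np.asarray(fluxes["glu_lv_fat"], float)
            - np.asarray(fluxes["glu_fat_lv"], float))


def fit_anestrus_response(c0_percent, first_ovulation_days,
                          p0: Optional[tuple] = None):
    """Least-squares fit of ``f(x) = a*exp(-b*x) + c`` to first-ovulation
    day vs glucose content of the DMI (x in percent).

    Returns ``(params, residuals)`` with ``params = (a, b, c)``.  Needs
    at least four points with detected ovulations.
    """
    x = np.asarray(c0_percent, float)
    y = np.asarray(first_ovulation_days, float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need >= 4 detected points for the fit, got {x.size}")

    def f(x, a, b, c):
        return a * np.exp(-b * x) + c

    if p0 is None:
        c0_guess = 0.9 * float(y.min())
        z = np.log(np.clip(y - c0_guess, 1e-9, None))
        b_guess = max(-np.polyfit(x, z, 1)[0], 1e-3)
        a_guess = float(np.exp(np.polyfit(x, z, 1)[1]))
        p0 = (a_guess, b_guess, c0_guess)
    try:
        popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
    except RuntimeError as e:
        raise RuntimeError(f"exponential fit failed (p0={p0})") from e
    resid = y - f(x, *popt)
    return tuple(popt), resid


def analyze(result, p4_threshold: float = 1.0, gap_d: float = 35.0,
            refeed_day: Optional[float] = None) -> EventLog:
    """Fill an :class:`EventLog` from a simulation result and attach it."""
    t = result.time
    log = EventLog()
    log.luteal_onset_d = detect_luteal_onset(t, result["p4"], p4_threshold)
    log.ovulation_times_d = detect_ovulations(t, result["lh_blood"],
                                              result["p4"])
    log.cycle_lengths_d = cycle_lengths(log.ovulation_times_d)
    log.first_ovulation_d = (log.ovulation_times_d[0]
                             if log.ovulation_times_d else NO_EVENT)
    log.cessation_d = detect_cessation(log.ovulation_times_d,
                                       float(t[-1]), gap_d)
    if refeed_day is not None:
        after = [o for o in log.ovulation_times_d if o > refeed_day]
        log.reinitiation_d = after[0] if after else NO_EVENT
    result.events = log
    return log
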