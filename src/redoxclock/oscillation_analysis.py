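"""Period, amplitude and phase extraction from simulated trajectories.

Phase is defined by peak maxima (the field convention for densitometry
time courses): peaks are located on the dense grid, refined by quadratic
interpolation through the three bracketing samples, and lags are circular
means of late-follows-early peak-time differences, reported in
[0, period).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.signal

from .simulate import Trajectory

__all__ = [
    "find_peaks",
    "period_estimate",
    "phase_difference",
    "summarize",
    "OscillationSummary",
    "PeriodEstimate",
    "NotOscillatoryError",
]


class NotOscillatoryError(ValueError):
    pass


def _refined_peaks(traj: Trajectory, variable: str, prominence_frac: float = 0.01):
    """Local maxima of one variable: (refined times, refined heights).

    Ripples with prominence below ``prominence_frac`` of the variable's
    range are rejected.
    """
    y = traj.series(variable)
    rng = float(y.max() - y.min())
    if rng == 0.0:
        return np.array([]), np.array([])
    idx, _ = scipy.signal.find_peaks(y, prominence=prominence_frac * rng)
    idx = idx[(idx > 0) & (idx < len(y) - 1)]
    t, dt = traj.times, traj.dt
    times, heights = [], []
    for j in idx:
        y0, y1, y2 = y[j - 1], y[j], y[j + 1]
        denom = y0 - 2.0 * y1 + y2
        off = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        times.append(t[j] + off * dt)
        heights.append(y1 - 0.25 * (y0 - y2) * off)
    return np.asarray(times), np.asarray(heights)


def find_peaks(traj: Trajectory, variable: str) -> np.ndarray:
    """Quadratically refined peak times of ``variable`` (empty if flat)."""
    return _refined_peaks(traj, variable)[0]


@dataclass(frozen=True)
class PeriodEstimate:
    period: float
    std: float
    n_cycles: int

    def __float__(self) -> float:
        return self.period


def period_estimate(traj: Trajectory, variable: str = "I", max_cv: float = 0.01) -> PeriodEstimate:
    """Mean successive peak spacing of ``variable``.

    Raises :class:`NotOscillatoryError` with fewer than 3 peaks or when the
    cycle-to-cycle coefficient of variation exceeds ``max_cv`` (1%), which
    indicates the trajectory has not settled on a limit cycle.
    """
    t_peaks = find_peaks(traj, variable)
    if len(t_peaks) < 3:
        raise NotOscillatoryError(
            f"{variable}: {len(t_peaks)} peaks found, need >= 3 for a period estimate"
        )
    gaps = np.diff(t_peaks)
    period = float(np.mean(gaps))
    std = float(np.std(gaps, ddof=1))
    if std / period > max_cv:
        raise NotOscillatoryError(
            f"{variable}: period CV {std / period:.2%} exceeds {max_cv:.0%}; not a settled cycle"
        )
    return PeriodEstimate(period, std, len(gaps))


def _circular_mean(lags: np.ndarray, period: float) -> float:
    ang = 2.0 * np.pi * np.asarray(lags) / period
    mean_ang = np.angle(np.mean(np.exp(1j * ang)))
    return float((mean_ang * period / (2.0 * np.pi)) % period)


def phase_difference(traj: Trajectory, var_late: str, var_early: str) -> float:
    """Circular-mean lag (h) from each ``var_early`` peak to the nearest
    following ``var_late`` peak, reported in [0, period)."""
    if var_late == var_early:
        return 0.0
    period = period_estimate(traj, var_early).period
    early = find_peaks(traj, var_early)
    late = find_peaks(traj, var_late)
    if len(late) < 3:
        raise NotOscillatoryError(f"{var_late} is not oscillatory")
    lags = []
    for t0 in early:
        nxt = late[late >= t0]
        if len(nxt):
            lags.append((nxt[0] - t0) % period)
    if not lags:
        raise NotOscillatoryError("no ordered peak pairs found")
    return _circular_mean(np.asarray(lags), period)


@dataclass(frozen=True)
class OscillationSummary:
    """Period, per-variable extrema/peak phases and pairwise lags."""

    period: float
    period_std: float
    extrema: dict[str, tuple[float, float]]  # variable -> (min, max)
    peak_phase: dict[str, float]  # peak time within one cycle, relative to I's peak
    lags: dict[str, float]  # "LATE-EARLY" -> lag in h

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "period": self.period,
                "period_std": self.period_std,
                "extrema": {k: list(v) for k, v in self.extrema.items()},
                "peak_phase": self.peak_phase,
                "lags": self.lags,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


#: lag pairs reported by default: R follows I, D2 follows D1, D2 follows I
DEFAULT_PAIRS = (("R", "I"), ("D2", "D1"), ("D2", "I"))


def summarize(traj: Trajectory, reference: str = "I", pairs=DEFAULT_PAIRS) -> OscillationSummary:
    """Full oscillation summary of a post-transient trajectory."""
    est = period_estimate(traj, reference)
    ref_peaks = find_peaks(traj, reference)
    extrema, phase = {}, {}
    for name in traj.names:
        y = traj.series(name)
        extrema[name] = (float(y.min()), float(y.max()))
        pk = find_peaks(traj, name)
        if len(pk) >= 3:
            lags = []
            for t0 in ref_peaks:
                nxt = pk[pk >= t0]
                if len(nxt):
                    lags.append((nxt[0] - t0) % est.period)
            phase[name] = _circular_mean(np.asarray(lags), est.period) if lags else float("nan")
    lags = {}
    for late, early in pairs:
        if late in traj.names and early in traj.names:
            lags[f"{late}-{early}"] = phase_difference(traj, late, early)
    return OscillationSummary(est.period, est.std, extrema, phase, lags)
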