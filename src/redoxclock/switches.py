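"""Three-phase / two-switch decomposition of the relaxation cycle.

Each cycle of the redox oscillator divides into

* phase 3, *reactivation*: from the activation (A) switch — the moment of
  steepest rise in active Prx3, when Srx-mediated rescue outruns
  hyperoxidation — until A peaks;
* phase 1, *A inactivation*: from the A peak until the
  inactivation/leakage (I/L) switch, when the active pool is nearly
  exhausted (A falls below a small threshold of the total pool while
  decreasing) and mitochondrial H2O2 starts leaking to the cytosol;
* phase 2, *leakage and feedback buildup*: from the I/L switch until the
  next A switch, while D1 accumulates, leaks to D2 and drives Srx import.

Cycles are anchored at the A switch, so within each cycle t_IL < t_A(next)
and the three half-open intervals partition the cycle exactly.

The I/L threshold (default 5% of the Prx3 pool) is a declared convention:
the transition is described verbally in the literature ("most of the
active pool has been hyperoxidized") without a numeric criterion; phase
durations are insensitive (< 5% change) to thresholds in 2-10% of T.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .oscillation_analysis import NotOscillatoryError, find_peaks, period_estimate
from .simulate import Trajectory

__all__ = ["SwitchAnnotation", "CycleAnnotation", "annotate_phases", "waveform_shape_index"]


@dataclass(frozen=True)
class CycleAnnotation:
    """Switch times and phase intervals of one cycle, anchored at the A switch."""

    t_A: float  # activation switch opening the cycle
    t_peak: float  # A maximum: end of reactivation
    t_IL: float  # inactivation/leakage switch
    t_A_next: float  # activation switch closing the cycle

    @property
    def phases(self) -> dict[int, tuple[float, float]]:
        return {
            3: (self.t_A, self.t_peak),
            1: (self.t_peak, self.t_IL),
            2: (self.t_IL, self.t_A_next),
        }

    @property
    def durations(self) -> dict[int, float]:
        return {k: hi - lo for k, (lo, hi) in self.phases.items()}

    @property
    def period(self) -> float:
        return self.t_A_next - self.t_A


@dataclass(frozen=True)
class SwitchAnnotation:
    cycles: tuple[CycleAnnotation, ...]
    theta_IL: float

    def mean_durations(self) -> dict[int, float]:
        return {k: float(np.mean([c.durations[k] for c in self.cycles])) for k in (1, 2, 3)}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "theta_IL": self.theta_IL,
                "cycles": [
                    {
                        "t_A": c.t_A,
                        "t_peak": c.t_peak,
                        "t_IL": c.t_IL,
                        "t_A_next": c.t_A_next,
                        "phases": {str(k): list(v) for k, v in c.phases.items()},
                    }
                    for c in self.cycles
                ],
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_intervals(self):
        """BED-like (cycle, phase, start_h, end_h) DataFrame for plotting."""
        import pandas as pd

        rows = []
        for i, c in enumerate(self.cycles):
            for k, (lo, hi) in c.phases.items():
                rows.append({"cycle": i, "phase": k, "start_h": lo, "end_h": hi})
        return pd.DataFrame(rows)


def _interp_crossing(t, y, i, level):
    """Linear interpolation of the time where y crosses `level` in [i, i+1]."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return t[i]
    return t[i] + (level - y0) / (y1 - y0) * (t[i + 1] - t[i])


def annotate_phases(traj: Trajectory, theta_IL: float = 0.05) -> SwitchAnnotation:
    """Locate the I/L and A switches on every complete cycle.

    The A switch is the time of maximum dA/dt within the cycle (the sharp
    reactivation is a slope feature); the I/L switch is the first downward
    crossing of A below ``theta_IL * T`` after the A peak.
    """
    if "A" not in traj.names:
        raise ValueError("trajectory must provide A (directly or via the QSSA)")
    A = traj.series("A")
    t = traj.times
    T = getattr(traj.params, "T", float(A.max()))
    level = theta_IL * T
    dA = np.gradient(A, t)

    peaks = find_peaks(traj, "A")
    if len(peaks) < 3:
        raise NotOscillatoryError("need >= 3 A peaks to annotate cycles")
    period_estimate(traj, "A")  # raises if not settled

    # A-switch candidates: local maxima of dA/dt exceeding half the global max
    import scipy.signal

    cand, _ = scipy.signal.find_peaks(dA, height=0.5 * dA.max())
    t_A_all = t[cand]
    if len(t_A_all) < 2:
        raise NotOscillatoryError("activation switch not found (no sharp A rise)")

    cycles = []
    for tA, tA_next in zip(t_A_all[:-1], t_A_all[1:]):
        in_cycle = peaks[(peaks > tA) & (peaks < tA_next)]
        if len(in_cycle) == 0:
            continue
        t_peak = float(in_cycle[0])
        # first downward crossing of the threshold after the A peak
        seg = (t >= t_peak) & (t < tA_next)
        idx = np.nonzero(seg)[0]
        below = np.nonzero((A[idx[:-1]] >= level) & (A[idx[1:]] < level))[0]
        if len(below) == 0:
            raise NotOscillatoryError(
                f"A never falls below theta_IL*T = {level:.3g} within a cycle"
            )
        i0 = idx[below[0]]
        t_IL = float(_interp_crossing(t, A, i0, level))
        cycles.append(CycleAnnotation(float(tA), t_peak, t_IL, float(tA_next)))
    if not cycles:
        raise NotOscillatoryError("no complete cycles found")
    return SwitchAnnotation(tuple(cycles), theta_IL)


def waveform_shape_index(traj: Trajectory, variable: str) -> float:
    """Rise/fall asymmetry: mean of (rise - fall)/period per cycle.

    Rise is the trough-to-peak duration, fall the peak-to-trough duration.
    Near zero for a sinusoid; |index| well above 0 marks the
    relaxation/triangular waveforms of the fast variables.
    """
    y = traj.series(variable)
    peaks = find_peaks(traj, variable)
    # troughs: peaks of the negated series
    neg = Trajectory(traj.times, -traj.states, traj.names, traj.model_tag, traj.params)
    troughs = find_peaks(neg, variable)
    if len(peaks) < 3 or len(troughs) < 3:
        raise NotOscillatoryError(f"{variable} is not oscillatory")
    period = period_estimate(traj, variable).period
    vals = []
    for tp in peaks:
        before = troughs[troughs < tp]
        after = troughs[troughs > tp]
        if len(before) and len(after):
            rise = tp - before[-1]
            fall = after[0] - tp
            vals.append((rise - fall) / period)
    if not vals:
        raise NotOscillatoryError("no complete rise/fall pairs")
    return float(np.mean(vals))
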