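"""Model reduction by clamping: fix a variable at its cycle mean and test
whether rhythms persist.

Clamping a variable severs every feedback routed through it while keeping
its average influence on the rest of the network, so rhythm loss under a
clamp identifies the variable as part of the oscillator's core motif.  The
clamp value is the mean over an integer number of post-transient cycles
(not the raw grid mean), avoiding partial-cycle bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_model import ParameterSet, get_model
from .oscillation_analysis import find_peaks
from .simulate import Trajectory, detect_limit_cycle, discard_transient, integrate

__all__ = ["ClampReport", "ClampedModel", "clamp_and_test", "cycle_mean"]


class ClampedModel:
    """Wrapper holding one state variable fixed (zero derivative)."""

    def __init__(self, base, variable: str, value: float):
        self.base = base
        self.names = base.names
        self.index = base.names.index(variable)
        self.value = float(value)
        self.tag = f"{base.tag}[{variable}={value:.4g}]"

    def rhs(self, t, y, params):
        y = np.array(y, dtype=float)
        y[self.index] = self.value
        dy = np.asarray(self.base.rhs(t, y, params), dtype=float)
        dy[self.index] = 0.0
        return dy

    def jac(self, t, y, params):
        base_jac = getattr(self.base, "jac", None)
        if base_jac is None:
            return None
        y = np.array(y, dtype=float)
        y[self.index] = self.value
        J = np.asarray(base_jac(t, y, params), dtype=float)
        J[self.index, :] = 0.0
        J[:, self.index] = 0.0
        return J

    def default_initial(self, params):
        y0 = np.array(self.base.default_initial(params), dtype=float)
        y0[self.index] = self.value
        return y0

    def derived(self, states, params):
        return self.base.derived(states, params)


def cycle_mean(traj: Trajectory, variable: str, reference: str | None = None) -> float:
    """Mean of ``variable`` over an integer number of cycles.

    Cycle boundaries are the first and last peak of ``reference`` (defaults
    to the clamped variable itself when it oscillates, else the first
    oscillating state variable).
    """
    ref = reference or variable
    peaks = find_peaks(traj, ref)
    if len(peaks) < 2:
        raise ValueError(f"{ref} has fewer than 2 peaks; cannot form whole cycles")
    mask = (traj.times >= peaks[0]) & (traj.times <= peaks[-1])
    return float(np.mean(traj.series(variable)[mask]))


@dataclass(frozen=True)
class ClampReport:
    variable: str
    clamp_value: float
    oscillatory: bool
    residual_amplitude_ratio: float
    baseline_period: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def clamp_and_test(
    model,
    params=None,
    variable: str = "R",
    t_end: float = 500.0,
    t_discard: float = 240.0,
    t_end_clamped: float = 2000.0,
    dt_out: float = 0.02,
    reference: str | None = None,
) -> ClampReport:
    """Clamp ``variable`` at its baseline cycle mean and re-test for rhythms.

    The clamped system is restarted from the end of the baseline run (with
    the clamped variable set to its mean) and integrated long enough for
    damped transients to die out; oscillation is judged by
    :func:`redoxclock.simulate.detect_limit_cycle`.
    """
    if params is None:
        params = ParameterSet()
    base = get_model(model, params if isinstance(params, ParameterSet) else None)
    if variable not in base.names:
        raise ValueError(f"{variable!r} is not a state variable of the {base.tag} model")
    baseline = discard_transient(integrate(base, params, t_end=t_end, dt_out=dt_out), t_discard)
    ref_var = reference or ("A" if "A" in baseline.names else baseline.names[0])
    baseline_lc = detect_limit_cycle(baseline, ref_var)
    if not baseline_lc:
        raise ValueError(f"baseline {base.tag} model is not oscillatory: {baseline_lc.reason}")
    ref_series = baseline.series(ref_var)
    baseline_amp = float(ref_series.max() - ref_series.min())

    value = cycle_mean(baseline, variable, reference=ref_var)
    clamped = ClampedModel(base, variable, value)
    y0 = np.array(baseline.states[-1, : len(base.names)], dtype=float)
    y0[clamped.index] = value
    traj = discard_transient(
        integrate(clamped, params, initial=y0, t_end=t_end_clamped, dt_out=dt_out),
        t_end_clamped - (t_end - t_discard),
    )
    lc = detect_limit_cycle(traj, ref_var)
    series = traj.series(ref_var)
    ratio = float((series.max() - series.min()) / baseline_amp) if baseline_amp else 0.0
    return ClampReport(
        variable=variable,
        clamp_value=value,
        oscillatory=bool(lc),
        residual_amplitude_ratio=ratio,
        baseline_period=float(baseline_lc.period),
    )
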