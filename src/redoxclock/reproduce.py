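"""End-to-end reproduction pipeline for the oscillator's headline numbers.

Runs the default-parameter reference simulation, the d and a bifurcation
scans and the period-sensitivity analysis, and compares the computed
quantities against the published reference values (period 24.2 h, I->R
lag 8.7 h, D1->D2 lag 3.9 h, I->D2 lag 4.5 h, oscillation window of d
[0.02, 0.5], a onset 120) at stated tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bifurcation import locate_hopf, period_sensitivity
from .core_model import ParameterSet
from .oscillation_analysis import period_estimate, phase_difference
from .simulate import discard_transient, integrate

__all__ = ["Check", "reference_summary", "hopf_points_d", "hopf_point_a", "run_checks"]

#: published reference values and comparison tolerances
REFERENCE = {
    "period_I": (24.2, 0.3, "abs"),
    "lag_R_I": (8.7, 0.3, "abs"),
    "lag_D2_D1": (3.9, 0.3, "abs"),
    "lag_D2_I": (4.5, 0.3, "abs"),
    "hopf_d_onset": (0.02, 0.25, "rel"),
    "hopf_d_offset": (0.5, 0.25, "rel"),
    "hopf_a_onset": (120.0, 0.15, "rel"),
}


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    reference: float
    tolerance: float
    kind: str  # abs | rel

    @property
    def passed(self) -> bool:
        if self.kind == "abs":
            return abs(self.computed - self.reference) <= self.tolerance
        return abs(self.computed - self.reference) <= self.tolerance * self.reference


def reference_trajectory(params: ParameterSet | None = None, t_end=500.0, t_discard=240.0, dt_out=0.01):
    """Default-parameter reduced-model limit cycle, transient removed."""
    return discard_transient(
        integrate("reduced", params or ParameterSet(), t_end=t_end, dt_out=dt_out), t_discard
    )


def reference_summary(params: ParameterSet | None = None) -> dict[str, float]:
    """Period and the three published peak lags of the reference simulation."""
    traj = reference_trajectory(params)
    return {
        "period_I": period_estimate(traj, "I").period,
        "lag_R_I": phase_difference(traj, "R", "I"),
        "lag_D2_D1": phase_difference(traj, "D2", "D1"),
        "lag_D2_I": phase_difference(traj, "D2", "I"),
    }


def hopf_points_d(params: ParameterSet | None = None, lo=0.005, hi=1.0):
    """Lower and upper stability changes of d (eigenvalue bisection)."""
    params = params or ParameterSet()
    onset = locate_hopf("d", (lo, params.d), params)
    offset = locate_hopf("d", (params.d, hi), params)
    return onset, offset


def hopf_point_a(params: ParameterSet | None = None, lo=10.0, hi=1000.0):
    params = params or ParameterSet()
    return locate_hopf("a", (lo, hi), params)


def run_checks(params: ParameterSet | None = None, include_sensitivity: bool = True):
    """Compute every headline number and compare at its tolerance.

    Returns (list of Check, extras dict).
    """
    params = params or ParameterSet()
    computed = reference_summary(params)
    d_on, d_off = hopf_points_d(params)
    computed["hopf_d_onset"] = d_on.value
    computed["hopf_d_offset"] = d_off.value
    computed["hopf_a_onset"] = hopf_point_a(params).value
    checks = [
        Check(name, computed[name], ref, tol, kind)
        for name, (ref, tol, kind) in REFERENCE.items()
    ]
    extras: dict[str, float] = {}
    if include_sensitivity:
        for name in ("d", "e", "q", "a"):
            lo, hi = {
                "d": (0.05, 0.45),
                "e": (0.05, 0.45),
                "q": (0.05, 0.45),
                "a": (200.0, 900.0),
            }[name]
            extras[f"sensitivity_{name}"] = period_sensitivity(
                name, lo, hi, n_points=5, params=params
            ).normalized_sensitivity
    return checks, extras
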