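"""One-parameter bifurcation scans, Hopf localization, period sensitivity.

Two complementary observables are computed along each scan:

* the leading real part of the steady-state Jacobian spectrum (the linear
  stability verdict; the steady state of the core model is closed-form, so
  this path needs no integration), and
* the post-transient amplitude envelope (Amin/Amax of the active fraction
  A) and period from direct simulation.

A grid point is flagged oscillatory when the steady state is unstable; the
amplitude criterion (relative A amplitude above 1% of its steady-state
value) is recorded alongside, since close to a Hopf point slow transients
blur amplitude-based verdicts.  Hopf points are refined by root finding on
the leading eigenvalue real part, which is continuous in the parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .core_model import ParameterSet, steady_state, qssa_active_fraction
from .oscillation_analysis import NotOscillatoryError, period_estimate
from .simulate import IntegrationError, discard_transient, integrate

__all__ = [
    "BifurcationResult",
    "HopfPoint",
    "scan_parameter",
    "locate_hopf",
    "find_hopf_points",
    "period_sensitivity",
    "SensitivityResult",
]

SCAN_PARAMS = ("p", "a", "b", "d", "e", "q")


def _leading_re(params: ParameterSet, model: str = "reduced") -> float:
    return steady_state(params, model=model).leading_real_part


def _steady_A(params: ParameterSet) -> float:
    D1, _, R = steady_state(params, model="reduced").state[:3]
    return float(qssa_active_fraction(D1, R, params))


@dataclass
class BifurcationResult:
    """Per-grid-point stability and amplitude data for one scanned parameter."""

    parameter: str
    values: np.ndarray
    oscillatory: np.ndarray  # eigenvalue criterion (authoritative)
    amp_oscillatory: np.ndarray  # amplitude > 1% of steady-state A
    Amin: np.ndarray
    Amax: np.ndarray
    period: np.ndarray  # NaN where not oscillatory
    steady_A: np.ndarray
    re_lambda: np.ndarray
    failed: np.ndarray  # integration failures (flagged, scan continues)
    hopf_points: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "param": self.parameter,
                "value": self.values,
                "oscillatory": self.oscillatory,
                "Amin": self.Amin,
                "Amax": self.Amax,
                "period": self.period,
                "re_lambda": self.re_lambda,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8g")


def _grid(lo: float, hi: float, n_points: int) -> np.ndarray:
    if hi / lo > 100:
        return np.geomspace(lo, hi, n_points)
    return np.linspace(lo, hi, n_points)


def scan_parameter(
    name: str,
    lo: float,
    hi: float,
    n_points: int = 60,
    params: ParameterSet | None = None,
    model: str = "reduced",
    t_end: float = 500.0,
    t_discard: float = 240.0,
    dt_out: float = 0.02,
    refine_hopf: bool = True,
) -> BifurcationResult:
    """Scan one core-model parameter over [lo, hi] (log grid when hi/lo > 100)."""
    if name not in SCAN_PARAMS:
        raise ValueError(f"scan parameter must be one of {SCAN_PARAMS}")
    if not lo < hi:
        raise ValueError("need lo < hi")
    params = params or ParameterSet()
    values = _grid(lo, hi, n_points)
    n = len(values)
    res = BifurcationResult(
        parameter=name,
        values=values,
        oscillatory=np.zeros(n, bool),
        amp_oscillatory=np.zeros(n, bool),
        Amin=np.full(n, np.nan),
        Amax=np.full(n, np.nan),
        period=np.full(n, np.nan),
        steady_A=np.full(n, np.nan),
        re_lambda=np.full(n, np.nan),
        failed=np.zeros(n, bool),
    )
    for i, v in enumerate(values):
        pars = params.replace(**{name: float(v)})
        ss_A = _steady_A(pars)
        res.steady_A[i] = ss_A
        res.re_lambda[i] = _leading_re(pars, model)
        res.oscillatory[i] = res.re_lambda[i] > 0
        try:
            traj = discard_transient(
                integrate(model, pars, t_end=t_end, dt_out=dt_out), t_discard
            )
        except IntegrationError:
            res.failed[i] = True
            continue
        A = traj.series("A")
        res.Amin[i], res.Amax[i] = float(A.min()), float(A.max())
        res.amp_oscillatory[i] = (res.Amax[i] - res.Amin[i]) > 0.01 * ss_A
        if res.oscillatory[i]:
            try:
                res.period[i] = period_estimate(traj, "A", max_cv=0.05).period
            except NotOscillatoryError:
                pass
    if refine_hopf:
        res.hopf_points = find_hopf_points(res, params, model)
    return res


@dataclass(frozen=True)
class HopfPoint:
    parameter: str
    value: float  # eigenvalue-crossing location (authoritative)
    amplitude_onset: float | None = None  # simulation cross-check, may differ near
    # the bifurcation where transients are slow

    def as_dict(self):
        return {
            "parameter": self.parameter,
            "value": self.value,
            "amplitude_onset": self.amplitude_onset,
        }


def locate_hopf(
    name: str,
    bracket: tuple[float, float],
    params: ParameterSet | None = None,
    model: str = "reduced",
    rel_xtol: float = 1e-3,
    amplitude_crosscheck: bool = False,
    amplitude_t_end: float = 2000.0,
) -> HopfPoint:
    """Refine a stability change of the steady state inside ``bracket``.

    Root finding is performed on the leading Jacobian eigenvalue real part
    (sign change required).  With ``amplitude_crosscheck`` the onset is also
    bisected on the simulated amplitude indicator (relative A amplitude
    above 1% of steady state, starting from a 5% perturbation of the fixed
    point so growth/decay of the local mode decides the verdict).
    """
    params = params or ParameterSet()
    lo, hi = bracket
    f = lambda v: _leading_re(params.replace(**{name: float(v)}), model)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(f"no stability change of {name} in {bracket}: Re(lambda) = {flo:.3g}, {fhi:.3g}")
    value = float(brentq(f, lo, hi, xtol=rel_xtol * lo, rtol=rel_xtol))
    amp_onset = None
    if amplitude_crosscheck:
        amp_onset = _amplitude_onset(
            name, (lo, hi), params, model, rel_xtol=5e-3, t_end=amplitude_t_end
        )
    return HopfPoint(name, value, amp_onset)


def _amplitude_indicator(name, v, params, model, t_end=2000.0):
    """Positive iff oscillations grow (or persist) from a small perturbation
    of the fixed point: compares the A-amplitude in a late window against an
    early one, so that slowly decaying transients near the bifurcation do
    not masquerade as rhythms."""
    pars = params.replace(**{name: float(v)})
    ss = steady_state(pars, model="reduced")
    y0 = ss.state * 1.05
    if model == "full":
        ssf = steady_state(pars, model="full")
        y0 = np.maximum(ssf.state * 1.05, 0.0)
        y0[1] = pars.T - y0[0]
    traj = integrate(model, pars, initial=y0, t_end=t_end, dt_out=0.05)
    A = traj.series("A")
    quarter = len(A) // 4
    early = A[quarter : 2 * quarter]
    late = A[3 * quarter :]
    amp_early = early.max() - early.min()
    amp_late = late.max() - late.min()
    # oscillatory = not decaying AND of nonnegligible size
    return min(amp_late - 0.99 * amp_early, amp_late - 0.01 * _steady_A(pars))


def _amplitude_onset(name, bracket, params, model, rel_xtol=5e-3, t_end=2000.0):
    lo, hi = bracket
    g = lambda v: _amplitude_indicator(name, v, params, model, t_end=t_end)
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        return None
    for _ in range(40):
        mid = np.sqrt(lo * hi) if hi / lo > 3 else 0.5 * (lo + hi)
        if (hi - lo) / mid < rel_xtol:
            break
        if g(mid) * glo > 0:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def find_hopf_points(result: BifurcationResult, params: ParameterSet, model: str = "reduced"):
    """Refine every sign change of Re(lambda) along an existing scan grid."""
    pts = []
    sign = np.sign(result.re_lambda)
    for i in np.nonzero(np.diff(sign) != 0)[0]:
        pts.append(
            locate_hopf(
                result.parameter,
                (float(result.values[i]), float(result.values[i + 1])),
                params,
                model,
            )
        )
    return pts


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    values: np.ndarray
    periods: np.ndarray  # NaN outside the oscillatory range
    normalized_sensitivity: float  # |d log(period) / d log(param)| at the default


def _period_at(params: ParameterSet, model: str, t_end=500.0, t_discard=240.0) -> float:
    traj = discard_transient(integrate(model, params, t_end=t_end, dt_out=0.02), t_discard)
    return period_estimate(traj, "A" if "A" in traj.names else traj.names[0], max_cv=0.05).period


def period_sensitivity(
    name: str,
    lo: float,
    hi: float,
    n_points: int = 25,
    params: ParameterSet | None = None,
    model: str = "reduced",
    rel_step: float = 0.05,
) -> SensitivityResult:
    """Period over the oscillatory sub-range of one parameter.

    The normalized sensitivity s = |d log(period)/d log(param)| is a central
    log-log difference at the default parameter point (relative step 5%).
    """
    params = params or ParameterSet()
    values = _grid(lo, hi, n_points)
    periods = np.full(len(values), np.nan)
    for i, v in enumerate(values):
        pars = params.replace(**{name: float(v)})
        if _leading_re(pars, model) <= 0:
            continue
        try:
            periods[i] = _period_at(pars, model)
        except (NotOscillatoryError, IntegrationError):
            pass
    v0 = getattr(params, name)
    try:
        up = _period_at(params.replace(**{name: v0 * (1 + rel_step)}), model)
        dn = _period_at(params.replace(**{name: v0 / (1 + rel_step)}), model)
        s = abs(np.log(up / dn) / (2 * np.log(1 + rel_step)))
    except (NotOscillatoryError, IntegrationError):
        s = float("nan")
    if np.all(np.isnan(periods)):
        raise NotOscillatoryError(f"no oscillatory points for {name} in [{lo}, {hi}]")
    return SensitivityResult(name, values, periods, float(s))
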