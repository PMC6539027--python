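"""Core five-variable model of the mitochondrial Prx3/Srx redox oscillator.

The model tracks active peroxiredoxin 3 (``A``, Prx3-SOH), hyperoxidized
inactive Prx3 (``I``, Prx3-SO2H), mitochondrial and cytosolic hydrogen
peroxide (``D1``, ``D2``) and mitochondrial sulfiredoxin (``R``).  All
reactions are mass action:

* constant mitochondrial H2O2 production at rate ``p``,
* hyperoxidation ``A + D1 -> I`` at rate ``a*A*D1`` (inactivates Prx3 while
  removing the oxidant),
* Srx-catalyzed rescue ``I -> A`` at rate ``b*I*R`` (R acts catalytically),
* leakage to the cytosol ``D1 -> D2`` at rate ``d*D1``,
* Srx import driven by cytosolic H2O2, ``D2 -> R`` at rate ``e*D2``,
* first-order Srx degradation ``q*R``.

The Prx3 pool is conserved, ``A + I = T``.  A quasi-steady-state
approximation (QSSA) on the fast ``A`` equation gives the reduced
three-variable form in (D1, D2, R) whose single nonlinearity
``a*b*D1*R*T / (b*R + a*D1)`` drives the oscillation; the reduced form is
the canonical one for quantitative analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ParameterSet",
    "SteadyState",
    "ConstraintCheck",
    "rhs_full",
    "rhs_reduced",
    "qssa_active_fraction",
    "jacobian",
    "steady_state",
    "linearized_rhs",
    "validate_physiology",
    "FullCoreModel",
    "ReducedCoreModel",
    "LinearizedCoreModel",
    "get_model",
    "FULL_NAMES",
    "REDUCED_NAMES",
]

FULL_NAMES = ("A", "I", "D1", "D2", "R")
REDUCED_NAMES = ("D1", "D2", "R")

#: Reference parameter values (arbitrary units, time in hours) that place the
#: oscillator in the circadian regime with a ~24.2 h period.
DEFAULTS = {"p": 1.0, "a": 1000.0, "b": 2.0, "d": 0.2, "e": 0.1, "q": 0.1, "T": 1.0}


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic rates of the core oscillator (a.u., hours).

    p : mitochondrial H2O2 production rate (a.u. h^-1)
    a : Prx3-SOH hyperoxidation rate (a.u.^-1 h^-1)
    b : Srx-mediated Prx3-SO2H reduction rate (a.u.^-1 h^-1)
    d : H2O2 translocation (mito -> cytosol) rate (h^-1)
    e : Srx translocation (cytosol -> mito) rate (h^-1)
    q : mitochondrial Srx degradation rate (h^-1)
    T : conserved total Prx3 pool A + I (a.u.)
    """

    p: float = DEFAULTS["p"]
    a: float = DEFAULTS["a"]
    b: float = DEFAULTS["b"]
    d: float = DEFAULTS["d"]
    e: float = DEFAULTS["e"]
    q: float = DEFAULTS["q"]
    T: float = DEFAULTS["T"]

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {f.name} must be finite and > 0, got {v}")

    def replace(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    # -- flat key/value config I/O (TOML or YAML by extension) ---------------
    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(path.read_text())
        else:
            import tomllib

            data = tomllib.loads(path.read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))
        else:
            lines = [f"{k} = {v!r}" for k, v in self.as_dict().items()]
            path.write_text("\n".join(lines) + "\n")


def _check_nonnegative(y: np.ndarray, what: str) -> None:
    if np.any(np.asarray(y) < 0):
        raise ValueError(f"negative component in {what}: {np.asarray(y)!r}")


def _rhs_full_raw(y, params: ParameterSet):
    A, I, D1, D2, R = y
    hyper = params.a * A * D1
    rescue = params.b * I * R
    return np.array(
        [
            rescue - hyper,
            hyper - rescue,
            params.p - hyper - params.d * D1,
            params.d * D1 - params.e * D2,
            params.e * D2 - params.q * R,
        ]
    )


def rhs_full(state, params: ParameterSet) -> np.ndarray:
    """Time derivatives (dA, dI, dD1, dD2, dR) of the full five-variable model."""
    state = np.asarray(state, dtype=float)
    _check_nonnegative(state, "state")
    return _rhs_full_raw(state, params)


def qssa_active_fraction(D1, R, params: ParameterSet):
    """Active Prx3 level A = b*R*T / (a*D1 + b*R) under the QSSA.

    At the singular point D1 = R = 0 the expression is 0/0; the pool is
    returned fully active (A = T), the limit along R > 0, D1 -> 0, and a
    warning is emitted since no oxidant is present.
    """
    D1 = np.asarray(D1, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(D1 < 0) or np.any(R < 0):
        raise ValueError("D1 and R must be nonnegative")
    den = params.a * D1 + params.b * R
    singular = den == 0
    if np.any(singular):
        warnings.warn(
            "QSSA active fraction evaluated at D1 = R = 0; returning fully "
            "active pool A = T",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(singular, params.T, params.b * R * params.T / np.where(singular, 1.0, den))
    return A if A.ndim else float(A)


def _removal_flux_raw(D1, R, params: ParameterSet):
    """QSSA hyperoxidation flux a*b*D1*R*T / (b*R + a*D1) (0 at the singular point)."""
    den = params.a * D1 + params.b * R
    if den == 0:
        return 0.0
    return params.a * params.b * D1 * R * params.T / den


def _rhs_reduced_raw(y, params: ParameterSet):
    D1, D2, R = y
    f = _removal_flux_raw(D1, R, params)
    return np.array(
        [
            params.p - f - params.d * D1,
            params.d * D1 - params.e * D2,
            params.e * D2 - params.q * R,
        ]
    )


def rhs_reduced(state, params: ParameterSet) -> np.ndarray:
    """Time derivatives (dD1, dD2, dR) of the QSSA-reduced model."""
    state = np.asarray(state, dtype=float)
    _check_nonnegative(state, "state")
    return _rhs_reduced_raw(state, params)


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------

def _jac_reduced(y, params: ParameterSet):
    D1, D2, R = y
    den = params.b * R + params.a * D1
    if den == 0:
        raise ValueError("Jacobian undefined at the QSSA singular point D1 = R = 0")
    # partials of f = a*b*D1*R*T/den
    fD1 = params.a * params.b**2 * R**2 * params.T / den**2
    fR = params.a**2 * params.b * D1**2 * params.T / den**2
    return np.array(
        [
            [-fD1 - params.d, 0.0, -fR],
            [params.d, -params.e, 0.0],
            [0.0, params.e, -params.q],
        ]
    )


def _jac_full(y, params: ParameterSet):
    A, I, D1, D2, R = y
    a, b, d, e, q = params.a, params.b, params.d, params.e, params.q
    return np.array(
        [
            [-a * D1, b * R, -a * A, 0.0, b * I],
            [a * D1, -b * R, a * A, 0.0, -b * I],
            [-a * D1, 0.0, -a * A - d, 0.0, 0.0],
            [0.0, 0.0, d, -e, 0.0],
            [0.0, 0.0, 0.0, e, -q],
        ]
    )


def jacobian(state, params: ParameterSet, model: str = "reduced") -> np.ndarray:
    """Analytic Jacobian of the chosen model at ``state``."""
    state = np.asarray(state, dtype=float)
    if model == "reduced":
        if state.shape != (3,):
            raise ValueError("reduced model state is (D1, D2, R)")
        return _jac_reduced(state, params)
    if model == "full":
        if state.shape != (5,):
            raise ValueError("full model state is (A, I, D1, D2, R)")
        return _jac_full(state, params)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyState:
    """A fixed point together with its linear stability.

    For the full model the Prx3 conservation law contributes an exactly zero
    eigenvalue; stability is judged on the remaining spectrum.
    """

    state: np.ndarray
    names: tuple[str, ...]
    jacobian_eigenvalues: np.ndarray
    stable: bool
    model: str

    @property
    def leading_real_part(self) -> float:
        return float(np.max(self.jacobian_eigenvalues.real))

    def __getitem__(self, name: str) -> float:
        return float(self.state[self.names.index(name)])


def _reduced_fixed_point(params: ParameterSet) -> np.ndarray:
    """Closed-form positive fixed point of the reduced model.

    Setting dD2 = dR = 0 gives the flux chain d*D1 = e*D2 = q*R, and
    substituting R = (d/q) D1 into dD1 = 0 collapses the nonlinearity to a
    linear relation, yielding D1* = p (b d + a q) / (d (a b T + b d + a q)).
    """
    p, a, b, d, e, q, T = (params.p, params.a, params.b, params.d, params.e, params.q, params.T)
    D1 = p * (b * d + a * q) / (d * (a * b * T + b * d + a * q))
    return np.array([D1, d * D1 / e, d * D1 / q])


def steady_state(params: ParameterSet, model: str = "reduced") -> SteadyState:
    """Positive steady state with eigenvalues and a stability verdict."""
    red = _reduced_fixed_point(params)
    if model == "reduced":
        y, names = red, REDUCED_NAMES
        eig = np.linalg.eigvals(_jac_reduced(y, params))
        stable = bool(np.all(eig.real < 0))
    elif model == "full":
        D1, D2, R = red
        A = qssa_active_fraction(D1, R, params)
        y = np.array([A, params.T - A, D1, D2, R])
        names = FULL_NAMES
        eig = np.linalg.eigvals(_jac_full(y, params))
        # drop the conservation zero mode before judging stability
        keep = np.abs(eig) > 1e-10
        stable = bool(np.all(eig.real[keep] < 0))
        eig = eig[keep]
    else:
        raise ValueError(f"unknown model {model!r}")
    res = _rhs_reduced_raw(red, params)
    if np.max(np.abs(res)) > 1e-9:
        raise RuntimeError(f"steady-state residual too large: {res}")
    return SteadyState(state=y, names=names, jacobian_eigenvalues=eig, stable=stable, model=model)


# ---------------------------------------------------------------------------
# Model objects (uniform interface for the integrator)
# ---------------------------------------------------------------------------

class FullCoreModel:
    """Five-variable core model with dynamic A and I."""

    tag = "full"
    names = FULL_NAMES

    def rhs(self, t, y, params: ParameterSet):
        return _rhs_full_raw(y, params)

    def jac(self, t, y, params: ParameterSet):
        return _jac_full(y, params)

    def default_initial(self, params: ParameterSet) -> np.ndarray:
        # "fresh mitochondrion": fully active pool, no oxidant, no rescuer
        return np.array([params.T, 0.0, 0.0, 0.0, 0.0])

    def derived(self, states: np.ndarray, params: ParameterSet) -> dict[str, np.ndarray]:
        return {}


class ReducedCoreModel:
    """QSSA-reduced model in (D1, D2, R); A and I are reported algebraically."""

    tag = "reduced"
    names = REDUCED_NAMES

    def rhs(self, t, y, params: ParameterSet):
        return _rhs_reduced_raw(y, params)

    def jac(self, t, y, params: ParameterSet):
        return _jac_reduced(y, params)

    def default_initial(self, params: ParameterSet) -> np.ndarray:
        return np.zeros(3)

    def derived(self, states: np.ndarray, params: ParameterSet) -> dict[str, np.ndarray]:
        D1, R = states[:, 0], states[:, 2]
        den = params.a * D1 + params.b * R
        A = np.where(den > 0, params.b * R * params.T / np.where(den > 0, den, 1.0), params.T)
        return {"A": A, "I": params.T - A}


class LinearizedCoreModel(ReducedCoreModel):
    """Reduced model with the nonlinearity replaced by its tangent plane.

    The QSSA flux a*b*D1*R*T/(bR + aD1) is expanded to first order about the
    fixed point.  A first-order expansion preserves the Jacobian there, so
    the linearized model's fixed point has exactly the nonlinear model's
    eigenvalues; being linear, however, the system cannot sustain a limit
    cycle — in the oscillatory regime its trajectories spiral outward
    unboundedly instead of settling on a rhythm.  Integrating it therefore
    shows that the saturating nonlinearity, not just the loop structure, is
    what shapes and bounds the oscillation.
    """

    tag = "linearized"

    def __init__(self, params: ParameterSet):
        ss = steady_state(params, model="reduced")
        D1s, _, Rs = ss.state
        den = params.b * Rs + params.a * D1s
        self.expansion_point = ss.state.copy()
        self.f0 = _removal_flux_raw(D1s, Rs, params)
        self.fD1 = params.a * params.b**2 * Rs**2 * params.T / den**2
        self.fR = params.a**2 * params.b * D1s**2 * params.T / den**2
        self._params = params

    def _flux(self, D1, R):
        D1s, _, Rs = self.expansion_point
        return self.f0 + self.fD1 * (D1 - D1s) + self.fR * (R - Rs)

    def rhs(self, t, y, params: ParameterSet):
        D1, D2, R = y
        f = self._flux(D1, R)
        return np.array(
            [
                params.p - f - params.d * D1,
                params.d * D1 - params.e * D2,
                params.e * D2 - params.q * R,
            ]
        )

    def jac(self, t, y, params: ParameterSet):
        return np.array(
            [
                [-self.fD1 - params.d, 0.0, -self.fR],
                [params.d, -params.e, 0.0],
                [0.0, params.e, -params.q],
            ]
        )

    def default_initial(self, params: ParameterSet) -> np.ndarray:
        # start near, but off, the fixed point so decay/growth is observable
        return self.expansion_point * 1.05

    def derived(self, states, params):
        # the QSSA A saturates in [0, T] and would mask unbounded growth of
        # the linear system; report only the integrated variables
        return {}


def linearized_rhs(params: ParameterSet) -> LinearizedCoreModel:
    """Model with the nonlinear flux replaced by its tangent plane at the fixed point."""
    return LinearizedCoreModel(params)


def get_model(tag: str, params: ParameterSet | None = None):
    """Resolve a model tag (full | reduced | linearized | detailed) to a model object."""
    if not isinstance(tag, str):
        return tag
    if tag == "full":
        return FullCoreModel()
    if tag == "reduced":
        return ReducedCoreModel()
    if tag == "linearized":
        return LinearizedCoreModel(params or ParameterSet())
    if tag == "detailed":
        from .detailed_model import DetailedModel

        return DetailedModel()
    raise ValueError(f"unknown model tag {tag!r}")


# ---------------------------------------------------------------------------
# Physiological plausibility checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintCheck:
    name: str
    ok: bool
    value: float
    message: str


def validate_physiology(params: ParameterSet) -> list[ConstraintCheck]:
    """Advisory checks against measured Prx3/Srx kinetics.

    * the hyperoxidation/translocation ratio a/d should be ~1e4 (within an
      order of magnitude), reflecting that only ~0.01% of the membrane area
      transports H2O2;
    * the hyperoxidation/reduction ratio a/b should be in 1e3..1e4 (Srx is a
      slow catalyst, ~2 M^-1 s^-1);
    * q should be consistent with the measured 4-5 h mitochondrial Srx
      half-life (ln 2 / q).
    """
    checks = []
    ad = params.a / params.d
    checks.append(
        ConstraintCheck(
            "a/d ~ 1e4",
            1e3 <= ad <= 1e5,
            ad,
            f"hyperoxidation/translocation ratio a/d = {ad:.3g} "
            "(expected within an order of magnitude of 1e4)",
        )
    )
    ab = params.a / params.b
    checks.append(
        ConstraintCheck(
            "a/b ~ 1e3..1e4",
            10**2.5 <= ab <= 10**4.5,
            ab,
            f"hyperoxidation/reduction ratio a/b = {ab:.3g} (expected within "
            "half an order of magnitude of the measured 1e3-1e4 band)",
        )
    )
    half_life = math.log(2) / params.q
    checks.append(
        ConstraintCheck(
            "Srx half-life 4-5 h",
            3.0 <= half_life <= 8.0,
            half_life,
            f"Srx half-life ln2/q = {half_life:.2f} h (measured 4-5 h; "
            "accepted within 3-8 h)",
        )
    )
    return checks
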