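"""Detailed nine-species biochemical model of the Prx3/Srx system.

Species (arbitrary units): the four Prx3 redox forms — reduced thiol
(``PrxSH``), sulfenic acid (``PrxSOH``), intersubunit disulfide (``PrxSS``)
and hyperoxidized sulfinic acid (``PrxSO2H``) — the two oxidant pools
(``H2O2_mito``, ``H2O2_cyto``) and the three sulfiredoxin pools
(``Srx_cyto``, ``SrxHsp90``, ``Srx_mito``).

Mass-action reactions:

* k1: PrxSH + H2O2_mito -> PrxSOH        (peroxidatic oxidation)
* k2: PrxSOH -> PrxSS                    (disulfide/resolution step)
* k3: PrxSS -> PrxSH                     (thioredoxin-mediated recycling;
                                          Trx is folded into k3 as a
                                          constant reductant reservoir)
* k4: PrxSOH + H2O2_mito -> PrxSO2H      (hyperoxidation, inactivating)
* k5: PrxSO2H + Srx_mito -> PrxSOH       (Srx rescue; Srx catalytic)
* k6: H2O2_mito -> H2O2_cyto             (leak to the cytosol)
* k7: Srx_cyto + H2O2_cyto -> SrxHsp90   (H2O2-stimulated Srx/Hsp90 complex)
* k8: SrxHsp90 -> Srx_mito               (mitochondrial import)
* k9: Srx_mito -> 0                      (degradation)

plus constant mitochondrial H2O2 production ``p_det`` and a buffered
cytosolic Srx supply ``ks*(S0 - Srx_cyto)`` (fresh synthesis balancing the
pool consumed by complex formation; without it the degradation k9 would
slowly empty total Srx and the rhythm would die out).

The total Prx3 pool (sum of the four redox forms) is conserved exactly.

The default :data:`CORRESPONDENCE` parameterization maps the core-model
rates onto this scheme (k4<->a, k5<->b, k6<->d, k8<->e, k9<->q, p_det<->p)
with the remaining steps chosen so they are not rate limiting: k1 is fast
(physically Prx oxidation by H2O2 is orders of magnitude faster than
hyperoxidation), k3 and k7 are 10-100x faster than the slow translocation/
degradation rates, and k2 is small so the disulfide recycle is a low-flux
side branch — which is exactly what makes the PrxSH/PrxSS branch
dispensable for rhythm generation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "DetailedParameters",
    "DetailedModel",
    "CORRESPONDENCE",
    "rhs_detailed",
    "amplitude_vs_k1",
    "DETAILED_NAMES",
]

DETAILED_NAMES = (
    "PrxSH",
    "PrxSOH",
    "PrxSS",
    "PrxSO2H",
    "H2O2_mito",
    "H2O2_cyto",
    "Srx_cyto",
    "SrxHsp90",
    "Srx_mito",
)


@dataclass(frozen=True)
class DetailedParameters:
    """Rate constants of the detailed model (a.u., hours)."""

    k1: float = 1e4
    k2: float = 0.2
    k3: float = 1.0
    k4: float = 1000.0
    k5: float = 2.0
    k6: float = 0.2
    k7: float = 10.0
    k8: float = 0.1
    k9: float = 0.1
    p_det: float = 1.0
    ks: float = 10.0  # cytosolic Srx replenishment rate (h^-1)
    S0: float = 1.0  # cytosolic Srx reservoir level (a.u.)
    prx_total: float = 1.0  # conserved Prx3 pool (a.u.)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {f.name} must be finite and > 0, got {v}")

    def replace(self, **kwargs: float) -> "DetailedParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


#: Correspondence parameterization: core defaults mapped onto k4..k9.
CORRESPONDENCE = DetailedParameters()


def _rhs_detailed_raw(y, params: DetailedParameters):
    SH, SOH, SS, SO2H, Dm, Dc, Sc, SH90, Sm = y
    k = params
    v1 = k.k1 * SH * Dm
    v2 = k.k2 * SOH
    v3 = k.k3 * SS
    v4 = k.k4 * SOH * Dm
    v5 = k.k5 * SO2H * Sm
    v6 = k.k6 * Dm
    v7 = k.k7 * Sc * Dc
    v8 = k.k8 * SH90
    v9 = k.k9 * Sm
    return np.array(
        [
            -v1 + v3,
            v1 - v2 - v4 + v5,
            v2 - v3,
            v4 - v5,
            k.p_det - v1 - v4 - v6,
            v6 - v7,
            k.ks * (k.S0 - Sc) - v7,
            v7 - v8,
            v8 - v9,
        ]
    )


def rhs_detailed(state, params: DetailedParameters) -> np.ndarray:
    """Mass-action time derivatives of the nine-species detailed model."""
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError(f"negative component in state: {state!r}")
    return _rhs_detailed_raw(state, params)


class DetailedModel:
    """Uniform model interface around :func:`rhs_detailed`."""

    tag = "detailed"
    names = DETAILED_NAMES

    def __init__(self, params: DetailedParameters | None = None):
        self.params_default = params or CORRESPONDENCE

    def rhs(self, t, y, params: DetailedParameters):
        return _rhs_detailed_raw(y, params)

    def jac(self, t, y, params: DetailedParameters):
        SH, SOH, SS, SO2H, Dm, Dc, Sc, SH90, Sm = y
        k = params
        J = np.zeros((9, 9))
        # d(v)/d(species) assembled reaction by reaction
        # v1 = k1*SH*Dm
        for i, s in ((0, -1), (1, +1), (4, -1)):
            J[i, 0] += s * k.k1 * Dm
            J[i, 4] += s * k.k1 * SH
        # v2 = k2*SOH
        J[1, 1] += -k.k2
        J[2, 1] += k.k2
        # v3 = k3*SS
        J[2, 2] += -k.k3
        J[0, 2] += k.k3
        # v4 = k4*SOH*Dm
        for i, s in ((1, -1), (3, +1), (4, -1)):
            J[i, 1] += s * k.k4 * Dm
            J[i, 4] += s * k.k4 * SOH
        # v5 = k5*SO2H*Sm
        for i, s in ((3, -1), (1, +1)):
            J[i, 3] += s * k.k5 * Sm
            J[i, 8] += s * k.k5 * SO2H
        # v6 = k6*Dm
        J[4, 4] += -k.k6
        J[5, 4] += k.k6
        # v7 = k7*Sc*Dc
        for i, s in ((5, -1), (6, -1), (7, +1)):
            J[i, 6] += s * k.k7 * Dc
            J[i, 5] += s * k.k7 * Sc
        # Srx_cyto replenishment
        J[6, 6] += -k.ks
        # v8 = k8*SH90
        J[7, 7] += -k.k8
        J[8, 7] += k.k8
        # v9 = k9*Sm
        J[8, 8] += -k.k9
        return J

    def default_initial(self, params: DetailedParameters) -> np.ndarray:
        y0 = np.zeros(9)
        y0[0] = params.prx_total  # fully reduced Prx3 pool
        y0[6] = params.S0  # cytosolic Srx at its reservoir level
        return y0

    def derived(self, states, params):
        return {}


def amplitude_vs_k1(
    params: DetailedParameters,
    k1_values,
    t_end: float = 700.0,
    t_discard: float = 300.0,
    dt_out: float = 0.02,
):
    """Post-transient PrxSO2H and Srx_mito oscillation amplitudes versus k1.

    Returns a pandas DataFrame sorted by k1 with columns
    ``k1, oscillatory, PrxSO2H_amplitude, Srx_mito_amplitude``.
    Non-oscillatory entries are flagged (not dropped); their amplitudes are
    the residual post-transient ranges.
    """
    import pandas as pd

    from .oscillation_analysis import find_peaks
    from .simulate import discard_transient, integrate

    rows = []
    model = DetailedModel()
    for k1 in sorted(float(v) for v in k1_values):
        pars = params.replace(k1=k1)
        traj = discard_transient(
            integrate(model, pars, t_end=t_end, dt_out=dt_out), t_discard
        )
        so2h = traj.series("PrxSO2H")
        srx = traj.series("Srx_mito")
        oscillatory = len(find_peaks(traj, "PrxSO2H")) >= 3
        rows.append(
            {
                "k1": k1,
                "oscillatory": oscillatory,
                "PrxSO2H_amplitude": float(so2h.max() - so2h.min()),
                "Srx_mito_amplitude": float(srx.max() - srx.min()),
            }
        )
    return pd.DataFrame(rows)
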