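# redoxclock

Simulation and analysis of the mitochondrial **Prx3-SO₂H / sulfiredoxin
circadian redox oscillator** — a transcription-independent ~24 h clock
observed in mammalian adrenal gland, heart and brown adipose tissue.

Peroxiredoxin 3 (Prx3) clears mitochondrial H₂O₂ and, as a side effect, is
slowly hyperoxidized to a catalytically inactive sulfinic form
(Prx3-SO₂H). When the active pool collapses, H₂O₂ accumulates and leaks to
the cytosol, where it drives sulfiredoxin (Srx) import into mitochondria;
imported Srx reduces Prx3-SO₂H back to the active form and the cycle
restarts. That delayed negative feedback — fast inactivation chased by a
slow, multi-step rescue — is sufficient to produce robust self-sustained
relaxation oscillations with a circadian period.

## The model

Core five-variable mass-action model (arbitrary units, time in hours);
`A` = active Prx3-SOH, `I` = inactive Prx3-SO₂H, `D1`/`D2` = mitochondrial/
cytosolic H₂O₂, `R` = mitochondrial Srx, with a conserved pool `A + I = T`:

    dA/dt  =  b·I·R − a·A·D1           (rescue − hyperoxidation)
    dI/dt  = −dA/dt
    dD1/dt =  p − a·A·D1 − d·D1
    dD2/dt =  d·D1 − e·D2
    dR/dt  =  e·D2 − q·R

A quasi-steady-state approximation on the fast `A` equation gives
`A = bRT/(aD1 + bR)` and the canonical reduced model in `(D1, D2, R)`,
whose single nonlinearity `abD1RT/(bR + aD1)` carries the rhythm. The
reference parameters `p=1, a=1000, b=2, d=0.2, e=q=0.1, T=1` yield a
24.2 h limit cycle.

The package ships, as tested modules:

* `core_model` — equations, closed-form steady states, analytic Jacobians,
  tangent-plane linearization, physiological parameter checks;
* `detailed_model` — a nine-species biochemical variant (full Prx3 redox
  cycle, cytosolic Srx/Hsp90 import pathway);
* `simulate` — tight-tolerance LSODA integration, transient handling,
  limit-cycle detection;
* `oscillation_analysis` — interpolated peak times, period, pairwise lags;
* `bifurcation` — parameter scans, eigenvalue-based Hopf localization with
  simulation cross-checks, period sensitivity;
* `switches` — the three-phase / two-switch cycle annotation;
* `reduction` — clamping variables at their cycle mean to identify the
  core motif;
* `synthetic_data` — western-blot-like noisy sparse time courses and a
  template-fit period/phase estimator with bootstrap CIs;
* `cli` — the `redoxclock` command-line entry point.

## Worked example

```python
from redoxclock import (ParameterSet, integrate, discard_transient,
                        period_estimate, phase_difference)

traj = discard_transient(integrate("reduced", ParameterSet(), t_end=500.0), 240.0)
print(f"period   {period_estimate(traj, 'I').period:.2f} h")
print(f"I -> R   {phase_difference(traj, 'R', 'I'):.2f} h")
print(f"D1 -> D2 {phase_difference(traj, 'D2', 'D1'):.2f} h")
```

prints

    period   24.23 h
    I -> R   8.66 h
    D1 -> D2 3.87 h

i.e. a circadian period, Srx peaking ~8.7 h after Prx3-SO₂H (the measured
mitochondrial import delay), and cytosolic H₂O₂ peaking ~3.9 h after
mitochondrial H₂O₂ — a predicted signaling window toward the canonical
clock. The same numbers are available from the shell:

```sh
redoxclock simulate --model reduced --t-end 500 --out traj.csv
redoxclock bifurcate --param d --lo 0.005 --hi 1 --points 60 --out scan.csv
redoxclock clamp --variable R        # rhythms are abolished: R closes the loop
redoxclock synth --seed 3            # noisy blot-like series + recovery
redoxclock reproduce --out report/   # all headline checks at once
```

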