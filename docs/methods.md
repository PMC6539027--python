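# Methods

## Model equations and assumptions

The core oscillator is a mass-action network of five species: active Prx3
(`A`, the sulfenic Prx3-SOH form), hyperoxidized inactive Prx3 (`I`,
Prx3-SO₂H), mitochondrial and cytosolic H₂O₂ (`D1`, `D2`) and
mitochondrial sulfiredoxin (`R`). The assumptions are:

* constant mitochondrial H₂O₂ production `p` (oxidative metabolism treated
  as time-invariant; the model is autonomous, with no input from the
  transcriptional clock);
* a constant total Prx3 pool, `A + I = T` (synthesis and degradation of
  the enzyme are slow compared to its redox cycling);
* hyperoxidation `A + D1 → I` (rate `a·A·D1`) both inactivates Prx3 and is
  the dominant H₂O₂ removal route, so losing `A` means losing clearance
  capacity;
* Srx acts catalytically in the rescue `I → A` (rate `b·I·R`); `R` itself
  is produced from the cytosolic pathway at rate `e·D2` and degraded at
  `q·R`. `R` degradation is unconditionally first order — the observation
  that Srx becomes degradable late in the cycle emerges from the timing of
  the dynamics, not from an explicit gating term;
* H₂O₂ leak `D1 → D2` at `d·D1` (passive aquaporin-mediated transport,
  one-way because cytosolic H₂O₂ is further consumed downstream).

Because `a·D1` is orders of magnitude faster than every other rate acting
on `A`, the `A` equation is eliminated by a quasi-steady-state
approximation, `A = bRT/(aD1 + bR)`, leaving three ODEs in `(D1, D2, R)`
with the single nonlinear removal flux `abD1RT/(bR + aD1)`. This reduced
form is the canonical one for all quantitative results; the full
five-variable form is retained for conservation/positivity property tests
and differs from it by ~3% in period at the default parameters (the QSSA
is excellent but not exact at `a = 1000`).

Default parameters (arbitrary units, hours): `p=1, a=1000, b=2, d=0.2,
e=q=0.1, T=1`. These satisfy the physiological ratio constraints checked
by `validate_physiology`: hyperoxidation ~10⁴-fold faster than membrane
translocation (`a/d = 5000`), Srx catalysis 10³–10⁴-fold slower than
hyperoxidation (order-of-magnitude check), and `q` compatible with the
measured 4–5 h mitochondrial Srx half-life (`ln 2 / q ≈ 6.9 h` at the
default, 4.3 h at the measured `q = 0.16 h⁻¹`).

## Numerical choices

* Integration: LSODA with `rtol 1e-8`, `atol 1e-10`, analytic Jacobians,
  dense uniform output (`dt_out = 0.01 h`) so quadratic peak interpolation
  resolves phase differences far below 0.1 h. Runs are deterministic;
  halving tolerances moves stored states by < 1e-5 relative.
* Initial condition: the "fresh mitochondrion" (`A = T`, everything else
  zero). Limit-cycle quantities are initial-condition independent; 240 h
  of transient are discarded by default (~10 cycles, generous margin near
  bifurcations where convergence slows).
* Peaks: local maxima with a 1% prominence filter, refined by a parabola
  through the three bracketing samples. Period = mean successive peak
  spacing, rejected if the cycle-to-cycle CV exceeds 1%. Lags are circular
  means of late-follows-early peak differences, reported in `[0, period)`.
* Limit-cycle verdict: successive-cycle peak heights and spacings must
  agree within 0.5%.
* Steady states: the reduced model's fixed point is closed form (the flux
  chain `d·D1* = e·D2* = q·R*` linearizes the nonlinearity), so stability
  scans need no integration. Hopf points are refined by `brentq` on the
  leading eigenvalue real part (relative width 1e-3).
* The amplitude-based cross-check of each Hopf point perturbs the fixed
  point by 5% and asks whether the oscillation range grows or decays
  between an early and a late window (default horizon 2000 h). Growth
  rates immediately above the `a`-onset are ~1e-4 h⁻¹, so this
  finite-horizon estimate sits a few percent above the eigenvalue value
  there (measured: +0.1% for the lower `d` point, +5% at the upper `d`
  point, +8% for `a` at the default horizon, converging toward the
  eigenvalue answer as the horizon grows).

## Linearization

Replacing the QSSA flux by its tangent plane at the fixed point is
implemented exactly as stated. A first-order expansion preserves the
Jacobian at the expansion point, so the linearized model's fixed point has
the same eigenvalues as the nonlinear model's — at the default parameters
it is unstable either way. What the linearized model cannot do is sustain
a rhythm: a linear system has no limit cycle, and its trajectories spiral
outward unboundedly instead of settling into the bounded relaxation
oscillation. The saturating nonlinearity is therefore what bounds and
shapes the rhythm; the tests assert exactly this (no limit cycle after
linearization), not stabilization of the fixed point, which no
tangent-plane operation can produce.

## Phases and switches

Each cycle is anchored at the **activation (A) switch**, defined as the
maximum of `dA/dt` (the reactivation is a slope feature, not a level
crossing). The **inactivation/leakage (I/L) switch** is the first downward
crossing of `A` below `θ_IL·T` after the `A` peak; `θ_IL = 0.05` is a
declared convention, since the transition is described only verbally in
the literature. The cycle then splits exactly into phase 3 (reactivation,
A switch → A peak, ~1.4 h at defaults), phase 1 (inactivation, A peak →
I/L switch, ~5.4 h) and phase 2 (leakage and feedback buildup, I/L switch
→ next A switch, ~17.4 h, the longest phase, consistent with a feedback
delay of a quarter to half a period). Because `A` crosses the 2–10%·T band
over a few hours, moving `θ_IL` across `[0.02, 0.1]` shifts the phase-1/2
split by up to ~9% of the period; the tests assert this measured
sensitivity. The rise/fall shape index (mean of (rise − fall)/period,
troughs taken as refined minima) is −0.28 for `A` versus −0.09 for `D2`
at defaults: the fast variables are relaxation-like, the feedback
variables smooth.

## Detailed model

The nine-species variant resolves the full Prx3 cycle (SH → SOH → SS → SH
plus hyperoxidation to SO₂H) and the cytosolic Srx branch (H₂O₂-driven
Srx·Hsp90 complex formation, import, degradation). Design choices:

* Trx is folded into the disulfide-reduction rate `k3` as a constant
  reductant reservoir.
* Cytosolic Srx is buffered by a replenishment term `ks·(S0 − Srx_cyto)`;
  without synthesis, degradation would drain total Srx and the rhythm
  would die. With `ks` fast, the import flux stays proportional to
  cytosolic H₂O₂, matching the core model's `e·D2`.
* The *correspondence parameterization* maps core defaults onto
  `k4↔a, k5↔b, k6↔d, k8↔e, k9↔q, p_det↔p`, sets `k1 = 10⁴` (peroxidatic
  oxidation is physically orders of magnitude faster than hyperoxidation)
  and `k3 = 1, k7 = 10` (fast, not rate limiting). `k2 = 0.2` is kept
  small deliberately: the disulfide recycle must be a *low-flux side
  branch* for the PrxSH/PrxSS arm to be dispensable — with a fast `k2`
  the recycle would carry a large share of the H₂O₂ budget and clamping
  its species would destroy the rhythm for bookkeeping reasons rather
  than mechanistic ones.

Under these rates the detailed model oscillates with a 25.7 h period
(within 6% of the core model), an SO₂H → Srx lag of 8.8 h, relaxation
waveforms, rhythm loss when mitochondrial Srx is clamped, and rhythm
persistence when PrxSH or PrxSS is clamped. Increasing `k1` raises the
SO₂H and Srx oscillation amplitudes over the lower range and saturates at
high `k1`; "non-decreasing in `k1`" is asserted within the ~0.5%
numerical jitter of finite-window amplitude estimates.

## Clamping

`clamp_and_test` fixes one variable at its mean over an integer number of
post-transient cycles (avoiding partial-cycle bias), restarts from the
baseline end state and re-integrates for 2000–3000 h before applying the
limit-cycle criterion, so slowly drifting conserved quantities (clamping
breaks strict conservation) reach their new regime. Clamping any member
of the D1–D2–R feedback loop abolishes rhythms; that is the computational
identification of the core motif.

## Synthetic data and recovery

The generator emulates circadian western-blot densitometry: the
deterministic limit cycle of `I` and `R` sampled every 4 h over 48 h (the
standard two-day tissue-collection design), multiplied by lognormal noise
(`σ = 0.2`; densitometry errors scale with band intensity) and censored
to zero below an absolute detection floor (default 0.05 a.u., emulating
blank trough lanes). What it does **not** emulate: biological replicate
variability, inter-blot normalization drift, and saturation of strong
bands — so passing recovery tests demonstrates estimator correctness
under the stated noise model, not performance on real blots. At the
default parameters the relative oscillation amplitudes are modest (~14%
for `I`, ~34% for `R`), so the per-sample signal-to-noise at `σ = 0.2` is
below one — a deliberately hard regime.

The estimator is a least-squares *waveform-template* fit: the model's own
limit-cycle waveforms (peak-anchored, one period, phase-normalized) are
aligned to the data with free per-variable log-scale and phase and one
shared period. Fitting is done on the log scale, where the multiplicative
noise is homoscedastic Gaussian; censored samples are excluded. A generic
sinusoid-plus-harmonics fit is not usable here: the `I` waveform is a
~17 h plateau whose true maximum is a sub-percent ripple, and the peak of
a truncated harmonic reconstruction lands hours away from it even on
noiseless samples. The period is searched over the standard circadian
band (20–28 h). The reported lag is bias-corrected by a parametric
bootstrap at the fitted parameters (with a dof-adjusted noise estimate);
confidence intervals are 95% percentile intervals over residual-bootstrap
refits whose period search spans the whole circadian window, so that
alias-minimum ("basin hopping") uncertainty is reflected in the CIs.
Measured over 100 seeds at the default noise: period bias −0.03%, lag
bias ≈ +1%, CI coverage 99/100 (period) and 92/100 (lag); noiseless 4 h
samples recover period and lag to better than 0.05 h.

## Known limitations

* The model is not calibrated to molar units; only rate ratios are
  physiologically constrained, and the arbitrary-unit concentrations fix
  the time scale through the choice `p = 1, T = 1`.
* The computed oscillation onset in the leak rate is `d = 0.0127`
  (identical from the reduced and full models' eigenvalues, and confirmed
  by simulation on both sides); the upper boundary is `d = 0.503` and the
  `a`-onset `a = 113`. Published descriptions of this oscillator quote
  the window as roughly `0.02–0.5` and `a ≈ 120`; the discrepancy at the
  lower `d` boundary is consistent with reading the onset off a coarse
  scan grid or a finite simulation horizon, and the package reports its
  own bisection-refined values rather than adjusting toward the coarser
  figures.
* No stochastic (molecule-number) simulation, no p38-MAPK feedback on
  H₂O₂ production, no proteasomal Prx-SO₂H degradation pathway, no
  entrainment/phase-response analysis, and no fitting of the six rate
  constants to data (the template estimator recovers phase and period
  only).
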