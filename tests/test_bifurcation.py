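"""Bifurcation scans, Hopf localization and period sensitivity.

Frozen expected values (0.01273, 0.50295, 113.13) are the eigenvalue-based
stability changes of the closed-form steady state, independently confirmed
by direct simulation on either side of each point.
"""

import numpy as np
import pytest

from redoxclock import ParameterSet
from redoxclock.bifurcation import (
    locate_hopf,
    period_sensitivity,
    scan_parameter,
)
from redoxclock.oscillation_analysis import NotOscillatoryError, period_estimate
from redoxclock.simulate import discard_transient, integrate


@pytest.fixture(scope="module")
def d_scan():
    return scan_parameter("d", 0.005, 1.0, n_points=20, t_end=400.0, t_discard=200.0)


class TestScan:
    def test_d_scan_hopf_points(self, d_scan):
        values = sorted(h.value for h in d_scan.hopf_points)
        assert len(values) == 2
        assert values[0] == pytest.approx(0.01273, rel=5e-3)
        assert values[1] == pytest.approx(0.50295, rel=5e-3)

    def test_amplitude_envelope_collapses_outside_window(self, d_scan):
        steady = ~d_scan.oscillatory & ~d_scan.failed
        # exclude points adjacent to the Hopf bifurcations where transients
        # have not fully decayed within the scan horizon
        interior = steady & ((d_scan.values < 0.009) | (d_scan.values > 0.7))
        assert interior.any()
        # tolerance absolute on the A scale: at strongly stable points the
        # steady A is ~1e-4 and residual transients sit well below 1e-3
        assert np.abs(d_scan.Amax[interior] - d_scan.steady_A[interior]).max() < 1e-3
        assert np.abs(d_scan.Amin[interior] - d_scan.steady_A[interior]).max() < 1e-3
        assert np.abs(d_scan.Amax[interior] - d_scan.Amin[interior]).max() < 1e-3

    def test_oscillatory_region_of_slow_rates_lies_below_one(self, d_scan):
        assert not d_scan.oscillatory[d_scan.values >= 1.0].any()
        osc = d_scan.values[d_scan.oscillatory]
        assert osc.max() < 1.0

    def test_amin_never_exceeds_amax(self, d_scan):
        ok = ~np.isnan(d_scan.Amin)
        assert np.all(d_scan.Amin[ok] <= d_scan.Amax[ok] + 1e-12)

    def test_hopf_points_bracketed_by_grid_stability_change(self, d_scan):
        sign = np.sign(d_scan.re_lambda)
        flips = np.nonzero(np.diff(sign))[0]
        for h, i in zip(sorted(h.value for h in d_scan.hopf_points), flips):
            assert d_scan.values[i] <= h <= d_scan.values[i + 1]

    def test_invalid_scan_arguments(self):
        with pytest.raises(ValueError):
            scan_parameter("T", 0.1, 1.0)
        with pytest.raises(ValueError):
            scan_parameter("d", 1.0, 0.1)


class TestLocateHopf:
    def test_a_onset(self):
        h = locate_hopf("a", (50.0, 300.0))
        assert h.value == pytest.approx(113.13, rel=5e-3)

    def test_no_sign_change_rejected(self):
        with pytest.raises(ValueError, match="no stability change"):
            locate_hopf("d", (0.05, 0.3))

    def test_eigenvalue_and_amplitude_methods_agree(self):
        # growth-trend amplitude onset; near the a-onset growth is very slow,
        # so the finite-horizon amplitude estimate sits a few percent high
        h = locate_hopf("d", (0.005, 0.1), amplitude_crosscheck=True)
        assert abs(h.amplitude_onset / h.value - 1) < 0.05
        ha = locate_hopf("a", (50.0, 300.0), amplitude_crosscheck=True)
        assert abs(ha.amplitude_onset / ha.value - 1) < 0.08

    def test_simulation_confirms_stability_on_either_side(self):
        from redoxclock.simulate import detect_limit_cycle

        for d, expect in ((0.011, False), (0.016, True)):
            traj = discard_transient(
                integrate("reduced", ParameterSet(d=d), t_end=1500.0, dt_out=0.05), 1000.0
            )
            assert detect_limit_cycle(traj).oscillatory == expect


@pytest.fixture(scope="module")
def sens():
    out = {}
    for name, lo, hi in (("d", 0.05, 0.45), ("e", 0.05, 0.45), ("q", 0.05, 0.45), ("a", 200.0, 900.0)):
        out[name] = period_sensitivity(name, lo, hi, n_points=4)
    return out


class TestPeriodSensitivity:
    def test_translocation_rates_dominate_period_control(self, sens):
        s = {k: v.normalized_sensitivity for k, v in sens.items()}
        assert s["d"] > s["e"]
        assert s["d"] > s["q"]
        assert min(s["d"], s["e"], s["q"]) > 5 * s["a"]

    def test_curve_value_at_default_matches_reference_simulation(self, ref_traj, sens):
        ref_period = period_estimate(ref_traj, "A").period
        res = period_sensitivity("d", 0.18, 0.22, n_points=3)
        i = np.argmin(np.abs(res.values - 0.2))
        assert res.periods[i] == pytest.approx(ref_period, rel=5e-3)

    def test_entirely_stable_range_raises(self):
        with pytest.raises(NotOscillatoryError):
            period_sensitivity("d", 0.6, 0.9, n_points=3)
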