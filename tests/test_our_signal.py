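"""OUR computation, derivative and feast-end detection."""

import numpy as np
import pytest

from feastfamine.our_signal import (
    OURSeries,
    d_our_dt,
    detect_feast_end,
    our_from_dual_do,
)


def series(values, dt=0.5):
    values = np.asarray(values, dtype=float)
    return OURSeries(np.arange(len(values)) * dt, values)


class TestOurFromDualDo:
    @pytest.mark.parametrize("di, do, tau, expected",
                             [(5.0, 5.0, 2.0, 0.0),
                              (6.0, 4.0, 2.0, 1.0),
                              (4.0, 6.0, 2.0, 0.0)])  # noise clips at zero
    def test_values(self, di, do, tau, expected):
        assert our_from_dual_do(di, do, tau) == pytest.approx(expected)

    def test_rejects_nonpositive_residence_time(self):
        with pytest.raises(ValueError):
            our_from_dual_do(6.0, 4.0, 0.0)

    def test_recovers_simulated_loop_our(self, fd_output):
        """Applying the dual-DO formula to the simulated probe pair
        recovers the true OUR within 1% away from transients."""
        traj = fd_output.result.trajectory
        feast = traj[traj.phase == "feast"].iloc[50:100]
        rec = our_from_dual_do(feast.do_in_mg_l.to_numpy(),
                               feast.do_out_mg_l.to_numpy(), 2.0) * 60.0
        true = feast.our_mg_l_h.to_numpy()
        ok = np.abs(rec - true) <= 0.05 * np.abs(true) + 0.5
        assert ok.mean() > 0.9


class TestDerivative:
    def test_constant_series_zero_everywhere(self):
        d = d_our_dt(series([2.0] * 20))
        assert np.allclose(d, 0.0)

    def test_two_point_difference(self):
        assert d_our_dt(series([5.0, 4.8]), n=0) == pytest.approx(-0.4)

    def test_linear_ramp_exact_slope_interior(self):
        t = np.arange(40) * 0.5
        s = OURSeries(t, 1.0 + 0.3 * t)
        d = d_our_dt(s, smooth_window=3)
        assert np.allclose(d[1:-2], 0.3, atol=1e-12)

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            d_our_dt(series([1.0, 2.0, 3.0]), n=5)

    def test_sign_pattern_robust_to_noise(self, fd_output):
        """At SNR 20 the smoothed derivative keeps the noise-free sign at
        >= 95% of the samples where the true derivative is substantial."""
        traj = fd_output.result.trajectory
        feast = traj[traj.phase == "feast"]
        true_our = feast.our_mg_l_h.to_numpy() / 60.0
        t = feast.t_h.to_numpy() * 60.0
        clean = OURSeries(t, true_our)
        rng = np.random.default_rng(7)
        sigma = true_our.mean() / 20.0
        noisy = OURSeries(t, true_our + sigma * rng.standard_normal(len(t)))
        d_clean = d_our_dt(clean, smooth_window=5)
        d_noisy = d_our_dt(noisy, smooth_window=5)
        strong = np.abs(d_clean) > 0.1 * np.abs(d_clean).max()
        agree = np.sign(d_clean[strong]) == np.sign(d_noisy[strong])
        assert agree.mean() >= 0.95


class TestFeastEndDetection:
    def test_never_fed_series_ends_at_start(self):
        s = series([0.08] * 30)
        assert detect_feast_end(s, baseline=0.08) == pytest.approx(0.0)

    def test_zero_baseline_terminates_via_floor(self):
        s = series(np.r_[np.full(20, 2.0), np.full(20, 0.01)])
        t = detect_feast_end(s, baseline=0.0)
        assert t == pytest.approx(20 * 0.5)

    def test_unreached_baseline_warns_and_returns_end(self):
        s = series(np.full(30, 2.0))
        with pytest.warns(UserWarning):
            t = detect_feast_end(s, baseline=0.1)
        assert t == pytest.approx(s.t_min[-1])

    def test_monotone_in_substrate_budget(self):
        """More substrate keeps OUR elevated longer, so the detected end
        never moves earlier when the budget grows."""
        def trace(n_high):
            return series(np.r_[np.full(n_high, 2.0), np.full(60, 0.08)])

        ends = [detect_feast_end(trace(n), baseline=0.08) for n in (10, 20, 40)]
        assert ends == sorted(ends)
        assert ends[0] < ends[-1]

    def test_detects_simulated_substrate_exhaustion(self, fd_output):
        """On the noise-free closed-loop feast, the OUR-return rule finds
        the end of storage within a couple of samples of the controller's
        own budget-exhaustion termination."""
        traj = fd_output.result.trajectory
        feast = traj[traj.phase == "feast"]
        s = OURSeries(feast.t_h.to_numpy() * 60.0,
                      feast.our_mg_l_h.to_numpy() / 60.0)
        baseline = float(s.values[:10].mean())
        detected = detect_feast_end(s, baseline=baseline, start_min=10.0)
        terminal = fd_output.result.pulses.terminal_t_min
        assert abs(detected - terminal) <= 2.0
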