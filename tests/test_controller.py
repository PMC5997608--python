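"""Feed-on-demand state machine and closed-loop behaviour."""

import numpy as np
import pytest

from feastfamine.controller import (
    ControllerConfig,
    ControllerNotStartedError,
    FdController,
)


def make_controller(**kw):
    cfg = ControllerConfig(pulse_dose_cmmol=kw.pop("dose", 20.0),
                           budget_cmmol=kw.pop("budget", 600.0), **kw)
    c = FdController(cfg)
    c.start(baseline=kw.pop("baseline", 0.08))
    return c


class TestStateMachine:
    def test_step_before_start_is_an_error(self):
        c = FdController(ControllerConfig(pulse_dose_cmmol=20.0, budget_cmmol=600.0))
        with pytest.raises(ControllerNotStartedError):
            c.step(0.0, 1.0)

    def test_compulsive_start_then_no_feed_on_flat_signal(self):
        """A non-declining OUR after the START pulse never triggers the
        pump: exactly one feeding event."""
        c = make_controller()
        actions = [c.step(0.5 * k, 1.5)[0] for k in range(50)]
        assert actions[0] == "feed"
        assert all(a == "hold" for a in actions[1:])
        assert c.log.n_pulses == 1
        assert c.log.events[0]["trigger"] == "START"

    def test_feeds_on_negative_derivative_only(self):
        c = make_controller(dose=5.0, budget=100.0)
        c.step(0.0, 1.5)  # START
        # rising signal: hold
        for k, v in enumerate([1.6, 1.7, 1.8], start=1):
            assert c.step(0.5 * k, v)[0] == "hold"
        # steep decline: feed
        fed = [c.step(0.5 * (k + 4), v)[0] for k, v in enumerate([1.2, 0.8, 0.5])]
        assert "feed" in fed
        for ev in c.log.events:
            if ev["trigger"] != "START":
                assert ev["d_our_dt"] < 0

    def test_zero_budget_terminates_after_baseline_check(self):
        cfg = ControllerConfig(pulse_dose_cmmol=5.0, budget_cmmol=0.0)
        c = FdController(cfg)
        c.start(baseline=0.08)
        last = "hold"
        for k in range(10):
            last, _ = c.step(0.5 * k, 0.08)
            if last == "terminate":
                break
        assert last == "terminate"
        assert c.cum_fed == 0.0

    def test_budget_cap_partial_final_dose(self):
        c = make_controller(dose=20.0, budget=30.0)
        c.step(0.0, 2.0)
        # force a second trigger with a steep decline
        for k, v in enumerate([2.0, 2.0, 1.5, 1.0, 0.6], start=1):
            c.step(0.5 * k, v)
        assert c.cum_fed == pytest.approx(30.0)  # 20 + capped 10
        cums = [e["cum_cmmol"] for e in c.log.events]
        assert cums == sorted(cums)


class TestClosedLoop:
    def test_staircase_hits_budget_exactly(self, fd_output):
        log = fd_output.result.pulses
        assert log.total_fed_cmmol == pytest.approx(618.8, abs=1e-9)
        assert log.n_pulses >= 5
        assert log.terminal_reason == "budget_exhausted -> famine"

    def test_pulse_count_and_spacing(self, fd_output):
        """At least budget/dose pulses, spaced no closer than the OUR
        sampling interval."""
        df = fd_output.result.pulses.to_dataframe()
        cfg = fd_output.config.controller
        assert len(df) >= int(cfg.budget_cmmol / cfg.pulse_dose_cmmol)
        gaps = df.t_min.diff().dropna()
        assert (gaps >= cfg.sample_interval_min - 1e-9).all()

    def test_no_feed_on_rising_smoothed_derivative(self, fd_output):
        df = fd_output.result.pulses.to_dataframe()
        non_start = df[df.trigger != "START"]
        assert (non_start.d_our_dt < 0).all()

    def test_do_and_our_anti_phase(self, fd_output):
        traj = fd_output.result.trajectory
        feast = traj[traj.phase == "feast"]
        ddo = np.diff(feast.do_in_mg_l.to_numpy())
        dour = np.diff(feast.our_mg_l_h.to_numpy())
        mask = (np.abs(ddo) > 1e-9) & (np.abs(dour) > 1e-9)
        agree = np.sign(ddo[mask]) == -np.sign(dour[mask])
        assert agree.mean() > 0.9

    def test_feast_terminates_near_observed_length(self, fd_output):
        assert fd_output.result.pulses.terminal_t_min / 60.0 == pytest.approx(
            5.6, abs=0.25)

    def test_budget_never_exceeded_under_sensor_noise(self):
        from feastfamine.pipeline import load_scenario, simulate_scenario

        out = simulate_scenario(load_scenario("FD", seed=11), do_noise_sigma=0.05)
        df = out.result.pulses.to_dataframe()
        assert (df.cum_cmmol <= 618.8 + 1e-9).all()
        assert df.cum_cmmol.iloc[-1] == pytest.approx(618.8)
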