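"""Cycle metrics: worked arithmetic, aggregation and table-driven assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from feastfamine.measurements import SamplingPlan, sample_trajectory
from feastfamine.metrics import (
    UndefinedRateError,
    feast_length_from_budget,
    metrics_from_samples,
    metrics_from_trajectory,
    specific_storage_rate,
    specific_uptake_rate,
    storage_yield,
    tfe_tfa,
    volumetric_productivity,
)

NOISELESS = SamplingPlan(cv={"hac": 0.0, "phb": 0.0, "vss": 0.0, "nh4": 0.0},
                         do_sigma_mg_l=0.0, sensor_lag_s=0.0)


class TestSpecificRates:
    def test_zero_numerators(self):
        assert specific_uptake_rate(0.0, 31.0, 5.6) == 0.0
        assert specific_storage_rate(0.0, 31.0, 5.6) == 0.0

    def test_undefined_for_zero_biomass_or_time(self):
        with pytest.raises(UndefinedRateError):
            specific_uptake_rate(10.0, 0.0, 1.0)
        with pytest.raises(UndefinedRateError):
            specific_storage_rate(10.0, 1.0, 0.0)

    def test_aggregate_matches_instantaneous_integral(self, fd_output):
        """The endpoint aggregate q_P equals the time-averaged
        instantaneous storage rate on noise-free simulator output."""
        traj = fd_output.result.trajectory
        m = fd_output.metrics
        feast = traj[traj.t_h <= m.t_phb_max_h]
        t = feast.t_h.to_numpy()
        x = (feast.x_st_cmmol_l + feast.x_ns_cmmol_l).to_numpy()
        inst_qp = np.gradient(feast.phb_cmmol_l.to_numpy(), t) / x
        integral = np.trapezoid(inst_qp, t) / (t[-1] - t[0])
        assert m.q_p == pytest.approx(integral, rel=0.01)


def test_yield_identity_by_construction(fd_output):
    m = fd_output.metrics
    assert m.y_ps == pytest.approx(m.q_p / m.q_ac, rel=1e-12)
    assert storage_yield(0.85, 0.85) == pytest.approx(1.0)
    with pytest.raises(UndefinedRateError):
        storage_yield(0.5, 0.0)


class TestFeastLength:
    def test_budget_inverse(self):
        assert feast_length_from_budget(0.0, 1.05, 31.0) == 0.0
        t = feast_length_from_budget(182.0, 1.05, 31.0)
        assert feast_length_from_budget(182.0, 1.05, 62.0) == pytest.approx(t / 2)


class TestVolumetricProductivity:
    @pytest.mark.parametrize("g, v, d, expected",
                             [(0.0, 3.4, 1.0, 0.0), (17.0, 3.4, 1.0, 5.0)])
    def test_values(self, g, v, d, expected):
        assert volumetric_productivity(g, v, d) == pytest.approx(expected)

    def test_simulated_cycle_against_mass_ledger(self, fd_output):
        """The metric equals the PHB mass in the withdrawal + decant
        streams divided by working volume and cycle time."""
        from feastfamine.stoichiometry import PHB_G_PER_CMOL

        led = fd_output.result.ledger
        phb_g = (led["withdrawn"]["phb_cmmol"]
                 + led["settled"]["phb_cmmol"]) * PHB_G_PER_CMOL / 1000.0
        expected = phb_g / 3.4 / (18.0 / 24.0)
        assert fd_output.metrics.volumetric_productivity_g_l_d == pytest.approx(
            expected, rel=1e-9)


class TestTfeTfa:
    def test_values_and_boundary(self):
        assert tfe_tfa(5.0, 5.0) == 1.0
        assert tfe_tfa(5.6, 12.4) == pytest.approx(0.45, abs=0.005)
        with pytest.raises(ValueError):
            tfe_tfa(5.0, 0.0)


class TestMetricsFromSamples:
    def test_noise_free_samples_match_trajectory_metrics(self, fd_output):
        traj = fd_output.result.trajectory
        table, _ = sample_trajectory(traj, NOISELESS, seed=0)
        m_s = metrics_from_samples(table, ac_fed_cmmol_l=182.0)
        m_t = fd_output.metrics
        # agreement limited by the 50-min offline grid
        assert abs(m_s.t_phb_max_h - m_t.t_phb_max_h) <= 50.0 / 60.0
        assert m_s.phb_max_cmmol_l == pytest.approx(m_t.phb_max_cmmol_l, rel=0.03)
        assert m_s.q_p == pytest.approx(m_t.q_p, rel=0.15)
        assert m_s.y_ps == pytest.approx(m_t.y_ps, rel=0.1)

    def test_all_zero_phb_flags_undefined_yield(self):
        table = pd.DataFrame({
            "t_min": [0.0, 50.0, 100.0],
            "hac_cmmol_l": [100.0, 50.0, 0.0],
            "phb_cmmol_l": [0.0, 0.0, 0.0],
            "vss_g_l": [0.8, 0.8, 0.8],
            "nh4_mmol_l": [0.1, 0.1, 0.1],
        })
        m = metrics_from_samples(table)
        assert m.q_p == 0.0
        assert math.isnan(m.y_ps)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_samples(pd.DataFrame({"t_min": [0, 1]}))

    def test_noisy_replicates_bracket_ground_truth(self, fd_output):
        """Mean +- sd of n = 20 noisy synthetic replicates brackets the
        trajectory-level ground truth for the storage rate."""
        traj = fd_output.result.trajectory
        truth = fd_output.metrics.q_p
        est = []
        for i in range(20):
            table, _ = sample_trajectory(traj, SamplingPlan(), seed=300 + i)
            est.append(metrics_from_samples(table, ac_fed_cmmol_l=182.0).q_p)
        est = np.asarray(est)
        assert est.mean() - 2 * est.std() <= truth <= est.mean() + 2 * est.std()


def test_trajectory_metrics_require_feast_boundary():
    df = pd.DataFrame({
        "t_h": [0.0, 1.0], "v_l": [3.4, 3.4],
        "s_ac_cmmol_l": [0.0, 0.0], "x_st_cmmol_l": [31.0, 31.0],
        "x_ns_cmmol_l": [0.0, 0.0], "phb_cmmol_l": [5.0, 1.0],
        "nh4_mmol_l": [0.1, 0.1],
    })

    class R:
        trajectory = df
        ledger = {"fed_carbon_cmmol": 0.0}

    with pytest.raises(ValueError):
        metrics_from_trajectory(R())
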