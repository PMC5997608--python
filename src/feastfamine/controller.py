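"""Feed-on-demand substrate controller driven by the OUR derivative.

State machine (per 0.5-min OUR sample): a compulsive START order launches
the first pulse; afterwards the micro pump fires a fixed-quantum acetate
pulse whenever the smoothed OUR derivative is negative (substrate running
out), holds while it is non-negative, and never exceeds a hard total
budget.  Once the budget is exhausted and OUR has returned to the
endogenous baseline for a few consecutive samples, the culture is declared
to be in famine and the controller terminates.

A relative deadband on the derivative (default 2% of the current OUR per
minute) plays the role of hysteresis: between pulses the OUR declines
smoothly through the Monod term, and a strict "< 0" test would chatter and
dump the budget in the first hour; with the deadband the pump refires only
once the decline steepens near substrate exhaustion, producing the
characteristic staircase of the cumulative-feed curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams, rates
from .our_signal import our_from_dual_do, smooth_median
from .reactor import ReactorState, RespirometerParams, respirometer_steady_state

__all__ = [
    "ControllerConfig",
    "PulseLog",
    "FdController",
    "run_feast_closed_loop",
    "run_closed_loop",
]


class ControllerNotStartedError(RuntimeError):
    """step() called before the compulsive START order."""


@dataclass
class ControllerConfig:
    """Feed-on-demand settings.

    ``pulse_dose_cmmol`` is the fixed pulse quantum (absolute Cmmol of
    acetate carbon), ``budget_cmmol`` the hard cap on the total fed amount.
    """

    pulse_dose_cmmol: float
    budget_cmmol: float
    sample_interval_min: float = 0.5
    smooth_window: int = 3
    deadband_per_min: float = 0.02   # relative derivative deadband, 1/min
    baseline_tol: float = 0.1
    baseline_k: int = 4
    our_floor: float = 0.05          # mg O2/L/min
    baseline_window_min: float = 5.0

    def __post_init__(self) -> None:
        if self.pulse_dose_cmmol <= 0:
            raise ValueError("pulse dose must be positive")
        if self.budget_cmmol < 0:
            raise ValueError("budget must be non-negative")
        if self.budget_cmmol > 0 and self.pulse_dose_cmmol > self.budget_cmmol:
            raise ValueError("pulse dose must not exceed a positive budget")
        if self.sample_interval_min <= 0:
            raise ValueError("sample interval must be positive")


@dataclass
class PulseLog:
    """Timestamped controller actions of one feast."""

    events: list = field(default_factory=list)
    terminal_reason: str | None = None
    terminal_t_min: float | None = None

    def add(self, t_min: float, dose: float, cumulative: float,
            trigger: str, derivative: float | None) -> None:
        self.events.append({
            "t_min": t_min, "dose_cmmol": dose, "cum_cmmol": cumulative,
            "trigger": trigger, "d_our_dt": derivative,
        })

    @property
    def n_pulses(self) -> int:
        return len(self.events)

    @property
    def total_fed_cmmol(self) -> float:
        return self.events[-1]["cum_cmmol"] if self.events else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events,
                            columns=["t_min", "dose_cmmol", "cum_cmmol",
                                     "trigger", "d_our_dt"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "n_pulses": self.n_pulses,
            "total_fed_cmmol": self.total_fed_cmmol,
            "terminal_reason": self.terminal_reason,
            "terminal_t_min": self.terminal_t_min,
        }


class FdController:
    """The per-sample decision logic; one instance per feast."""

    def __init__(self, config: ControllerConfig):
        self.config = config
        self.started = False
        self.terminated = False
        self.baseline: float | None = None
        self.cum_fed = 0.0
        self.log = PulseLog()
        self._samples: list[float] = []
        self._smoothed_prev: float | None = None
        self._start_pending = False
        self._below_count = 0

    def start(self, baseline: float) -> None:
        """Arm the controller with the pre-feed endogenous OUR baseline."""
        self.started = True
        self.baseline = float(baseline)
        self._start_pending = True

    @property
    def remaining(self) -> float:
        return self.config.budget_cmmol - self.cum_fed

    def _derivative(self, our: float) -> float | None:
        """Smoothed discrete derivative at the newest sample, mg/L/min^2."""
        self._samples.append(our)
        w = self.config.smooth_window
        if len(self._samples) < w:
            return None
        sm = float(np.median(self._samples[-w:]))
        prev, self._smoothed_prev = self._smoothed_prev, sm
        if prev is None:
            return None
        return (sm - prev) / self.config.sample_interval_min

    def step(self, t_min: float, our_sample: float):
        """Consume one OUR sample; returns ('feed', dose) | ('hold', 0) |
        ('terminate', 0)."""
        if not self.started:
            raise ControllerNotStartedError("controller stepped before START order")
        deriv = self._derivative(our_sample)
        if self.terminated:
            return "hold", 0.0

        if self._start_pending:
            self._start_pending = False
            if self.remaining > 0:
                dose = min(self.config.pulse_dose_cmmol, self.remaining)
                self.cum_fed += dose
                self.log.add(t_min, dose, self.cum_fed, "START", deriv)
                return "feed", dose

        if self.remaining > 1e-12:
            threshold = -self.config.deadband_per_min * max(our_sample,
                                                            self.config.our_floor)
            if deriv is not None and deriv < min(threshold, 0.0):
                dose = min(self.config.pulse_dose_cmmol, self.remaining)
                self.cum_fed += dose
                self.log.add(t_min, dose, self.cum_fed, "dOURdt<0", deriv)
                return "feed", dose
            return "hold", 0.0

        # budget exhausted: wait for OUR to settle on the endogenous baseline
        settle = max(self.baseline * (1.0 + self.config.baseline_tol),
                     self.config.our_floor)
        if our_sample <= settle:
            self._below_count += 1
        else:
            self._below_count = 0
        if self._below_count >= self.config.baseline_k:
            self.terminated = True
            self.log.terminal_reason = "budget_exhausted -> famine"
            self.log.terminal_t_min = t_min
            return "terminate", 0.0
        return "hold", 0.0


# ---------------------------------------------------------------------------
# closed-loop simulation

@dataclass
class FeastLoopResult:
    trajectory: pd.DataFrame
    end_state: ReactorState
    pulses: PulseLog
    co2_cmmol_l: float
    feast_end_min: float
    consumed_cmmol: float


def _rk4_step(y, dt_h, p: KineticParams):
    """One fixed RK4 step of [S, Xs, Xn, PHB, NH4, CO2]."""

    def f(v):
        r = rates(max(v[0], 0.0), v[1], v[2], max(v[3], 0.0), max(v[4], 0.0), p)
        return (r.ds, r.dxs, r.dxn, r.dphb, r.dnh4, r.dco2)

    k1 = f(y)
    k2 = f([y[i] + 0.5 * dt_h * k1[i] for i in range(6)])
    k3 = f([y[i] + 0.5 * dt_h * k2[i] for i in range(6)])
    k4 = f([y[i] + dt_h * k3[i] for i in range(6)])
    return [y[i] + dt_h / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
            for i in range(6)]


def run_feast_closed_loop(state: ReactorState, params: KineticParams,
                          config: ControllerConfig, feast_min: float = 360.0,
                          resp: RespirometerParams | None = None,
                          seed: int | None = None, do_noise_sigma: float = 0.0,
                          sensor_lag_s: float = 10.0,
                          n_substeps: int = 5) -> FeastLoopResult:
    """Simulate one feed-on-demand feast at the controller's 0.5-min grid.

    The first ``baseline_window_min`` run unfed to establish the endogenous
    OUR baseline (the stable pre-feed level), then the START pulse fires
    and the controller takes over.  DO readings come from the quasi-steady
    respirometer map, optionally passed through a first-order sensor lag
    and additive Gaussian noise; the controller only ever sees the measured
    OUR, never the true state.  Integration between samples is fixed-step
    RK4 (``n_substeps`` per sample).
    """
    if resp is None:
        resp = RespirometerParams()
    rng = np.random.default_rng(seed)
    dt_min = config.sample_interval_min
    dt_h = dt_min / 60.0
    sub_h = dt_h / n_substeps
    n_samples = int(round(feast_min / dt_min))
    n_baseline = max(int(round(config.baseline_window_min / dt_min)), 1)

    controller = FdController(config)
    y = [state.s, state.xs, state.xn, state.phb, state.nh4, 0.0]
    v = state.v
    s0 = state.s
    lag_alpha = (dt_min * 60.0) / (sensor_lag_s + dt_min * 60.0) \
        if sensor_lag_s > 0 else 1.0
    do_in_f = do_out_f = None
    baseline_samples: list[float] = []

    rows = []
    for k in range(n_samples + 1):
        t_min = k * dt_min
        r = rates(max(y[0], 0.0), y[1], y[2], max(y[3], 0.0), max(y[4], 0.0), params)
        our_mg_h = r.our_total * 32.0
        do_in, do_out = respirometer_steady_state(our_mg_h, resp)
        do_in, do_out = float(do_in), float(do_out)
        if do_in_f is None:
            do_in_f, do_out_f = do_in, do_out
        else:
            do_in_f += lag_alpha * (do_in - do_in_f)
            do_out_f += lag_alpha * (do_out - do_out_f)
        do_in_m = do_in_f + (do_noise_sigma * rng.standard_normal()
                             if do_noise_sigma > 0 else 0.0)
        do_out_m = do_out_f + (do_noise_sigma * rng.standard_normal()
                               if do_noise_sigma > 0 else 0.0)
        our_meas = our_from_dual_do(do_in_m, do_out_m, resp.residence_min)

        if k < n_baseline:
            baseline_samples.append(our_meas)
            action, dose = "baseline", 0.0
        else:
            if not controller.started:
                controller.start(float(np.mean(baseline_samples)))
            action, dose = controller.step(t_min, our_meas)
            if action == "feed":
                y[0] += dose / v

        rows.append({
            "t_h": t_min / 60.0,
            "s_ac_cmmol_l": max(y[0], 0.0),
            "x_st_cmmol_l": y[1],
            "x_ns_cmmol_l": y[2],
            "phb_cmmol_l": max(y[3], 0.0),
            "nh4_mmol_l": max(y[4], 0.0),
            "our_mg_l_h": our_mg_h,
            "our_meas_mg_l_min": our_meas,
            "do_in_mg_l": do_in_m,
            "do_out_mg_l": do_out_m,
            "cum_fed_cmmol": controller.cum_fed,
            "action": action,
        })
        if k < n_samples:
            for _ in range(n_substeps):
                y = _rk4_step(y, sub_h, params)

    end = state.copy()
    end.s, end.xs, end.xn, end.phb, end.nh4 = (max(float(x), 0.0) for x in y[:5])
    end.t_h = state.t_h + feast_min / 60.0
    feast_end = (controller.log.terminal_t_min
                 if controller.log.terminal_t_min is not None else feast_min)
    consumed = controller.cum_fed + (s0 - end.s) * v
    return FeastLoopResult(pd.DataFrame(rows), end, controller.log,
                           float(y[5]), float(feast_end), float(consumed))


def run_closed_loop(state: ReactorState, schedule, params: KineticParams,
                    config: ControllerConfig, seed: int | None = None,
                    do_noise_sigma: float = 0.0):
    """Run a whole feed-on-demand SBR cycle; returns (PulseLog, CycleResult)."""
    from .reactor import run_cycle

    result = run_cycle(state, schedule, params, controller_config=config,
                       seed=seed, do_noise_sigma=do_noise_sigma)
    return result.pulses, result
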