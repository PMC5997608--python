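"""Cycle-level stoichiometric and kinetic performance metrics.

The feast-aggregate observables of one SBR cycle: specific acetate uptake
rate q_AC = Ac/(X t), specific PHB storage rate q_P = PHB/(X t), storage
yield Y_P/S = q_P/q_AC, the feast PHB maximum (Cmmol/L and wt% of total
solids), volumetric productivity of the harvested polymer and the
feast-to-famine length ratio.  All rates are Cmol/Cmol/h on the Cmol basis
of the stoichiometry module; aggregates are computed from feast-window
endpoints, with sliding-window "max" variants also available since the
single printed per-experiment values are defined through maximum rates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .stoichiometry import (
    BIOMASS_G_PER_CMOL,
    PHB_G_PER_CMOL,
    mass_to_cmol,
    phb_weight_fraction,
)

__all__ = [
    "CycleMetrics",
    "specific_uptake_rate",
    "specific_storage_rate",
    "storage_yield",
    "feast_length_from_budget",
    "volumetric_productivity",
    "tfe_tfa",
    "metrics_from_samples",
    "metrics_from_trajectory",
]


class UndefinedRateError(ZeroDivisionError):
    """Raised when a specific rate is requested with zero biomass or time."""


@dataclass
class CycleMetrics:
    """One record of cycle performance (a Table-style row)."""

    t_phb_max_h: float
    phb_max_cmmol_l: float
    phb_max_wt_pct: float
    q_ac: float
    q_p: float
    y_ps: float
    volumetric_productivity_g_l_d: float | None = None
    t_fe_over_t_fa: float | None = None

    def __post_init__(self) -> None:
        if self.q_ac < 0 or self.q_p < 0:
            raise ValueError("specific rates must be non-negative")
        if not 0.0 <= self.phb_max_wt_pct <= 100.0:
            raise ValueError("PHB wt% must be within [0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)


def specific_uptake_rate(ac_consumed_cmmol_l: float, x_cmmol_l: float,
                         t_feast_h: float) -> float:
    """q_AC = Ac/(X t), Cmol Ac/Cmol X/h."""
    if x_cmmol_l <= 0 or t_feast_h <= 0:
        raise UndefinedRateError("q_AC undefined for zero biomass or feast length")
    if ac_consumed_cmmol_l < 0:
        raise ValueError("consumed acetate must be non-negative")
    return ac_consumed_cmmol_l / x_cmmol_l / t_feast_h


def specific_storage_rate(phb_formed_cmmol_l: float, x_cmmol_l: float,
                          t_feast_h: float) -> float:
    """q_P = PHB/(X t), Cmol PHB/Cmol X/h."""
    if x_cmmol_l <= 0 or t_feast_h <= 0:
        raise UndefinedRateError("q_P undefined for zero biomass or feast length")
    if phb_formed_cmmol_l < 0:
        raise ValueError("formed PHB must be non-negative")
    return phb_formed_cmmol_l / x_cmmol_l / t_feast_h


def storage_yield(q_p: float, q_ac: float) -> float:
    """Y_P/S = q_P/q_AC, Cmol PHB/Cmol Ac."""
    if q_ac <= 0:
        raise UndefinedRateError("yield undefined for zero uptake rate")
    return q_p / q_ac


def feast_length_from_budget(ac_total_cmmol_l: float, q_ac: float,
                             x_cmmol_l: float) -> float:
    """Feast length (h) implied by a substrate budget: t = Ac/(q_AC X)."""
    if q_ac <= 0 or x_cmmol_l <= 0:
        raise UndefinedRateError("feast length undefined for zero rate or biomass")
    if ac_total_cmmol_l < 0:
        raise ValueError("budget must be non-negative")
    return ac_total_cmmol_l / (q_ac * x_cmmol_l)


def volumetric_productivity(harvested_phb_g: float, working_volume_l: float,
                            elapsed_days: float) -> float:
    """Harvested PHB per working volume per day, g PHB/L/day."""
    if working_volume_l <= 0 or elapsed_days <= 0:
        raise ValueError("volume and elapsed time must be positive")
    if harvested_phb_g < 0:
        raise ValueError("harvested mass must be non-negative")
    return harvested_phb_g / working_volume_l / elapsed_days


def tfe_tfa(t_feast_h: float, t_famine_h: float) -> float:
    """Feast-to-famine duration ratio, the ADF stability indicator."""
    if t_famine_h <= 0:
        raise ValueError("famine length must be positive")
    if t_feast_h < 0:
        raise ValueError("feast length must be non-negative")
    return t_feast_h / t_famine_h


def _sliding_max_rate(t_h: np.ndarray, series: np.ndarray, x: float,
                      window_h: float = 0.5) -> float:
    """Maximum specific rate over a sliding window (Cmol/Cmol/h)."""
    best = 0.0
    j = 0
    for i in range(len(t_h)):
        while t_h[i] - t_h[j] > window_h:
            j += 1
        if i > j:
            rate = abs(series[i] - series[j]) / (t_h[i] - t_h[j]) / x
            best = max(best, rate)
    return best


def metrics_from_samples(table: pd.DataFrame, ac_fed_cmmol_l: float | None = None,
                         t_famine_h: float | None = None,
                         harvested_phb_g: float | None = None,
                         working_volume_l: float | None = None,
                         cycle_days: float | None = None,
                         plateau_tol: float = 0.04) -> CycleMetrics:
    """Assemble cycle metrics from an offline measurement table.

    The table needs columns ``t_min`` (or ``t_h``), ``hac_cmmol_l``,
    ``phb_cmmol_l``, ``vss_g_l`` and ``nh4_mmol_l``.  The feast window runs
    from the first sample to the sampled PHB maximum; because PHB plateaus
    after substrate exhaustion, the boundary is taken at the first sample
    within ``plateau_tol`` (relative, defaulting to the analytical CV) of
    the maximum, which is robust to measurement noise along the plateau.
    Rates are endpoint differences over that window; active biomass
    X = VSS - PHB averaged over the feast.  Acetate consumed is the fed
    amount (when given, the pulsed-feeding case) plus the drop in residual
    acetate.
    """
    df = table.copy()
    df.columns = [c.lower() for c in df.columns]
    if "t_h" not in df.columns:
        if "t_min" not in df.columns:
            raise ValueError("table needs a t_min or t_h column")
        df["t_h"] = df["t_min"] / 60.0
    for col in ("hac_cmmol_l", "phb_cmmol_l", "vss_g_l", "nh4_mmol_l"):
        if col not in df.columns:
            raise ValueError(f"table is missing required column {col}")
    if len(df) < 2:
        raise ValueError("need at least two samples to locate the feast boundary")

    df = df.reset_index(drop=True)
    phb_col = df["phb_cmmol_l"].to_numpy(dtype=float)
    phb_peak = float(phb_col.max())
    if phb_peak <= 0.0:
        i_max = len(df) - 1  # no storage at all; q_P = 0, yield undefined
    else:
        i_max = int(np.argmax(phb_col >= (1.0 - plateau_tol) * phb_peak))
    if i_max == 0 and phb_peak > 0.0:
        raise ValueError("feast boundary not found: PHB maximum at first sample")
    feast = df.loc[:i_max]
    t_feast = float(feast["t_h"].iloc[-1] - feast["t_h"].iloc[0])

    phb_g = feast["phb_cmmol_l"] * PHB_G_PER_CMOL / 1000.0
    x_g = (feast["vss_g_l"] - phb_g).clip(lower=0.0)
    x_cmmol = float(mass_to_cmol(float(x_g.mean()), BIOMASS_G_PER_CMOL))

    phb_formed = float(feast["phb_cmmol_l"].iloc[-1] - feast["phb_cmmol_l"].iloc[0])
    phb_formed = max(phb_formed, 0.0)
    ac_drop = float(feast["hac_cmmol_l"].iloc[0] - feast["hac_cmmol_l"].iloc[-1])
    ac_consumed = (ac_fed_cmmol_l if ac_fed_cmmol_l is not None else 0.0) + ac_drop
    ac_consumed = max(ac_consumed, 0.0)

    q_p = (specific_storage_rate(phb_formed, x_cmmol, t_feast)
           if phb_formed > 0 else 0.0)
    q_ac = (specific_uptake_rate(ac_consumed, x_cmmol, t_feast)
            if ac_consumed > 0 else 0.0)
    # yield undefined (not zero) when no storage was observed at all
    y = (storage_yield(q_p, q_ac)
         if q_ac > 0 and phb_peak > 0 else float("nan"))

    phb_max = float(df.loc[i_max, "phb_cmmol_l"])
    x_at_max = float(mass_to_cmol(
        max(float(df.loc[i_max, "vss_g_l"]) - phb_max * PHB_G_PER_CMOL / 1000.0, 0.0),
        BIOMASS_G_PER_CMOL))
    vp = None
    if harvested_phb_g is not None and working_volume_l and cycle_days:
        vp = volumetric_productivity(harvested_phb_g, working_volume_l, cycle_days)
    ratio = tfe_tfa(t_feast, t_famine_h) if t_famine_h else None
    return CycleMetrics(
        t_phb_max_h=float(df.loc[i_max, "t_h"]),
        phb_max_cmmol_l=phb_max,
        phb_max_wt_pct=100.0 * phb_weight_fraction(phb_max, x_at_max),
        q_ac=q_ac, q_p=q_p, y_ps=y,
        volumetric_productivity_g_l_d=vp,
        t_fe_over_t_fa=ratio,
    )


def metrics_from_trajectory(result, cycle_h: float | None = None) -> CycleMetrics:
    """Cycle metrics straight from a simulated :class:`CycleResult`.

    The feast window runs from cycle start to the trajectory PHB maximum;
    acetate consumed = fed + residual drop over that window; harvested PHB
    comes from the withdrawal/settling ledger.
    """
    traj = result.trajectory
    ledger = result.ledger
    i_max = int(traj["phb_cmmol_l"].idxmax())
    if i_max == 0:
        raise ValueError("feast boundary not found in trajectory")
    t_feast = float(traj.loc[i_max, "t_h"] - traj["t_h"].iloc[0])
    x_mean = float((traj.loc[:i_max, "x_st_cmmol_l"]
                    + traj.loc[:i_max, "x_ns_cmmol_l"]).mean())
    phb_formed = float(traj.loc[i_max, "phb_cmmol_l"] - traj["phb_cmmol_l"].iloc[0])
    v = float(traj["v_l"].iloc[0])
    fed_per_l = ledger.get("fed_carbon_cmmol", 0.0) / v
    # residual acetate before any feed, so single-pulse doses are not
    # double counted through the first trajectory row
    s_prefeed = float(ledger.get("s_prefeed_cmmol_l", traj["s_ac_cmmol_l"].iloc[0]))
    ac_consumed = max(fed_per_l + s_prefeed
                      - float(traj.loc[i_max, "s_ac_cmmol_l"]), 0.0)

    q_p = specific_storage_rate(max(phb_formed, 0.0), x_mean, t_feast) \
        if phb_formed > 0 else 0.0
    q_ac = specific_uptake_rate(ac_consumed, x_mean, t_feast) \
        if ac_consumed > 0 else 0.0
    y = storage_yield(q_p, q_ac) if q_ac > 0 else float("nan")

    phb_max = float(traj.loc[i_max, "phb_cmmol_l"])
    x_at_max = float(traj.loc[i_max, "x_st_cmmol_l"] + traj.loc[i_max, "x_ns_cmmol_l"])

    vp = None
    harvested = ledger.get("withdrawn") or {}
    if harvested and cycle_h:
        harvested_g = ((harvested.get("phb_cmmol", 0.0)
                        + (ledger.get("settled") or {}).get("phb_cmmol", 0.0))
                       * PHB_G_PER_CMOL / 1000.0)
        vp = volumetric_productivity(harvested_g, float(traj["v_l"].max()),
                                     cycle_h / 24.0)
    ratio = None
    if cycle_h:
        t_famine = cycle_h - t_feast
        if t_famine > 0:
            ratio = tfe_tfa(t_feast, t_famine)
    return CycleMetrics(
        t_phb_max_h=float(traj.loc[i_max, "t_h"]),
        phb_max_cmmol_l=phb_max,
        phb_max_wt_pct=100.0 * phb_weight_fraction(phb_max, x_at_max),
        q_ac=q_ac, q_p=q_p, y_ps=y,
        volumetric_productivity_g_l_d=vp,
        t_fe_over_t_fa=ratio,
    )
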