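"""Synthetic measurement generator: simulator truth -> noisy lab tables.

Converts dense simulated trajectories into the two data streams a real
feast-famine SBR campaign produces: an offline chemistry table (acetate,
PHB, VSS, ammonium) sampled every ~50 min with multiplicative analytical
noise, and a 0.5-min dual-probe DO log with additive sensor noise and a
first-order probe lag.  The generator is a pure function of (trajectory,
plan, seed): noise-free plans reproduce the interpolated trajectory
exactly, so every analysis stage can be tested against simulator ground
truth without any external data.

Default analytical CVs (3% HAc, 4% PHB, 3% VSS, 5% NH4) are plausible
GC / gravimetric / colorimetric wet-chemistry precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stoichiometry import BIOMASS_G_PER_CMOL, PHB_G_PER_CMOL

__all__ = ["SamplingPlan", "sample_trajectory", "make_fixture_suite"]

GENERATOR_VERSION = "1"


def _default_cv() -> dict:
    return {"hac": 0.03, "phb": 0.04, "vss": 0.03, "nh4": 0.05}


@dataclass
class SamplingPlan:
    """Offline / online sampling grid and noise model."""

    offline_interval_min: float = 50.0
    do_interval_min: float = 0.5
    cv: dict = field(default_factory=_default_cv)
    do_sigma_mg_l: float = 0.05
    sensor_lag_s: float = 10.0

    def __post_init__(self) -> None:
        if self.offline_interval_min <= 0 or self.do_interval_min <= 0:
            raise ValueError("sampling intervals must be positive")
        if any(v < 0 for v in self.cv.values()) or self.do_sigma_mg_l < 0:
            raise ValueError("noise levels must be non-negative")


def _interp(traj: pd.DataFrame, t_h: np.ndarray, col: str) -> np.ndarray:
    return np.interp(t_h, traj["t_h"].to_numpy(), traj[col].to_numpy())


def sample_trajectory(traj: pd.DataFrame, plan: SamplingPlan | None = None,
                      seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample one trajectory into (offline table, DO log).

    The offline table carries t_min, hac_cmmol_l, phb_cmmol_l, vss_g_l,
    nh4_mmol_l with independent multiplicative Gaussian noise per analyte;
    VSS is reconstructed as X*24.6 + PHB*21.5 on a g/L basis.  The DO log
    carries both probes (do_in, do_out) with probe lag and additive noise.
    """
    if plan is None:
        plan = SamplingPlan()
    if traj is None or len(traj) == 0:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(seed)
    t0, t1 = float(traj["t_h"].iloc[0]), float(traj["t_h"].iloc[-1])

    # offline chemistry
    t_off = np.arange(t0, t1 + 1e-9, plan.offline_interval_min / 60.0)
    hac = _interp(traj, t_off, "s_ac_cmmol_l")
    phb = _interp(traj, t_off, "phb_cmmol_l")
    x = _interp(traj, t_off, "x_st_cmmol_l") + _interp(traj, t_off, "x_ns_cmmol_l")
    nh4 = _interp(traj, t_off, "nh4_mmol_l")
    vss = (x * BIOMASS_G_PER_CMOL + phb * PHB_G_PER_CMOL) / 1000.0

    def noisy(values, key):
        cv = plan.cv.get(key, 0.0)
        if cv == 0.0:
            return values
        return np.clip(values * (1.0 + cv * rng.standard_normal(len(values))),
                       0.0, None)

    offline = pd.DataFrame({
        "t_min": t_off * 60.0,
        "hac_cmmol_l": noisy(hac, "hac"),
        "phb_cmmol_l": noisy(phb, "phb"),
        "vss_g_l": noisy(vss, "vss"),
        "nh4_mmol_l": noisy(nh4, "nh4"),
    })

    # DO log
    t_do = np.arange(t0, t1 + 1e-9, plan.do_interval_min / 60.0)
    do_in = _interp(traj, t_do, "do_in_mg_l")
    do_out = _interp(traj, t_do, "do_out_mg_l")
    if plan.sensor_lag_s > 0 and len(t_do) > 1:
        dt_s = plan.do_interval_min * 60.0
        alpha = dt_s / (plan.sensor_lag_s + dt_s)
        for arr in (do_in, do_out):
            for i in range(1, len(arr)):
                arr[i] = arr[i - 1] + alpha * (arr[i] - arr[i - 1])
    if plan.do_sigma_mg_l > 0:
        do_in = do_in + plan.do_sigma_mg_l * rng.standard_normal(len(t_do))
        do_out = do_out + plan.do_sigma_mg_l * rng.standard_normal(len(t_do))
    do_log = pd.DataFrame({
        "t_min": t_do * 60.0,
        "do_in_mg_l": np.clip(do_in, 0.0, None),
        "do_out_mg_l": np.clip(do_out, 0.0, None),
    })
    return offline, do_log


def _write_with_header(df: pd.DataFrame, path: Path, scenario: str, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scenario={scenario} seed={seed} generator_version={GENERATOR_VERSION}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def make_fixture_suite(seed: int = 0, outdir: str | Path = "fixtures") -> dict:
    """Generate the small CSV fixture bundle (SBR, FD and batch scenarios).

    Each scenario is simulated for one cycle (batch: one accumulation run),
    sampled with the default plan, and written as commented CSVs.  Byte
    identical for identical seeds.  Returns {name: {kind: path}}.
    """
    from .pipeline import load_scenario, simulate_scenario

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    for name in ("SBR1", "FD", "batch"):
        cfg = load_scenario(name, seed=seed)
        out = simulate_scenario(cfg)
        offline, do_log = sample_trajectory(out.result.trajectory,
                                            SamplingPlan(), seed=seed)
        p_off = outdir / f"{name.lower()}_offline.csv"
        p_do = outdir / f"{name.lower()}_do.csv"
        _write_with_header(offline, p_off, name, seed)
        _write_with_header(do_log, p_do, name, seed)
        paths[name] = {"offline": p_off, "do": p_do}
    return paths
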