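"""Two-guild feast-famine storage kinetics.

The culture is split into a PHB-storing guild and a non-storing guild.
Under double growth limitation (carbon at feast start, nitrogen at famine
start) the storers convert external acetate to PHB during the feast and
grow on the stored PHB during the famine; non-storers can only grow when
external substrate and ammonium co-occur, which the regime denies them.

Rate laws (the observable rates and yields are reproduced, the functional
forms are this package's model):

* feast acetate uptake by storers, Cmol Ac/Cmol X/h::

      q_S = q_S_max * S/(K_S+S) * K_I/(K_I+S) * (1 - (f/f_max)^alpha)

  Monod uptake, a Haldane-type substrate-inhibition factor, and a storage
  capacity-saturation factor in the internal PHB fraction f = PHB/X_st;
  a fixed fraction Y_PS of the carbon taken up is stored as PHB, the rest
  is respired;
* famine growth of storers on PHB, gated off while external substrate is
  present (storage takes precedence over polymer degradation)::

      mu = mu_max * f/(K_f+f) * NH4/(K_N+NH4) * K_rep/(K_rep+S)

  PHB is consumed at mu/Y_X_PHB;
* non-storer growth requires both S and NH4 (double Monod) with biomass
  yield ``y_xs_ns`` on acetate.

Oxygen uptake follows from the electron balance: gamma-weighted carbon
fluxes divided by 4 e-/mol O2, plus an endogenous maintenance respiration
``m_o2 * X`` that is not coupled to the tracked carbon pools.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .stoichiometry import GAMMA_ACETATE, GAMMA_BIOMASS, GAMMA_PHB

__all__ = ["KineticParams", "RateVector", "rates", "calibrate", "CalibrationError"]

#: nitrogen content of biomass, mmol N per Cmmol X (CH1.8O0.5N0.2)
N_CONTENT = 0.2


class CalibrationError(ValueError):
    """Raised for thermodynamically or numerically infeasible targets."""


@dataclass
class KineticParams:
    """Kinetic and stoichiometric parameters of one mixed culture.

    Units: substrate-related half-saturation constants in Cmmol/L, specific
    rates per hour, yields Cmol/Cmol, maintenance respiration in
    mmol O2/Cmol X/h, ammonium constants in mmol N/L.
    """

    # storer guild, feast
    q_s_max: float = 1.419   # Cmol Ac/Cmol X/h, calibrated (see calibrate())
    k_s: float = 1.0         # Cmmol/L
    k_i: float = 60.0        # Cmmol/L, substrate inhibition
    y_ps: float = 0.81       # Cmol PHB/Cmol Ac
    f_phb_max: float = 7.5   # Cmol PHB/Cmol X, storage capacity (~87 wt%)
    alpha: float = 4.0       # capacity-saturation exponent
    # storer guild, famine
    mu_max: float = 0.35     # 1/h, growth on PHB
    k_f: float = 0.3         # Cmol PHB/Cmol X
    k_n: float = 0.2         # mmol N/L
    k_rep: float = 0.5       # Cmmol/L, PHB degradation repressed by external S
    y_x_phb: float = 0.70    # Cmol X/Cmol PHB
    # non-storer guild
    mu_max_ns: float = 0.30  # 1/h
    k_s_ns: float = 1.0      # Cmmol/L
    y_xs_ns: float = 0.50    # Cmol X/Cmol Ac
    # respiration
    m_o2: float = 5.0        # mmol O2/Cmol X/h, endogenous baseline
    # overflow (uncoupled) acetate oxidation at inhibitory substrate levels,
    # the carbon-wasting face of substrate inhibition: rate
    # m_over * S/(k_i + S) * X, vanishing with the inhibition itself as
    # k_i -> infinity
    m_over: float = 0.10     # Cmol Ac/Cmol X/h

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise ValueError(f"kinetic parameter {name} must be positive, got {value}")
        # electron balance requires catabolic electron supply in every mode
        if self.y_ps >= GAMMA_ACETATE / GAMMA_PHB:
            raise ValueError(
                f"y_ps={self.y_ps} violates the electron balance "
                f"(must be < {GAMMA_ACETATE / GAMMA_PHB:.3f})"
            )
        if self.y_x_phb >= GAMMA_PHB / GAMMA_BIOMASS:
            raise ValueError(
                f"y_x_phb={self.y_x_phb} violates the electron balance "
                f"(must be < {GAMMA_PHB / GAMMA_BIOMASS:.3f})"
            )
        if self.y_xs_ns >= GAMMA_ACETATE / GAMMA_BIOMASS:
            raise ValueError(
                f"y_xs_ns={self.y_xs_ns} violates the electron balance "
                f"(must be < {GAMMA_ACETATE / GAMMA_BIOMASS:.3f})"
            )


@dataclass
class RateVector:
    """Concentration derivatives (per hour) and the oxygen uptake rate.

    ``ds``, ``dxs``, ``dxn``, ``dphb`` in Cmmol/L/h, ``dnh4`` in mmol/L/h,
    ``dco2`` in Cmmol/L/h (CO2 carbon evolved), ``our_exo`` and
    ``our_total`` in mmol O2/L/h.
    """

    ds: float
    dxs: float
    dxn: float
    dphb: float
    dnh4: float
    dco2: float
    our_exo: float
    our_total: float


def rates(s: float, xs: float, xn: float, phb: float, nh4: float,
          p: KineticParams) -> RateVector:
    """Evaluate the kinetic right-hand side at one state.

    State components are concentrations (Cmmol/L; NH4 in mmol/L).  Small
    negative excursions from the integrator (>-1e-6) are clamped to zero;
    anything larger is an error.
    """
    for name, v in (("S", s), ("X_storer", xs), ("X_nonstorer", xn),
                    ("PHB", phb), ("NH4", nh4)):
        if v < -1e-6:
            raise ValueError(f"negative state component {name}={v}")
    s = max(s, 0.0)
    xs = max(xs, 0.0)
    xn = max(xn, 0.0)
    phb = max(phb, 0.0)
    nh4 = max(nh4, 0.0)

    # storers: feast storage
    if xs > 0.0:
        f = min(phb / xs, 1e12)  # keep Monod ratios finite at vanishing X
        cap = 0.0 if f >= p.f_phb_max else 1.0 - (f / p.f_phb_max) ** p.alpha
        q_s = p.q_s_max * s / (p.k_s + s) * p.k_i / (p.k_i + s) * cap
    else:
        f = 0.0
        q_s = 0.0
    uptake_st = q_s * xs                      # Cmmol Ac/L/h
    storage = p.y_ps * uptake_st              # Cmmol PHB/L/h

    # storers: famine growth on PHB (repressed while external S present)
    if xs > 0.0 and phb > 0.0:
        mu_st = (p.mu_max * f / (p.k_f + f) * nh4 / (p.k_n + nh4)
                 * p.k_rep / (p.k_rep + s))
    else:
        mu_st = 0.0
    growth_st = mu_st * xs                    # Cmmol X/L/h
    phb_consumption = growth_st / p.y_x_phb   # Cmmol PHB/L/h

    # non-storers: double-Monod growth on external S and NH4
    if xn > 0.0:
        mu_ns = p.mu_max_ns * s / (p.k_s_ns + s) * nh4 / (p.k_n + nh4)
    else:
        mu_ns = 0.0
    growth_ns = mu_ns * xn                    # Cmmol X/L/h
    uptake_ns = growth_ns / p.y_xs_ns         # Cmmol Ac/L/h

    # overflow oxidation (both guilds): substrate burnt to CO2 at
    # inhibitory acetate levels, no storage or growth
    overflow = p.m_over * s / (p.k_i + s) * (xs + xn)

    ds = -uptake_st - uptake_ns - overflow
    dxs = growth_st
    dxn = growth_ns
    dphb = storage - phb_consumption
    dnh4 = -N_CONTENT * (growth_st + growth_ns)
    # CO2 carbon closes the carbon balance identically
    dco2 = ((uptake_st - storage)
            + (phb_consumption - growth_st)
            + (uptake_ns - growth_ns)
            + overflow)

    # exogenous OUR from the electron balance (4 e- per mol O2)
    e_flux = (GAMMA_ACETATE * (uptake_st + uptake_ns + overflow)
              - GAMMA_PHB * dphb
              - GAMMA_BIOMASS * (dxs + dxn))
    our_exo = e_flux / 4.0
    our_total = our_exo + p.m_o2 * (xs + xn) / 1000.0
    return RateVector(ds, dxs, dxn, dphb, dnh4, dco2, our_exo, our_total)


def calibrate(q_ac: float, q_p: float, y_ps: float,
              base: KineticParams | None = None,
              x0: float = 31.0, budget_cmmol_l: float = 182.0,
              volume_l: float = 3.4) -> KineticParams:
    """Fit q_s_max and y_ps so a simulated feed-on-demand feast reproduces
    the observed feast-aggregate rates.

    ``q_ac``/``q_p`` are the observed specific uptake and storage rates
    (Cmol/Cmol/h) and ``y_ps`` the storage yield; self-consistency
    (y = q_p/q_ac) is assumed but not enforced beyond a sanity window.
    The storage yield maps directly onto the model's ``y_ps``; ``q_s_max``
    is found by bisection so that the closed-loop feast consumes the
    substrate budget at the observed aggregate rate (consumed / X / t at
    detected substrate exhaustion).
    """
    from scipy.optimize import brentq

    from .controller import ControllerConfig, run_feast_closed_loop
    from .reactor import ReactorState

    if base is None:
        base = KineticParams()
    if not (0.0 < y_ps < GAMMA_ACETATE / GAMMA_PHB):
        raise CalibrationError(
            f"target yield {y_ps} infeasible: no catabolic electron supply "
            f"(need 0 < Y < {GAMMA_ACETATE / GAMMA_PHB:.3f})"
        )
    if q_ac <= 0 or q_p <= 0 or q_p > q_ac:
        raise CalibrationError(f"inconsistent targets q_ac={q_ac}, q_p={q_p}")

    budget = budget_cmmol_l * volume_l

    def simulated_q_ac(q_s_max: float) -> float:
        p = replace(base, y_ps=y_ps, q_s_max=q_s_max)
        state = ReactorState(v=volume_l, s=0.0, xs=x0, xn=0.0, phb=2.0, nh4=0.1)
        cfg = ControllerConfig(pulse_dose_cmmol=budget / 30.0, budget_cmmol=budget)
        res = run_feast_closed_loop(state, p, cfg, feast_min=600.0)
        t_end_h = res.feast_end_min / 60.0
        consumed_per_l = res.consumed_cmmol / volume_l
        return consumed_per_l / (x0 * t_end_h)

    def objective(q: float) -> float:
        return simulated_q_ac(q) - q_ac

    lo, hi = 0.3, 6.0
    flo, fhi = objective(lo), objective(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"target q_ac={q_ac} outside the attainable range "
            f"[{flo + q_ac:.3f}, {fhi + q_ac:.3f}]"
        )
    q_fit = brentq(objective, lo, hi, xtol=1e-3)
    return replace(base, y_ps=y_ps, q_s_max=float(q_fit))
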