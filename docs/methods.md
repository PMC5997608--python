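# Methods

## The system being modelled

An 18-h sequencing batch reactor cycle for mixed-culture PHB production
that couples the enrichment of storing organisms with polymer harvest in
one tank: a 360-min feast (carbon feed at t = 0, 3/4 of the mixed liquor
withdrawn at the end as product), an optional 25-min settle-and-decant
selection step, and a ~695–720-min famine opened by the nutrient feed.
Withdrawal sets the solids retention time at ≈1 day. The working volume is
3.4 L; a respirometer loop (3 L aerated tank, 1 L unaerated reaction tank,
0.5 L/min recirculation) provides dual-probe DO readings from which the
oxygen uptake rate is computed every 0.5 min.

Two feeding regimens are modelled: a single acetate pulse of 124.5 Cmmol/L
per cycle (start-up), and feed-on-demand control in which a fixed quantum
of acetate is pulsed whenever the OUR derivative turns negative, up to a
budget of 182 Cmmol/L per cycle (operation).

## Kinetic model

State per tank: acetate S, storer biomass X_st, non-storer biomass X_ns,
PHB, ammonium, all as concentrations (Cmmol/L; NH4 in mmol/L). The rate
laws are the minimal forms that produce the three behaviours the model
exists to reproduce — the observed feast rates, the pulsed-feeding
advantage, and the storage-rate decline at high polymer content:

* **Feast storage.** q_S = q_S,max · S/(K_S+S) · K_I/(K_I+S) ·
  (1 − (f/f_max)^α), with f = PHB/X_st. The Haldane factor K_I/(K_I+S)
  embodies substrate inhibition; the capacity factor shuts storage down as
  cells approach f_max. A fixed fraction Y_P/S of the carbon taken up is
  stored, the remainder respired. Storers do not grow during the feast:
  under double growth limitation no significant ammonium is present.
* **Overflow oxidation.** At inhibitory acetate levels both guilds burn
  substrate without storage or growth at m_over · S/(K_I+S) · X. This is
  the carbon-wasting face of substrate inhibition: it lowers the realised
  storage yield of single-pulse feeding, and it vanishes together with the
  inhibition as K_I → ∞, so the pulsed/single comparison has a clean
  inhibition-free limit. It also keeps start-up simulations physical: a
  crashed culture confronted with more acetate than it can store burns the
  excess instead of letting it accumulate without bound across cycles.
* **Famine growth on PHB.** μ = μ_max · f/(K_f+f) · NH4/(K_N+NH4) ·
  K_rep/(K_rep+S); the last factor represses polymer degradation while
  external substrate remains (storage takes precedence). PHB is consumed
  at μ/Y_X/PHB; biomass nitrogen demand is 0.2 mol N per Cmol X.
* **Non-storers.** Double-Monod growth on S and NH4 with yield Y_XS; they
  can only grow where the regime leaks both resources at once.
* **Oxygen.** Exogenous OUR follows from the degree-of-reduction balance
  (γ_acetate = 4.0, γ_PHB = 4.5, γ_biomass = 4.2; 4 e⁻ per mol O₂), plus
  an endogenous respiration m_O2·X not coupled to the tracked carbon
  pools. Because the CO₂ rate is defined as the carbon-balance residual at
  the level of the right-hand side, carbon and electron closure hold to
  integrator round-off by construction, for any integrator; the test suite
  asserts <1e-6 relative, observed ~1e-14.

DO is kept non-limiting (the plant holds DO above 2 mg/L), so oxygen never
enters the kinetics; the respirometer loop is evaluated as the quasi-steady
map DO_in = DO_sat − OUR·V_r/(kLa·V_aer), DO_out = DO_in − OUR·V_r/Q,
justified because the loop's time constant (~2 min) is far below the
process time scales. The full two-tank ODE (`simulate_do_loop`) exists for
studying the transient itself.

### Parameters, units, defaults

| parameter | meaning | default | basis |
|---|---|---|---|
| q_S,max | max specific uptake, Cmol/Cmol/h | 1.419 | calibrated so the closed-loop feast reproduces q_AC = 1.05 at X = 31 Cmmol/L (see below) |
| K_S | uptake half-saturation, Cmmol/L | 1.0 | typical VFA affinity |
| K_I | inhibition constant, Cmmol/L | 60 | single 124.5 Cmmol/L pulse roughly halves the uptake rate |
| Y_P/S | storage yield, Cmol/Cmol | 0.81 | observed feed-on-demand yield |
| f_max, α | storage capacity and sharpness | 7.5, 4 | ≈87 wt% attainable, matching the batch plateau |
| μ_max, K_f, K_N | famine growth on PHB | 0.35 /h, 0.3, 0.2 | famine regrowth 7.9 → 31 Cmmol/L completes within ~12 h |
| Y_X/PHB | growth yield on PHB, Cmol/Cmol | 0.70 | famine PHB (≈37 Cmmol/L) just covers the nitrogen-limited growth (≈23.5 Cmmol/L), leaving both near zero, as observed |
| K_rep | degradation repression, Cmmol/L | 0.5 | storage-before-degradation switch |
| μ_max,ns, K_S,ns, Y_XS | non-storer guild | 0.30 /h, 1.0, 0.50 | ordinary heterotroph an order slower at VFA scavenging than a storer |
| m_O2 | endogenous respiration, mmol O₂/Cmol X/h | 5.0 | ≈5 mg O₂/L/h at X = 31 Cmmol/L — a stable, measurable OUR baseline for the controller's arming step |
| m_over | overflow oxidation, Cmol/Cmol/h | 0.10 | splits the realised yields of pulsed vs single-pulse feeding in the observed direction |
| kLa, DO_sat | aeration | 20 /h, 7.5 mg/L | keeps DO > 2 mg/L at peak OUR |

Electron-balance feasibility is enforced at construction: Y_P/S < 4/4.5,
Y_X/PHB < 4.5/4.2, Y_XS < 4/4.2; a yield of 1 is rejected as having no
catabolic electron supply.

### Calibration

`calibrate(q_AC, q_P, Y)` maps the observed feast aggregates onto model
parameters: Y is Y_P/S directly (during a DGL feast every stored Cmol comes
through the storage pathway), and q_S,max is found by bisection so that the
simulated closed-loop feast consumes its budget at the observed aggregate
rate. The shipped default q_S,max = 1.419 is the output of this procedure
for the targets (1.05, 0.85, 0.81); it is reproducible by calling
`calibrate` and is deliberately larger than the realised 1.05 because the
Monod, inhibition and capacity factors each shave the instantaneous rate.

## Controller

The feed-on-demand state machine consumes one OUR sample per 0.5 min:
a compulsive START pulse after a 5-min baseline window (the endogenous OUR
level is recorded then), afterwards a fixed dose whenever the smoothed
derivative is negative, a hold otherwise, a hard stop at the budget, and
termination once OUR has returned to within 10% of the baseline for 4
consecutive samples after budget exhaustion. Derivatives are moving-median
smoothed (window 3). The raw "< 0" rule needs one guard: between pulses the
OUR declines smoothly through the Monod term, so a strict sign test fires
at almost every sample and collapses the pulse train into a continuous
dump. A relative deadband (feed only when dOUR/dt < −2%/min of the current
OUR) lets the pump refire only when the decline steepens near substrate
exhaustion, producing the observed staircase: ~30 pulses over ~5.6 h whose
cumulative curve ends exactly at the budget. All thresholds are exposed in
`ControllerConfig`. Pump dynamics are idealised as instantaneous boluses;
pulse volumes are treated as volume-free concentrate (see below).

With the alternative reading of the printed derivative denominator (n·Δt
rather than Δt) every derivative scales by a positive factor, so no control
decision changes; Δt is used.

## Reactor engine and events

Continuous segments are integrated with LSODA (rtol 1e-8 for single-cycle
work, 1e-6 in multi-cycle enrichment runs); the closed-loop feast uses
fixed-step RK4 at 0.1 min between controller samples. Discrete actions —
carbon dose, withdrawal (concentrations unchanged, volume scaled),
settling selection, nutrient feed — restart the integration and are logged
with exact mass and volume bookkeeping. Feeds are dosed as volume-free
concentrate and the famine make-up water restores the working volume, so
the famine opens with exactly a fourfold dilution (31 → 7.75 Cmmol/L
biomass), matching the physical reactor's 0.85 + 2.3 + 0.25 L budget while
keeping the volume ledger exact. No reaction is computed during the 25-min
settle (no aeration or mixing).

Settling selection removes a fraction r_g = clamp(r_base·(1 − s·f_g/f_max))
of each guild's suspended biomass, r_base = 0.25, s = 3: removal falls to
zero once cells carry f ≳ f_max/3 ≈ 2.5 Cmol/Cmol — at that loading a cell
is already two-thirds polymer by weight and settles fast, so the decant
only skims polymer-poor cells. Non-storers always lose the full r_base.

## Scenarios and the synthetic study conditions

Presets: `SBR1` (start-up, settling on, famine 695 min), `SBR2` (start-up,
settling off, famine 720 min), `FD` (operational feed-on-demand cycle,
budget 182 Cmmol/L, pulse dose budget/30), `batch` (4 L, nitrogen-free,
controller-fed accumulation to capacity). The start-up nutrient feed doses
12 mmol NH4 per cycle — matched to the growth the 124.5 Cmmol/L carbon
dose can support, as an operator balancing the DGL cycle would choose —
while the operational FD cycle doses 16 mmol (4.7 mmol/L at the famine
start, drawn down to ~0.1 by nitrogen-limited regrowth).

The enrichment inoculum emulates activated sludge: 5.13 g/L MLSS (80%
volatile), 3% of it storers — storers are a minor guild in municipal
sludge, and starting them below their steady-state level is what produces
the observed fall-and-recover MLSS trajectory. Seeds jitter the inoculum
(±5% MLSS, log-normal storer fraction); the cycle dynamics are
deterministic. The reported MLSS-equivalent is sampled at the end of the
feast, before withdrawal, when the sludge is polymer-laden. Steady state
is declared on the day from which the per-cycle PHB maximum (wt%) spans
less than one percentage point over three solids retention times.

The synthetic measurement generator turns trajectories into what a wet-lab
campaign would record: offline chemistry every 50 min with multiplicative
Gaussian noise (CVs 3% acetate, 4% PHB, 3% VSS, 5% NH4 — plausible
GC/gravimetric/colorimetric precision), and 0.5-min dual-probe DO logs
with a 10-s first-order probe lag and 0.05 mg/L additive noise. It is a
pure function of (trajectory, plan, seed); with zero noise it returns the
interpolated trajectory exactly. What it does **not** emulate: sampling
dead volume, drift or recalibration of probes, day-to-day biomass
variability, or any community structure beyond the two guilds — so passing
tests demonstrate correct analysis of data with this noise structure, not
robustness to every failure mode of real instrumentation.

When metrics are computed from sampled tables, the feast boundary is the
first sample within one analytical CV of the sampled PHB maximum: PHB
plateaus after substrate exhaustion, and a plain argmax on a noisy plateau
scatters the feast-length estimate across the plateau.

## Numerical and degenerate-input choices

Integrator trial steps may probe slightly negative concentrations; the
rate function clamps anything above −1e-6 to zero and raises beyond that.
The internal polymer ratio is capped (f ≤ 1e12) so vanishing biomass with
finite PHB stays finite. Zero-duration phases are identities; withdrawing
the full volume is refused (volume floor); a zero substrate budget is
legal and terminates the controller after its baseline check. The
feast-end detector applies an absolute OUR floor (0.05 mg/L/min) so a
(near-)zero baseline still terminates detection.

## Known limitations

* The two-guild ecology is a caricature: real enrichments shift species
  composition continuously, so start-up takes weeks, not the ~9–11
  simulated days; only the ordering (settling accelerates start-up) and
  the shapes are meaningful, not the absolute days.
* Yields are constants per pathway; the model therefore realises a
  feed-on-demand storage yield of ≈0.80 and a single-pulse yield of ≈0.75,
  reproducing the direction but not the full spread of the observed
  0.81 vs 0.60 split.
* The volumetric productivity of the simulated FD cycle computes to
  ≈3.2 g PHB/L/day from the harvest ledger (harvested polymer / working
  volume / cycle time); the reported 5.0 g/L/day for the same operating
  point is not recoverable from the printed concentrations, volume and
  time by any convention we tried, so the formula is implemented as
  defined and the discrepancy noted rather than tuned away.
* Famine-end ammonium reaches ~0.0 mmol/L where ~0.1 is observed —
  the model lacks a residual-nitrogen floor (cell lysis, measurement
  blank).
* No pH, temperature or DO feedback on kinetics; no PHV co-polymer; no
  hydraulic detail of the settle (a two-class removal rule stands in for
  sedimentation physics).
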