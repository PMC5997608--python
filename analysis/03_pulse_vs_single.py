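"""Pulsed feeding versus a single pulse at equal total substrate.

Sweeps the substrate-inhibition constant K_I and compares the final PHB
content of the feed-on-demand cycle against a single pulse of the same
182 Cmmol/L budget in the same feast window.  The pulsed advantage is the
inhibition avoided; it vanishes as K_I grows.  Writes
results/pulse_vs_single.csv.
"""

from pathlib import Path

import pandas as pd

from feastfamine.pipeline import load_scenario, simulate_scenario

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for k_i in (30.0, 60.0, 120.0, 500.0, 1e7):
    fd = simulate_scenario(load_scenario("FD", seed=0,
                                         overrides={"kinetics": {"k_i": k_i}}))
    sp = simulate_scenario(load_scenario("FD", seed=0, overrides={
        "kinetics": {"k_i": k_i},
        "controller": None,
        "schedule": {"carbon_dose_cmmol_l": 182.0},
    }))
    rows.append({
        "k_i_cmmol_l": k_i,
        "fd_phb_wt_pct": fd.metrics.phb_max_wt_pct,
        "single_phb_wt_pct": sp.metrics.phb_max_wt_pct,
        "gap_wt_pct": fd.metrics.phb_max_wt_pct - sp.metrics.phb_max_wt_pct,
        "fd_phb_cmmol_l": fd.metrics.phb_max_cmmol_l,
        "single_phb_cmmol_l": sp.metrics.phb_max_cmmol_l,
    })

df = pd.DataFrame(rows)
df.to_csv(OUT / "pulse_vs_single.csv", index=False, float_format="%.3f")
print(df.to_string(index=False))
print("\nWith the default K_I = 60 Cmmol/L the pulse train stores "
      f"{df.iloc[1].gap_wt_pct:.1f} percentage points more polymer than the "
      "single pulse; at effectively infinite K_I the two regimens coincide "
      f"(gap {df.iloc[-1].gap_wt_pct:.2f} points).")
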