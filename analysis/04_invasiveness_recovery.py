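#!/usr/bin/env python
"""Cross-validate the two D/rho estimators against full PI-model simulations.

For D/rho values spanning the clinical range, simulate the reaction-diffusion
model to the established-wave regime, image the density field virtually at the
80%/16% thresholds, and estimate D/rho from the resulting radius pair with
(a) the closed-form leading-edge formula and (b) the PDE gap lookup.

Finding: the lookup is calibration-free and recovers truth to well under 1%,
while the closed form overestimates by a stable factor of ~14 -- the 80/16
contours sit in the nonlinear front region, where the profile is ~6*sqrt(D/rho)
wide rather than the ln5*sqrt(D/rho) of the exponential-tail approximation.
Because the factor is stable, the closed form remains a faithful *ranking*
metric (it distorts the scale, not the order), which is what the tertile-based
response analysis relies on.  Writes results/dr_recovery.csv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from piresponse import (PIParameters, estimate_d_over_rho, estimate_d_over_rho_pde,
                        simulate_pi_model, virtual_radii)
from piresponse.pi_model import simulation_plan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
lookup = np.geomspace(0.004, 10.5, 10)
for i, true_dr in enumerate(np.geomspace(0.01, 9.5, 12)):
    rho = [5.0, 10.0, 20.0, 40.0][i % 4]
    plan = simulation_plan(true_dr, rho)
    p = PIParameters(D_mm2_per_year=plan["D"], rho_per_year=rho)
    prof = simulate_pi_model(p, domain_mm=plan["domain_mm"],
                             duration_years=plan["duration_years"],
                             dr_mm=plan["dr_mm"], init=plan["init"])[-1]
    r1, r2 = virtual_radii(prof, p)
    cf = estimate_d_over_rho(r1, r2).d_over_rho_mm2
    pde = estimate_d_over_rho_pde(r1, r2, lookup_grid=lookup).d_over_rho_mm2
    rows.append({"true_d_over_rho_mm2": true_dr, "rho_per_year": rho,
                 "r_t1gd_mm": r1, "r_t2_mm": r2, "gap_mm": r2 - r1,
                 "closed_form_mm2": cf, "pde_lookup_mm2": pde,
                 "closed_form_factor": cf / true_dr,
                 "pde_rel_err_pct": 100 * (pde / true_dr - 1)})

df = pd.DataFrame(rows)
df.to_csv(OUT / "dr_recovery.csv", index=False)
print(df.round(4).to_string(index=False))
print(f"\nclosed-form overestimation factor: "
      f"{df['closed_form_factor'].min():.1f}-{df['closed_form_factor'].max():.1f} "
      f"(stable -> ranks preserved)")
print(f"PDE-lookup recovery error: max {df['pde_rel_err_pct'].abs().max():.2f}%")
print(f"wrote {OUT/'dr_recovery.csv'}")
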