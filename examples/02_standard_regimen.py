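"""Simulate the standard 350 mg / 4-weekly infliximab regimen in CD.

Integrates the stiff four-state model over three 2-hour infusions (weeks
0/4/8) and prints per-cycle extrema: drug peaks right after each infusion,
TNF-α collapses, then both drift back as the drug is cleared — the drug
trough just before the next dose is the therapeutic-drug-monitoring readout.
"""

from ifxsim import (
    THERAPEUTIC_TROUGH_MG_L,
    UnitConventions,
    cycle_extrema,
    disease_preset,
    integrate_regimen,
    molar_to_mass_conc,
    standard_sweep_schedule,
)

conv = UnitConventions()
params, init = disease_preset("CD", k_el_ab=3.5e-6)
ts = integrate_regimen(params, init, standard_sweep_schedule(dose_mg=350.0))

print("cycle  weeks        drug peak (M)  trough (mg/L)  TNF peak (M)  TNF min (M)")
for c in cycle_extrema(ts):
    a, b = (x / 604800.0 for x in c.interval)
    trough_mgl = molar_to_mass_conc(c.A_min, conv.ifx_molar_mass)
    print(
        f"{c.cycle_index:>5}  [{a:4.1f},{b:5.1f}]  {c.A_max:12.3e}  "
        f"{trough_mgl:12.3f}  {c.L_max:12.3e}  {c.L_min:12.3e}"
    )

print()
print(f"conservation drift of the TNF pool: {ts.conservation_drift():.2e} M "
      f"(pool {ts.total_pool:.4g} M)")
print(f"at clearance 3.5e-6 1/s the troughs sit far below the "
      f"{THERAPEUTIC_TROUGH_MG_L} mg/L therapeutic threshold, so 350 mg 4-weekly "
      "is sub-therapeutic for this patient.")
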