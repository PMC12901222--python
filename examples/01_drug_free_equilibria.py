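"""Closed-form drug-free equilibria for CD and UC, and the production calibration.

Without antibody the model's equilibria solve a quadratic in the receptor
occupancy r*; the biologically admissible root gives the chronic inflammatory
TNF-α level each disease relaxes to, and fixes the TNF-α production rate that
keeps that state stationary.
"""

from ifxsim import disease_preset, drug_free_equilibria, production_rate_at_equilibrium

for name in ("CD", "UC"):
    params, init = disease_preset(name)
    eq = drug_free_equilibria(params, init.tnf, init.r, init.cx)
    w1 = production_rate_at_equilibrium(params, eq.L_star, eq.r_star)
    print(f"{name}: baseline TNF-α L0 = {init.tnf:.3g} M, occupancy r0 = {init.r}")
    print(f"    quadratic roots r* = {eq.r1_star:.4f}, {eq.r2_star:.4f}")
    print(f"    admissible equilibrium: L* = {eq.L_star:.4g} M (r* = {eq.r_star:.4f})")
    print(f"    stationary TNF-α production = {w1:.5g} M/s")

print()
print("L* is the untreated chronic-inflammation TNF-α level (2.07e-11 M in CD,")
print("1.41e-11 M in UC); the production rate is the value that makes that")
print("level an exact steady state of the dynamics.")
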