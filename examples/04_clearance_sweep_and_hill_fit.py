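"""Sweep the infliximab clearance rate and refit the inverted Hill model.

For each clearance in the literature range [1.5e-6, 5e-6] 1/s, the standard
350 mg 4-weekly protocol is simulated and the final-cycle drug trough and
TNF-α peak recorded.  Low clearance keeps the trough inside the therapeutic
range (≥ 3 mg/L); high clearance lets TNF-α rebound toward the untreated
equilibrium.  The trough↔clearance relation is then summarised by the
inverted Hill model δ(A_min) = V / (1 + (A_min/K)^n).
"""

import warnings

import numpy as np

from ifxsim import clearance_sweep, disease_preset, fit_hill
from ifxsim.dosing import therapeutic_threshold_molar

warnings.filterwarnings("ignore", message="antibody clearance")

params, init = disease_preset("CD")
sweep = clearance_sweep(params, init=init)

print(sweep[["k_el_ab", "A_min_mgL", "A_max_mgL", "L_max", "L_min"]]
      .iloc[::7].to_string(index=False))

thr = therapeutic_threshold_molar()
a_min = sweep["A_min"].to_numpy()
crossing = np.exp(np.interp(np.log(thr), np.log(a_min[::-1]),
                            np.log(sweep["k_el_ab"].to_numpy()[::-1])))
print(f"\ntrough falls below 3 mg/L above clearance ≈ {crossing:.3g} 1/s")

fit = fit_hill(a_min, sweep["k_el_ab"].to_numpy())
print("\ninverted Hill refit of the sweep (clearance as a function of trough):")
print(f"  V (max clearance)    = {fit.params.v_max:.5g} 1/s")
print(f"  K (half-max trough)  = {fit.params.k_half:.5g} M")
print(f"  n (Hill exponent)    = {fit.params.n:.4f}")
print(f"  residual norm        = {fit.residual_norm:.3g} over {fit.n_points} points")
print("\nThe shallow exponent (n ≈ 0.25) means clearance responds to trough")
print("changes over several orders of magnitude of exposure.")
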