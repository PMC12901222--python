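"""Adaptive dosing: update the clearance from each measured trough.

Inflammation accelerates infliximab loss, so as troughs rise the clearance
falls — captured by the inverted Hill relation.  The loop mirrors therapeutic
drug monitoring: dose every 4 weeks, measure the trough immediately before
the next dose, update the clearance, repeat.  The regimen "reaches the
therapeutic level" at the first dose whose end-of-interval trough meets
3 mg/L.
"""

import warnings

from ifxsim import disease_preset, recommend_dose, simulate_adaptive_regimen

warnings.filterwarnings("ignore", message="antibody clearance")

params, init = disease_preset("CD")

for dose in (350.0, 500.0, 700.0):
    res = simulate_adaptive_regimen(
        params, dose_mg=dose, n_doses=13, clearance0=3.5e-6, init=init
    )
    frame = res.to_frame()
    outcome = (
        f"therapeutic after {res.doses_to_therapeutic} doses"
        if res.reached
        else "not therapeutic within one year (13 doses)"
    )
    print(f"{dose:.0f} mg every 4 weeks, initial clearance 3.5e-6 1/s: {outcome}")
    print(
        "  troughs (mg/L):",
        " ".join(f"{v:.2f}" for v in frame["trough_mgL"]),
    )
    print(
        "  clearance trace (1e-6/s):",
        " ".join(f"{v * 1e6:.2f}" for v in frame["clearance_per_s"]),
    )

best = recommend_dose(params, clearance0=3.5e-6, candidate_doses=(350.0, 500.0, 700.0),
                      init=init)
print(f"\nsmallest candidate dose that reaches the range within a year: {best:.0f} mg")
print("Higher doses push troughs up faster, which feeds back through the Hill")
print("relation to lower clearance — so the benefit compounds across doses.")
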