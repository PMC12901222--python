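"""Disease presets: baseline parameters and initial conditions for CD and UC.

The two IBD subtypes share the kinetic rate constants and differ only in the
baseline free TNF-α level, chosen so the drug-free equilibrium matches the
reported values in active Crohn's disease (2.07e-11 M) and active ulcerative
colitis (1.40e-11 M).  Both start with receptor occupancy 0.0827 and no drug.
"""

from __future__ import annotations

from .model import ModelParams, ModelState

__all__ = ["PRESETS", "disease_preset", "CD_INIT", "UC_INIT"]

#: Initial conditions (free TNF-α M, receptor occupancy, antibody M, complex M)
CD_INIT = ModelState(tnf=4.35e-11, r=0.0827, ab=0.0, cx=0.0)
UC_INIT = ModelState(tnf=2.75e-11, r=0.0827, ab=0.0, cx=0.0)

PRESETS: dict[str, ModelState] = {"CD": CD_INIT, "UC": UC_INIT}


def disease_preset(name: str, k_el_ab: float = 3.5e-6) -> tuple[ModelParams, ModelState]:
    """Return ``(params, initial_state)`` for a disease preset.

    Parameters
    ----------
    name
        ``"CD"`` (Crohn's disease) or ``"UC"`` (ulcerative colitis),
        case-insensitive.
    k_el_ab
        Infliximab clearance rate (1/s) to plug into the shared parameter set.
    """
    key = name.upper()
    if key not in PRESETS:
        raise KeyError(f"unknown disease preset {name!r}; choose from {sorted(PRESETS)}")
    return ModelParams(k_el_ab=k_el_ab), PRESETS[key]
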