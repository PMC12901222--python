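"""Scenario configuration: YAML/JSON schemas, presets, and fixture generation.

A scenario bundles everything one simulation needs — disease preset or custom
parameters, initial state, unit conventions, dose schedule, which model system
to integrate, and (optionally) the adaptive-regimen settings.  Time fields in
config files use the clinical framing (weeks, hours, mg); everything is
normalised to seconds/molar on load.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .adaptive import HillParams
from .dosing import (
    DoseSchedule,
    UnitConventions,
    mass_to_molar_conc,
    schedule_from_dicts,
    schedule_to_dicts,
)
from .model import ModelParams, ModelState
from .presets import PRESETS
from .simulate import SYSTEMS

__all__ = ["ScenarioConfig", "AdaptiveSettings", "load_config", "save_config", "generate_fixtures"]


@dataclass(frozen=True)
class AdaptiveSettings:
    """Adaptive-regimen block of a scenario."""

    clearance0: float = 3.5e-6
    dose_mg: float = 500.0
    n_doses: int = 13
    interval_weeks: float = 4.0
    threshold_mg_l: float = 3.0
    hill: HillParams = field(default_factory=HillParams)

    def threshold_molar(self, conv: UnitConventions) -> float:
        return mass_to_molar_conc(self.threshold_mg_l, conv.ifx_molar_mass)


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully resolved simulation scenario."""

    disease_preset: str            # "CD", "UC" or "custom"
    params: ModelParams
    init: ModelState
    conventions: UnitConventions
    schedule: DoseSchedule
    system: str = "full"
    adaptive: AdaptiveSettings | None = None
    output_dir: str = "."


def _merge_params(base: ModelParams, overrides: dict, where: str) -> ModelParams:
    if not isinstance(overrides, dict):
        raise ValueError(f"{where}: expected a mapping of parameter overrides")
    names = {f.name for f in dataclasses.fields(ModelParams) if f.name != "clearance_window"}
    unknown = set(overrides) - names
    if unknown:
        raise ValueError(f"{where}: unknown parameter fields {sorted(unknown)}")
    for key, value in overrides.items():
        if not isinstance(value, (int, float)):
            raise ValueError(f"{where}.{key}: expected a number, got {value!r}")
    return dataclasses.replace(base, **{k: float(v) for k, v in overrides.items()})


def _merge_init(base: ModelState, overrides: dict, where: str) -> ModelState:
    if not isinstance(overrides, dict):
        raise ValueError(f"{where}: expected a mapping of state overrides")
    names = {"tnf", "r", "ab", "cx"}
    unknown = set(overrides) - names
    if unknown:
        raise ValueError(f"{where}: unknown state fields {sorted(unknown)}")
    for key, value in overrides.items():
        if not isinstance(value, (int, float)):
            raise ValueError(f"{where}.{key}: expected a number, got {value!r}")
    kw = {"tnf": base.tnf, "r": base.r, "ab": base.ab, "cx": base.cx}
    kw.update({k: float(v) for k, v in overrides.items()})
    return ModelState(**kw)


def _merge_conventions(overrides: dict, where: str) -> UnitConventions:
    if not isinstance(overrides, dict):
        raise ValueError(f"{where}: expected a mapping")
    names = {f.name for f in dataclasses.fields(UnitConventions)}
    unknown = set(overrides) - names
    if unknown:
        raise ValueError(f"{where}: unknown convention fields {sorted(unknown)}")
    for key, value in overrides.items():
        if not isinstance(value, (int, float)):
            raise ValueError(f"{where}.{key}: expected a number, got {value!r}")
    return UnitConventions(**{k: float(v) for k, v in overrides.items()})


def config_from_dict(doc: dict) -> ScenarioConfig:
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    preset = doc.get("preset", "custom")
    if preset not in set(PRESETS) | {"custom"}:
        raise ValueError(f"preset: unknown preset {preset!r}; choose CD, UC or custom")

    params = ModelParams()
    if preset == "custom":
        if "init" not in doc:
            raise ValueError("init: required for preset 'custom'")
        init = ModelState(tnf=1e-11, r=0.0)
    else:
        init = PRESETS[preset]
    if "params" in doc:
        params = _merge_params(params, doc["params"], "params")
    if "init" in doc:
        init = _merge_init(init, doc["init"], "init")

    conv = _merge_conventions(doc.get("conventions", {}), "conventions")

    if "schedule" in doc:
        sched_doc = doc["schedule"]
        if isinstance(sched_doc, dict) and "weeks" in sched_doc:
            schedule = DoseSchedule.at_weeks(
                [float(w) for w in sched_doc["weeks"]],
                dose_mg=float(sched_doc.get("dose_mg", 350.0)),
                duration_hours=float(sched_doc.get("duration_hours", 2.0)),
                horizon_weeks=(
                    float(sched_doc["horizon_weeks"]) if "horizon_weeks" in sched_doc else None
                ),
            )
        else:
            schedule = schedule_from_dicts(sched_doc)
    else:
        schedule = DoseSchedule.empty(horizon_weeks=12.0)

    system = doc.get("system", "full")
    if system not in SYSTEMS:
        raise ValueError(f"system: unknown system {system!r}; choose from {SYSTEMS}")

    adaptive = None
    if "adaptive" in doc:
        a = doc["adaptive"]
        if not isinstance(a, dict):
            raise ValueError("adaptive: expected a mapping")
        hill_doc = a.pop("hill", None) if isinstance(a, dict) else None
        a = dict(a)
        names = {"clearance0", "dose_mg", "n_doses", "interval_weeks", "threshold_mg_l"}
        unknown = set(a) - names
        if unknown:
            raise ValueError(f"adaptive: unknown fields {sorted(unknown)}")
        hill = HillParams(**hill_doc) if hill_doc else HillParams()
        adaptive = AdaptiveSettings(
            clearance0=float(a.get("clearance0", 3.5e-6)),
            dose_mg=float(a.get("dose_mg", 500.0)),
            n_doses=int(a.get("n_doses", 13)),
            interval_weeks=float(a.get("interval_weeks", 4.0)),
            threshold_mg_l=float(a.get("threshold_mg_l", 3.0)),
            hill=hill,
        )

    return ScenarioConfig(
        disease_preset=preset,
        params=params,
        init=init,
        conventions=conv,
        schedule=schedule,
        system=system,
        adaptive=adaptive,
        output_dir=str(doc.get("output_dir", ".")),
    )


def config_to_dict(cfg: ScenarioConfig) -> dict:
    doc: dict = {"preset": cfg.disease_preset, "system": cfg.system}
    doc["params"] = {
        f.name: getattr(cfg.params, f.name)
        for f in dataclasses.fields(ModelParams)
        if f.name != "clearance_window"
    }
    doc["init"] = {"tnf": cfg.init.tnf, "r": cfg.init.r, "ab": cfg.init.ab, "cx": cfg.init.cx}
    doc["conventions"] = dataclasses.asdict(cfg.conventions)
    doc["schedule"] = schedule_to_dicts(cfg.schedule)
    if cfg.adaptive is not None:
        doc["adaptive"] = {
            "clearance0": cfg.adaptive.clearance0,
            "dose_mg": cfg.adaptive.dose_mg,
            "n_doses": cfg.adaptive.n_doses,
            "interval_weeks": cfg.adaptive.interval_weeks,
            "threshold_mg_l": cfg.adaptive.threshold_mg_l,
            "hill": dataclasses.asdict(cfg.adaptive.hill),
        }
    doc["output_dir"] = cfg.output_dir
    return doc


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario config from YAML or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    return config_from_dict(doc)


def save_config(cfg: ScenarioConfig, path) -> None:
    path = Path(path)
    doc = config_to_dict(cfg)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def generate_fixtures(out_dir, seed: int = 20260923) -> list[Path]:
    """Write the standard scenario fixtures used in examples and tests.

    Produces CD/UC preset configs, the induction (weeks 0/2/6/10), standard
    3-dose (weeks 0/4/8) and one-year adaptive (13 × 4-weekly 500 mg)
    schedules, plus noiseless and seeded-noise inverted-Hill datasets.
    Deterministic: rerunning with the same seed reproduces every file
    byte-for-byte.
    """
    from .adaptive import hill_clearance

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for preset, sched in (("CD", [0.0, 4.0, 8.0]), ("UC", [0.0, 4.0, 8.0])):
        cfg = config_from_dict(
            {"preset": preset, "schedule": {"weeks": sched, "dose_mg": 350.0, "horizon_weeks": 12.0}}
        )
        p = out / f"{preset.lower()}_standard.yaml"
        save_config(cfg, p)
        written.append(p)

    induction = config_from_dict(
        {"preset": "CD", "schedule": {"weeks": [0.0, 2.0, 6.0, 10.0], "dose_mg": 350.0,
                                      "horizon_weeks": 14.0}}
    )
    p = out / "cd_induction.yaml"
    save_config(induction, p)
    written.append(p)

    adaptive_year = config_from_dict(
        {
            "preset": "CD",
            "schedule": {"weeks": [float(4 * k) for k in range(13)], "dose_mg": 500.0,
                         "horizon_weeks": 52.0},
            "adaptive": {"clearance0": 3.5e-6, "dose_mg": 500.0, "n_doses": 13},
        }
    )
    p = out / "cd_adaptive_year.yaml"
    save_config(adaptive_year, p)
    written.append(p)

    # noiseless inverted-Hill dataset: exact curve on a log-spaced trough grid
    hp = HillParams()
    troughs = np.logspace(-11, -7, 30)
    clean = hill_clearance(troughs, hp)
    p = out / "hill_noiseless.csv"
    _write_hill_csv(p, troughs, clean, header=f"# exact inverted Hill, v={hp.v_max:g}, k={hp.k_half:g}, n={hp.n:g}")
    written.append(p)

    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + 0.01 * rng.standard_normal(len(clean)))
    p = out / "hill_noisy.csv"
    _write_hill_csv(p, troughs, noisy, header=f"# 1% multiplicative noise, seed={seed}")
    written.append(p)

    return written


def _write_hill_csv(path: Path, troughs, clearances, header: str) -> None:
    lines = [header, "a_min_M,clearance_per_s"]
    lines += [f"{a:.12e},{d:.12e}" for a, d in zip(troughs, clearances)]
    path.write_text("\n".join(lines) + "\n")
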