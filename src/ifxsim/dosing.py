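"""Clinical dose schedules and their conversion to molar infusion rates.

Infliximab is given as timed constant-rate intravenous infusions specified in
mg over a duration (2 h clinically).  This module turns a schedule of such
events into the piecewise-constant molar input rate ω_a(t) the model consumes,
and converts between molar and mg/L concentrations for both drug and TNF-α.

The molar masses (infliximab 144190 g/mol, TNF-α 17 kg/mol) and the 1 L
reference distribution volume are conventions, chosen to reproduce the
standard correspondences 350 mg / 2 h → 3.3713e-10 M/s and
2.6e-13 M TNF-α → 4.42e-6 mg/L; all are user-overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "SECONDS_PER_HOUR",
    "SECONDS_PER_WEEK",
    "THERAPEUTIC_TROUGH_MG_L",
    "UnitConventions",
    "InfusionEvent",
    "DoseSchedule",
    "dose_to_input_rate",
    "molar_to_mass_conc",
    "mass_to_molar_conc",
    "weight_based_dose_mg",
    "therapeutic_threshold_molar",
    "build_infusion_profile",
    "schedule_to_dicts",
    "schedule_from_dicts",
    "save_schedule",
    "load_schedule",
]

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_WEEK = 604800.0

#: Lower edge of the infliximab therapeutic trough range, mg/L.
THERAPEUTIC_TROUGH_MG_L = 3.0


@dataclass(frozen=True)
class UnitConventions:
    """Molar masses and reference volume for mass↔molar conversions."""

    ifx_molar_mass: float = 144190.0  # g/mol, infliximab (IgG1)
    tnf_molar_mass: float = 17000.0   # g/mol, soluble TNF-α monomer
    reference_volume: float = 1.0     # L, distribution volume convention

    def __post_init__(self) -> None:
        for name in ("ifx_molar_mass", "tnf_molar_mass", "reference_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_CONVENTIONS = UnitConventions()


@dataclass(frozen=True)
class InfusionEvent:
    """One constant-rate infusion: ``dose`` mg delivered over ``duration`` s."""

    start: float     # s
    duration: float  # s
    dose: float      # mg

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be positive, got {self.duration:g}")
        if self.dose < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose:g}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered, non-overlapping infusion events plus the simulation horizon."""

    events: tuple[InfusionEvent, ...]
    horizon: float  # s

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.start))
        object.__setattr__(self, "events", events)
        for prev, nxt in zip(events, events[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping infusions: event at {prev.start:g}s runs to "
                    f"{prev.end:g}s but next starts at {nxt.start:g}s"
                )
        if events and events[-1].end > self.horizon:
            raise ValueError(
                f"last infusion ends at {events[-1].end:g}s, beyond the "
                f"horizon {self.horizon:g}s"
            )
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @classmethod
    def at_weeks(
        cls,
        weeks: Sequence[float],
        dose_mg: float,
        duration_hours: float = 2.0,
        horizon_weeks: float | None = None,
    ) -> "DoseSchedule":
        """Schedule identical ``dose_mg`` infusions starting at the given weeks."""
        events = tuple(
            InfusionEvent(
                start=w * SECONDS_PER_WEEK,
                duration=duration_hours * SECONDS_PER_HOUR,
                dose=dose_mg,
            )
            for w in weeks
        )
        if horizon_weeks is None:
            horizon_weeks = (max(weeks) + 4.0) if len(weeks) else 4.0
        return cls(events=events, horizon=horizon_weeks * SECONDS_PER_WEEK)

    @classmethod
    def empty(cls, horizon_weeks: float) -> "DoseSchedule":
        return cls(events=(), horizon=horizon_weeks * SECONDS_PER_WEEK)

    def dose_starts(self) -> np.ndarray:
        return np.array([e.start for e in self.events])


def dose_to_input_rate(
    dose_mg: float, duration_s: float, conv: UnitConventions = DEFAULT_CONVENTIONS
) -> float:
    """Molar input rate (M/s) of a constant infusion of ``dose_mg`` over ``duration_s``."""
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s:g}")
    if dose_mg < 0:
        raise ValueError(f"dose must be non-negative, got {dose_mg:g}")
    return dose_mg * 1e-3 / (duration_s * conv.ifx_molar_mass * conv.reference_volume)


def molar_to_mass_conc(conc_molar: float, molar_mass: float):
    """Convert a molar concentration to mg/L (``conc * M_w * 1000``)."""
    return conc_molar * molar_mass * 1e3


def mass_to_molar_conc(conc_mg_l: float, molar_mass: float):
    """Convert mg/L to molar concentration."""
    return conc_mg_l / (molar_mass * 1e3)


def weight_based_dose_mg(mg_per_kg: float, weight_kg: float = 70.0) -> float:
    """Convenience conversion for weight-based dosing (e.g. 5 mg/kg × 70 kg)."""
    return mg_per_kg * weight_kg


def therapeutic_threshold_molar(conv: UnitConventions = DEFAULT_CONVENTIONS) -> float:
    """The 3 mg/L infliximab trough threshold expressed in molar units."""
    return mass_to_molar_conc(THERAPEUTIC_TROUGH_MG_L, conv.ifx_molar_mass)


def build_infusion_profile(
    schedule: DoseSchedule, conv: UnitConventions = DEFAULT_CONVENTIONS
) -> tuple[Callable[[float], float], np.ndarray]:
    """Piecewise-constant drug input rate ω_a(t) and its breakpoints.

    Returns a callable mapping time (s) to the molar input rate (M/s) — the
    event's constant rate while an infusion is running, zero otherwise — and
    the sorted array of every infusion start and end time.  Integrating the
    rate over the horizon recovers the total scheduled dose exactly.
    """
    starts = np.array([e.start for e in schedule.events])
    ends = np.array([e.end for e in schedule.events])
    rates = np.array([dose_to_input_rate(e.dose, e.duration, conv) for e in schedule.events])
    breakpoints = np.unique(np.concatenate([starts, ends])) if len(starts) else np.array([])

    def rate(t: float) -> float:
        i = np.searchsorted(starts, t, side="right") - 1
        if i >= 0 and t < ends[i]:
            return float(rates[i])
        return 0.0

    return rate, breakpoints


# ---------------------------------------------------------------------------
# schedule serialisation: list of {start_weeks, duration_hours, dose_mg}

def schedule_to_dicts(schedule: DoseSchedule) -> dict:
    return {
        "horizon_weeks": schedule.horizon / SECONDS_PER_WEEK,
        "events": [
            {
                "start_weeks": e.start / SECONDS_PER_WEEK,
                "duration_hours": e.duration / SECONDS_PER_HOUR,
                "dose_mg": e.dose,
            }
            for e in schedule.events
        ],
    }


def schedule_from_dicts(data: dict) -> DoseSchedule:
    if not isinstance(data, dict) or "events" not in data:
        raise ValueError("schedule document must be a mapping with an 'events' list")
    events = []
    for i, ev in enumerate(data["events"]):
        missing = {"start_weeks", "duration_hours", "dose_mg"} - set(ev)
        if missing:
            raise ValueError(f"schedule event {i} missing fields: {sorted(missing)}")
        events.append(
            InfusionEvent(
                start=float(ev["start_weeks"]) * SECONDS_PER_WEEK,
                duration=float(ev["duration_hours"]) * SECONDS_PER_HOUR,
                dose=float(ev["dose_mg"]),
            )
        )
    horizon_weeks = data.get("horizon_weeks")
    if horizon_weeks is None:
        horizon = max(e.end for e in events) + 4 * SECONDS_PER_WEEK if events else 4 * SECONDS_PER_WEEK
    else:
        horizon = float(horizon_weeks) * SECONDS_PER_WEEK
    return DoseSchedule(events=tuple(events), horizon=horizon)


def save_schedule(schedule: DoseSchedule, path) -> None:
    path = Path(path)
    doc = schedule_to_dicts(schedule)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_schedule(path) -> DoseSchedule:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    return schedule_from_dicts(doc)
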