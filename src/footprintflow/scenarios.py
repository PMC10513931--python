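"""Dietary-substitution and food-waste scenario arithmetic.

Two counterfactuals on a baseline per-capita food footprint (FF):

* iso-caloric substitution: a fraction of one food's intake is replaced by
  another food providing the same kcal; the FF change is the replaced
  energy times the difference in per-1,000-kcal footprint intensities;
* waste elimination at the diet's current average intensity: removing a
  mass of wasted food reduces the FF proportionally to its share of total
  food supply mass.

Scenario functions never mutate baselines; they return new values with a
provenance note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a dietary intervention.

    For ``kind="substitution"``: replace ``fraction_replaced`` of the
    ``intake_kg`` of ``item_from`` (energy density ``kcal_density_from``,
    kcal/kg) by iso-caloric intake of ``item_to``; intensities are in gha
    per 1,000 kcal.
    """

    kind: Literal["substitution", "waste_elimination"]
    item_from: str = ""
    item_to: str = ""
    fraction_replaced: float = 0.0
    intake_kg: float = 0.0
    kcal_density_from: float = 1.0
    kcal_density_to: float = 1.0
    intensity_from: float = 0.0
    intensity_to: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "waste_elimination"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0.0 <= self.fraction_replaced <= 1.0:
            raise ValueError(f"fraction_replaced must be in [0, 1], got {self.fraction_replaced}")
        if self.kind == "substitution":
            if self.kcal_density_from <= 0 or self.kcal_density_to <= 0:
                raise ValueError("kcal densities must be > 0 for substitution")
            if self.intake_kg < 0:
                raise ValueError("intake_kg must be >= 0")
        if self.intensity_from < 0 or self.intensity_to < 0:
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome of a scenario: the new FF, the relative reduction, and a note."""

    ff_before: float
    ff_after: float
    reduction: float  # fraction of the baseline FF removed
    note: str


@dataclass(frozen=True)
class WasteRecord:
    """Per-capita food waste of one region by stream, with its population."""

    region: str
    household_kg: float
    food_service_kg: float
    retail_kg: float
    population: float

    def __post_init__(self) -> None:
        for name in ("household_kg", "food_service_kg", "retail_kg", "population"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.region}: {name} must be >= 0")

    @property
    def total_kg(self) -> float:
        return self.household_kg + self.food_service_kg + self.retail_kg


def substitute_isocaloric(ff: float, spec: ScenarioSpec) -> ScenarioResult:
    """Replace part of a food's intake with iso-caloric intake of another.

    ``replaced_kcal = fraction * intake_kg * kcal_density_from``;
    ``dFF = replaced_kcal / 1000 * (intensity_from - intensity_to)``.
    The new FF is floored at zero (with a warning) should the substitution
    exceed the whole baseline.
    """
    if spec.kind != "substitution":
        raise ValueError(f"spec kind must be 'substitution', got {spec.kind!r}")
    if ff <= 0:
        raise ValueError(f"baseline FF must be > 0, got {ff}")
    replaced_kcal = spec.fraction_replaced * spec.intake_kg * spec.kcal_density_from
    delta = replaced_kcal / 1000.0 * (spec.intensity_from - spec.intensity_to)
    new_ff = ff - delta
    if new_ff < 0:
        warnings.warn(
            f"substitution removes more footprint ({delta:.6g}) than the baseline "
            f"({ff:.6g}); flooring at 0",
            stacklevel=2,
        )
        new_ff = 0.0
    return ScenarioResult(
        ff_before=ff,
        ff_after=new_ff,
        reduction=(ff - new_ff) / ff,
        note=(
            f"substitute {spec.fraction_replaced:.0%} of {spec.item_from or 'item'} "
            f"({spec.intake_kg} kg/yr) with iso-caloric {spec.item_to or 'alternative'}"
        ),
    )


def eliminate_waste(ff: float, waste_kg: float, supply_kg: float) -> ScenarioResult:
    """FF after eliminating food waste, at the diet's current average intensity.

    The reduction equals the waste's share of the total food supply mass:
    ``new_ff = ff * (1 - waste_kg / supply_kg)``.
    """
    if supply_kg <= 0:
        raise ValueError(f"supply_kg must be > 0, got {supply_kg}")
    if waste_kg < 0:
        raise ValueError(f"waste_kg must be >= 0, got {waste_kg}")
    if waste_kg > supply_kg:
        raise ValueError(f"waste ({waste_kg} kg) cannot exceed supply ({supply_kg} kg)")
    reduction = waste_kg / supply_kg
    return ScenarioResult(
        ff_before=ff,
        ff_after=ff * (1.0 - reduction),
        reduction=reduction,
        note=f"eliminate {waste_kg} kg/yr of waste out of {supply_kg} kg/yr supplied",
    )


def weighted_waste_average(records: Iterable[WasteRecord]) -> dict[str, float]:
    """Population-weighted waste averages (kg/person/yr) per stream and total."""
    records = list(records)
    if not records:
        raise ValueError("no waste records to average")
    pop = sum(r.population for r in records)
    if pop <= 0:
        raise ValueError("total population must be > 0")
    out = {
        "household_kg": sum(r.household_kg * r.population for r in records) / pop,
        "food_service_kg": sum(r.food_service_kg * r.population for r in records) / pop,
        "retail_kg": sum(r.retail_kg * r.population for r in records) / pop,
    }
    out["total_kg"] = out["household_kg"] + out["food_service_kg"] + out["retail_kg"]
    return out


def trend_change(v_start: float, v_end: float) -> float:
    """Percent change from start to end: ``100 * (end - start) / start``."""
    if v_start == 0:
        raise ValueError("trend change undefined for a zero start value")
    return 100.0 * (v_end - v_start) / v_start
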