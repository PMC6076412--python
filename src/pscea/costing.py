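"""Dosing and cost building blocks: BSA dosing, drug/ward/test schedules, AEs.

Chemotherapy doses are body-surface-area (BSA) based; BSA uses the linear
Chinese-population formula ``0.0061·height(cm) + 0.0128·weight(kg) − 0.1529``
(m²).  Drug costs default to proportional (per-mg) pricing, which is how the
published monthly costs were constructed; a whole-pack (ceiling) mode is
available for wastage scenarios.  Adverse-event (AE) treatment costs are
charged once per patient in expectation (incidence × cost, with listed AE
pairs treated simultaneously billed once at the higher incidence) and then
spread across cycles in proportion to the number of patients still alive.

All treatment-related costs — drugs, general ward, tests, AEs — accrue only
while a patient is progression-free, because treatment stops at progression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .partition import StateOccupancyTrace

__all__ = [
    "Patient",
    "DrugComponent",
    "Regimen",
    "NonDrugSchedule",
    "AEItem",
    "DoseLine",
    "bsa",
    "per_cycle_doses",
    "monthly_drug_cost",
    "monthly_nondrug_cost",
    "ae_expected_cost",
    "ae_monthly_allocation",
]

#: Days per model month (one Markov cycle).
DAYS_PER_MONTH = 30.0


@dataclass(frozen=True)
class Patient:
    """Average patient anthropometrics used for BSA dosing."""

    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise InvalidParameterError("height and weight must be positive")


@dataclass(frozen=True)
class DrugComponent:
    """One drug of a regimen.

    ``dosing`` is ``"per_m2"`` (dose_per_admin in mg/m², given
    ``admins_per_cycle`` times per treatment cycle) or ``"fixed_daily"``
    (dose_per_admin in mg/day, continuous).  ``unit_pack`` is the pack size
    in mg and ``pack_cost`` its price in US$.
    """

    drug: str
    dose_per_admin: float
    admins_per_cycle: float
    unit_pack: float
    pack_cost: float
    dosing: str = "per_m2"

    def __post_init__(self) -> None:
        if self.unit_pack <= 0 or self.pack_cost < 0:
            raise InvalidParameterError(f"{self.drug}: pack size must be > 0 and cost >= 0")
        if self.dosing not in ("per_m2", "fixed_daily"):
            raise ConfigurationError(f"{self.drug}: unknown dosing mode {self.dosing!r}")


@dataclass(frozen=True)
class Regimen:
    """A named drug regimen and its treatment-cycle frequency."""

    name: str
    components: tuple
    cycles_per_month: float = 1.0
    administered_inpatient: bool = False

    def __post_init__(self) -> None:
        if self.cycles_per_month <= 0:
            raise InvalidParameterError("cycles_per_month must be positive")


@dataclass(frozen=True)
class NonDrugSchedule:
    """Ward and monitoring-test schedule while on treatment (in PFS)."""

    ward_cost_per_day: float = 0.0
    ward_days_per_month: float = 0.0
    test_set_cost: float = 0.0
    tests_per_month: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ward_cost_per_day", "ward_days_per_month", "test_set_cost", "tests_per_month"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


@dataclass(frozen=True)
class AEItem:
    """One adverse event: per-event treatment cost and trial-period incidence.

    AEs sharing a ``simultaneity_group`` are treated in the same encounter;
    their combined cost is charged once at the highest incidence in the group.
    """

    name: str
    cost_per_event: float
    incidence: float
    simultaneity_group: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise InvalidParameterError(f"{self.name}: incidence must be in [0, 1]")
        if self.cost_per_event < 0:
            raise InvalidParameterError(f"{self.name}: cost must be non-negative")


@dataclass(frozen=True)
class DoseLine:
    """Per-cycle dose of one drug: rounded mg for reporting, exact mg internally."""

    drug: str
    mg: int
    mg_exact: float


def bsa(patient: Patient) -> float:
    """Body surface area in m²: ``0.0061·h + 0.0128·w − 0.1529``."""
    value = 0.0061 * patient.height_cm + 0.0128 * patient.weight_kg - 0.1529
    if value <= 0:
        raise InvalidParameterError(
            f"BSA formula gives non-positive area ({value:.4f} m²) for "
            f"height {patient.height_cm} cm / weight {patient.weight_kg} kg"
        )
    return value


def per_cycle_doses(regimen: Regimen, patient: Patient) -> list[DoseLine]:
    """Per-treatment-cycle drug requirements in mg for BSA-dosed components.

    Fixed-daily components (oral drugs) have no per-cycle dose and are
    skipped.  The rounded value is for reporting; pricing uses ``mg_exact``.
    """
    area = bsa(patient)
    lines = []
    for comp in regimen.components:
        if comp.dosing != "per_m2":
            continue
        exact = comp.dose_per_admin * area * comp.admins_per_cycle
        lines.append(DoseLine(comp.drug, int(round(exact)), exact))
    return lines


def monthly_drug_cost(
    regimen: Regimen,
    patient: Patient,
    pricing_mode: str = "proportional",
    dose_overrides: dict | None = None,
    price_multiplier: float = 1.0,
) -> float:
    """Drug cost in US$ per month spent progression-free.

    ``proportional`` (default) prices drugs per mg, reproducing published
    monthly costs; ``whole_pack`` rounds up to whole packs per treatment
    cycle (per month for fixed-daily drugs).  ``dose_overrides`` maps drug
    name → per-cycle mg, replacing the BSA-computed dose (used by the
    sensitivity analyses); ``price_multiplier`` scales all pack prices.
    """
    if pricing_mode not in ("proportional", "whole_pack"):
        raise ConfigurationError(f"unknown pricing_mode {pricing_mode!r}")
    dose_overrides = dose_overrides or {}
    total = 0.0
    for comp in regimen.components:
        price = comp.pack_cost * price_multiplier
        if comp.dosing == "fixed_daily":
            mg_per_month = comp.dose_per_admin * DAYS_PER_MONTH
            if pricing_mode == "proportional":
                total += price * mg_per_month / comp.unit_pack
            else:
                total += price * math.ceil(mg_per_month / comp.unit_pack)
        else:
            mg_per_cycle = dose_overrides.get(
                comp.drug, comp.dose_per_admin * bsa(patient) * comp.admins_per_cycle
            )
            if pricing_mode == "proportional":
                total += price * (mg_per_cycle / comp.unit_pack) * regimen.cycles_per_month
            else:
                total += price * math.ceil(mg_per_cycle / comp.unit_pack) * regimen.cycles_per_month
    return total


def monthly_nondrug_cost(schedule: NonDrugSchedule) -> tuple[float, float]:
    """(ward US$/month, tests US$/month) while progression-free."""
    return (
        schedule.ward_cost_per_day * schedule.ward_days_per_month,
        schedule.test_set_cost * schedule.tests_per_month,
    )


def ae_expected_cost(ae_profile: list[AEItem]) -> float:
    """Expected AE treatment cost per patient (undiscounted lump), US$.

    Ungrouped items contribute ``cost × incidence``.  Items in a
    simultaneity group contribute their combined cost once, at the maximum
    incidence within the group.
    """
    total = 0.0
    groups: dict[str, list[AEItem]] = {}
    for item in ae_profile:
        if item.simultaneity_group is None:
            total += item.cost_per_event * item.incidence
        else:
            groups.setdefault(item.simultaneity_group, []).append(item)
    for items in groups.values():
        total += sum(i.cost_per_event for i in items) * max(i.incidence for i in items)
    return total


def ae_monthly_allocation(total_ae_cost: float, occupancy: StateOccupancyTrace) -> np.ndarray:
    """Spread a per-patient AE lump across cycles, proportional to survivors.

    Returns a stream indexed t = 0..T with index 0 = 0 and
    ``alloc(t) = total · alive(t) / Σ_{t>=1} alive(t)``; the allocation
    conserves the total exactly.  If the whole cohort is dead from cycle 1
    on, the entire cost is charged at t = 1.
    """
    if total_ae_cost < 0:
        raise InvalidParameterError("total_ae_cost must be non-negative")
    alive = occupancy.alive
    alloc = np.zeros_like(alive)
    weights = alive[1:]
    wsum = weights.sum()
    if wsum > 0:
        alloc[1:] = total_ae_cost * weights / wsum
    else:
        alloc[1] = total_ae_cost
    return alloc
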