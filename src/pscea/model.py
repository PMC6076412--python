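"""Assembly of the two-arm cohort model and its parameterized evaluation.

A :class:`TwoArmModel` bundles, for each arm, the survivor curves, the drug
regimen, the non-drug schedule and the adverse-event profile, together with
the shared patient, utilities and discounting.  ``evaluate`` runs both arms
through the partitioned-survival trace and the cohort engine and returns
per-arm economics plus the incremental comparison.

Every quantity the sensitivity analyses perturb is addressed by an override
key ``(target, qualifier)`` — e.g. ``("survival_multiplier", "folfox4")`` or
``("utility_pfs", None)`` — so that one-way and probabilistic analyses can
re-evaluate the model without mutating it.  A drawn arm-level monthly drug
cost acts as a price-level multiplier (draw / base monthly cost) so that it
composes with independently drawn per-cycle doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .cea import ICERResult, incremental
from .costing import (
    AEItem,
    NonDrugSchedule,
    Patient,
    Regimen,
    ae_expected_cost,
    ae_monthly_allocation,
    monthly_drug_cost,
    monthly_nondrug_cost,
)
from .curves import ArmCurves
from .engine import DiscountConfig, EconResult, UtilitySet, run_cohort
from .errors import ConfigurationError
from .partition import apply_survival_multiplier, occupancy_from_curves

__all__ = ["ArmSpec", "TwoArmModel", "ModelOutcome", "OVERRIDE_TARGETS"]

#: Recognized override targets; qualifier is an arm name, a drug name or None.
OVERRIDE_TARGETS = frozenset(
    {
        "survival_multiplier",
        "monthly_drug_cost",
        "dose",
        "utility_pfs",
        "utility_pd",
        "ward_monthly_cost",
        "ae_cost_multiplier",
        "test_set_cost",
        "hospitalized_fraction",
        "discount_rate",
    }
)


@dataclass(frozen=True)
class ArmSpec:
    """Everything specific to one treatment arm."""

    name: str
    curves: ArmCurves
    regimen: Regimen
    schedule: NonDrugSchedule
    ae_profile: tuple


@dataclass(frozen=True)
class ModelOutcome:
    """Base-case (or scenario) result: both arms plus the increment."""

    intervention: EconResult
    comparator: EconResult
    icer: ICERResult


def _check_overrides(overrides: dict) -> None:
    for key in overrides:
        target = key[0] if isinstance(key, tuple) else key
        if target not in OVERRIDE_TARGETS:
            raise ConfigurationError(f"unknown sensitivity target {target!r}")


@dataclass(frozen=True)
class TwoArmModel:
    """A configured two-arm cost-effectiveness model."""

    intervention: ArmSpec
    comparator: ArmSpec
    patient: Patient
    utilities: UtilitySet = UtilitySet()
    discount: DiscountConfig = DiscountConfig()
    pricing_mode: str = "proportional"
    costs_only_half_cycle: bool = False

    @property
    def arms(self) -> tuple[ArmSpec, ArmSpec]:
        return (self.intervention, self.comparator)

    def evaluate_arm(self, arm: ArmSpec, overrides: dict | None = None) -> EconResult:
        """Run one arm through the trace and engine, applying overrides."""
        ov = overrides or {}
        _check_overrides(ov)

        curves = arm.curves
        factor = ov.get(("survival_multiplier", arm.name), 1.0)
        if factor != 1.0:
            curves = apply_survival_multiplier(curves, factor)
        occ = occupancy_from_curves(curves.with_terminal_death())

        dose_overrides = {
            key[1]: value for key, value in ov.items() if key[0] == "dose"
        }
        price_multiplier = 1.0
        drawn_monthly = ov.get(("monthly_drug_cost", arm.name))
        if drawn_monthly is not None:
            base_monthly = monthly_drug_cost(arm.regimen, self.patient, self.pricing_mode)
            price_multiplier = drawn_monthly / base_monthly
        drug = monthly_drug_cost(
            arm.regimen,
            self.patient,
            self.pricing_mode,
            dose_overrides=dose_overrides,
            price_multiplier=price_multiplier,
        )

        ward, tests = monthly_nondrug_cost(arm.schedule)
        ward = ov.get(("ward_monthly_cost", arm.name), ward)
        ward *= ov.get(("hospitalized_fraction", arm.name), 1.0)
        test_set = ov.get(("test_set_cost", None))
        if test_set is not None:
            tests = test_set * arm.schedule.tests_per_month

        ae_total = ae_expected_cost(list(arm.ae_profile))
        ae_total *= ov.get(("ae_cost_multiplier", None), 1.0)
        ae_stream = ae_monthly_allocation(ae_total, occ)

        utilities = self.utilities
        u_pfs = ov.get(("utility_pfs", None))
        u_pd = ov.get(("utility_pd", None))
        if u_pfs is not None or u_pd is not None:
            utilities = UtilitySet(
                u_pfs if u_pfs is not None else utilities.u_pfs,
                u_pd if u_pd is not None else utilities.u_pd,
                utilities.u_dead,
            )
        discount = self.discount
        rate = ov.get(("discount_rate", None))
        if rate is not None:
            discount = replace(discount, annual_rate=rate)

        return run_cohort(
            occ,
            {"drug": drug, "ward": ward, "tests": tests},
            ae_stream,
            utilities,
            discount,
            arm_name=arm.name,
            costs_only_half_cycle=self.costs_only_half_cycle,
        )

    def evaluate(self, overrides: dict | None = None) -> ModelOutcome:
        """Evaluate both arms under one override vector and compare them."""
        res1 = self.evaluate_arm(self.intervention, overrides)
        res0 = self.evaluate_arm(self.comparator, overrides)
        return ModelOutcome(res1, res0, incremental(res1, res0))
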