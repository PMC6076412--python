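"""Loading and validation of the packaged (or a user) parameter file.

The packaged default configuration encodes the published cost table for the
China advanced-HCC comparison — FOLFOX4 regimen pricing and schedule,
sorafenib pricing, adverse-event costs and incidences, utilities,
discounting, copayment maps and the full sensitivity table.  Users can pass
their own YAML file with the same layout.

Two documented conventions are switchable here:

``ward_per``
    ``"month"`` (default) bills the ward days once per model month, which is
    what the published per-patient ward totals imply; ``"cycle"`` bills them
    once per treatment cycle (the literal table footnote), i.e. 2.14× as
    often for FOLFOX4.
``cycles``
    ``"printed"`` (default) uses the printed 2.14 treatment cycles per
    month; ``"exact_30_14"`` uses 30/14 = 2.142857…
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .cea import CopayMap, WTPThresholds
from .costing import AEItem, DrugComponent, NonDrugSchedule, Patient, Regimen
from .curves import make_arm_curves
from .engine import DiscountConfig, UtilitySet
from .errors import ConfigurationError
from .model import ArmSpec, TwoArmModel
from .sensitivity import SensitivitySpec

__all__ = [
    "load_params",
    "build_model",
    "sensitivity_specs",
    "copay_map",
    "thresholds",
    "default_model",
    "CYCLES_PER_MONTH_PRINTED",
    "CYCLES_PER_MONTH_EXACT",
]

#: Treatment cycles per 30-day month for a 14-day regimen, as printed.
CYCLES_PER_MONTH_PRINTED = 2.14
#: The exact ratio 30/14.
CYCLES_PER_MONTH_EXACT = 30.0 / 14.0


def load_params(path: str | Path | None = None) -> dict:
    """Load a parameter file; with no path, the packaged defaults."""
    if path is None:
        text = resources.files("pscea").joinpath("data/default_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    params = yaml.safe_load(text)
    for section in ("patient", "utilities", "discount", "arms", "intervention", "comparator"):
        if section not in params:
            raise ConfigurationError(f"parameter file missing section {section!r}")
    return params


def _build_regimen(name: str, raw: dict, cycles: str) -> Regimen:
    components = tuple(
        DrugComponent(
            drug=c["drug"],
            dose_per_admin=c["dose_per_admin"],
            admins_per_cycle=c["admins_per_cycle"],
            unit_pack=c["unit_pack"],
            pack_cost=c["pack_cost"],
            dosing=c.get("dosing", "per_m2"),
        )
        for c in raw["components"]
    )
    cpm = raw["cycles_per_month"]
    if cycles == "exact_30_14" and abs(cpm - CYCLES_PER_MONTH_PRINTED) < 1e-9:
        cpm = CYCLES_PER_MONTH_EXACT
    return Regimen(
        name=name,
        components=components,
        cycles_per_month=cpm,
        administered_inpatient=raw.get("administered_inpatient", False),
    )


def _build_arm(
    name: str,
    raw: dict,
    horizon: int,
    pfs_median_override: float | None,
    ward_per: str,
    cycles: str,
) -> ArmSpec:
    surv = raw["survival"]
    pfs_median = pfs_median_override if pfs_median_override is not None else surv.get("pfs_median")
    if pfs_median is None:
        raise ConfigurationError(
            f"arm {name!r}: pfs_median is not set and has no published default; "
            "it must be supplied explicitly (e.g. default_model(sorafenib_pfs_median=...))"
        )
    regimen = _build_regimen(name, raw["regimen"], cycles)
    sched = raw["schedule"]
    ward_days = sched["ward_days_per_month"]
    if ward_per == "cycle":
        ward_days *= regimen.cycles_per_month
    elif ward_per != "month":
        raise ConfigurationError(f"ward_per must be 'month' or 'cycle', got {ward_per!r}")
    schedule = NonDrugSchedule(
        ward_cost_per_day=sched["ward_cost_per_day"],
        ward_days_per_month=ward_days,
        test_set_cost=sched["test_set_cost"],
        tests_per_month=sched["tests_per_month"],
    )
    ae_profile = tuple(
        AEItem(
            name=a["name"],
            cost_per_event=a["cost"],
            incidence=a["incidence"],
            simultaneity_group=a.get("group"),
        )
        for a in raw["ae_profile"]
    )
    curves = make_arm_curves(surv["os_median"], pfs_median, horizon, arm_name=name)
    return ArmSpec(name, curves, regimen, schedule, ae_profile)


def build_model(
    params: dict,
    pfs_median_overrides: dict | None = None,
    horizon: int | None = None,
    ward_per: str = "month",
    cycles: str = "printed",
    pricing_mode: str = "proportional",
    costs_only_half_cycle: bool = False,
) -> TwoArmModel:
    """Assemble a :class:`~pscea.model.TwoArmModel` from a parameter dict.

    ``pfs_median_overrides`` maps arm name → PFS median in months, for arms
    whose median is not in the file (mandatory for the default sorafenib
    arm) or to substitute e.g. the Chinese-subgroup medians.
    """
    if cycles not in ("printed", "exact_30_14"):
        raise ConfigurationError(f"cycles must be 'printed' or 'exact_30_14', got {cycles!r}")
    overrides = pfs_median_overrides or {}
    horizon = horizon if horizon is not None else params.get("horizon_months", 60)
    arms = {
        name: _build_arm(name, raw, horizon, overrides.get(name), ward_per, cycles)
        for name, raw in params["arms"].items()
    }
    try:
        intervention = arms[params["intervention"]]
        comparator = arms[params["comparator"]]
    except KeyError as exc:
        raise ConfigurationError(f"intervention/comparator arm not defined: {exc}") from exc
    u = params["utilities"]
    d = params["discount"]
    return TwoArmModel(
        intervention=intervention,
        comparator=comparator,
        patient=Patient(params["patient"]["height_cm"], params["patient"]["weight_kg"]),
        utilities=UtilitySet(u["pfs"], u["pd"], u.get("dead", 0.0)),
        discount=DiscountConfig(d["annual_rate"], d.get("mode", "annual_compound_monthly")),
        pricing_mode=pricing_mode,
        costs_only_half_cycle=costs_only_half_cycle,
    )


def sensitivity_specs(params: dict) -> list[SensitivitySpec]:
    """The sensitivity table (one-way ranges + PSA distributions)."""
    specs = []
    for row in params.get("sensitivity", []):
        specs.append(
            SensitivitySpec(
                id=row["id"],
                target=row["target"],
                base=row["base"],
                low=row["low"],
                high=row["high"],
                sd=row.get("sd", 0.0),
                distribution=row.get("distribution", "none"),
                arm=row.get("arm"),
                drug=row.get("drug"),
            )
        )
    return specs


def sensitivity_specs_from_cv(
    params: dict, therapy_cv: float = 0.20, nontherapy_cv: float = 0.60
) -> list[SensitivitySpec]:
    """Alternative PSA spec: SDs as fixed fractions of the base values.

    Encodes the stated rule of thumb (20% of base for therapy-related
    parameters, 60% for non-therapy costs: ward, AEs, tests) instead of the
    printed SD column, which disagrees with it for several rows.
    """
    nontherapy = {"ward_monthly_cost", "ae_cost_multiplier", "test_set_cost"}
    out = []
    for spec in sensitivity_specs(params):
        if spec.distribution == "none":
            out.append(spec)
            continue
        cv = nontherapy_cv if spec.target in nontherapy else therapy_cv
        out.append(
            SensitivitySpec(
                id=spec.id,
                target=spec.target,
                base=spec.base,
                low=spec.low,
                high=spec.high,
                sd=cv * abs(spec.base),
                distribution=spec.distribution,
                arm=spec.arm,
                drug=spec.drug,
            )
        )
    return out


def copay_map(params: dict, which: str = "reconciled") -> CopayMap:
    """A patient-perspective copayment map from the parameter file."""
    try:
        return CopayMap(params["copay"][which])
    except KeyError as exc:
        raise ConfigurationError(f"copay map {which!r} not in parameter file") from exc


def thresholds(params: dict) -> WTPThresholds:
    t = params.get("thresholds", {})
    return WTPThresholds(
        gdp_per_capita=t.get("gdp_per_capita", 7358),
        lambda_3x=t.get("lambda_3x", 22073),
    )


def default_model(sorafenib_pfs_median: float, **kwargs) -> TwoArmModel:
    """The packaged FOLFOX4-vs-sorafenib model.

    The sorafenib PFS median was never published, so it is a required
    argument; any keyword accepted by :func:`build_model` can be passed on.
    """
    params = load_params()
    overrides = kwargs.pop("pfs_median_overrides", {}) or {}
    overrides.setdefault("sorafenib", sorafenib_pfs_median)
    return build_model(params, pfs_median_overrides=overrides, **kwargs)
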