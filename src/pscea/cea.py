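"""Two-arm comparison: increments, ICER/dominance, net benefit, perspectives.

The comparison reports the incremental cost ΔC = C1 − C0 and incremental
effect ΔE = E1 − E0 of the intervention (arm 1) over the comparator
(arm 0).  When the signs oppose, one arm *dominates* (cheaper and more
effective) and no ICER is reported; otherwise ICER = ΔC/ΔE in US$/QALY.
The incremental net health benefit INHB(λ) = ΔE − ΔC/λ (QALYs) and net
monetary benefit NMB(λ) = λ·E − C (US$) express the same preference:
NMB1 − NMB0 = λ·INHB for every willingness-to-pay λ > 0.

WHO threshold convention: an intervention is highly cost-effective below
1× GDP per capita per QALY and cost-effective below 3× GDP per capita.
For the Chinese setting modelled here, GDP per capita is US$ 7358 and the
published 3× threshold is US$ 22,073 (kept as printed rather than the
product 22,074; both are exposed as named constants).

The patient-perspective transformation multiplies each cost component by
its copayment share.  The reconciled default map uses 15% for inpatient
drug administration and ward stays, and 25% for outpatient drugs, tests
and AE treatment; a ``literal_text`` map (drugs and AE at 25%, ward and
tests at 15%) encodes the narrower published sentence, whose printed
totals it does not reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import COST_COMPONENTS, EconResult
from .errors import InvalidParameterError

__all__ = [
    "GDP_PER_CAPITA",
    "WTP_3X_GDP",
    "WTPThresholds",
    "CopayMap",
    "ICERResult",
    "incremental",
    "inhb",
    "nmb",
    "cea_summary",
    "apply_perspective",
    "reconciled_copay_map",
    "literal_text_copay_map",
]

#: GDP per capita (US$) underlying the WHO thresholds.
GDP_PER_CAPITA = 7358.0
#: Published 3×-GDP cost-effectiveness threshold (US$/QALY), as printed.
WTP_3X_GDP = 22073.0

DOMINANT = "intervention_dominates"
DOMINATED = "comparator_dominates"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class WTPThresholds:
    """Willingness-to-pay thresholds derived from GDP per capita."""

    gdp_per_capita: float = GDP_PER_CAPITA
    lambda_3x: float = WTP_3X_GDP

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0 or self.lambda_3x <= 0:
            raise InvalidParameterError("thresholds must be positive")

    @property
    def lambda_1x(self) -> float:
        return self.gdp_per_capita


@dataclass(frozen=True)
class CopayMap:
    """Patient copayment proportion per cost component, per arm.

    ``proportions`` maps arm name → {component → share in [0, 1]}.
    """

    proportions: dict

    def __post_init__(self) -> None:
        for arm, comps in self.proportions.items():
            for comp, p in comps.items():
                if comp not in COST_COMPONENTS:
                    raise InvalidParameterError(f"{arm}: unknown component {comp!r}")
                if not 0.0 <= p <= 1.0:
                    raise InvalidParameterError(f"{arm}/{comp}: copay {p} outside [0, 1]")

    def share(self, arm: str, component: str) -> float:
        return self.proportions.get(arm, {}).get(component, 1.0)


def reconciled_copay_map(intervention: str, comparator: str) -> CopayMap:
    """Default copay map: inpatient regimen drugs+ward at 15%, rest at 25%."""
    return CopayMap(
        {
            intervention: {"drug": 0.15, "ward": 0.15, "tests": 0.25, "ae": 0.25},
            comparator: {"drug": 0.25, "ward": 0.15, "tests": 0.25, "ae": 0.25},
        }
    )


def literal_text_copay_map(intervention: str, comparator: str) -> CopayMap:
    """Copay map as the published sentence reads: drugs+AE 25%, ward+tests 15%."""
    per_arm = {"drug": 0.25, "ward": 0.15, "tests": 0.15, "ae": 0.25}
    return CopayMap({intervention: dict(per_arm), comparator: dict(per_arm)})


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of intervention (1) vs comparator (0)."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str

    @property
    def dominant(self) -> bool:
        return self.label == DOMINANT


def incremental(res1: EconResult, res0: EconResult, discounted: bool = True) -> ICERResult:
    """ΔC, ΔE and ICER/dominance of ``res1`` (intervention) vs ``res0``.

    Cheaper-and-more-effective yields the ``intervention_dominates`` label,
    more-expensive-and-less-effective ``comparator_dominates``; ΔE = 0
    yields an explicit ``undefined`` label, never a division.
    """
    key = "discounted" if discounted else "undiscounted"
    c1 = getattr(res1, key)["total"]
    c0 = getattr(res0, key)["total"]
    e1 = res1.qaly if discounted else res1.qaly_undiscounted
    e0 = res0.qaly if discounted else res0.qaly_undiscounted
    d_cost = c1 - c0
    d_eff = e1 - e0
    if d_eff > 0 and d_cost < 0:
        return ICERResult(d_cost, d_eff, None, DOMINANT)
    if d_eff < 0 and d_cost > 0:
        return ICERResult(d_cost, d_eff, None, DOMINATED)
    if d_eff == 0:
        return ICERResult(d_cost, d_eff, None, UNDEFINED)
    return ICERResult(d_cost, d_eff, d_cost / d_eff, "icer_value")


def inhb(delta_effect: float, delta_cost: float, lam: float) -> float:
    """Incremental net health benefit ΔE − ΔC/λ, in QALYs."""
    if lam <= 0:
        raise InvalidParameterError(f"willingness-to-pay must be positive, got {lam}")
    return delta_effect - delta_cost / lam


def nmb(effect: float, cost: float, lam: float) -> float:
    """Net monetary benefit λ·E − C, in US$."""
    if lam <= 0:
        raise InvalidParameterError(f"willingness-to-pay must be positive, got {lam}")
    return lam * effect - cost


def cea_summary(res1: EconResult, res0: EconResult, thresholds: WTPThresholds = WTPThresholds()) -> dict:
    """JSON-ready comparison: components, deltas, ICER/dominance, INHB/NMB.

    INHB and the net-monetary-benefit difference are reported at both WHO
    thresholds (1× and 3× GDP per capita).
    """
    inc = incremental(res1, res0)
    out = {
        "arms": {
            res1.arm_name: {
                "cost_components": dict(res1.discounted),
                "qaly": res1.qaly,
                "life_months": res1.life_months,
            },
            res0.arm_name: {
                "cost_components": dict(res0.discounted),
                "qaly": res0.qaly,
                "life_months": res0.life_months,
            },
        },
        "delta_cost": inc.delta_cost,
        "delta_effect": inc.delta_effect,
        "icer": inc.icer,
        "label": inc.label,
    }
    for name, lam in (("1x_gdp", thresholds.lambda_1x), ("3x_gdp", thresholds.lambda_3x)):
        out[f"inhb_{name}"] = inhb(inc.delta_effect, inc.delta_cost, lam)
        out[f"nmb_diff_{name}"] = nmb(res1.qaly, res1.discounted["total"], lam) - nmb(
            res0.qaly, res0.discounted["total"], lam
        )
    return out


def apply_perspective(res: EconResult, copay: CopayMap) -> EconResult:
    """Rescale each cost component by its patient copayment share.

    Effects (QALYs, life-months) are unchanged; totals are recomputed from
    the rescaled components, for discounted and undiscounted streams alike.
    """

    def scale(components: dict) -> dict:
        out = {c: components[c] * copay.share(res.arm_name, c) for c in COST_COMPONENTS}
        out["total"] = sum(out.values())
        return out

    return EconResult(
        arm_name=res.arm_name,
        discounted=scale(res.discounted),
        undiscounted=scale(res.undiscounted),
        qaly=res.qaly,
        qaly_undiscounted=res.qaly_undiscounted,
        life_months=res.life_months,
    )
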