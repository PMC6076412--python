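"""Discounted cohort trace: cost and QALY accrual over the occupancy trace.

Accounting conventions
----------------------
Half-period allocation: a patient who leaves a state during a cycle does so,
on average, halfway through the month, and accrues half of that cycle's
costs.  For a per-cycle state occupancy this is exactly the trapezoid rule:

    accrual(t) = (occ(t−1) + occ(t)) / 2 × monthly amount

(stayers get a full month, exiters half; for the progressed-disease state,
whose occupancy first rises, entrants likewise get half a month).  By
default the same rule is applied to utility accrual so that QALYs and
life-months are internally consistent; ``costs_only_half_cycle=True``
restricts the rule to costs and credits utilities on end-of-cycle occupancy
only.

Costs accrue only in the progression-free state (treatment stops at
progression); the adverse-event stream is pre-allocated per cycle and is
only discounted here.  The cohort is computed on fractions (cohort of 1) —
a 1000-patient cohort is a presentation scaling by linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .partition import StateOccupancyTrace

__all__ = ["UtilitySet", "DiscountConfig", "EconResult", "discount_factor", "run_cohort"]

COST_COMPONENTS = ("drug", "ward", "ae", "tests")


@dataclass(frozen=True)
class UtilitySet:
    """Annual health-state utilities (QALY weights).

    Each utility must lie in [0, 1] and the dead-state utility may not
    exceed the living states'.  The PFS >= PD ordering holds for the
    defaults but is deliberately not enforced: the published one-way range
    for the PD utility (up to 0.82) crosses the base PFS utility.
    """

    u_pfs: float = 0.76
    u_pd: float = 0.68
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_pfs", "u_pd", "u_dead"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} = {v} outside [0, 1]")
        if self.u_dead > min(self.u_pfs, self.u_pd):
            raise InvalidParameterError("dead-state utility may not exceed living states'")


@dataclass(frozen=True)
class DiscountConfig:
    """Annual discount rate and cycle-timing mode.

    ``annual_compound_monthly`` (default) discounts cycle t by
    ``(1+r)^(−(t−0.5)/12)`` — continuous annual compounding evaluated at
    mid-cycle; ``yearly_step`` applies ``(1+r)^(−floor((t−1)/12))``, i.e. a
    constant factor within each model year.  The two differ by well under
    1% at the horizons used here.
    """

    annual_rate: float = 0.05
    mode: str = "annual_compound_monthly"

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise InvalidParameterError("discount rate must be non-negative")
        if self.mode not in ("annual_compound_monthly", "yearly_step"):
            raise ConfigurationError(f"unknown discount mode {self.mode!r}")


@dataclass(frozen=True)
class EconResult:
    """Per-patient economics of one arm.

    ``discounted`` / ``undiscounted`` map component name (``drug``, ``ward``,
    ``ae``, ``tests``, ``total``) to US$; ``qaly`` is discounted QALYs,
    ``life_months`` the undiscounted mean survival in months.
    """

    arm_name: str
    discounted: dict
    undiscounted: dict
    qaly: float
    qaly_undiscounted: float
    life_months: float

    def as_records(self) -> list[dict]:
        """Flat records keyed (arm, component, discounting) for CSV/JSON export."""
        rows = []
        for label, comps in (("discounted", self.discounted), ("undiscounted", self.undiscounted)):
            for comp, value in comps.items():
                rows.append(
                    {"arm": self.arm_name, "component": comp, "discounting": label, "value": value}
                )
        rows.append(
            {"arm": self.arm_name, "component": "qaly", "discounting": "discounted", "value": self.qaly}
        )
        rows.append(
            {
                "arm": self.arm_name,
                "component": "qaly",
                "discounting": "undiscounted",
                "value": self.qaly_undiscounted,
            }
        )
        rows.append(
            {
                "arm": self.arm_name,
                "component": "life_months",
                "discounting": "undiscounted",
                "value": self.life_months,
            }
        )
        return rows


def discount_factor(t, cfg: DiscountConfig):
    """Discount factor for cycle t ≥ 1 (vectorized over t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise InvalidParameterError("cycle index must be >= 1")
    r = cfg.annual_rate
    if cfg.mode == "annual_compound_monthly":
        return (1.0 + r) ** (-(t - 0.5) / 12.0)
    return (1.0 + r) ** (-np.floor((t - 1.0) / 12.0))


def run_cohort(
    occupancy: StateOccupancyTrace,
    monthly_costs: dict,
    ae_stream: np.ndarray,
    utilities: UtilitySet = UtilitySet(),
    cfg: DiscountConfig = DiscountConfig(),
    arm_name: str = "arm",
    costs_only_half_cycle: bool = False,
) -> EconResult:
    """Accrue discounted costs and QALYs over a state-occupancy trace.

    Parameters
    ----------
    monthly_costs
        US$ per month spent progression-free, keyed ``drug``, ``ward``,
        ``tests`` (missing keys are 0).
    ae_stream
        Per-cycle adverse-event cost stream (length horizon+1, index 0
        unused), already allocated across cycles.
    costs_only_half_cycle
        If True, the half-period rule applies to costs only and utilities
        accrue on end-of-cycle occupancy (the literal convention); the
        default also half-credits the utility of the departed state.
    """
    T = occupancy.horizon
    ae_stream = np.asarray(ae_stream, dtype=float)
    if ae_stream.size != T + 1:
        raise InvalidParameterError(
            f"ae_stream length {ae_stream.size} does not match horizon {T}"
        )
    unknown = set(monthly_costs) - {"drug", "ward", "tests"}
    if unknown:
        raise ConfigurationError(f"unknown cost component(s): {sorted(unknown)}")

    t = np.arange(1, T + 1)
    df = discount_factor(t, cfg)

    # trapezoid weights = stayers at full month + exiters at half
    pfs_w = 0.5 * (occupancy.occ_pfs[:-1] + occupancy.occ_pfs[1:])
    pd_w = 0.5 * (occupancy.occ_pd[:-1] + occupancy.occ_pd[1:])
    alive_w = 0.5 * (occupancy.alive[:-1] + occupancy.alive[1:])

    disc: dict[str, float] = {}
    undisc: dict[str, float] = {}
    for comp in ("drug", "ward", "tests"):
        stream = monthly_costs.get(comp, 0.0) * pfs_w
        disc[comp] = float(stream @ df)
        undisc[comp] = float(stream.sum())
    disc["ae"] = float(ae_stream[1:] @ df)
    undisc["ae"] = float(ae_stream[1:].sum())
    disc["total"] = sum(disc[c] for c in COST_COMPONENTS)
    undisc["total"] = sum(undisc[c] for c in COST_COMPONENTS)

    if costs_only_half_cycle:
        u_stream = (
            utilities.u_pfs * occupancy.occ_pfs[1:] + utilities.u_pd * occupancy.occ_pd[1:]
        ) / 12.0
    else:
        u_stream = (utilities.u_pfs * pfs_w + utilities.u_pd * pd_w) / 12.0

    return EconResult(
        arm_name=arm_name,
        discounted=disc,
        undiscounted=undisc,
        qaly=float(u_stream @ df),
        qaly_undiscounted=float(u_stream.sum()),
        life_months=float(alive_w.sum()),
    )
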