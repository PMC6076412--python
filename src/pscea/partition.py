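"""Partitioned-survival decomposition of OS/PFS curves into state occupancy.

The three-state model (progression-free, progressed disease, death) is
partitioned directly from the two survivor curves:

    occ_pfs(t)  = S_pfs(t)
    occ_pd(t)   = S_os(t) − S_pfs(t)
    occ_dead(t) = 1 − S_os(t)

so no transition matrix is estimated; monthly transition probabilities are
derived (``1 − S(t)/S(t−1)``) only where needed — to rescale survival in
sensitivity analyses and as the driver of the microsimulation test oracle.
There are no back-transitions: treatment stops at progression and progressed
patients cannot return to the progression-free state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ArmCurves, SurvivalCurve
from .errors import InvalidParameterError, InvalidScenarioError

__all__ = [
    "StateOccupancyTrace",
    "MonthlyTransitionProbs",
    "occupancy_from_curves",
    "transition_probs",
    "curves_from_transition_probs",
    "apply_survival_multiplier",
]


@dataclass(frozen=True)
class StateOccupancyTrace:
    """Cohort fractions per state and per-cycle exit flows, t = 0..T.

    ``exit_pfs[t]`` is the fraction leaving the progression-free state during
    cycle t (to progression or death); ``exit_alive[t]`` the fraction dying
    during cycle t.  Index 0 of the exit arrays is 0 by convention.
    """

    occ_pfs: np.ndarray
    occ_pd: np.ndarray
    occ_dead: np.ndarray
    exit_pfs: np.ndarray
    exit_alive: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occ_pfs.size - 1

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occ_dead


@dataclass(frozen=True)
class MonthlyTransitionProbs:
    """Conditional monthly exit probabilities, indexed t = 1..T.

    ``tp_pfs_exit[t-1] = 1 − S_pfs(t)/S_pfs(t−1)`` and
    ``tp_death[t-1] = 1 − S_os(t)/S_os(t−1)``; when the denominator is 0 the
    probability is defined as 1 (the state is exhausted, so the convention
    cannot affect costs or QALYs).
    """

    tp_pfs_exit: np.ndarray
    tp_death: np.ndarray


def occupancy_from_curves(curves: ArmCurves) -> StateOccupancyTrace:
    """Partition an arm's OS/PFS curves into the three-state occupancy trace."""
    s_os = curves.os.values
    s_pfs = curves.pfs.values
    occ_pfs = s_pfs.copy()
    occ_dead = 1.0 - s_os
    occ_pd = s_os - s_pfs
    exit_pfs = np.concatenate(([0.0], -np.diff(occ_pfs)))
    exit_alive = np.concatenate(([0.0], np.diff(occ_dead)))
    return StateOccupancyTrace(occ_pfs, occ_pd, occ_dead, exit_pfs, exit_alive)


def _conditional_exit(values: np.ndarray) -> np.ndarray:
    prev = values[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tp = np.where(prev > 0, 1.0 - values[1:] / np.where(prev > 0, prev, 1.0), 1.0)
    return np.clip(tp, 0.0, 1.0)


def transition_probs(curves: ArmCurves) -> MonthlyTransitionProbs:
    """Monthly conditional exit probabilities for PFS and for death."""
    return MonthlyTransitionProbs(
        tp_pfs_exit=_conditional_exit(curves.pfs.values),
        tp_death=_conditional_exit(curves.os.values),
    )


def curves_from_transition_probs(
    tps: MonthlyTransitionProbs, arm_name: str = "arm", cycle_length: float = 1.0
) -> ArmCurves:
    """Rebuild survivor curves from monthly transition probabilities.

    Inverse of :func:`transition_probs` up to the zero-denominator
    convention: ``S(t) = S(t−1) · (1 − tp(t))`` from ``S(0) = 1``.
    """
    s_pfs = np.concatenate(([1.0], np.cumprod(1.0 - tps.tp_pfs_exit)))
    s_os = np.concatenate(([1.0], np.cumprod(1.0 - tps.tp_death)))
    return ArmCurves(
        arm_name,
        SurvivalCurve("OS", s_os, cycle_length),
        SurvivalCurve("PFS", s_pfs, cycle_length),
    )


def apply_survival_multiplier(curves: ArmCurves, factor: float) -> ArmCurves:
    """Rescale an arm's survival by a multiplier on both sets of monthly TPs.

    The sensitivity convention varies the monthly transition probabilities
    for PFS and OS *simultaneously*: ``new_tp(t) = clip(old_tp(t)/factor,
    0, 1)`` and the curves are rebuilt from the rescaled TPs.  ``factor > 1``
    therefore means better survival (pointwise higher survivor proportions);
    ``factor = 1`` returns the input unchanged.
    """
    if factor <= 0:
        raise InvalidParameterError(f"survival multiplier must be positive, got {factor}")
    if factor == 1.0:
        return curves
    tps = transition_probs(curves)
    scaled = MonthlyTransitionProbs(
        tp_pfs_exit=np.clip(tps.tp_pfs_exit / factor, 0.0, 1.0),
        tp_death=np.clip(tps.tp_death / factor, 0.0, 1.0),
    )
    try:
        return curves_from_transition_probs(scaled, curves.arm_name, curves.os.cycle_length)
    except Exception as exc:  # PFS > OS after rescaling
        raise InvalidScenarioError(
            f"survival multiplier {factor} produced invalid curves for arm "
            f"{curves.arm_name!r}: {exc}"
        ) from exc
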