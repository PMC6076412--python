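"""Independent brute-force oracles used by the test suite.

The microsimulation drives individual patients through the three states
using the monthly transition probabilities with a single uniform draw per
patient-cycle (deaths nested inside progression-free exits, which requires
tp_death <= tp_pfs_exit — true for all curves used as oracles here).  It
applies the same half-period and discounting rules as the cohort engine but
computes everything per patient, so it checks the cohort algebra through an
entirely different code path.
"""

from __future__ import annotations

import numpy as np

from pscea.curves import ArmCurves
from pscea.engine import DiscountConfig, UtilitySet, discount_factor
from pscea.partition import transition_probs

PFS, PD, DEAD = 0, 1, 2


def microsim(
    curves: ArmCurves,
    n_patients: int,
    seed: int,
    monthly_costs: dict | None = None,
    utilities: UtilitySet = UtilitySet(),
    cfg: DiscountConfig = DiscountConfig(),
):
    """Per-patient simulation; returns (occupancy fractions, econ means, econ SEs).

    ``occupancy`` is a dict of arrays (occ_pfs, occ_pd, occ_dead) over
    t = 0..T.  ``econ`` holds Monte-Carlo means of the discounted per-patient
    PFS-state cost and QALYs; ``se`` their standard errors.
    """
    tps = transition_probs(curves)
    if np.any(tps.tp_death > tps.tp_pfs_exit + 1e-12):
        raise ValueError("oracle requires tp_death <= tp_pfs_exit at every cycle")
    T = curves.horizon
    rng = np.random.default_rng(seed)
    monthly = sum((monthly_costs or {}).values())

    state = np.full(n_patients, PFS, dtype=np.int8)
    occ = {k: np.zeros(T + 1) for k in ("occ_pfs", "occ_pd", "occ_dead")}
    occ["occ_pfs"][0] = 1.0
    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)

    for t in range(1, T + 1):
        u = rng.random(n_patients)
        df = float(discount_factor(t, cfg))
        in_pfs = state == PFS
        in_pd = state == PD

        die_from_pfs = in_pfs & (u < tps.tp_death[t - 1])
        to_pd = in_pfs & ~die_from_pfs & (u < tps.tp_pfs_exit[t - 1])
        stay_pfs = in_pfs & ~die_from_pfs & ~to_pd
        die_from_pd = in_pd & (u < tps.tp_death[t - 1])
        stay_pd = in_pd & ~die_from_pd

        # half-period rule: exiters accrue half of the departed state's month
        cost += df * monthly * (stay_pfs + 0.5 * (die_from_pfs | to_pd))
        qaly += df * (utilities.u_pfs / 12.0) * (stay_pfs + 0.5 * (die_from_pfs | to_pd))
        qaly += df * (utilities.u_pd / 12.0) * (stay_pd + 0.5 * to_pd + 0.5 * die_from_pd)

        state[die_from_pfs | die_from_pd] = DEAD
        state[to_pd] = PD
        occ["occ_pfs"][t] = np.mean(state == PFS)
        occ["occ_pd"][t] = np.mean(state == PD)
        occ["occ_dead"][t] = np.mean(state == DEAD)

    econ = {"cost": cost.mean(), "qaly": qaly.mean()}
    se = {
        "cost": cost.std(ddof=1) / np.sqrt(n_patients),
        "qaly": qaly.std(ddof=1) / np.sqrt(n_patients),
    }
    return occ, econ, se
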