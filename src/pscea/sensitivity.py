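"""One-way (tornado) and probabilistic sensitivity analyses.

One-way analysis re-evaluates the model with a single parameter set to the
low and then the high end of its published range, reporting the incremental
net health benefit (INHB) at each end, rows sorted by tornado width.

The probabilistic sensitivity analysis (PSA) samples *all* parameters
jointly: gamma distributions (moment-matched: shape = (mean/sd)²,
scale = sd²/mean) for costs, normal distributions for proportions,
doses and utilities, truncated to each parameter's valid domain by
redrawing (never clipping, to avoid point masses at the bounds).  Survival
uncertainty enters as a per-arm multiplier applied to the monthly PFS and
OS transition probabilities simultaneously.  Each draw evaluates both arms
under one shared parameter vector; draws that produce an invalid scenario
(e.g. PFS exceeding OS after rescaling) are redrawn and counted, with a
hard error if more than 10% of draws needed redrawing.

All randomness flows from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import inhb
from .errors import ConfigurationError, InvalidParameterError, PsceaError
from .model import OVERRIDE_TARGETS, TwoArmModel

__all__ = [
    "SensitivitySpec",
    "PSASample",
    "one_way",
    "draw_parameters",
    "run_psa",
    "ce_plane_quadrants",
    "ceac",
]

#: Valid domain (closed unless infinite; lower bound exclusive where noted)
#: used to truncate PSA draws, keyed by override target.
_DOMAINS = {
    "survival_multiplier": (0.0, np.inf, True),  # strictly positive
    "monthly_drug_cost": (0.0, np.inf, False),
    "dose": (0.0, np.inf, False),
    "utility_pfs": (0.0, 1.0, False),
    "utility_pd": (0.0, 1.0, False),
    "ward_monthly_cost": (0.0, np.inf, False),
    "ae_cost_multiplier": (0.0, np.inf, False),
    "test_set_cost": (0.0, np.inf, False),
    "hospitalized_fraction": (0.0, 1.0, False),
    "discount_rate": (0.0, 1.0, False),
}

_MAX_TRIES = 1000


@dataclass(frozen=True)
class SensitivitySpec:
    """One perturbable parameter: base value, one-way range, PSA distribution.

    ``target`` names the model input perturbed (see
    :data:`pscea.model.OVERRIDE_TARGETS`); ``arm``/``drug`` qualify it where
    needed.  ``distribution`` is ``normal``, ``gamma`` or ``none`` (one-way
    only, excluded from the PSA).
    """

    id: str
    target: str
    base: float
    low: float
    high: float
    sd: float = 0.0
    distribution: str = "none"
    arm: str | None = None
    drug: str | None = None

    def __post_init__(self) -> None:
        if self.target not in OVERRIDE_TARGETS:
            raise ConfigurationError(f"{self.id}: unknown target {self.target!r}")
        if not self.low <= self.base <= self.high:
            raise InvalidParameterError(
                f"{self.id}: range must satisfy low <= base <= high "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.sd < 0:
            raise InvalidParameterError(f"{self.id}: sd must be non-negative")
        if self.distribution not in ("normal", "gamma", "none"):
            raise ConfigurationError(f"{self.id}: unknown distribution {self.distribution!r}")
        if self.distribution == "gamma" and self.base < 0:
            raise InvalidParameterError(f"{self.id}: gamma requires a non-negative base value")

    @property
    def key(self) -> tuple:
        """Override key ``(target, qualifier)`` understood by the model."""
        qualifier = self.drug if self.target == "dose" else self.arm
        return (self.target, qualifier)


@dataclass(frozen=True)
class PSASample:
    """One PSA draw: the parameter vector and both arms' outcomes."""

    draw: int
    params: dict
    cost1: float
    effect1: float
    cost0: float
    effect0: float

    @property
    def delta_cost(self) -> float:
        return self.cost1 - self.cost0

    @property
    def delta_effect(self) -> float:
        return self.effect1 - self.effect0


def one_way(
    spec_table: list[SensitivitySpec], model: TwoArmModel, lam: float
) -> pd.DataFrame:
    """Tornado table of INHB at each parameter's low and high end.

    One parameter moves at a time, all others stay at base.  Rows are
    sorted by ``|inhb_high − inhb_low|`` descending.  The base-case INHB is
    repeated in every row for reference.
    """
    base = model.evaluate()
    base_inhb = inhb(base.icer.delta_effect, base.icer.delta_cost, lam)
    rows = []
    for spec in spec_table:
        endpoints = {}
        for side in ("low", "high"):
            out = model.evaluate({spec.key: getattr(spec, side)})
            endpoints[side] = inhb(out.icer.delta_effect, out.icer.delta_cost, lam)
        rows.append(
            {
                "parameter": spec.id,
                "base": spec.base,
                "low": spec.low,
                "high": spec.high,
                "inhb_low": endpoints["low"],
                "inhb_high": endpoints["high"],
                "inhb_base": base_inhb,
                "width": abs(endpoints["high"] - endpoints["low"]),
            }
        )
    df = pd.DataFrame(rows).sort_values("width", ascending=False, ignore_index=True)
    return df


def _draw_one(rng: np.random.Generator, spec: SensitivitySpec) -> float:
    """Draw one value for one parameter, truncated to its valid domain."""
    if spec.sd == 0.0:
        return spec.base
    lo, hi, lo_exclusive = _DOMAINS[spec.target]
    for _ in range(_MAX_TRIES):
        if spec.distribution == "normal":
            value = rng.normal(spec.base, spec.sd)
        else:  # gamma, moment-matched
            shape = (spec.base / spec.sd) ** 2
            scale = spec.sd**2 / spec.base
            value = rng.gamma(shape, scale)
        if (value > lo if lo_exclusive else value >= lo) and value <= hi:
            return value
    raise PsceaError(f"{spec.id}: could not draw a value inside its domain")


def draw_parameters(
    spec_table: list[SensitivitySpec], master_seed: int, n_draws: int = 1000
) -> list[dict]:
    """Joint parameter vectors for the PSA, reproducible given the seed.

    Specs with ``distribution: none`` (one-way only) are excluded.  A spec
    with ``sd = 0`` contributes its base value in every draw.
    """
    if n_draws < 1:
        raise InvalidParameterError("n_draws must be >= 1")
    rng = np.random.default_rng(master_seed)
    sampled = [s for s in spec_table if s.distribution != "none"]
    return [{s.key: _draw_one(rng, s) for s in sampled} for _ in range(n_draws)]


def run_psa(
    model: TwoArmModel,
    spec_table: list[SensitivitySpec],
    master_seed: int,
    n_draws: int = 1000,
) -> list[PSASample]:
    """Probabilistic sensitivity analysis: n jointly sampled model runs.

    Invalid draws (model validation failures such as PFS > OS after a
    survival multiplier) are redrawn; more than 10% redraws is a hard error.
    """
    if n_draws < 1:
        raise InvalidParameterError("n_draws must be >= 1")
    rng = np.random.default_rng(master_seed)
    sampled = [s for s in spec_table if s.distribution != "none"]
    samples: list[PSASample] = []
    redraws = 0
    while len(samples) < n_draws:
        params = {s.key: _draw_one(rng, s) for s in sampled}
        try:
            out = model.evaluate(params)
        except PsceaError:
            redraws += 1
            if redraws > 0.10 * n_draws:
                raise PsceaError(
                    f"more than 10% of PSA draws were invalid ({redraws} redraws "
                    f"for {len(samples)} accepted samples)"
                ) from None
            continue
        samples.append(
            PSASample(
                draw=len(samples),
                params=params,
                cost1=out.intervention.discounted["total"],
                effect1=out.intervention.qaly,
                cost0=out.comparator.discounted["total"],
                effect0=out.comparator.qaly,
            )
        )
    return samples


def ce_plane_quadrants(samples: list[PSASample]) -> dict:
    """Shares of the cost-effectiveness plane quadrants across PSA draws.

    ``dominant``: ΔE > 0 and ΔC < 0 (intervention cheaper and more
    effective); ``dominated``: ΔE < 0 and ΔC > 0; ``ne``/``sw``: the
    trade-off quadrants.  Boundary draws (a zero delta) are assigned to the
    adjacent non-dominant quadrant, so the four shares always sum to 1.
    """
    if not samples:
        raise InvalidParameterError("quadrant shares need at least one sample")
    counts = {"dominant": 0, "dominated": 0, "ne": 0, "sw": 0}
    for s in samples:
        de, dc = s.delta_effect, s.delta_cost
        if de > 0 and dc < 0:
            counts["dominant"] += 1
        elif de < 0 and dc > 0:
            counts["dominated"] += 1
        elif de >= 0 and dc >= 0:
            counts["ne"] += 1
        else:
            counts["sw"] += 1
    n = len(samples)
    return {k: v / n for k, v in counts.items()}


def ceac(samples: list[PSASample], lambda_grid) -> np.ndarray:
    """Cost-effectiveness acceptability: P(INHB(λ) > 0) per grid point.

    As λ → ∞ the probability tends to P(ΔE > 0), as λ → 0⁺ to P(ΔC < 0).
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise InvalidParameterError("lambda grid must be nonempty")
    if np.any(lambda_grid <= 0):
        raise InvalidParameterError("willingness-to-pay values must be positive")
    if not samples:
        raise InvalidParameterError("CEAC needs at least one sample")
    de = np.array([s.delta_effect for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    return np.array([(de - dc / lam > 0).mean() for lam in lambda_grid])
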