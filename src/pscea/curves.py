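"""Synthetic survivor curves on a monthly grid.

Trial Kaplan–Meier curves for the two treatment arms are published only as
figures, so this module generates parametric (exponential) stand-ins matched
to the printed median OS / median PFS, adds optional binomial sampling noise
to emulate a finite trial cohort, and reads/writes the plain-CSV curve
exchange format (``month,os_prop,pfs_prop``).

The exponential family is the natural choice when only a median is known:
S(t) = exp(−ln 2 · t / median) is the unique constant-hazard survivor
function with that median.  A Weibull shape parameter is accepted as an
extension hook and defaults to 1 (exponential).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CurveFormatError, InvalidParameterError

__all__ = [
    "SurvivalCurve",
    "ArmCurves",
    "exp_survival_curve",
    "make_arm_curves",
    "binomial_km_noise",
    "read_curve_csv",
    "write_curve_csv",
]

#: Tolerance used when validating curve invariants on float inputs.
_TOL = 1e-9


@dataclass(frozen=True)
class SurvivalCurve:
    """Survivor proportions S(t) for one endpoint at integer months t = 0..T.

    Parameters
    ----------
    endpoint
        ``"OS"`` (overall survival) or ``"PFS"`` (progression-free survival).
    values
        Survivor proportions, ``values[t] = S(t)``; ``S(0)`` must be 1, all
        values in [0, 1] and non-increasing.
    cycle_length
        Cycle length in months (the model runs on a 1-month cycle).
    """

    endpoint: str
    values: np.ndarray
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.endpoint not in ("OS", "PFS"):
            raise InvalidParameterError(f"endpoint must be 'OS' or 'PFS', got {self.endpoint!r}")
        v = self.values
        if v.ndim != 1 or v.size < 2:
            raise CurveFormatError("curve needs at least months 0 and 1")
        if abs(v[0] - 1.0) > _TOL:
            raise CurveFormatError(f"S(0) must be 1, got {v[0]}")
        if np.any(v < -_TOL) or np.any(v > 1 + _TOL):
            t = int(np.argmax((v < -_TOL) | (v > 1 + _TOL)))
            raise CurveFormatError(f"survivor proportion outside [0, 1] at month {t}")
        if np.any(np.diff(v) > _TOL):
            t = int(np.argmax(np.diff(v) > _TOL)) + 1
            raise CurveFormatError(
                f"{self.endpoint} survivor proportion rises at month {t}; S must be non-increasing"
            )

    @property
    def horizon(self) -> int:
        """Last month index T."""
        return self.values.size - 1

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ArmCurves:
    """The OS and PFS curves of one treatment arm over a common horizon."""

    arm_name: str
    os: SurvivalCurve
    pfs: SurvivalCurve

    def __post_init__(self) -> None:
        if self.os.endpoint != "OS" or self.pfs.endpoint != "PFS":
            raise InvalidParameterError("ArmCurves requires an OS curve and a PFS curve")
        if self.os.horizon != self.pfs.horizon:
            raise CurveFormatError(
                f"OS horizon {self.os.horizon} != PFS horizon {self.pfs.horizon}"
            )
        bad = self.pfs.values > self.os.values + _TOL
        if np.any(bad):
            t = int(np.argmax(bad))
            raise CurveFormatError(
                f"PFS proportion exceeds OS proportion at month {t}; "
                "progression-free patients must be alive (PFS <= OS)"
            )

    @property
    def horizon(self) -> int:
        return self.os.horizon

    def with_terminal_death(self) -> "ArmCurves":
        """Append one month in which any residual survivors die.

        The cohort is followed until extinction; survivors left at the
        horizon are assumed to die in the following cycle.
        """
        if self.os.values[-1] == 0.0 and self.pfs.values[-1] == 0.0:
            return self
        os_v = np.append(self.os.values, 0.0)
        pfs_v = np.append(self.pfs.values, 0.0)
        return ArmCurves(
            self.arm_name,
            SurvivalCurve("OS", os_v, self.os.cycle_length),
            SurvivalCurve("PFS", pfs_v, self.pfs.cycle_length),
        )


def exp_survival_curve(
    median: float,
    horizon: int,
    cycle_length: float = 1.0,
    endpoint: str = "OS",
    shape: float = 1.0,
) -> SurvivalCurve:
    """Constant-hazard survivor curve matched to a printed median.

    ``S(t) = exp(−ln 2 · (t / median) ** shape)`` evaluated at integer
    months; ``shape`` defaults to 1 (exponential).  Sub-month medians are
    handled analytically — no grid interpolation is involved.
    """
    if median <= 0:
        raise InvalidParameterError(f"median must be positive, got {median}")
    if horizon < 1:
        raise InvalidParameterError(f"horizon must be >= 1 month, got {horizon}")
    if shape <= 0:
        raise InvalidParameterError(f"shape must be positive, got {shape}")
    t = np.arange(horizon + 1) * cycle_length
    values = np.exp(-math.log(2.0) * (t / median) ** shape)
    return SurvivalCurve(endpoint, values, cycle_length)


def make_arm_curves(
    os_median: float,
    pfs_median: float,
    horizon: int = 60,
    arm_name: str = "arm",
    cycle_length: float = 1.0,
    shape: float = 1.0,
) -> ArmCurves:
    """Exponential OS and PFS curves for one arm from their medians.

    Requires ``pfs_median <= os_median`` so that the PFS <= OS invariant
    holds exactly under exponentials (equal medians give an arm that never
    occupies the progressed-disease state).  Warns if the cohort is not
    essentially extinct at the horizon (S_os(T) > 0.001), since the model
    follows patients until death.
    """
    if pfs_median > os_median:
        raise InvalidParameterError(
            f"pfs_median ({pfs_median}) exceeds os_median ({os_median}); "
            "refusing to clip — the PFS <= OS invariant would be violated"
        )
    os_curve = exp_survival_curve(os_median, horizon, cycle_length, "OS", shape)
    pfs_curve = exp_survival_curve(pfs_median, horizon, cycle_length, "PFS", shape)
    if os_curve.values[-1] > 0.001:
        warnings.warn(
            f"S_os({horizon}) = {os_curve.values[-1]:.4f} > 0.001: cohort not "
            "extinct at the horizon; residual survivors are moved to death one "
            "cycle after the horizon when the model is run",
            stacklevel=2,
        )
    return ArmCurves(arm_name, os_curve, pfs_curve)


def binomial_km_noise(curve: SurvivalCurve, n_patients: int, seed: int) -> SurvivalCurve:
    """Add finite-cohort sampling noise to a survivor curve.

    Survivors are thinned sequentially: the ``s(t-1)`` patients alive at
    month t−1 each survive month t independently with the input curve's
    conditional probability ``S(t)/S(t-1)``, so the noisy curve matches the
    input in expectation and is itself a valid (non-increasing) step
    function on the k/n grid.  Reproducible given ``seed``.
    """
    if n_patients < 1:
        raise InvalidParameterError(f"n_patients must be >= 1, got {n_patients}")
    rng = np.random.default_rng(seed)
    s = n_patients
    out = np.empty_like(curve.values)
    out[0] = 1.0
    for t in range(1, curve.values.size):
        prev = curve.values[t - 1]
        p = curve.values[t] / prev if prev > 0 else 0.0
        s = rng.binomial(s, min(max(p, 0.0), 1.0))
        out[t] = s / n_patients
    return SurvivalCurve(curve.endpoint, out, curve.cycle_length)


def read_curve_csv(path, arm_name: str = "arm") -> ArmCurves:
    """Read an arm's curves from CSV (columns ``month,os_prop,pfs_prop``).

    Months must start at 0 and be consecutive integers; proportion columns
    must satisfy all curve invariants.  Violations raise
    :class:`~pscea.errors.CurveFormatError` naming the offending row/rule.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["month", "os_prop", "pfs_prop"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CurveFormatError(f"curve CSV missing column(s): {', '.join(missing)}")
    months = df["month"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(months, expected):
        bad = int(np.argmax(months != expected))
        raise CurveFormatError(
            f"month column must be consecutive integers starting at 0; "
            f"row {bad} has month {months[bad]}"
        )
    os_curve = SurvivalCurve("OS", df["os_prop"].to_numpy(dtype=float))
    pfs_curve = SurvivalCurve("PFS", df["pfs_prop"].to_numpy(dtype=float))
    return ArmCurves(arm_name, os_curve, pfs_curve)


def write_curve_csv(curves: ArmCurves, path) -> None:
    """Write an arm's curves to the CSV exchange format (full precision)."""
    df = pd.DataFrame(
        {
            "month": np.arange(curves.horizon + 1),
            "os_prop": curves.os.values,
            "pfs_prop": curves.pfs.values,
        }
    )
    df.to_csv(path, index=False)  # default formatting is shortest round-trip repr
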