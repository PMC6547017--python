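"""Imposing MCAR and MAR missingness on the outcome column.

Two mechanisms are supported, both confined to the outcome Y:

* **MCAR** — the first ``round(p * n)`` rows are deleted.  Rows are iid, so
  deterministic truncation is equal in distribution to random deletion and
  keeps the achieved proportion exact.
* **MAR** — each row's outcome goes missing independently with probability
  ``expit(alpha + c1 * Z1 + cx * X)``.  The intercept ``alpha`` is calibrated
  numerically so the *expected* proportion of missing outcomes equals the
  target; the achieved proportion then varies from data set to data set, as
  it would under the mechanism itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

from .data_model import Cohort

__all__ = [
    "CANONICAL_PROPORTIONS",
    "MissingnessScenario",
    "MaskedCohort",
    "apply_mcar",
    "calibrate_alpha",
    "apply_mar",
    "write_masked_csv",
    "read_masked_csv",
]

#: The grid of target missingness proportions used in the replication runs.
CANONICAL_PROPORTIONS: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.90)


@dataclass(frozen=True)
class MissingnessScenario:
    """One missingness mechanism at one target proportion.

    For MAR, ``alpha`` is the intercept of the logistic selection model
    ``logit(P(missing)) = alpha + coefficient_z1 * Z1 + coefficient_x * X``;
    it is usually filled in by :func:`calibrate_alpha` via
    :meth:`calibrated`.  MCAR scenarios carry no ``alpha``.
    """

    mechanism: Literal["MCAR", "MAR"]
    target_proportion: float
    alpha: float | None = None
    coefficient_z1: float = 1.0
    coefficient_x: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 <= self.target_proportion < 1.0):
            raise ValueError(
                f"target proportion must lie in [0, 1); got {self.target_proportion}"
            )
        if self.mechanism == "MCAR" and self.alpha is not None:
            raise ValueError("MCAR scenarios carry no selection-model intercept")

    def calibrated(self) -> "MissingnessScenario":
        """Return a copy with ``alpha`` solved for the target proportion."""
        if self.mechanism != "MAR":
            return self
        a = calibrate_alpha(self.target_proportion,
                            self.coefficient_z1, self.coefficient_x)
        return replace(self, alpha=a)


@dataclass(frozen=True)
class MaskedCohort:
    """A cohort with some outcome values flagged missing.

    ``data`` keeps the original simulated values in every cell; ``mask`` is
    True where Y is to be treated as unobserved.  Keeping the true values
    alongside the mask lets diagnostics compare imputations to the deleted
    truth without re-simulating.
    """

    data: pd.DataFrame
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.shape != (len(self.data),):
            raise ValueError(
                f"mask length {mask.shape} does not match cohort rows {len(self.data)}"
            )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def complete_data(self) -> pd.DataFrame:
        return self.data.loc[~self.mask]

    def observed_y(self) -> pd.Series:
        """Y with missing entries as NaN, as an analyst would see it."""
        y = self.data["Y"].copy()
        y[self.mask] = np.nan
        return y


def apply_mcar(cohort: Cohort, p: float) -> MaskedCohort:
    """Delete the outcome for the first ``round(p * n)`` rows.

    Rounding is half-away-from-zero so that, e.g., p = 0.005 with n = 1000
    masks 5 rows; at the replication grid p * n is always integral.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError(f"missing proportion must lie in [0, 1); got {p}")
    n_missing = int(math.floor(p * cohort.n + 0.5))
    mask = np.zeros(cohort.n, dtype=bool)
    mask[:n_missing] = True
    return MaskedCohort(data=cohort.data, mask=mask)


# Gauss–Hermite rule (probabilists' weight) reused across calibrations; 80
# nodes put the quadrature error far below the 1e-6 calibration tolerance.
_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(80)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def calibrate_alpha(p_target: float, coeff_z1: float = 1.0,
                    coeff_x: float = 1.0) -> float:
    """Solve for the MAR selection-model intercept hitting a target proportion.

    The linear predictor ``coeff_z1 * Z1 + coeff_x * X`` is normal with mean 0
    and variance ``coeff_z1**2 + coeff_x**2`` (Z1 and X are independent
    standard normals), so the expected missingness proportion is a 1-D
    integral ``E[expit(alpha + s * U)]`` over standard-normal U.  It is
    evaluated by Gauss–Hermite quadrature and inverted by bracketed root
    finding to within 1e-6 on the proportion scale.
    """
    if not (0.0 < p_target < 1.0):
        raise ValueError(f"target proportion must lie in (0, 1); got {p_target}")
    if p_target == 0.5:
        # expit(a + u) + expit(a - u) = 1 and the linear predictor is
        # symmetric about 0, so the expectation at a = 0 is exactly 1/2.
        return 0.0
    scale = math.hypot(coeff_z1, coeff_x)

    def achieved(alpha: float) -> float:
        return float(np.sum(_GH_WEIGHTS * expit(alpha + scale * _GH_NODES)))

    lo, hi = -60.0, 60.0
    if not (achieved(lo) < p_target < achieved(hi)):
        raise RuntimeError(
            f"calibration bracket [{lo}, {hi}] does not contain the solution "
            f"for p_target={p_target}, scale={scale}"
        )
    alpha = brentq(lambda a: achieved(a) - p_target, lo, hi, xtol=1e-10)
    if abs(achieved(alpha) - p_target) >= 1e-6:
        raise RuntimeError(
            f"calibration did not converge: target {p_target}, achieved "
            f"{achieved(alpha)} at alpha={alpha}"
        )
    return float(alpha)


def apply_mar(cohort: Cohort, scenario: MissingnessScenario,
              seed: int) -> MaskedCohort:
    """Mask each outcome independently under the logistic selection model."""
    if scenario.mechanism != "MAR":
        raise ValueError("apply_mar requires a MAR scenario")
    if scenario.alpha is None:
        raise ValueError(
            "scenario.alpha is not set; call scenario.calibrated() first"
        )
    eta = (scenario.alpha
           + scenario.coefficient_z1 * cohort.data["Z1"].to_numpy()
           + scenario.coefficient_x * cohort.data["X"].to_numpy())
    rng = np.random.default_rng(seed)
    mask = rng.random(cohort.n) < expit(eta)
    return MaskedCohort(data=cohort.data, mask=mask)


def write_masked_csv(masked: MaskedCohort, path) -> None:
    """Serialize with empty cells where the outcome is missing."""
    out = masked.data.copy()
    out["Y"] = masked.observed_y()
    out.to_csv(path, index=False)


def read_masked_csv(path) -> MaskedCohort:
    data = pd.read_csv(path)
    mask = data["Y"].isna().to_numpy()
    # Deleted values are unrecoverable from the file; keep NaN placeholders.
    return MaskedCohort(data=data, mask=mask)
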