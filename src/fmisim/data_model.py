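"""Synthetic cohort generation for the missing-data simulation study.

The population model is a multivariate normal vector of one outcome ``Y``,
one exposure ``X`` and a bank of auxiliary variables ``Z1, Z2, ...``, all
standardised (mean 0, SD 1).  Every variable is correlated with the outcome,
but the non-outcome variables are mutually uncorrelated.  That orthogonality
is what makes the squared coefficient of multiple correlation with the
outcome, R^2_Y, decompose into a simple sum of squared marginal
correlations — the quantity used throughout as the measure of auxiliary
information carried by an imputation model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "CorrelationSpec",
    "Cohort",
    "DEFAULT_OUTCOME_CORRELATIONS",
    "build_correlation_matrix",
    "simulate_cohort",
    "multiple_r2",
    "read_cohort_csv",
]


class ConfigurationError(ValueError):
    """A correlation/scenario specification that cannot define a valid model."""


#: Population correlations of (X, Z1, ..., Z11) with the outcome Y:
#: 0.6 for the exposure, 0.4 for two strong auxiliaries, 0.2 for five
#: moderate ones and 0.1 for four weak ones.
DEFAULT_OUTCOME_CORRELATIONS: tuple[float, ...] = (
    0.6, 0.4, 0.4, 0.2, 0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.1, 0.1,
)


@dataclass(frozen=True)
class CorrelationSpec:
    """Population correlation structure tying the outcome to its predictors.

    Parameters
    ----------
    outcome_correlations
        Correlations of (X, Z1, ..., Zk) with Y, in that order.  The default
        reproduces the 12-predictor structure used by the simulation study.
    n
        Cohort size (rows per simulated data set).
    """

    outcome_correlations: tuple[float, ...] = DEFAULT_OUTCOME_CORRELATIONS
    n: int = 1000

    def __post_init__(self) -> None:
        rho = tuple(float(r) for r in self.outcome_correlations)
        object.__setattr__(self, "outcome_correlations", rho)
        if len(rho) < 1:
            raise ConfigurationError("at least one predictor correlation is required")
        if any(not (-1.0 < r < 1.0) for r in rho):
            raise ConfigurationError(
                f"outcome correlations must lie strictly in (-1, 1); got {rho}"
            )
        if self.n < 1:
            raise ConfigurationError(f"cohort size must be positive; got {self.n}")
        # With orthogonal predictors the matrix is positive definite iff the
        # squared correlations with Y sum to less than 1 (Schur complement).
        if sum(r * r for r in rho) >= 1.0:
            raise ConfigurationError(
                "correlation matrix is not positive definite: squared outcome "
                f"correlations sum to {sum(r * r for r in rho):.4f} >= 1 "
                f"for spec {rho}"
            )

    @property
    def columns(self) -> list[str]:
        """Column labels in storage order: Y, X, Z1, ..., Zk."""
        k = len(self.outcome_correlations) - 1
        return ["Y", "X"] + [f"Z{i}" for i in range(1, k + 1)]

    @property
    def predictor_labels(self) -> list[str]:
        return self.columns[1:]


@dataclass(frozen=True)
class Cohort:
    """A fully observed simulated data set plus the seed that produced it."""

    data: pd.DataFrame
    seed: int
    spec: CorrelationSpec = field(default_factory=CorrelationSpec)

    def __post_init__(self) -> None:
        expected = self.spec.columns
        if list(self.data.columns) != expected:
            raise ValueError(f"cohort columns must be {expected}")
        if len(self.data) != self.spec.n:
            raise ValueError(
                f"cohort has {len(self.data)} rows; spec requires {self.spec.n}"
            )
        if self.data.isna().any().any():
            raise ValueError("cohorts are fully observed; missingness is imposed downstream")

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def build_correlation_matrix(spec: CorrelationSpec) -> np.ndarray:
    """Assemble the (k+1) x (k+1) population correlation matrix.

    Row/column 0 is the outcome; entry (0, j) holds its correlation with the
    j-th predictor and every other off-diagonal entry is zero.
    """
    rho = np.asarray(spec.outcome_correlations, dtype=float)
    d = rho.size + 1
    corr = np.eye(d)
    corr[0, 1:] = rho
    corr[1:, 0] = rho
    # Guarded by the spec invariant, but verify outright so any future
    # relaxation of the structure still fails loudly.
    if np.linalg.eigvalsh(corr)[0] <= 0.0:
        raise ConfigurationError(
            f"correlation matrix for spec {spec.outcome_correlations} is not "
            "positive definite"
        )
    return corr


def simulate_cohort(spec: CorrelationSpec, seed: int) -> Cohort:
    """Draw one cohort from the multivariate normal population.

    Sampling applies the Cholesky factor of the correlation matrix to iid
    standard normals, so the population covariance is matched exactly and the
    draw is reproducible from the single integer seed.
    """
    corr = build_correlation_matrix(spec)
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(seed)
    iid = rng.standard_normal((spec.n, corr.shape[0]))
    values = iid @ chol.T
    data = pd.DataFrame(values, columns=spec.columns)
    return Cohort(data=data, seed=int(seed), spec=spec)


def multiple_r2(spec: CorrelationSpec, predictors: Iterable[str]) -> float:
    """Squared coefficient of multiple correlation of Y with a predictor set.

    Because the predictors are mutually uncorrelated in the population, R^2_Y
    is exactly the sum of the squared marginal correlations over the subset —
    a closed form, not a simulation estimate.
    """
    labels = list(predictors)
    if not labels:
        warnings.warn("empty predictor set carries no information; R^2_Y = 0",
                      stacklevel=2)
        return 0.0
    available = spec.predictor_labels
    unknown = sorted(set(labels) - set(available))
    if unknown:
        raise KeyError(f"unknown predictors {unknown}; available: {available}")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate predictors in {labels}")
    lookup = dict(zip(available, spec.outcome_correlations, strict=True))
    return float(sum(lookup[name] ** 2 for name in labels))


def read_cohort_csv(path, seed: int = -1,
                    spec: CorrelationSpec | None = None) -> Cohort:
    """Load a cohort written by :meth:`Cohort.to_csv`.

    The stored file does not carry the seed; pass it explicitly if known
    (``-1`` marks it as unknown).
    """
    data = pd.read_csv(path)
    if spec is None:
        k = data.shape[1] - 1
        if k < 1:
            raise ValueError("cohort file must contain Y plus at least one predictor")
        if k == len(DEFAULT_OUTCOME_CORRELATIONS):
            rho = DEFAULT_OUTCOME_CORRELATIONS
        else:
            # Externally supplied data of arbitrary width: only the column
            # layout matters downstream, so use placeholder correlations.
            rho = tuple([0.0] * k)
        spec = CorrelationSpec(outcome_correlations=rho, n=len(data))
    return Cohort(data=data, seed=int(seed), spec=spec)
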