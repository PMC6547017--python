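"""Proper multiple imputation of a missing continuous outcome.

The imputation model is a normal linear regression of the outcome on the
chosen predictor set, fitted to the complete rows.  "Proper" means each
imputation draws the regression parameters from their posterior under the
standard noninformative prior before drawing the missing outcomes:

    sigma*^2 = sigma2_hat * nu / ChiSquare(nu),        nu = residual df
    beta*    ~ Normal(beta_hat, sigma*^2 * (X'X)^{-1})
    y*_i     ~ Normal(beta* . x_i, sigma*^2)           for each missing row

Between-imputation variability then reflects parameter uncertainty as well
as residual noise, which is what Rubin's-rules variance estimation and the
fraction of missing information require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .missingness import MaskedCohort

__all__ = [
    "CANONICAL_MODELS",
    "ImputationModelSpec",
    "ObservedFit",
    "PosteriorDraw",
    "ImputedStack",
    "fit_observed_regression",
    "draw_posterior",
    "impute_stack",
]

#: The five imputation models of the replication study, by label.  Model 1
#: carries no auxiliary information (analysis-model variables only); models
#: 2-5 add increasing amounts, measured by R^2_Y of the predictor set.
CANONICAL_MODELS: dict[str, tuple[str, ...]] = {
    "1": ("X",),
    "2": ("X", "Z3"),
    "3": ("X", "Z1"),
    "4": ("X", "Z1", "Z2", "Z3", "Z4"),
    "5": ("X",) + tuple(f"Z{i}" for i in range(1, 12)),
}


@dataclass(frozen=True)
class ImputationModelSpec:
    """Predictor set and imputation count for one imputation model."""

    label: str
    predictors: tuple[str, ...]
    m: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if "X" not in self.predictors:
            raise ValueError(
                "the imputation model must contain every analysis-model "
                f"variable; X is missing from {self.predictors}"
            )
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError(f"duplicate predictors in {self.predictors}")
        if self.m < 2:
            raise ValueError(f"at least 2 imputations are required; got m={self.m}")

    @classmethod
    def canonical(cls, label: str, m: int = 1000) -> "ImputationModelSpec":
        return cls(label=str(label), predictors=CANONICAL_MODELS[str(label)], m=m)


class ObservedFit(NamedTuple):
    """OLS summary of the imputation model on the complete rows."""

    beta_hat: np.ndarray      # intercept first, then predictors
    sigma2_hat: float         # residual-df-corrected residual variance
    xtx_inverse: np.ndarray   # (X'X)^{-1} for the intercept-augmented design
    residual_df: int
    predictors: tuple[str, ...]


class PosteriorDraw(NamedTuple):
    beta_star: np.ndarray
    sigma_star: float


@dataclass(frozen=True)
class ImputedStack:
    """m completed copies of a masked cohort.

    Stored compactly: the shared source data, the mask, and an
    (m, n_missing) array of imputed outcome values.  ``completed(j)``
    materialises the j-th completed data set on demand.
    """

    source: pd.DataFrame
    source_mask: np.ndarray
    imputed_y: np.ndarray
    model: ImputationModelSpec

    def __post_init__(self) -> None:
        if self.imputed_y.shape != (self.model.m, int(self.source_mask.sum())):
            raise ValueError(
                f"imputed_y has shape {self.imputed_y.shape}; expected "
                f"({self.model.m}, {int(self.source_mask.sum())})"
            )

    @property
    def m(self) -> int:
        return self.model.m

    def completed(self, j: int) -> pd.DataFrame:
        frame = self.source.copy()
        frame.loc[self.source_mask, "Y"] = self.imputed_y[j]
        return frame

    def completed_y(self) -> np.ndarray:
        """All m completed outcome vectors as an (m, n) array."""
        y = np.broadcast_to(self.source["Y"].to_numpy(),
                            (self.m, len(self.source))).copy()
        y[:, self.source_mask] = self.imputed_y
        return y

    def to_long_frame(self) -> pd.DataFrame:
        """Audit export: (imputation_index, row_index, Y) for masked rows."""
        rows = np.flatnonzero(self.source_mask)
        idx = np.repeat(np.arange(self.m), rows.size)
        return pd.DataFrame({
            "imputation_index": idx,
            "row_index": np.tile(rows, self.m),
            "Y": self.imputed_y.ravel(),
        })


def _design(data: pd.DataFrame, predictors: Sequence[str],
            rows: np.ndarray | None = None) -> np.ndarray:
    frame = data if rows is None else data.loc[rows]
    mat = frame[list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(mat)), mat])


def fit_observed_regression(masked: MaskedCohort,
                            spec: ImputationModelSpec) -> ObservedFit:
    """OLS of the observed outcome on intercept + predictors."""
    observed = ~masked.mask
    n_obs = int(observed.sum())
    k = len(spec.predictors) + 1
    if n_obs <= k:
        raise ValueError(
            f"{n_obs} complete rows cannot identify {k} regression "
            f"parameters; at least {k + 1} are required"
        )
    X = _design(masked.data, spec.predictors, observed)
    y = masked.data.loc[observed, "Y"].to_numpy(dtype=float)
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"singular design for predictors {spec.predictors}"
        ) from err
    # Explicit rank check: np.linalg.inv can succeed on numerically singular
    # matrices without raising.
    if np.linalg.matrix_rank(X) < k:
        raise ValueError(f"rank-deficient design for predictors {spec.predictors}")
    beta_hat = xtx_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    df = n_obs - k
    ss = float(resid @ resid)
    # Snap rounding-noise residuals to an exactly degenerate fit so that a
    # noiseless outcome yields deterministic imputations.
    if ss <= 1e-24 * (float(y @ y) + 1.0):
        ss = 0.0
    sigma2_hat = ss / df
    return ObservedFit(beta_hat=beta_hat, sigma2_hat=sigma2_hat,
                       xtx_inverse=xtx_inv, residual_df=df,
                       predictors=spec.predictors)


def _draw_posterior_batch(fit: ObservedFit, rng: np.random.Generator,
                          size: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised posterior draws: (size, k) betas and (size,) sigma^2."""
    nu = fit.residual_df
    if fit.sigma2_hat == 0.0:
        sigma2 = np.zeros(size)
        betas = np.broadcast_to(fit.beta_hat, (size, fit.beta_hat.size)).copy()
        return betas, sigma2
    sigma2 = fit.sigma2_hat * nu / rng.chisquare(nu, size)
    chol = np.linalg.cholesky(fit.xtx_inverse)
    z = rng.standard_normal((size, fit.beta_hat.size))
    betas = fit.beta_hat + np.sqrt(sigma2)[:, None] * (z @ chol.T)
    return betas, sigma2


def draw_posterior(fit: ObservedFit, rng: np.random.Generator) -> PosteriorDraw:
    """One posterior draw of (beta, sigma) under the noninformative prior."""
    betas, sigma2 = _draw_posterior_batch(fit, rng, 1)
    return PosteriorDraw(beta_star=betas[0], sigma_star=float(np.sqrt(sigma2[0])))


def impute_stack(masked: MaskedCohort, spec: ImputationModelSpec,
                 seed: int | np.random.SeedSequence) -> ImputedStack:
    """Produce m completed data sets by proper imputation.

    Each of the m imputations takes an independent posterior draw, then fills
    every masked outcome with its linear prediction plus Normal(0, sigma*^2)
    noise.  Observed values are never touched.
    """
    rng = np.random.default_rng(seed)
    n_mis = masked.n_missing
    if n_mis == 0:
        imputed = np.empty((spec.m, 0))
        return ImputedStack(source=masked.data, source_mask=masked.mask,
                            imputed_y=imputed, model=spec)
    fit = fit_observed_regression(masked, spec)
    betas, sigma2 = _draw_posterior_batch(fit, rng, spec.m)
    X_mis = _design(masked.data, spec.predictors, masked.mask)
    noise = rng.standard_normal((spec.m, n_mis)) * np.sqrt(sigma2)[:, None]
    imputed = betas @ X_mis.T + noise
    return ImputedStack(source=masked.data, source_mask=masked.mask,
                        imputed_y=imputed, model=spec)
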