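"""Monte-Carlo performance summaries across simulation replicates.

The estimands follow the usual simulation-study conventions (as implemented
by tools such as Stata's ``simsum``): bias is the mean estimate minus the
truth with MCSE ``sd / sqrt(n_sim)``; the empirical SE is the sample SD of
the estimates with normal-theory MCSE ``emp_se / sqrt(2 (n_sim - 1))``.
FMI is summarised by its median and interquartile range across replicates,
using linear-interpolation (type-7) quantiles.

Efficiency and bias gains of MI over complete-case analysis are expressed as
percentage reductions computed from the scenario-level summaries:

    100 * (se_CCA - se_MI) / se_CCA
    100 * (|bias_CCA| - |bias_MI|) / |bias_CCA|
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "bias",
    "empirical_se",
    "summarize_fmi",
    "pct_se_reduction",
    "pct_bias_reduction",
    "ScenarioResult",
    "PerformanceTable",
    "summarize_scenarios",
]

TRUE_COEFFICIENTS = {"intercept": 0.0, "slope": 0.6}


def bias(estimates, truth: float) -> tuple[float, float]:
    """Mean estimate minus truth, with its Monte-Carlo standard error."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("bias needs at least 2 replicate estimates")
    return float(est.mean() - truth), float(est.std(ddof=1) / np.sqrt(est.size))


def empirical_se(estimates) -> tuple[float, float]:
    """Sample SD of the estimates, with its normal-theory MCSE."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("empirical SE needs at least 2 replicate estimates")
    se = float(est.std(ddof=1))
    return se, float(se / np.sqrt(2.0 * (est.size - 1)))


def summarize_fmi(fmis) -> tuple[float, float]:
    """Median and interquartile range of per-replicate FMI estimates."""
    vals = np.asarray(fmis, dtype=float)
    if vals.size < 1:
        raise ValueError("summarize_fmi needs at least 1 value")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # type-7 linear
    return float(med), float(q3 - q1)


def pct_se_reduction(se_cca: float, se_mi: float) -> float:
    """Percentage reduction in empirical SE of MI relative to CCA."""
    if se_cca <= 0.0:
        raise ValueError(f"CCA empirical SE must be positive; got {se_cca}")
    return 100.0 * (se_cca - se_mi) / se_cca


def pct_bias_reduction(bias_cca: float, bias_mi: float) -> float:
    """Percentage reduction in absolute bias of MI relative to CCA.

    Negative values mean MI is more biased than CCA.  A zero CCA bias leaves
    the ratio undefined; NaN is returned with a warning.
    """
    if bias_cca == 0.0:
        warnings.warn("CCA bias is exactly 0; percentage reduction is undefined",
                      stacklevel=2)
        return float("nan")
    return 100.0 * (abs(bias_cca) - abs(bias_mi)) / abs(bias_cca)


@dataclass
class ScenarioResult:
    """Per-replicate records for one (mechanism, p, imputation model) cell.

    MI and CCA arrays are index-aligned: entry i of each comes from the same
    simulated and masked data set, so between-method comparisons are paired.
    Each record holds the pooled (or complete-case) estimate, its model-based
    SE and, for MI, the df-adjusted FMI — per analysis-model coefficient.
    """

    mechanism: str
    p: float
    model_label: str
    mi_estimates: np.ndarray    # (n_sim, 2): intercept, slope
    mi_se: np.ndarray           # (n_sim, 2)
    mi_fmi: np.ndarray          # (n_sim, 2)
    mi_df: np.ndarray           # (n_sim, 2)
    cca_estimates: np.ndarray   # (n_sim, 2)
    cca_se: np.ndarray          # (n_sim, 2)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.mi_estimates, self.mi_se, self.mi_fmi,
                                    self.mi_df, self.cca_estimates, self.cca_se)}
        if len(shapes) != 1:
            raise ValueError(f"replicate arrays disagree in shape: {shapes}")
        if self.n_sim < 2:
            raise ValueError("a scenario needs at least 2 replicates")

    @property
    def n_sim(self) -> int:
        return self.mi_estimates.shape[0]


@dataclass
class PerformanceTable:
    """Tidy per-scenario summaries with CSV export in two layouts."""

    frame: pd.DataFrame

    def to_tidy_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_wide_csv(self, path) -> None:
        """Layout mirroring the percentage-reduction summary table: one row
        per (p, model), reduction columns split by mechanism."""
        slope = self.frame[self.frame["coefficient"] == "slope"]
        wide = slope.pivot_table(
            index=["p", "model"], columns="mechanism",
            values=["pct_se_reduction", "pct_bias_reduction"],
        )
        wide.columns = [f"{metric}_{mech}" for metric, mech in wide.columns]
        wide.reset_index().to_csv(path, index=False)


def _summarize_cell(res: ScenarioResult) -> list[dict]:
    rows = []
    for c, coef in enumerate(("intercept", "slope")):
        truth = TRUE_COEFFICIENTS[coef]
        bias_mi, bias_mi_mcse = bias(res.mi_estimates[:, c], truth)
        bias_cca, bias_cca_mcse = bias(res.cca_estimates[:, c], truth)
        se_mi, se_mi_mcse = empirical_se(res.mi_estimates[:, c])
        se_cca, se_cca_mcse = empirical_se(res.cca_estimates[:, c])
        fmi_med, fmi_iqr = summarize_fmi(res.mi_fmi[:, c])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bias_red = pct_bias_reduction(bias_cca, bias_mi)
        rows.append({
            "mechanism": res.mechanism,
            "p": res.p,
            "model": res.model_label,
            "coefficient": coef,
            "n_sim": res.n_sim,
            "bias": bias_mi,
            "bias_mcse": bias_mi_mcse,
            "emp_se": se_mi,
            "emp_se_mcse": se_mi_mcse,
            "fmi_median": fmi_med,
            "fmi_iqr": fmi_iqr,
            "cca_bias": bias_cca,
            "cca_bias_mcse": bias_cca_mcse,
            "cca_emp_se": se_cca,
            "cca_emp_se_mcse": se_cca_mcse,
            "pct_se_reduction": pct_se_reduction(se_cca, se_mi),
            "pct_bias_reduction": bias_red,
        })
    return rows


def summarize_scenarios(results: list[ScenarioResult]) -> PerformanceTable:
    """Reduce per-replicate records to the scenario-level performance table."""
    rows: list[dict] = []
    for res in results:
        rows.extend(_summarize_cell(res))
    return PerformanceTable(frame=pd.DataFrame(rows))
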