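"""Configuration-driven orchestration of the simulation grid.

A study is a grid of cells (missingness mechanism x target proportion).
Within a cell, every replicate simulates one cohort, imposes missingness,
runs the complete-case analysis, and then — on the *same* masked data set —
runs every requested imputation model, so all between-model and MI-vs-CCA
comparisons are paired.

Seeding is index-derived, not stream-order-derived: each (cell, replicate,
stage) triple maps to its own seed through ``numpy.random.SeedSequence``, so
results are identical whether cells run serially, in any order, or in
parallel, and any single cell of the results grid can be recomputed in
isolation.  The per-replicate seeds are written to the archive as a ledger.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import CorrelationSpec, simulate_cohort
from .imputation import CANONICAL_MODELS, ImputationModelSpec, impute_stack
from .missingness import (CANONICAL_PROPORTIONS, MissingnessScenario, apply_mar,
                          apply_mcar)
from .performance import PerformanceTable, ScenarioResult, summarize_scenarios
from .pooling import fit_analysis_model, pool_imputed_stack

__all__ = ["StudyConfig", "StudyResult", "run_study", "replicate_seed"]

logger = logging.getLogger("fmisim")

_MECHANISM_CODE = {"MCAR": 0, "MAR": 1}
_STAGE_COHORT = 0
_STAGE_MASK = 1
_STAGE_IMPUTE = 2


@dataclass(frozen=True)
class StudyConfig:
    """Full description of one simulation study run."""

    master_seed: int = 0
    n_sim: int = 1000
    n: int = 1000
    m: int = 1000
    proportions: tuple[float, ...] = CANONICAL_PROPORTIONS
    mechanisms: tuple[str, ...] = ("MCAR", "MAR")
    models: tuple[ImputationModelSpec, ...] = ()
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "proportions", tuple(float(p) for p in self.proportions))
        object.__setattr__(self, "mechanisms", tuple(self.mechanisms))
        if not self.models:
            object.__setattr__(self, "models", tuple(
                ImputationModelSpec.canonical(lbl, m=self.m)
                for lbl in CANONICAL_MODELS
            ))
        if min(self.n_sim, self.n, self.m) < 2:
            raise ValueError("n_sim, n and m must all be at least 2")
        if any(not (0.0 < p < 1.0) for p in self.proportions):
            raise ValueError(f"proportions must lie in (0, 1); got {self.proportions}")
        unknown = set(self.mechanisms) - set(_MECHANISM_CODE)
        if unknown:
            raise ValueError(f"unknown mechanisms {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        models = []
        for entry in raw.pop("models", list(CANONICAL_MODELS)):
            if isinstance(entry, dict):
                models.append(ImputationModelSpec(
                    label=str(entry["label"]),
                    predictors=tuple(entry["predictors"]),
                    m=int(entry.get("m", raw.get("m", 1000))),
                ))
            else:
                models.append(ImputationModelSpec.canonical(
                    str(entry), m=int(raw.get("m", 1000))))
        out_dir = raw.pop("output_dir", None)
        return cls(models=tuple(models),
                   output_dir=Path(out_dir) if out_dir else None,
                   **{k: v for k, v in raw.items()})

    def to_yaml(self, path) -> None:
        payload = {
            "master_seed": self.master_seed,
            "n_sim": self.n_sim,
            "n": self.n,
            "m": self.m,
            "proportions": list(self.proportions),
            "mechanisms": list(self.mechanisms),
            "models": [{"label": s.label, "predictors": list(s.predictors),
                        "m": s.m} for s in self.models],
            "output_dir": str(self.output_dir) if self.output_dir else None,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class StudyResult:
    config: StudyConfig
    scenarios: list[ScenarioResult]
    archive: pd.DataFrame
    summary: PerformanceTable


def replicate_seed(master_seed: int, mechanism: str, p: float, replicate: int,
                   stage: int, model_label: str | None = None) -> int:
    """Deterministic seed for one stage of one replicate of one cell."""
    entropy = [int(master_seed), _MECHANISM_CODE[mechanism],
               int(round(p * 10_000)), int(replicate), int(stage)]
    if model_label is not None:
        entropy.append(zlib.crc32(model_label.encode()))
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _run_cell(config: StudyConfig, mechanism: str, p: float,
              spec: CorrelationSpec) -> tuple[list[ScenarioResult], list[dict]]:
    scenario = MissingnessScenario(mechanism=mechanism, target_proportion=p)
    if mechanism == "MAR":
        scenario = scenario.calibrated()

    n_sim = config.n_sim
    models = config.models
    mi_est = {s.label: np.empty((n_sim, 2)) for s in models}
    mi_se = {s.label: np.empty((n_sim, 2)) for s in models}
    mi_fmi = {s.label: np.empty((n_sim, 2)) for s in models}
    mi_df = {s.label: np.empty((n_sim, 2)) for s in models}
    cca_est = np.empty((n_sim, 2))
    cca_se = np.empty((n_sim, 2))
    seed_rows: list[dict] = []

    for rep in range(n_sim):
        cohort_seed = replicate_seed(config.master_seed, mechanism, p, rep,
                                     _STAGE_COHORT)
        mask_seed = replicate_seed(config.master_seed, mechanism, p, rep,
                                   _STAGE_MASK)
        cohort = simulate_cohort(spec, seed=cohort_seed)
        if mechanism == "MCAR":
            masked = apply_mcar(cohort, p)
        else:
            masked = apply_mar(cohort, scenario, seed=mask_seed)

        cca = fit_analysis_model(masked, complete_rows_only=True)
        cca_est[rep] = cca.coefficients
        cca_se[rep] = np.sqrt(cca.variances)

        seed_row = {"mechanism": mechanism, "p": p, "replicate": rep,
                    "cohort_seed": cohort_seed, "mask_seed": mask_seed}
        for model in models:
            imp_seed = replicate_seed(config.master_seed, mechanism, p, rep,
                                      _STAGE_IMPUTE, model.label)
            stack = impute_stack(masked, model, seed=imp_seed)
            pooled = pool_imputed_stack(stack)
            for c, coef in enumerate(("intercept", "slope")):
                pc = pooled[coef]
                mi_est[model.label][rep, c] = pc.estimate
                mi_se[model.label][rep, c] = pc.se
                mi_fmi[model.label][rep, c] = pc.fmi_adjusted
                mi_df[model.label][rep, c] = pc.df
            seed_row[f"imputation_seed_model_{model.label}"] = imp_seed
        seed_rows.append(seed_row)

    results = [
        ScenarioResult(mechanism=mechanism, p=p, model_label=s.label,
                       mi_estimates=mi_est[s.label], mi_se=mi_se[s.label],
                       mi_fmi=mi_fmi[s.label], mi_df=mi_df[s.label],
                       cca_estimates=cca_est, cca_se=cca_se)
        for s in models
    ]
    return results, seed_rows


def _archive_frame(results: list[ScenarioResult],
                   seed_rows: list[dict]) -> pd.DataFrame:
    """Long-format per-replicate archive with the seed ledger merged in."""
    frames = []
    for res in results:
        n = res.n_sim
        for c, coef in enumerate(("intercept", "slope")):
            frames.append(pd.DataFrame({
                "mechanism": res.mechanism, "p": res.p,
                "model": res.model_label, "method": "MI",
                "replicate": np.arange(n), "coefficient": coef,
                "estimate": res.mi_estimates[:, c], "se": res.mi_se[:, c],
                "fmi": res.mi_fmi[:, c], "df": res.mi_df[:, c],
            }))
    # CCA rows: emit once per (mechanism, p) cell (identical across models)
    seen = set()
    for res in results:
        key = (res.mechanism, res.p)
        if key in seen:
            continue
        seen.add(key)
        n = res.n_sim
        for c, coef in enumerate(("intercept", "slope")):
            frames.append(pd.DataFrame({
                "mechanism": res.mechanism, "p": res.p,
                "model": "CCA", "method": "CCA",
                "replicate": np.arange(n), "coefficient": coef,
                "estimate": res.cca_estimates[:, c], "se": res.cca_se[:, c],
                "fmi": np.nan, "df": np.nan,
            }))
    archive = pd.concat(frames, ignore_index=True)
    seeds = pd.DataFrame(seed_rows)
    return archive.merge(seeds, on=["mechanism", "p", "replicate"], how="left")


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full scenario grid described by ``config``.

    A failure inside one (mechanism, p) cell is logged and skipped; the
    remaining cells still run.  Outputs are written to ``config.output_dir``
    when set: the per-replicate archive, tidy and wide summary tables, and an
    echo of the configuration.
    """
    spec = CorrelationSpec(n=config.n)
    all_results: list[ScenarioResult] = []
    all_seed_rows: list[dict] = []
    for mechanism in config.mechanisms:
        for p in config.proportions:
            t0 = time.perf_counter()
            try:
                results, seed_rows = _run_cell(config, mechanism, p, spec)
            except Exception:
                logger.exception("cell (%s, p=%.2f) failed; continuing", mechanism, p)
                continue
            all_results.extend(results)
            all_seed_rows.extend(seed_rows)
            logger.info("cell (%s, p=%.2f): %d replicates x %d models in %.1fs",
                        mechanism, p, config.n_sim, len(config.models),
                        time.perf_counter() - t0)

    archive = _archive_frame(all_results, all_seed_rows)
    summary = summarize_scenarios(all_results)
    result = StudyResult(config=config, scenarios=all_results,
                         archive=archive, summary=summary)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        archive.to_csv(out / "archive.csv", index=False)
        summary.to_tidy_csv(out / "summary_tidy.csv")
        summary.to_wide_csv(out / "summary_wide.csv")
        config.to_yaml(out / "config_used.yaml")
    return result
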