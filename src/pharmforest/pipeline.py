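"""One-command orchestration of the full mining framework.

Stages: parse/match (or synthesize) the study -> three-step predictor
reduction -> per-compound loop {drop missing AUCs, fit forest, stability
check, OOB concordance, permutation importance with z-tests} -> per-drug
missingness QC -> Reports 1 and 2 -> candidate-pair screen and interaction
ANOVAs.  All artifacts are written as CSV/JSON plus a provenance record
(parameters, seeds, library versions, per-stage counts, wall time).

Defaults equal the reference analysis settings: minimum alteration
proportion 0.05, redundancy correlation 0.95, B = 500 trees, m = one third
of the predictors, CCC report threshold 20, significance level 0.005,
candidate-pair AUC tolerance 0.02.  Per-drug forests get seeds derived as
``seed + drug index`` so adding or removing drugs does not shift the other
models.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (
    AlterationMatrix,
    DriverGeneSet,
    MatchedStudy,
    ResponseMatrix,
    load_driver_genes,
    match_cell_lines,
    parse_alteration_gct,
    parse_response_table,
)
from .evaluation import evaluate_concordance
from .forest import drop_missing, fit_forest, stability_indicator
from .importance import ImportanceTable, importance_test, permutation_importance
from .interactions import (
    CandidatePair,
    InteractionResult,
    candidate_pairs,
    interaction_anova,
    pair_long_table,
)
from .qc import missingness_table
from .reduction import ClusterMap, ReductionResult, reduce_predictors
from .reporting import DrugModelResult, build_report1, build_report2, write_text_table
from .synthetic import SyntheticConfig, SyntheticTruth, demo_config, driver_gene_set, make_study

__all__ = ["RunConfig", "RunResult", "PipelineError", "run_pipeline",
           "rebuild_reports", "retest_pair"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending unit."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    alterations_path: str | None = None
    responses_path: str | None = None
    drivers_path: str | None = None
    synthetic: SyntheticConfig | None = None
    min_proportion: float = 0.05
    min_correlation: float = 0.95
    n_trees: int = 500
    m: int | str = "one-third"
    seed: int = 0
    ccc_threshold: float = 20.0
    alpha: float = 0.005
    auc_tolerance: float = 0.02
    ci_level: float = 0.95
    stability_window: int = 10
    min_samples_leaf: int = 5
    output_dir: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.min_proportion <= 0.5:
            raise ValueError(
                "infeasible threshold: min_proportion must be in (0, 0.5], "
                f"got {self.min_proportion}"
            )
        if not 0.0 < self.min_correlation < 1.0:
            raise ValueError(f"min_correlation outside (0, 1): {self.min_correlation}")
        if self.synthetic is None and not (
            self.alterations_path and self.responses_path and self.drivers_path
        ):
            raise ValueError(
                "provide either a synthetic config or all three input paths"
            )


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    config: RunConfig
    study: MatchedStudy
    truth: SyntheticTruth | None
    reduction: ReductionResult
    drug_results: list[DrugModelResult]
    qc: pd.DataFrame
    report1: pd.DataFrame
    report2: pd.DataFrame
    candidates: list[CandidatePair]
    interactions: list[InteractionResult]
    provenance: dict


def _stage(name: str, unit: str | None = None):
    where = f"stage {name}" + (f" / {unit}" if unit else "")

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"{where}: {exc}") from exc
            return False

    return _ctx()


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and (optionally) write artifacts to disk."""
    t0 = time.time()
    config.validate()

    truth: SyntheticTruth | None = None
    with _stage("data_io"):
        if config.synthetic is not None:
            study, truth = make_study(config.synthetic, config.seed)
            drivers = driver_gene_set(truth)
        else:
            alt = parse_alteration_gct(config.alterations_path)
            resp = parse_response_table(config.responses_path)
            drivers = load_driver_genes(config.drivers_path)
            study = match_cell_lines(alt, resp)

    with _stage("reduction"):
        reduction = reduce_predictors(
            study.alterations,
            drivers,
            min_proportion=config.min_proportion,
            min_correlation=config.min_correlation,
        )
    retained = reduction.retained
    X_all = retained.values.to_numpy()
    feature_names = retained.alterations
    responses = study.responses.values

    drug_results: list[DrugModelResult] = []
    importance_by_compound: dict[str, ImportanceTable] = {}
    for idx, compound in enumerate(responses.columns):
        with _stage("forest", f"drug {compound!r}"):
            y_all = responses[compound].to_numpy()
            y, X, _ = drop_missing(y_all, X_all)
            drug_seed = config.seed + idx
            fit = fit_forest(
                X,
                y,
                B=config.n_trees,
                m=config.m,
                seed=drug_seed,
                min_samples_leaf=config.min_samples_leaf,
                feature_names=feature_names,
            )
            stability = stability_indicator(fit, window=config.stability_window)
            valid = ~np.isnan(fit.oob_pred)
            ccc_result = evaluate_concordance(
                y[valid], fit.oob_pred[valid], level=config.ci_level
            )
        with _stage("importance", f"drug {compound!r}"):
            table = permutation_importance(fit, X, y, seed=config.seed, drug_index=idx)
            table = importance_test(table, alpha=config.alpha)
        importance_by_compound[compound] = table
        drug_results.append(
            DrugModelResult(
                compound=compound,
                ccc=ccc_result,
                mean_auc=float(y.mean()),
                sample_size=int(y.size),
                stability=stability,
                importance=table,
                seed=drug_seed,
            )
        )

    with _stage("qc_missingness"):
        qc = missingness_table(
            retained,
            responses,
            min_proportion=config.min_proportion,
            min_correlation=config.min_correlation,
        )

    with _stage("reporting"):
        report1 = build_report1(drug_results, threshold=config.ccc_threshold)
        report2 = build_report2(report1, importance_by_compound, reduction.clusters)

    with _stage("interactions"):
        pairs = candidate_pairs(
            report1, importance_by_compound, auc_tolerance=config.auc_tolerance
        )
        tested: list[InteractionResult] = []
        for pair in pairs:
            long = pair_long_table(responses, retained, pair)
            tested.append(interaction_anova(long, pair.compound_a, pair.compound_b))

    counts = {
        "cell_lines": study.n_cell_lines,
        "alterations_in": study.alterations.n_alterations,
        "step1_kept": reduction.step1_kept,
        "step2_excluded": reduction.step2_excluded,
        "step3_merged": (reduction.step1_kept - reduction.step2_excluded)
        - reduction.clusters.n_clusters,
        "predictors_entering": retained.n_alterations,
        "n_drugs": len(drug_results),
        "report1_rows": len(report1),
        "report2_rows": len(report2),
        "candidate_pairs": len(pairs),
    }
    import sklearn, scipy, statsmodels  # local: version stamps only

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_proportion": config.min_proportion,
            "min_correlation": config.min_correlation,
            "variance_threshold": reduction.variance_threshold,
            "distance_threshold": reduction.distance_threshold,
            "n_trees": config.n_trees,
            "m": config.m,
            "ccc_threshold": config.ccc_threshold,
            "alpha": config.alpha,
            "auc_tolerance": config.auc_tolerance,
            "ci_level": config.ci_level,
            "stability_window": config.stability_window,
            "min_samples_leaf": config.min_samples_leaf,
        },
        "counts": counts,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "wall_time_s": round(time.time() - t0, 3),
    }

    result = RunResult(
        config=config,
        study=study,
        truth=truth,
        reduction=reduction,
        drug_results=drug_results,
        qc=qc,
        report1=report1,
        report2=report2,
        candidates=pairs,
        interactions=tested,
        provenance=provenance,
    )
    if config.output_dir is not None:
        write_artifacts(result, Path(config.output_dir))
    return result


def write_artifacts(result: RunResult, out: Path) -> None:
    """Serialize every run artifact under ``out``."""
    out = Path(out)
    for sub in ("study", "reduction", "models", "importance", "qc", "reports", "interactions"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    result.study.alterations.to_gct(out / "study" / "alterations.gct")
    result.study.responses.to_csv(out / "study" / "responses.csv")
    result.reduction.retained.values.to_csv(out / "study" / "retained.csv")
    if result.truth is not None:
        (out / "study" / "truth.json").write_text(
            json.dumps(result.truth.to_dict(), indent=2)
        )
        (out / "study" / "drivers.txt").write_text(
            "\n".join(result.truth.driver_genes) + "\n"
        )

    result.reduction.clusters.to_csv(out / "reduction" / "cluster_map.csv")
    (out / "reduction" / "params.json").write_text(
        json.dumps(result.reduction.params(), indent=2)
    )

    for res in result.drug_results:
        name = _safe_name(res.compound)
        (out / "models" / f"{name}.json").write_text(json.dumps(res.to_dict(), indent=2))
        res.importance.to_csv(out / "importance" / f"{name}.csv")

    result.qc.to_csv(out / "qc" / "missingness.csv", index=False)

    result.report1.to_csv(out / "reports" / "report1.csv", index=False)
    result.report2.to_csv(out / "reports" / "report2.csv", index=False)
    write_text_table(result.report1, out / "reports" / "report1.txt")
    write_text_table(result.report2, out / "reports" / "report2.txt")

    for pair, anova in zip(result.candidates, result.interactions):
        stem = f"{_safe_name(pair.compound_a)}__{_safe_name(pair.compound_b)}"
        payload = {**pair.to_dict(), **anova.to_dict()}
        (out / "interactions" / f"{stem}.json").write_text(json.dumps(payload, indent=2))
        anova.group_summaries.to_csv(
            out / "interactions" / f"{stem}_boxplot.csv", index=False
        )

    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))


def _load_cached(run_dir: Path) -> tuple[pd.DataFrame, dict[str, ImportanceTable], ClusterMap, list[DrugModelResult]]:
    from .evaluation import CCCResult
    from .forest import StabilityValue

    run_dir = Path(run_dir)
    clusters = ClusterMap.from_frame(pd.read_csv(run_dir / "reduction" / "cluster_map.csv"))
    results: list[DrugModelResult] = []
    importance_by_compound: dict[str, ImportanceTable] = {}
    for model_file in sorted((run_dir / "models").glob("*.json")):
        info = json.loads(model_file.read_text())
        table = ImportanceTable.from_frame(
            pd.read_csv(run_dir / "importance" / f"{model_file.stem}.csv")
        )
        compound = info["compound"]
        importance_by_compound[compound] = table
        results.append(
            DrugModelResult(
                compound=compound,
                ccc=CCCResult(
                    ccc=info["ccc_ccc"],
                    ci_lower=info["ccc_ci_lower"],
                    ci_upper=info["ccc_ci_upper"],
                    n=info["ccc_n"],
                    label=info["ccc_label"],
                ),
                mean_auc=info["mean_auc"],
                sample_size=info["sample_size"],
                stability=StabilityValue(
                    value=info["stability_value"],
                    window=info["stability_window"],
                    reached=info["stability_reached"],
                ),
                importance=table,
                seed=info["seed"],
            )
        )
    retained = pd.read_csv(run_dir / "study" / "retained.csv", index_col=0)
    return retained, importance_by_compound, clusters, results


def rebuild_reports(run_dir: str | Path, threshold: float = 20.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rebuild Reports 1-2 from a previous run's cached per-drug summaries."""
    _, importance_by_compound, clusters, results = _load_cached(Path(run_dir))
    report1 = build_report1(results, threshold=threshold)
    report2 = build_report2(report1, importance_by_compound, clusters)
    return report1, report2


def retest_pair(
    run_dir: str | Path, compound_a: str, compound_b: str, auc_tolerance: float = np.inf
) -> InteractionResult:
    """Re-run the interaction ANOVA for a named compound pair from cache."""
    run_dir = Path(run_dir)
    retained_df, importance_by_compound, _, results = _load_cached(run_dir)
    responses = pd.read_csv(run_dir / "study" / "responses.csv", index_col=0).T
    by_name = {r.compound: r for r in results}
    for name in (compound_a, compound_b):
        if name not in by_name:
            raise KeyError(f"no cached model for compound {name!r}")
    pair = CandidatePair(
        compound_a=compound_a,
        compound_b=compound_b,
        mean_auc_a=by_name[compound_a].mean_auc,
        mean_auc_b=by_name[compound_b].mean_auc,
        top_alteration_a=importance_by_compound[compound_a].significant_alterations()[0],
        top_alteration_b=importance_by_compound[compound_b].significant_alterations()[0],
    )
    retained = AlterationMatrix(retained_df)
    long = pair_long_table(responses, retained, pair)
    return interaction_anova(long, compound_a, compound_b)


def demo_run_config(seed: int = 0, output_dir: str | None = None, n_trees: int = 500) -> RunConfig:
    """A ready-made synthetic demonstration run."""
    return RunConfig(synthetic=demo_config(), seed=seed, output_dir=output_dir, n_trees=n_trees)
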