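"""End-to-end run orchestration and report rendering.

``run_all`` drives: integrate -> encode -> enumerate -> grid -> best ->
removal importance -> one-feature models, writing a CSV report bundle:

* ``group_summaries.csv``   descriptive means/SEm per EC group (ingestion check)
* ``grid_results.csv``      tidy grid, one row per (dataset, classifier)
* ``best_models.csv``       best model per output
* ``onehot_vs_ma.csv``      one-hot arms vs best MA-encoded model per output
* ``importance.csv``        removal-importance rows for each best model
* ``one_feature.csv``       one-feature model rows for each best model
* ``refined_best.csv``      best model after dropping one noise feature, if any
* ``run_config.yaml``       the archived configuration of the run

Identical config and inputs give byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import datasets, evaluation, importance, study_io

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration of one full run."""

    input_path: str | None = None          # integrated table, or
    bone_path: str | None = None           # bone + serum tables to integrate
    serum_path: str | None = None
    schema: dict | None = None             # column-name map for input files
    combinations: list | None = None       # dataset enumeration override
    outputs: list | None = None
    classifiers: list | None = None
    cv: str = "LOOCV"
    seed: int = 42
    output_dir: str = "bonemetab_report"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def load_input(config: RunConfig) -> pd.DataFrame:
    """Read the modelling table: either a pre-integrated CSV or a bone/serum
    pair joined on (serum_id, animal, treat, period)."""
    if config.input_path:
        return study_io.read_study_table(config.input_path, config.schema)
    if not (config.bone_path and config.serum_path):
        raise FileNotFoundError(
            "config must give input_path, or bone_path and serum_path")
    bone = study_io.read_study_table(config.bone_path, config.schema)
    serum = study_io.read_study_table(config.serum_path, config.schema)
    return study_io.integrate(bone, serum)


def one_hot_comparison(grid: pd.DataFrame) -> pd.DataFrame:
    """Encoding-comparison table: per output, best one-hot-arm score vs best
    MA/metabolic-arm score."""
    rows = []
    onehot = grid[grid["blocks"].str.contains("OneHot")]
    ma = grid[~grid["blocks"].str.contains("OneHot")]
    for output in dict.fromkeys(grid["output"]):
        row = {"output": output}
        for label, part in (("onehot", onehot), ("ma", ma)):
            sub = part[(part["output"] == output) & part["score"].notna()]
            if sub.empty:
                row[f"{label}_score"] = float("nan")
                continue
            best = evaluation.select_best(sub, output)
            row[f"{label}_score"] = best["score"]
            row[f"{label}_blocks"] = best["blocks"]
            row[f"{label}_classifier"] = best["classifier"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline; returns the bundle as DataFrames and writes
    it under ``config.output_dir``. Any stage error aborts with the stage
    name attached."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        if table is None:
            table = load_input(config)
        logger.info("run_all: %d integrated records", len(table))

        stage = "summaries"
        summaries = pd.concat([
            study_io.summarize_groups(table, ["animal", "treat", "period"]),
            study_io.summarize_groups(table, ["animal", "period"]),
        ], ignore_index=True)

        stage = "enumerate"
        specs = datasets.enumerate_datasets(config.combinations, config.outputs)
        logger.info("run_all: %d dataset specs", len(specs))

        stage = "grid"
        grid = evaluation.grid_evaluate(table, specs, config.classifiers,
                                        config.cv, config.seed)

        stage = "best"
        best = evaluation.best_per_output(grid)
        fig2 = one_hot_comparison(grid)

        stage = "importance"
        ablation_rows, onefeat_rows, refined_rows = [], [], []
        for _, row in best.iterrows():
            spec = datasets.DatasetSpec(output=row["output"],
                                        blocks=tuple(row["blocks"].split("+")))
            ds = datasets.assemble(table, spec)
            pool = evaluation.EvalResult(
                spec.dataset_id, spec.output, spec.blocks, row["classifier"],
                row["cv"], row["score"], row["n_features"], row["n_records"])
            abl = importance.importance_by_removal(
                ds, row["classifier"], pool_score=row["score"], seed=config.seed)
            onf = importance.one_feature_models(
                ds, row["classifier"], pool_score=row["score"], seed=config.seed)
            refined = importance.refine_best(pool, abl)
            ablation_rows.append(importance.ablation_frame(abl))
            onefeat_rows.append(importance.one_feature_frame(onf))
            refined_rows.append({
                "output": refined.output, "classifier": refined.family,
                "pool_acc": row["score"], "refined_acc": refined.score,
                "removed_feature": refined.removed_feature or ""})
    except Exception as err:
        raise RuntimeError(f"run_all failed at stage {stage!r}: {err}") from err

    bundle = {
        "table": table,
        "group_summaries": summaries,
        "grid_results": grid,
        "best_models": best,
        "onehot_vs_ma": fig2,
        "importance": pd.concat(ablation_rows, ignore_index=True),
        "one_feature": pd.concat(onefeat_rows, ignore_index=True),
        "refined_best": pd.DataFrame(refined_rows),
    }
    for name, frame in bundle.items():
        if name != "table":
            frame.to_csv(out / f"{name}.csv", index=False)
    config.to_yaml(out / "run_config.yaml")
    return bundle
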