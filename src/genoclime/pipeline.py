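"""End-to-end orchestration: simulate/load → aggregate → index → climate → merge → GxE.

A run is described by a :class:`RunConfig` (YAML- and dict-serialisable).
Each stage writes a plain CSV/JSON artifact stamped with the config hash and
seed, and the final summary collects, per trait column, the moderated
regression in the layout of the study's headline table: coefficients, the
interaction ΔF, the full-model F with its df, and the R² decomposition into
main effects, interaction increment and full model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import aggregation, climate, gene_index, gxe
from .synthetic import SyntheticConfig, simulate_dataset

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``synthetic`` holds generator settings, or the four ``*_path``
    fields point at CSV inputs (sample table, climate extremes, covariates,
    trait means).
    """

    output_dir: str = "genoclime_run"
    synthetic: SyntheticConfig | None = None
    sample_path: str | None = None
    climate_path: str | None = None
    covariate_path: str | None = None
    trait_path: str | None = None
    #: trait columns to analyse mapped to hypothesis direction ("pos"/"neg");
    #: empty = every trait column, direction inferred from the name
    traits: dict = field(default_factory=dict)
    covariates: tuple[str, ...] = ()
    dummies: str | None = None
    bootstrap: int = 0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _infer_direction(trait_column: str) -> str:
    """Avoidance-pole traits get the negative a-priori direction."""
    return "neg" if trait_column.lower().startswith("neuroticism") else "pos"


def _stamp_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index=False, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genoclime config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=index, index_label=index_label)


def _load_tables(cfg: RunConfig):
    if cfg.synthetic is not None:
        ds = simulate_dataset(cfg.synthetic)
        return ds.sample_table, ds.climate_table, ds.covariate_table, ds.trait_table
    tables = []
    for stage, path in (
        ("load_samples", cfg.sample_path),
        ("load_climate", cfg.climate_path),
        ("load_covariates", cfg.covariate_path),
        ("load_traits", cfg.trait_path),
    ):
        if path is None or not Path(path).exists():
            raise PipelineStageError(stage, FileNotFoundError(path))
        try:
            if stage == "load_samples":
                tables.append(aggregation.read_sample_table(path))
            elif stage == "load_climate":
                tables.append(climate.read_climate_table(path))
            else:
                tables.append(pd.read_csv(path, comment="#"))
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineStageError(stage, exc) from exc
    return tuple(tables)


def merge_dataset(
    sample_table: pd.DataFrame,
    climate_table: pd.DataFrame,
    covariate_table: pd.DataFrame | None = None,
    trait_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, "gene_index.GeneIndexResult"]:
    """Aggregate, score and merge tables into one analysis-ready frame.

    Returns the merged per-population frame (dopamine index, climatic
    demand, plus any covariate and trait columns) and the full index result.
    """
    matrix = aggregation.aggregate_samples(sample_table)
    index_result = gene_index.build_gene_index(matrix)
    merged = pd.DataFrame({
        "population_id": index_result.scaled_scores.index,
        "dopamine_raw": index_result.raw_scores.to_numpy(),
        "dopamine_index": index_result.scaled_scores.to_numpy(),
    }).merge(climate.demand_table(climate_table), on="population_id")
    if covariate_table is not None:
        merged = merged.merge(covariate_table, on="population_id")
    if trait_table is not None:
        merged = merged.merge(trait_table, on="population_id")
    return merged, index_result


def analyse_dataset(
    ds,
    trait: str,
    direction: str = "pos",
    covariates=(),
    dummies: str | None = None,
    bootstrap: int = 0,
    bootstrap_seed: int | None = None,
) -> gxe.ModeratedRegressionResult:
    """Run the full estimation chain on a :class:`SyntheticDataset`-like object."""
    merged, _ = merge_dataset(
        ds.sample_table, ds.climate_table, ds.covariate_table, ds.trait_table
    )
    return gxe.fit_moderated(
        merged, y=trait, x="dopamine_index", z="climatic_demand",
        covariates=covariates, dummies=dummies, direction=direction,
        bootstrap=bootstrap, bootstrap_seed=bootstrap_seed,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    sample_table, climate_table, covariate_table, trait_table = _load_tables(cfg)
    if cfg.synthetic is not None:
        _stamp_csv(sample_table, outdir / "sample_table.csv", cfg)
        _stamp_csv(climate_table, outdir / "climate_table.csv", cfg)
        _stamp_csv(covariate_table, outdir / "covariate_table.csv", cfg)
        _stamp_csv(trait_table, outdir / "trait_table.csv", cfg)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(name, exc) from exc

    matrix = stage("aggregate", aggregation.aggregate_samples, sample_table)
    with open(outdir / "population_frequencies.csv", "w") as fh:
        fh.write(f"# genoclime config_hash={stamp['config_hash']} seed={cfg.seed}\n")
        matrix.frequencies.to_csv(fh, index_label="population_id")

    sample_matrix = stage("sample_matrix", aggregation.sample_level_matrix, sample_table)
    index_result = stage("gene_index", gene_index.build_gene_index, matrix, sample_matrix)
    (outdir / "gene_index.json").write_text(
        json.dumps({**stamp, **index_result.report()}, indent=2) + "\n"
    )
    scores = pd.DataFrame({
        "population_id": index_result.raw_scores.index,
        "dopamine_raw": index_result.raw_scores.to_numpy(),
        "dopamine_index": index_result.scaled_scores.to_numpy(),
    })
    _stamp_csv(scores, outdir / "dopamine_index.csv", cfg)

    demand = stage("climate", climate.demand_table, climate_table)
    _stamp_csv(demand, outdir / "climatic_demand.csv", cfg)

    merged = stage(
        "merge",
        lambda: scores.merge(demand, on="population_id")
        .merge(covariate_table, on="population_id")
        .merge(trait_table, on="population_id"),
    )
    _stamp_csv(merged, outdir / "merged.csv", cfg)
    logger.info("merged dataset: %d populations", len(merged))

    trait_cols = cfg.traits or {
        c: _infer_direction(c)
        for c in trait_table.columns
        if c != "population_id"
    }
    summary: dict = {**stamp, "n_populations": len(merged), "models": {}}
    for trait_col, direction in trait_cols.items():
        res = stage(
            f"gxe[{trait_col}]",
            gxe.fit_moderated,
            merged, y=trait_col, x="dopamine_index", z="climatic_demand",
            covariates=cfg.covariates, dummies=cfg.dummies,
            direction=direction, bootstrap=cfg.bootstrap,
            bootstrap_seed=cfg.seed,
        )
        d = res.to_dict()
        d["table"] = {
            "intercept": float(res.terms.loc["const", "estimate"]),
            "dopamine": float(res.terms.loc["dopamine_index", "estimate"]),
            "climatic_stress": float(res.terms.loc["climatic_demand", "estimate"]),
            "dopamine_x_climatic_stress": float(res.terms.loc[res.interaction_term, "estimate"]),
            "dopamine_x_climatic_stress_std": float(res.terms.loc[res.interaction_term, "estimate_std"]),
            "delta_F_interaction": float(res.delta_F),
            "F": float(res.f_full),
            "df": f"{res.f_df[0]}, {res.f_df[1]}",
            "r2_pct_main": 100.0 * res.r2_main,
            "r2_pct_interaction": 100.0 * res.delta_r2,
            "r2_pct_full": 100.0 * res.r2_full,
        }
        summary["models"][trait_col] = d

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
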