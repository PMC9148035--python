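"""Pipeline orchestration: exclusions -> densities -> patterns -> clusters ->
profiling -> adequacy, with per-stage table output and a run manifest.

Every stage writes its result as a delimited text table under the output
directory; a ``manifest.json`` records package version, seed, a hash of the
configuration, and per-stage input/output row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adequacy import build_adequacy_report, load_dri_table
from .clustering import FactorScoreClustering
from .cohort import CohortTable, PATTERN_VARIABLES, RATIO_VARIABLES
from .diet_quality import (
    cluster_index_table,
    group_energy_shares,
    load_default_standards,
    score_cohort,
)
from .group_comparison import compare_across_clusters
from .patterns import NutrientPatternModel
from .preprocessing import apply_exclusions, build_density_matrix
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger("nutripatterns")

STAGES = ("exclusions", "densities", "patterns", "clustering", "profiling", "adequacy")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort_path: str | None = None       # None -> simulate the default cohort
    dri_path: str | None = None
    meddiet_standards: str = "meddiet_standards.yaml"
    hei_standards: str = "hei2010_standards.yaml"
    gi_table: str = "gi_table.yaml"
    out_dir: str = "nutripatterns_run"
    stages: tuple[str, ...] = STAGES
    n_factors: int = 2
    k_clusters: int = 6
    loading_threshold: float = 0.5
    energy_cap: float = 3500.0
    bootstrap_B: int = 500
    n_mc: int = 10_000
    seed: int = 0
    sep: str = ","

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_cohort(path: str | Path, column_map: dict | None = None,
                sep: str = ",") -> CohortTable:
    """Read and validate a participant-level intake table.

    ``column_map`` renames file columns to canonical names
    (e.g. ``{"kcal": "energy_kcal"}``). Negative intakes and missing mapped
    columns raise named validation errors.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        missing = [c for c in column_map if c not in df.columns]
        if missing:
            raise ValueError(f"mapped column(s) absent from {path}: {missing}")
        df = df.rename(columns=column_map)
    if "energy_kcal" not in df.columns:
        raise ValueError(f"{path}: no 'energy_kcal' column after mapping")
    if "participant_id" not in df.columns:
        df.insert(0, "participant_id", np.arange(1, len(df) + 1))
    numeric = df.drop(columns=["participant_id"]).select_dtypes(exclude="number")
    if not numeric.empty:
        raise ValueError(f"{path}: non-numeric cells in columns {list(numeric.columns)}")
    value_cols = [c for c in df.columns
                  if c not in ("participant_id", "cluster_truth")
                  and not c.endswith("_gi")]
    for c in value_cols:
        bad = df.index[df[c] < 0]
        if len(bad):
            raise ValueError(f"{path}: negative value in column '{c}', row {bad[0]}")
    return CohortTable(df, {"source": str(path)})


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure aborts the run with the failing stage named; tables
    written by earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = config.sep
    manifest: dict = {
        "package": "nutripatterns",
        "version": __version__(),
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": asdict(config),
        "delimiter": sep,
        "stages_completed": [],
        "stage_log": {},
    }

    def _finish(stage: str, n_in: int, n_out: int) -> None:
        manifest["stages_completed"].append(stage)
        manifest["stage_log"][stage] = {"rows_in": n_in, "rows_out": n_out}
        logger.info("stage %-11s rows in: %5d  rows out: %5d", stage, n_in, n_out)
        _write_manifest(out, manifest)

    stage = "load"
    try:
        if config.cohort_path is None:
            cohort = generate_cohort(SyntheticConfig(seed=config.seed))
        else:
            cohort = CohortTable.read(config.cohort_path, sep=sep)

        stage = "exclusions"
        if stage in config.stages:
            n_in = len(cohort)
            cohort, excluded = apply_exclusions(cohort, config.energy_cap)
            cohort.write(out / "cohort_included.csv", sep=sep)
            pd.DataFrame({"participant_id": excluded}).to_csv(
                out / "excluded.csv", sep=sep, index=False)
            _finish(stage, n_in, len(cohort))

        stage = "densities"
        density = None
        if stage in config.stages:
            density = build_density_matrix(cohort)
            density.to_csv(out / "densities.csv", sep=sep)
            _finish(stage, len(cohort), len(density))

        stage = "patterns"
        pattern_res = None
        if stage in config.stages:
            if density is None:
                density = build_density_matrix(cohort)
            model = NutrientPatternModel(density, n_factors=config.n_factors,
                                         threshold=config.loading_threshold)
            pattern_res = model.fit()
            pattern_res.loading_table().to_csv(out / "loadings.csv", sep=sep)
            pattern_res.scores.to_csv(out / "factor_scores.csv", sep=sep)
            with open(out / "pattern_diagnostics.json", "w") as fh:
                chi2, dof, pval = pattern_res.bartlett
                json.dump({
                    "kmo": pattern_res.kmo,
                    "bartlett_chi2": chi2, "bartlett_df": dof, "bartlett_p": pval,
                    "variance_explained_pct": list(
                        pattern_res.variance_explained_unrotated[:config.n_factors]),
                }, fh, indent=2)
            _finish(stage, len(density), len(pattern_res.scores))

        stage = "clustering"
        cluster_res = None
        if stage in config.stages:
            if pattern_res is None:
                raise RuntimeError("clustering requires the patterns stage")
            cluster_res = FactorScoreClustering(pattern_res.scores).fit(
                k=config.k_clusters)
            cluster_res.label_table().to_csv(out / "clusters.csv", sep=sep, index=False)
            cluster_res.eta.to_csv(out / "cluster_eta_squared.csv", sep=sep)
            with open(out / "dendrogram.nwk", "w") as fh:
                fh.write(cluster_res.to_newick())
            _finish(stage, len(pattern_res.scores), len(cluster_res.labels))

        stage = "profiling"
        if stage in config.stages:
            if cluster_res is None:
                raise RuntimeError("profiling requires the clustering stage")
            labels = cluster_res.labels
            shares = group_energy_shares(cohort)
            shares.to_csv(out / "group_shares.csv", sep=sep)
            med = shares.copy()
            med["cluster"] = labels
            med.groupby("cluster").median().to_csv(out / "group_shares_by_cluster.csv", sep=sep)

            standards = load_default_standards(
                config.meddiet_standards, config.hei_standards, config.gi_table)
            idx_scores = score_cohort(cohort, standards)
            idx_scores.to_csv(out / "index_scores.csv", sep=sep)
            cluster_index_table(idx_scores, labels).to_csv(
                out / "index_scores_by_cluster.csv", sep=sep)

            comp_rows = []
            for col in idx_scores.columns:
                res = compare_across_clusters(idx_scores[col].to_numpy(), labels)
                comp_rows.append({
                    "variable": col, "test": res.test,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "letters": ";".join(f"{g}={v}" for g, v in res.letters.items()),
                })
            pd.DataFrame(comp_rows).to_csv(out / "index_comparisons.csv",
                                           sep=sep, index=False)
            _finish(stage, len(cohort), len(idx_scores))

        stage = "adequacy"
        if stage in config.stages:
            if cluster_res is None:
                raise RuntimeError("adequacy requires the clustering stage")
            dri = load_dri_table(config.dri_path)
            adequacy = build_adequacy_report(
                cohort, cluster_res.labels, dri,
                B=config.bootstrap_B, seed=config.seed)
            adequacy.report.to_csv(out / "adequacy.csv", sep=sep, index=False)
            _finish(stage, len(cohort), len(adequacy.report))

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def __version__() -> str:
    from . import __version__ as v
    return v
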