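"""End-to-end orchestration: simulate/load -> label -> CV grid -> stability.

A single configuration mapping drives the whole analysis and yields the
familiar summary tables: accuracy and MVAV over a grid of polynomial
degrees x selected-gene counts (correlation mode), an optional
quadratic-with-gene-pairs grid, and an optional pathway-mode row of
settings.  Grid cells where the requested number of gene pairs exceeds
C(k, 2) are rendered as "not applicable" (NaN in the numeric tables).

Every numeric output is a deterministic function of the configuration;
the run manifest records the config echo, seeds, package version, output
paths and per-stage wall-clock so a run can be replayed and checked.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import pandas as pd

from .errors import ConfigError, ParameterError
from .evaluation import CVConfig, run_repeated_cv
from .features import (
    APOPTOSIS_GENES,
    DEFAULT_REGULATORY_PAIRS,
    pathway_feature_set,
    select_top_correlated,
)
from .io import ExpressionMatrix, ensure_log, load_config, read_expression_matrix
from .labeling import DEFAULT_MARKERS, compute_death_probability, exclude_marker_genes
from .simulate import SimulationConfig, simulate_dataset
from .stability import sample_stability_points, stability_report


def _package_version() -> str:
    try:
        return _pkg_version("polyfate")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    """Machine-readable record of one full analysis run."""

    config: dict
    seed: int
    version: str = field(default_factory=_package_version)
    outputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        for name, out in self.outputs.items():
            if not Path(out).exists():
                raise ParameterError(f"manifest output {name} missing: {out}")
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "outputs": self.outputs,
                    "stage_seconds": self.stage_seconds,
                },
                indent=1,
                default=str,
            )
        )


_GRID_DEFAULTS = {
    "degrees": [1, 2, 3],
    "gene_counts": [5, 10, 30, 50, 70],
    "pair_counts": [],
}


def _validate(config: dict) -> dict:
    cfg = {
        "seed": 0,
        "out_dir": "polyfate_run",
        "markers": list(DEFAULT_MARKERS),
        "cv": {},
        "correlation_grid": dict(_GRID_DEFAULTS),
        "pathway_grid": None,
        "stability": {"n_points": 10_000},
        "data": None,
    }
    for key, val in config.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key: {key}")
        if key in ("cv", "correlation_grid", "stability") and val is not None:
            if not isinstance(val, dict):
                raise ConfigError(f"{key}: must be a mapping")
            base = dict(cfg[key])
            for sub, v in val.items():
                if key == "correlation_grid" and sub not in _GRID_DEFAULTS:
                    raise ConfigError(f"correlation_grid.{sub}: unknown key")
                base[sub] = v
            cfg[key] = base
        else:
            cfg[key] = val
    if cfg["data"] is None:
        cfg["data"] = {"simulate": {}}
    if not isinstance(cfg["data"], dict) or not (
        "simulate" in cfg["data"] or "path" in cfg["data"]
    ):
        raise ConfigError("data: needs either 'simulate' settings or a 'path'")
    return cfg


def _load_data(cfg: dict, seed: int) -> ExpressionMatrix:
    data = cfg["data"]
    if "path" in data:
        return read_expression_matrix(
            data["path"],
            orientation=data.get("orientation", "cells_by_genes"),
            group_column=data.get("group_column"),
        )
    sim_kwargs = dict(data["simulate"])
    sim_kwargs.setdefault("seed", seed)
    try:
        sim_cfg = SimulationConfig(**sim_kwargs)
    except TypeError as exc:
        raise ConfigError(f"data.simulate: {exc}") from None
    return simulate_dataset(sim_cfg).matrix


def run_full_analysis(config: dict | str | Path) -> RunManifest:
    """Run the configured analysis grid and write TSV tables + manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _validate(config)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed)

    t0 = time.perf_counter()
    matrix = _load_data(cfg, seed)
    manifest.stage_seconds["data"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    labels = compute_death_probability(matrix, cfg["markers"])
    predictors = ensure_log(exclude_marker_genes(matrix, cfg["markers"]))
    labels_path = out_dir / "labels.tsv"
    pd.DataFrame(
        {
            "cell_id": labels.cell_ids,
            "p_death": labels.p_death,
            "fate_class": labels.fate_class,
        }
    ).to_csv(labels_path, sep="\t", index=False)
    manifest.outputs["labels"] = str(labels_path)
    manifest.stage_seconds["labeling"] = time.perf_counter() - t0

    cv_kwargs = {
        k: int(v) for k, v in cfg["cv"].items() if k in ("n_folds", "n_repeats")
    }
    n_points = int(cfg["stability"]["n_points"])
    grid = cfg["correlation_grid"]
    degrees = [int(d) for d in grid["degrees"]]
    gene_counts = [int(k) for k in grid["gene_counts"]]
    pair_counts = [int(p) for p in grid["pair_counts"]]

    t0 = time.perf_counter()
    acc = pd.DataFrame(index=degrees, columns=gene_counts, dtype=float)
    mvav = pd.DataFrame(index=degrees, columns=gene_counts, dtype=float)
    acc.index.name = mvav.index.name = "degree"
    for k in gene_counts:
        # Reference top-k genes on the full data give the sampling ranges;
        # one shared point set per gene count keeps MVAVs comparable.
        ref = select_top_correlated(predictors, labels, k)
        points = sample_stability_points(predictors, ref.genes, n_points, seed)
        for d in degrees:
            cv = run_repeated_cv(
                predictors,
                labels,
                CVConfig(degree=d, mode="correlation", top_k=k, seed=seed,
                         **cv_kwargs),
            )
            acc.loc[d, k] = cv.mean_accuracy
            mvav.loc[d, k] = stability_report(cv.models, points).mvav
    _write_table(acc, out_dir / "correlation_accuracy.tsv", manifest,
                 "correlation_accuracy")
    _write_table(mvav, out_dir / "correlation_mvav.tsv", manifest,
                 "correlation_mvav")

    if pair_counts:
        pacc = pd.DataFrame(index=pair_counts, columns=gene_counts, dtype=float)
        pmv = pd.DataFrame(index=pair_counts, columns=gene_counts, dtype=float)
        pacc.index.name = pmv.index.name = "n_pairs"
        for k in gene_counts:
            ref = select_top_correlated(predictors, labels, k)
            points = sample_stability_points(predictors, ref.genes, n_points, seed)
            for npair in pair_counts:
                if npair > k * (k - 1) // 2:
                    continue  # "-" cell: too few genes for that many pairs
                cv = run_repeated_cv(
                    predictors,
                    labels,
                    CVConfig(degree=2, mode="correlation", top_k=k,
                             n_pairs=npair, seed=seed, **cv_kwargs),
                )
                pacc.loc[npair, k] = cv.mean_accuracy
                pmv.loc[npair, k] = stability_report(cv.models, points).mvav
        _write_table(pacc, out_dir / "pairs_accuracy.tsv", manifest,
                     "pairs_accuracy")
        _write_table(pmv, out_dir / "pairs_mvav.tsv", manifest, "pairs_mvav")
    manifest.stage_seconds["correlation_grid"] = time.perf_counter() - t0

    if cfg["pathway_grid"]:
        t0 = time.perf_counter()
        pg = cfg["pathway_grid"]
        gene_list = pg.get("genes", list(APOPTOSIS_GENES))
        pairs = [tuple(p) for p in pg.get("pairs", DEFAULT_REGULATORY_PAIRS)]
        settings = pg.get(
            "settings",
            [{"degree": 1}, {"degree": 2},
             {"degree": 2, "cross_terms": True}, {"degree": 3}],
        )
        missing = [g for g in gene_list if g not in predictors.gene_ids]
        if missing:
            raise ConfigError(f"pathway genes absent from data: {missing}")
        points = sample_stability_points(predictors, gene_list, n_points, seed)
        rows = []
        for s in settings:
            fs = pathway_feature_set(
                gene_list, pairs if s.get("cross_terms") else []
            )
            cv = run_repeated_cv(
                predictors,
                labels,
                CVConfig(degree=int(s["degree"]), mode="pathway",
                         pathway_features=fs, seed=seed, **cv_kwargs),
            )
            label = f"{s['degree']}" + (" (cross terms)" if s.get("cross_terms") else "")
            rows.append(
                {
                    "setting": label,
                    "accuracy": cv.mean_accuracy,
                    "mvav": stability_report(cv.models, points).mvav,
                }
            )
        ptab = pd.DataFrame(rows).set_index("setting")
        _write_table(ptab, out_dir / "pathway_results.tsv", manifest,
                     "pathway_results")
        manifest.stage_seconds["pathway_grid"] = time.perf_counter() - t0

    manifest_path = out_dir / "run_manifest.json"
    manifest.save(manifest_path)
    return manifest


def _write_table(
    df: pd.DataFrame, path: Path, manifest: RunManifest, name: str
) -> None:
    df.to_csv(path, sep="\t", na_rep="-")
    manifest.outputs[name] = str(path)
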