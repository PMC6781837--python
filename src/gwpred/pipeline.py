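"""End-to-end experiment: data -> filter -> standardize -> split -> paths ->
evaluation -> model-comparison tables.

The experiment mirrors a standard genomic-prediction benchmark: a leading
block of individuals trains penalized regressions (ridge, LASSO, adaptive
LASSO) over a 100-value penalty path, the trailing block is the hold-out
test set, and each method is scored with the competing statistics (test MSE,
r^2, R^2). The headline diagnostic is ``compare_criteria``: whether r^2
crowns a different winner than MSE/R^2, and how much the top-individual
rankings move when the selection statistic changes.

Within one method's path, the min-MSE and max-R^2 penalties coincide by
identity (R^2 is a monotone transform of MSE for a fixed test set); the
pipeline asserts this. Any disagreement between MSE-best and R^2-best
methods can therefore only arise across methods.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data_io import (
    GenotypeMatrix,
    load_qtlmas_zip,
    make_split,
    maf_filter,
    read_genotypes,
    read_phenotypes,
    standardize,
)
from .evaluation import (
    EvaluationReport,
    ModelSelection,
    RankingTable,
    evaluate_path,
    rank_individuals,
    select_model,
    write_table1,
    write_table2,
)
from .simulate import ArchitectureSpec, SimConfig, simulate
from .solvers import PathResult, alasso_weights, fit_path, lambda_grid

logger = logging.getLogger("gwpred")

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "compare_criteria"]

METHODS = ("RR", "LASSO", "ALASSO")


@dataclass
class ExperimentConfig:
    """Everything needed to rerun one experiment deterministically."""

    # data source: exactly one of (genotypes+phenotypes, zip_path, sim)
    genotypes: str | None = None
    phenotypes: str | None = None
    zip_path: str | None = None
    sim: SimConfig | None = None

    maf: float = 0.01
    train_last: int | None = None  # 1-based; default: ~72% leading block
    stats_from: str = "all"  # "all" reproduces single-matrix standardization
    methods: tuple[str, ...] = METHODS
    criteria: tuple[str, ...] = ("min_mse", "max_r2", "max_R2")
    n_lambda: int = 100
    min_ratio: float | None = None
    tol: float = 1e-7
    max_sweeps: int = 10_000
    weight_mode: str = "inverse"
    top_k: int = 10
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sources = [self.genotypes is not None, self.zip_path is not None,
                   self.sim is not None]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one data source required: genotypes+phenotypes files, "
                "zip_path, or sim"
            )
        if self.genotypes is not None and self.phenotypes is None:
            raise ValueError("phenotypes file required with genotypes file")
        if not self.methods or not self.criteria:
            raise ValueError("need at least one method and one criterion")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")
        if self.stats_from not in ("all", "train"):
            raise ValueError("stats_from must be 'all' or 'train'")

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "architecture" in sim and sim["architecture"] is not None:
                arch = dict(sim["architecture"])
                if "minor_bounds" in arch:
                    arch["minor_bounds"] = tuple(arch["minor_bounds"])
                if "dominance_loci" in arch:
                    arch["dominance_loci"] = tuple(
                        tuple(x) for x in arch["dominance_loci"]
                    )
                sim["architecture"] = ArchitectureSpec(**arch)
            if "generation_sizes" in sim:
                sim["generation_sizes"] = tuple(sim["generation_sizes"])
            raw["sim"] = SimConfig(**sim)
        for key in ("methods", "criteria"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and log
        verbosity excluded, so reruns into different directories match)."""
        d = json.loads(self.to_json())
        d.pop("outdir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    paths: dict[str, PathResult]
    selections: dict[str, dict[str, ModelSelection]]
    table1: dict[str, EvaluationReport]
    table2: dict[str, RankingTable]
    n_markers_after_maf: int
    test_ids: list[str]
    provenance: dict = field(default_factory=dict)


def _load(cfg: ExperimentConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    if cfg.sim is not None:
        out = simulate(cfg.sim)
        return out.genotypes, out.phenotypes
    if cfg.zip_path is not None:
        return load_qtlmas_zip(cfg.zip_path)
    g = read_genotypes(cfg.genotypes)
    y = read_phenotypes(cfg.phenotypes)
    return g, y


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full comparison; deterministic given the config (incl. seed)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    t0 = time.perf_counter()

    def stage(name):
        logger.info("[%7.2fs] %s", time.perf_counter() - t0, name)

    try:
        stage("loading data")
        g, y = _load(cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'load': {exc}") from exc

    stage(f"MAF filter at {cfg.maf}")
    g = maf_filter(g, cfg.maf)

    n = g.n_individuals
    train_last = cfg.train_last if cfg.train_last is not None else int(round(0.72 * n))
    split = make_split(n, train_last)

    stage("standardizing")
    rows = split.train_index if cfg.stats_from == "train" else None
    design = standardize(g, y, stats_from=rows)
    Xtr, ytr = design.X[split.train_index], design.y[split.train_index]
    Xte, yte = design.X[split.test_index], design.y[split.test_index]
    test_ids = [g.individual_ids[i] for i in split.test_index]

    paths: dict[str, PathResult] = {}
    selections: dict[str, dict[str, ModelSelection]] = {}
    for method in cfg.methods:
        stage(f"fitting {method} path ({cfg.n_lambda} lambdas)")
        weights = (
            alasso_weights(Xtr, ytr, mode=cfg.weight_mode)
            if method == "ALASSO"
            else None
        )
        grid = lambda_grid(
            Xtr, ytr, weights=weights, n_lambda=cfg.n_lambda, min_ratio=cfg.min_ratio
        )
        try:
            path = fit_path(
                Xtr, ytr, method, grid, weights=weights,
                tol=cfg.tol, max_sweeps=cfg.max_sweeps,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'fit:{method}': {exc}") from exc
        evaluate_path(path, Xte, yte)
        paths[method] = path
        selections[method] = {
            c: select_model(path, c) for c in cfg.criteria if c != "cp_variant"
        }
        # identity: for a fixed test set, min MSE and max R^2 pick the same lambda
        if "min_mse" in selections[method] and "max_R2" in selections[method]:
            assert (
                selections[method]["min_mse"].best_index
                == selections[method]["max_R2"].best_index
            ), "min-MSE and max-R2 selections diverged on a fixed test set"

    stage("building tables")
    table1: dict[str, EvaluationReport] = {}
    table2: dict[str, RankingTable] = {}
    for method in cfg.methods:
        sel = selections[method]
        sel_mse = sel.get("min_mse") or next(iter(sel.values()))
        sel_r2 = sel.get("max_r2", sel_mse)
        # each statistic is reported at its own path-optimal lambda; the
        # COV/VAR decomposition belongs to the r^2-optimal fit
        table1[method] = EvaluationReport(
            mse=sel_mse.best_report.mse,
            r2_pearson=sel_r2.best_report.r2_pearson,
            r2_determination=sel_mse.best_report.r2_determination,
            cov_y_yhat=sel_r2.best_report.cov_y_yhat,
            var_y=sel_mse.best_report.var_y,
            var_yhat=sel_r2.best_report.var_yhat,
            n_test=sel_mse.best_report.n_test,
        )
        for cname, s in (("min_mse", sel_mse), ("max_r2", sel_r2)):
            yhat = paths[method].predict(Xte)[:, s.best_index]
            table2[f"{method}/{cname}"] = rank_individuals(
                yhat, test_ids, min(cfg.top_k, len(test_ids))
            )

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "gwpred_version": __version__,
        "numpy_version": np.__version__,
        "n_individuals": n,
        "n_markers_after_maf": g.n_markers,
        "train_last": train_last,
    }
    result = ExperimentResult(
        config=cfg,
        paths=paths,
        selections=selections,
        table1=table1,
        table2=table2,
        n_markers_after_maf=g.n_markers,
        test_ids=test_ids,
        provenance=provenance,
    )
    if cfg.outdir:
        _write_reports(result)
    stage("done")
    return result


def _write_reports(res: ExperimentResult) -> None:
    out = Path(res.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"gwpred {__version__}",
        f"config_hash {res.provenance['config_hash']}",
        f"seed {res.config.seed}",
    ]
    write_table1(res.table1, out / "table1.csv", header_lines=header)
    write_table1(
        res.table1, out / "table1_sample_moments.csv",
        header_lines=header, moment_convention="sample",
    )
    write_table2(res.table2, out / "table2.csv", header_lines=header)
    for method, path in res.paths.items():
        with open(out / f"path_{method}.csv", "w") as fh:
            for ln in header:
                fh.write(f"# {ln}\n")
            fh.write("lambda,mse,r2,R2\n")
            for lam, rep in zip(path.grid.values, path.reports):
                fh.write(
                    f"{lam:.10g},{rep.mse:.10g},{rep.r2_pearson:.10g},"
                    f"{rep.r2_determination:.10g}\n"
                )
    with open(out / "provenance.json", "w") as fh:
        json.dump(res.provenance, fh, indent=2, sort_keys=True)
    logger.info("reports written to %s", out)


def compare_criteria(res: ExperimentResult) -> dict:
    """Cross-method winners per criterion and where they disagree.

    Returns the winning method for each criterion (computed from the Table-1
    grid), the criterion pairs whose winners differ, and — per method — the
    top-k overlap between the min-MSE-selected and max-r^2-selected
    individual rankings.
    """
    if len(res.table1) < 2:
        raise ValueError("need at least two methods to compare")
    winners: dict[str, str] = {}
    for crit in res.config.criteria:
        if crit == "cp_variant":
            continue
        key, best = {
            "min_mse": ("mse", min),
            "max_r2": ("r2_pearson", max),
            "max_R2": ("r2_determination", max),
        }[crit]
        winners[crit] = best(res.table1, key=lambda m: getattr(res.table1[m], key))

    crits = list(winners)
    disagreements = [
        (a, b)
        for i, a in enumerate(crits)
        for b in crits[i + 1 :]
        if winners[a] != winners[b]
    ]
    ranking_overlap = {}
    for method in res.config.methods:
        t_mse = res.table2.get(f"{method}/min_mse")
        t_r2 = res.table2.get(f"{method}/max_r2")
        if t_mse is None or t_r2 is None:
            continue
        k = len(t_mse.top_ids)
        ranking_overlap[method] = len(set(t_mse.top_ids) & set(t_r2.top_ids)) / k
    return {
        "winners": winners,
        "disagreements": disagreements,
        "ranking_overlap": ranking_overlap,
    }
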