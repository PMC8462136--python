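"""End-to-end experiment orchestration.

``run_experiment`` takes one configuration (simulate a landscape or load
a lake-table CSV), builds the five response datasets, fits the ten
random-forest SDM variants (five kinds, each with and without the
spatial autocovariate), evaluates discrimination under the three schemes
and functional accuracy, and writes every artifact — lake table, dataset
CSVs, hull WKT, importance/partial-dependence tables, residual Moran's I
diagnostics, the evaluation report, the wedge table and a JSON manifest
— under an output directory. ``replicate_study`` repeats the experiment
across seeds and summarizes the discrimination-vs-functional contrast.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    SCHEMES,
    evaluate_discrimination,
    functional_accuracy,
    suitability_on_table,
    wedge_quantiles,
)
from .landscape import (
    SimulationConfig,
    generate_landscape,
    read_lake_table,
    validate_lake_table,
    write_lake_table,
)
from .models import RFHyper, fit_sdm, partial_dependence, permutation_importance
from .pseudoabsence import KINDS, build_dataset, presence_hull
from .spatial import attach_autocovariate, build_weights, morans_i

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "replicate_study"]


@dataclass
class ExperimentConfig:
    """Full recipe for one experiment run."""

    mode: str = "simulate"                      # "simulate" | "load"
    lake_table_path: str | None = None          # required in load mode
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    kinds: tuple[str, ...] = KINDS
    include_autocov: tuple[bool, ...] = (False, True)
    n_pseudo: int | None = None                 # default: number of true absences
    autocov_radius: str | float = "auto"
    block_side_occurrence: float = 10.0         # landscape units (km)
    block_side_proximal: float = 5.0
    k_folds: int = 5
    cv_iterations: int = 50
    hyper: RFHyper = field(default_factory=RFHyper)
    importance_repeats: int = 10      # 0 skips importance/PDP artifacts
    moran_diagnostics: bool = True
    pdp_covariates: tuple[str, ...] = ("gdd_wtr_10c", "lake_depth", "road_density")
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load":
            if not self.lake_table_path or not Path(self.lake_table_path).exists():
                raise ValueError("load mode requires an existing lake_table_path")
        unknown = set(self.kinds) - set(KINDS)
        if unknown:
            raise ValueError(f"unknown dataset kinds {sorted(unknown)}")

    def block_side(self, kind: str) -> float:
        return self.block_side_proximal if kind == "PO_proximal" else self.block_side_occurrence

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "hyper" in d and isinstance(d["hyper"], dict):
            d["hyper"] = RFHyper(**d["hyper"])
        for key in ("kinds", "include_autocov", "pdp_covariates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentResult:
    report: pd.DataFrame
    wedge: pd.DataFrame
    diagnostics: pd.DataFrame
    out_dir: Path


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Guard:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"experiment stage {name!r} failed: {exc}") from exc
            return False
    return _Guard()


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full comparison and write all artifacts under out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    with _stage("landscape"):
        if config.mode == "simulate":
            sim = replace(config.simulation, seed=config.seed)
            table = generate_landscape(sim)
        else:
            table = read_lake_table(config.lake_table_path)
            validate_lake_table(table, allow_missing_covariates=True)
        write_lake_table(table, out / "lake_table.csv")
        log.info("lake table: %d lakes (%d surveyed)", len(table),
                 int(table["surveyed"].sum()))

    with _stage("datasets"):
        datasets = {}
        for kind in config.kinds:
            ds = build_dataset(
                table, kind, n_pseudo=config.n_pseudo,
                rng=np.random.default_rng(int(rng.integers(2**31))),
            )
            if True in config.include_autocov:
                attach_autocovariate(ds, radius=config.autocov_radius)
            ds.to_csv(out / f"dataset_{kind}.csv")
            datasets[kind] = ds
        if any(k.startswith("PO_") for k in config.kinds):
            (out / "presence_hull.wkt").write_text(presence_hull(table).wkt + "\n")

    report_rows = []
    wedge_rows = []
    with _stage("models_and_evaluation"):
        for kind in config.kinds:
            ds = datasets[kind]
            for ac in config.include_autocov:
                tag = f"{kind}{'_ac' if ac else ''}"
                model_seed = int(rng.integers(2**31))
                if config.importance_repeats > 0:
                    split_model = fit_sdm(ds, include_autocov=ac,
                                          hyper=config.hyper, seed=model_seed)
                    imp = permutation_importance(
                        split_model, n_repeats=config.importance_repeats,
                        rng=np.random.default_rng(int(rng.integers(2**31))),
                    )
                    imp.to_csv(out / f"importance_{tag}.csv", index=False)
                    for cov in config.pdp_covariates:
                        if cov in split_model.feature_names:
                            partial_dependence(split_model, cov).to_csv(
                                out / f"pdp_{tag}_{cov}.csv", index=False
                            )
                row = {"model": kind, "autocov": ac}
                if ds.is_occurrence:
                    for scheme in SCHEMES:
                        m = evaluate_discrimination(
                            ds, scheme,
                            hyper=config.hyper,
                            seed=int(rng.integers(2**31)),
                            n_iterations=config.cv_iterations,
                            block_side=config.block_side(kind),
                            k_folds=config.k_folds,
                            include_autocov=ac,
                        )
                        row[f"auc_{scheme}"] = m.auc
                        row[f"tss_{scheme}"] = m.tss
                        row[f"kappa_{scheme}"] = m.kappa
                    for metric in ("auc", "tss", "kappa"):
                        row[f"{metric}_combined"] = float(
                            np.mean([row[f"{metric}_{s}"] for s in SCHEMES])
                        )
                    full_model = fit_sdm(ds, include_autocov=ac,
                                         hyper=config.hyper, seed=model_seed,
                                         train_fraction=None)
                    fm = functional_accuracy(full_model, table)
                    row.update(r_all=fm.r_all, r_nonzero=fm.r_nonzero,
                               rho_all=fm.rho_all, rho_nonzero=fm.rho_nonzero)
                    surveyed = table[table["surveyed"].astype(bool)]
                    wedge = wedge_quantiles(
                        suitability_on_table(full_model, table),
                        surveyed["freq_occ"].to_numpy(dtype=float),
                    )
                    for tau in wedge.taus:
                        wedge_rows.append({
                            "model": kind, "autocov": ac, "tau": tau,
                            "slope": wedge.slopes[tau],
                            "intercept": wedge.intercepts[tau],
                            "wedge_strength": wedge.wedge_strength,
                        })
                report_rows.append(row)

    with _stage("moran_diagnostics"):
        diag_rows = []
        for kind in ("PA", "ABUNDANCE"):
            if (not config.moran_diagnostics or kind not in datasets
                    or False not in config.include_autocov):
                continue
            ds = datasets[kind]
            full = fit_sdm(ds, include_autocov=False, hyper=config.hyper,
                           seed=int(rng.integers(2**31)), train_fraction=None)
            resid = ds.labels - full.predict(ds.features)
            weights = build_weights(ds.coords, radius=config.autocov_radius)
            res = morans_i(weights, resid, n_perm=999,
                           rng=np.random.default_rng(int(rng.integers(2**31))))
            diag_rows.append({"model": kind, "morans_i": res.I, "p": res.p})
        diagnostics = pd.DataFrame(diag_rows)
        diagnostics.to_csv(out / "moran_residuals.csv", index=False)

    with _stage("report"):
        report = pd.DataFrame(report_rows)
        report.to_csv(out / "evaluation_report.csv", index=False)
        wedge_df = pd.DataFrame(wedge_rows)
        wedge_df.to_csv(out / "wedge_quantiles.csv", index=False)
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "milfoilsdm": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return ExperimentResult(report=report, wedge=wedge_df,
                            diagnostics=diagnostics, out_dir=out)


def replicate_study(
    config: ExperimentConfig, n_seeds: int, seeds: list[int] | None = None
) -> pd.DataFrame:
    """Run the experiment across seeds and summarize the headline contrast.

    Returns the per-seed report rows stacked with a ``seed`` column, plus
    a ``median`` row per (model, autocov) cell; logs the signs of
    AUC(PO_distant) - AUC(PA) and r_all(PA) - r_all(PO_distant) medians
    when both model kinds are present.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    if seeds is None:
        seeds = [int(config.seed + i) for i in range(n_seeds)]
    if len(seeds) != n_seeds:
        raise ValueError("len(seeds) must equal n_seeds")
    frames = []
    for s in seeds:
        cfg = replace(config, seed=int(s),
                      out_dir=str(Path(config.out_dir) / f"seed_{s}"))
        rep = run_experiment(cfg).report.copy()
        rep.insert(0, "seed", s)
        frames.append(rep)
    stacked = pd.concat(frames, ignore_index=True)
    med = (
        stacked.drop(columns=["seed"])
        .groupby(["model", "autocov"], as_index=False)
        .median(numeric_only=True)
    )
    med.insert(0, "seed", "median")
    summary = pd.concat([stacked, med], ignore_index=True)
    try:
        m = med[~med["autocov"].astype(bool)].set_index("model")
        d_auc = m.loc["PO_distant", "auc_combined"] - m.loc["PA", "auc_combined"]
        d_r = m.loc["PA", "r_all"] - m.loc["PO_distant", "r_all"]
        log.info("median AUC(PO_distant) - AUC(PA) = %+.3f; "
                 "median r_all(PA) - r_all(PO_distant) = %+.3f", d_auc, d_r)
    except KeyError:
        pass
    summary.to_csv(Path(config.out_dir) / "replicate_summary.csv", index=False)
    return summary
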