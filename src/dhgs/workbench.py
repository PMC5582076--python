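"""Orchestration: configuration, the end-to-end replay pipeline, provenance.

``replay_pipeline`` sequences the whole study design on one dataset
(simulated by default, or loaded from files): GBS-style masking, call-rate
filtering, mean and EM imputation, within-year and cross-year evaluation of
GBLUP and RKHS under the covariate scenarios, G-by-E-BLUP-trained
prediction, the marker-thinning experiment, and the selection-consistency
profiles.  Every output CSV is accompanied by a provenance JSON (config
hash, seed, library versions).

All randomness flows from the single config seed through named substreams;
two runs with equal config produce byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    CVConfig,
    run_cross_year,
    run_within_year_cv,
    year_table,
)
from .genotypes import (
    MarkerMatrix,
    filter_by_call_rate,
    gaussian_kernel,
    impute_em,
    impute_mean,
    read_genotype_tsv,
    vanraden_grm,
)
from .gxe import fit_gxe_model, run_blup_trained_prediction
from .predictors import ChainConfig, ModelSpec
from .ranking import mean_rank_index, rank_by_gebv, ranking_distance_profile
from .simulate import SimConfig, simulate_population, write_population
from .thinning import run_thinning_experiment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "replay_pipeline"]

DEFAULT_SCENARIOS = (
    {"covariates": (), "covariate_mode": "fixed"},
    {"covariates": ("HD",), "covariate_mode": "fixed"},
    {"covariates": ("HD",), "covariate_mode": "corrector"},
)


@dataclass
class RunConfig:
    """Everything one replay run needs; file paths override simulation."""

    genotype_path: str | None = None
    phenotype_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    call_rate_grid: tuple[float, ...] = (0.25, 0.4, 0.5, 0.6, 0.75)
    imputation_methods: tuple[str, ...] = ("mean", "em")
    h: float = 0.5
    h_grid: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0)
    t_grid: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)
    cv: CVConfig = field(default_factory=CVConfig)
    chain: ChainConfig = field(default_factory=lambda: ChainConfig(3000, 500, 5))
    scenarios: tuple[dict, ...] = DEFAULT_SCENARIOS
    outdir: str = "dhgs_results"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("call_rate_grid", "imputation_methods", "h_grid", "t_grid"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        for p in (self.genotype_path, self.phenotype_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "dhgs": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def _impute(M: MarkerMatrix, method: str) -> MarkerMatrix:
    if method == "mean":
        return impute_mean(M)
    if method == "em":
        return impute_em(M)[0]
    raise ValueError(f"unknown imputation method {method!r}")


def _spec(config: RunConfig, algorithm: str, **kw) -> ModelSpec:
    chain = dataclasses.replace(config.chain, seed=config.seed)
    h = config.h if algorithm == "RKHS" else None
    return ModelSpec(algorithm=algorithm, h=h, chain=chain, **kw)


def replay_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full study design; returns (and writes) the result tables.

    Emits four analogue tables: ``imputation`` (predictive ability by
    call-rate subset x imputation method), ``scenarios`` (within/cross-year
    ability per algorithm and covariate scenario, plus the BLUP-trained
    rows), ``thinning`` (ability and marker counts over the correlation
    threshold grid), and ``ranking`` (cumulative ranking-distance profiles
    for the non-G-by-E and G-by-E model sets).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    results: dict[str, pd.DataFrame] = {}
    try:
        # ------------------------------------------------------------ data
        stage = "data"
        sim = dataclasses.replace(config.sim, seed=config.seed)
        if config.genotype_path and config.phenotype_path:
            masked = read_genotype_tsv(config.genotype_path)
            trials = pd.read_csv(config.phenotype_path, na_values=["NA"])
        else:
            pop, trials, masked = simulate_population(sim)
            write_population(pop, trials, masked, outdir / "data")
        years = sorted(trials["year"].unique())
        tabs = {y: year_table(trials, y) for y in years}

        # ------------------------------------- call-rate x imputation grid
        stage = "imputation-grid"
        imput_rows = []
        imputed_cache: dict[tuple[float, str], MarkerMatrix] = {}
        for rate in config.call_rate_grid:
            filtered = filter_by_call_rate(masked, rate)
            if filtered.n_markers == 0:
                logger.warning("call rate %.2f: no markers retained; skipped", rate)
                continue
            for method in config.imputation_methods:
                Mi = _impute(filtered, method)
                imputed_cache[(rate, method)] = Mi
                for algorithm in ("GBLUP", "RKHS"):
                    spec = _spec(config, algorithm)
                    R = vanraden_grm(Mi) if algorithm == "GBLUP" else gaussian_kernel(Mi, config.h)
                    for y in years:
                        pa = run_within_year_cv(tabs[y], R, spec, config.cv)
                        imput_rows.append(
                            {
                                "year": y,
                                "call_rate": rate,
                                "imputation": method,
                                "algorithm": algorithm,
                                "n_markers": Mi.n_markers,
                                "mean_r": pa.mean_r,
                                "se": pa.se,
                            }
                        )
        results["imputation"] = pd.DataFrame(imput_rows)

        # --- scenario table over the EM-imputed call-rate subsets: the
        # "best" model per kind/target/algorithm is selected over this grid,
        # which is what differentiates the per-year rankings later
        stage = "scenarios"
        from .evaluation import _assemble_holdout  # holdout GEBVs for ranking

        scen_method = "em" if "em" in config.imputation_methods else config.imputation_methods[0]
        subsets = {
            rate: imputed_cache[(rate, scen_method)]
            for rate in config.call_rate_grid
            if (rate, scen_method) in imputed_cache
        }
        scen_rows = []
        gebv_store: dict[tuple, pd.Series] = {}  # (kind, target, algo, label, rate)

        def record(kind, training, target, algorithm, label, rate, n_markers, pa, pred):
            scen_rows.append(
                {
                    "training": training,
                    "target": target,
                    "kind": kind,
                    "algorithm": algorithm,
                    "model": label,
                    "mean_r": pa.mean_r,
                    "se": pa.se,
                    "n_markers": n_markers,
                    "call_rate": rate,
                }
            )
            gebv_store[(kind, target, algorithm, label, rate)] = pred

        for rate, Mi in subsets.items():
            for algorithm in ("GBLUP", "RKHS"):
                R = vanraden_grm(Mi) if algorithm == "GBLUP" else gaussian_kernel(Mi, config.h)
                for scen in config.scenarios:
                    usable = [
                        c
                        for c in scen["covariates"]
                        if all(c in tabs[y] and tabs[y][c].notna().all() for y in years)
                    ]
                    if len(usable) < len(scen["covariates"]):
                        continue  # covariate not scored in some year
                    spec = _spec(config, algorithm, **scen)
                    label = "+".join(scen["covariates"]) or "G"
                    if scen["covariate_mode"] == "corrector" and scen["covariates"]:
                        label += " (corrector)"
                    for y in years:
                        pa = run_within_year_cv(tabs[y], R, spec, config.cv)
                        pred, _ = _assemble_holdout(tabs[y], R, spec, config.cv, rep=0)
                        record("within-year", y, y, algorithm, label, rate, Mi.n_markers, pa, pred)
                        for y2 in years:
                            if y2 == y:
                                continue
                            pa2 = run_cross_year(tabs[y], tabs[y2], R, spec, config.cv)
                            record(
                                "cross-year", y, y2, algorithm, label, rate, Mi.n_markers, pa2, pred
                            )

        # ------------------------------------------------ G x E BLUP rows
        stage = "gxe-blup"
        gxe_fit = fit_gxe_model(trials)
        blup_tab = pd.DataFrame({"y": gxe_fit.line_blups})
        for rate, Mi in subsets.items():
            for algorithm in ("GBLUP", "RKHS"):
                R = vanraden_grm(Mi) if algorithm == "GBLUP" else gaussian_kernel(Mi, config.h)
                spec = _spec(config, algorithm)
                pas = run_blup_trained_prediction(trials, R, spec, config.cv, gxe_fit=gxe_fit)
                pred, _ = _assemble_holdout(blup_tab, R, spec, config.cv, rep=0)
                for y, pa in pas.items():
                    record("gxe-blup", "BLUP", y, algorithm, "G", rate, Mi.n_markers, pa, pred)
        results["scenarios"] = pd.DataFrame(scen_rows)

        # ---------------------------------------------------- thinning
        stage = "thinning"
        scen_df = results["scenarios"]
        best_overall = scen_df.sort_values(["mean_r", "se"], ascending=[False, True]).iloc[0]
        M_thin = subsets[float(best_overall["call_rate"])]
        thin_year = years[0]
        thin_results = run_thinning_experiment(
            tabs[thin_year], M_thin, _spec(config, "GBLUP"), config.cv, config.t_grid
        )
        results["thinning"] = pd.DataFrame(
            {
                "t": [tr.t for tr in thin_results],
                "n_retained": [tr.n_retained for tr in thin_results],
                "mean_r": [tr.predictive.mean_r for tr in thin_results],
                "se": [tr.predictive.se for tr in thin_results],
                "flagged": [tr.flagged for tr in thin_results],
            }
        )

        # --- ranking: per target year, the best model of each kind and
        # algorithm contributes one GEBV ranking; four rankings per year for
        # the non-G-by-E set, two for the G-by-E set
        stage = "ranking"

        def best_pred(kind, target, algorithm) -> pd.Series:
            sub = scen_df[
                (scen_df["kind"] == kind)
                & (scen_df["target"] == target)
                & (scen_df["algorithm"] == algorithm)
            ]
            row = sub.sort_values(["mean_r", "se"], ascending=[False, True]).iloc[0]
            return gebv_store[
                (kind, target, algorithm, str(row["model"]), float(row["call_rate"]))
            ]

        sets = {
            "non-gxe": ("within-year", "cross-year"),
            "gxe": ("gxe-blup",),
        }
        common: set[str] = set.intersection(*(set(s.index) for s in gebv_store.values()))
        order = sorted(common)
        rank_rows = []
        for model_set, kinds in sets.items():
            indices = {}
            for y in years:
                ranks = [
                    rank_by_gebv(best_pred(k, y, a).loc[order])
                    for k in kinds
                    for a in ("GBLUP", "RKHS")
                ]
                indices[y] = mean_rank_index(ranks)
            profile = ranking_distance_profile(indices[years[0]], indices[years[1]])
            profile["model_set"] = model_set
            rank_rows.append(profile)
        results["ranking"] = pd.concat(rank_rows, ignore_index=True)
    except Exception as exc:  # preserve partial outputs, name the failing stage
        _write_results(results, config, outdir, error=f"{stage}: {exc}")
        raise RuntimeError(f"replay pipeline failed at stage {stage!r}: {exc}") from exc
    _write_results(results, config, outdir)
    return results


def _write_results(
    results: dict[str, pd.DataFrame], config: RunConfig, outdir: Path, error: str | None = None
) -> None:
    for name, df in results.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
    prov = _provenance(config)
    if error:
        prov["error"] = error
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))
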