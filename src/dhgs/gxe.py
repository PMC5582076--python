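"""Genotype-by-environment correction via a two-way mixed model.

The two trial years are combined in the plot-level model

    y = year (fixed) + line (random) + year x line (random) + residual

with independent random effects: line effects ~ N(0, I sigma2_l) and
interaction effects ~ N(0, I sigma2_i).  Variance components are estimated
by REML (through statsmodels' mixed linear model); best linear unbiased
predictions (BLUPs) of the random line effects are then computed exactly
from the generalized-least-squares equations at the REML variances.  These
line BLUPs — multi-year means shrunk toward zero according to the variance
components — serve as G-by-E-corrected phenotypes for the genomic
prediction models: the training response carries less year-specific noise
than any single year's observed mean.

Lines without within-year replication confound the interaction with the
plot residual and are excluded before fitting (mirroring the removal of
once-screened lines from the source design).  If no line is replicated,
mean-level data are accepted with a warning and the interaction variance is
reported as zero (it is inestimable at mean level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .evaluation import CVConfig, PredictiveAbility, _assemble_holdout, year_table
from .genotypes import RelationshipMatrix
from .predictors import ModelSpec

__all__ = ["GxEFit", "fit_gxe_model", "run_blup_trained_prediction"]


@dataclass
class GxEFit:
    """REML fit of the year + line + year-x-line model."""

    year_effects: pd.Series  # fixed: intercept + year contrasts
    line_blups: pd.Series  # per retained line
    interaction_blups: pd.DataFrame  # line x year
    var_line: float
    var_interaction: float
    var_residual: float
    excluded_lines: list[str]
    converged: bool


def _blups_from_variances(
    data: pd.DataFrame, var_l: float, var_i: float, var_e: float
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Exact GLS fixed effects and BLUPs at given variance components.

    Dense computation of beta = (X'V^-1 X)^-1 X'V^-1 y,
    l_hat = sigma2_l Zl' V^-1 (y - X beta), and the interaction analogue.
    """
    lines = pd.Categorical(data["line"])
    years = pd.Categorical(data["year"])
    n = len(data)
    Zl = np.zeros((n, len(lines.categories)))
    Zl[np.arange(n), lines.codes] = 1.0
    combo = pd.Categorical(
        data["line"].astype(str) + ":" + data["year"].astype(str)
    )
    Zi = np.zeros((n, len(combo.categories)))
    Zi[np.arange(n), combo.codes] = 1.0
    Xy = np.zeros((n, len(years.categories)))
    Xy[np.arange(n), years.codes] = 1.0
    X = np.column_stack([np.ones(n), Xy[:, 1:]])  # intercept + year contrasts

    V = var_l * (Zl @ Zl.T) + var_i * (Zi @ Zi.T) + (var_e + 1e-10) * np.eye(n)
    Vinv_y = np.linalg.solve(V, data["yield"].to_numpy())
    Vinv_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    resid = data["yield"].to_numpy() - X @ beta
    Vinv_r = np.linalg.solve(V, resid)
    l_hat = var_l * (Zl.T @ Vinv_r)
    i_hat = var_i * (Zi.T @ Vinv_r)
    line_blups = pd.Series(l_hat, index=list(lines.categories), name="blup")
    inter = pd.Series(i_hat, index=list(combo.categories))
    rows = inter.index.str.rsplit(":", n=1)
    inter_df = pd.DataFrame(
        {
            "line": [r[0] for r in rows],
            "year": [r[1] for r in rows],
            "blup": inter.to_numpy(),
        }
    ).pivot(index="line", columns="year", values="blup")
    names = ["intercept"] + [f"year[{c}]" for c in list(years.categories)[1:]]
    return pd.Series(beta, index=names), line_blups, inter_df


def _fit_mixedlm(md):
    """REML fit with optimizer fallbacks (lbfgs can hit singular steps)."""
    last: Exception | None = None
    for method in ("lbfgs", None, "powell"):
        try:
            return md.fit(reml=True, method=method) if method else md.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise RuntimeError(f"mixed-model REML failed with every optimizer: {last}")


def fit_gxe_model(trials: pd.DataFrame) -> GxEFit:
    """REML fit of the two-way model on plot-level two-year data.

    Requires at least two years.  Lines lacking within-year replication are
    excluded (their interaction would be confounded with the plot residual);
    if no line is replicated, per-line-year means are accepted with a
    warning and the interaction variance is fixed at zero.
    """
    data = trials.dropna(subset=["yield"]).copy()
    years = sorted(data["year"].unique())
    if len(years) < 2:
        raise ValueError("the G-by-E model needs at least two years")
    counts = data.groupby(["line", "year"]).size().unstack(fill_value=0)
    replicated = counts[(counts >= 2).all(axis=1)].index
    excluded = [l for l in counts.index if l not in set(replicated)]
    mean_level = False
    if len(replicated) == 0:
        warnings.warn(
            "no line has within-year replication: fitting at mean level; "
            "interaction variance is inestimable and reported as 0",
            RuntimeWarning,
        )
        mean_level = True
        keep = counts[(counts >= 1).all(axis=1)].index
        excluded = [l for l in counts.index if l not in set(keep)]
        data = data[data["line"].isin(keep)]
    else:
        data = data[data["line"].isin(replicated)]
    if data.empty:
        raise ValueError("no usable lines for the G-by-E model")
    data["line"] = data["line"].astype(str)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if mean_level:
            md = smf.mixedlm("Q('yield') ~ C(year)", data, groups="line", re_formula="1")
            res = _fit_mixedlm(md)
            var_l = float(res.cov_re.iloc[0, 0])
            var_i = 0.0
        else:
            md = smf.mixedlm(
                "Q('yield') ~ C(year)",
                data,
                groups="line",
                re_formula="1",
                vc_formula={"gxe": "0 + C(year)"},
            )
            res = _fit_mixedlm(md)
            var_l = float(res.cov_re.iloc[0, 0])
            var_i = float(np.asarray(res.vcomp).ravel()[0])
    var_e = float(res.scale)
    var_l, var_i = max(var_l, 0.0), max(var_i, 0.0)

    year_effects, line_blups, inter = _blups_from_variances(data, var_l, var_i, var_e)
    return GxEFit(
        year_effects=year_effects,
        line_blups=line_blups,
        interaction_blups=inter,
        var_line=var_l,
        var_interaction=var_i,
        var_residual=var_e,
        excluded_lines=excluded,
        converged=bool(getattr(res, "converged", True)),
    )


def run_blup_trained_prediction(
    trials: pd.DataFrame,
    R: RelationshipMatrix,
    spec: ModelSpec,
    cv: CVConfig,
    gxe_fit: GxEFit | None = None,
) -> dict[int, PredictiveAbility]:
    """Genomic prediction trained on G-by-E-corrected line BLUPs.

    The line BLUPs from :func:`fit_gxe_model` are the training response (no
    environmental covariates); GEBVs are assembled through the standard
    k-fold x replicates holdout scheme and scored per replicate against each
    year's observed mean phenotype.  Returns one PredictiveAbility per year.
    """
    fit = gxe_fit or fit_gxe_model(trials)
    lines = [l for l in fit.line_blups.index if l in set(R.line_ids)]
    if not lines:
        raise ValueError("no overlap between BLUP lines and the relationship matrix")
    tab = pd.DataFrame({"y": fit.line_blups.loc[lines]})
    base_spec = ModelSpec(**{**spec.__dict__, "covariates": (), "covariate_mode": "fixed"})
    years = sorted(trials["year"].unique())
    per_rep: dict[int, list[float]] = {y: [] for y in years}
    for rep in range(cv.reps):
        pred, _ = _assemble_holdout(tab, R, base_spec, cv, rep)
        for y in years:
            obs = year_table(trials, y)["y"].reindex(lines)
            ok = obs.notna()
            per_rep[y].append(
                float(np.corrcoef(pred.loc[lines][ok.to_numpy()], obs[ok])[0, 1])
            )
    return {y: PredictiveAbility.from_reps(rs) for y, rs in per_rep.items()}
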