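"""Validation engine: within-year k-fold cross-validation, cross-year
prediction, bandwidth grid search, and rust-covariate preselection.

Predictive ability is the Pearson product-moment correlation between
genomic predictions and observed phenotypes of validation material
(r_GS = r_GEBV,Obs).  The default scheme is 10-fold cross-validation
repeated 5 times with different random foldings; the reported value is the
mean of the per-replicate correlations with its standard error (SD over
replicates / sqrt(reps)).

Cross-year prediction routes the training year through the same k-fold
scheme: per replicate, holdout predictions are assembled for every training
line and correlated with the other year's observed phenotypes, so the
cross-year estimate carries a standard error on the same footing as the
within-year one.  A no-holdout whole-population fit is available as an
alternative (``holdout=False``).

Covariates enter either as fixed effects (the prediction for a validation
line is then x' beta_hat + GEBV) or as phenotype correctors (the response is
the OLS residual of yield on the covariate, with corrector coefficients
estimated on training lines only so validation phenotypes never inform
training).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MarkerMatrix, RelationshipMatrix, gaussian_kernel, vanraden_grm
from .predictors import FitResult, ModelSpec, fit_gblup, fit_rkhs

__all__ = [
    "CVConfig",
    "PredictiveAbility",
    "make_folds",
    "run_within_year_cv",
    "run_cross_year",
    "grid_search_bandwidth",
    "preselect_covariate",
    "year_table",
    "relationship_for_spec",
]

#: candidate rust covariates screened by default (severity/incidence at two
#: time points plus their products)
DEFAULT_RUST_CANDIDATES = ("RS5", "RI5", "RS11", "RI11", "RS5xRI5", "RS11xRI11")


@dataclass
class CVConfig:
    """k-fold cross-validation design: folds, replicates, seed."""

    k: int = 10
    reps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class PredictiveAbility:
    """Mean predictive ability over replicates with its standard error."""

    mean_r: float
    se: float
    per_rep_r: np.ndarray

    @classmethod
    def from_reps(cls, rs: list[float]) -> "PredictiveAbility":
        arr = np.asarray(rs, dtype=float)
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return cls(mean_r=float(arr.mean()), se=se, per_rep_r=arr)


def make_folds(line_ids: list[str], cv: CVConfig, rep_index: int) -> np.ndarray:
    """Assign each line a fold label 0..k-1; deterministic in (seed, rep).

    Folds are disjoint, cover every line, and differ in size by at most one.
    """
    n = len(line_ids)
    if n < cv.k:
        raise ValueError(f"cannot split {n} lines into {cv.k} folds")
    rng = np.random.default_rng(np.random.SeedSequence((cv.seed, 7919, rep_index)))
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    # first (n mod k) folds get the extra line
    sizes = np.full(cv.k, n // cv.k)
    sizes[: n % cv.k] += 1
    start = 0
    for f, s in enumerate(sizes):
        labels[perm[start : start + s]] = f
        start += s
    return labels


def year_table(
    trials: pd.DataFrame, year: int, response: str = "yield"
) -> pd.DataFrame:
    """Per-line means for one year, with rust product covariates added.

    Lines with a single replicate contribute that single observation as
    their phenotype.  Adds RS5xRI5 and RS11xRI11 product columns when both
    factors are present.
    """
    sub = trials[trials["year"] == year]
    if sub.empty:
        raise ValueError(f"no records for year {year}")
    cols = [c for c in (response, "HD", "RS5", "RI5", "RS11", "RI11") if c in sub]
    tab = sub.groupby("line", sort=False)[cols].mean()
    tab = tab.rename(columns={response: "y"})
    for a, b in (("RS5", "RI5"), ("RS11", "RI11")):
        if a in tab and b in tab:
            tab[f"{a}x{b}"] = tab[a] * tab[b]
    return tab


def relationship_for_spec(M: MarkerMatrix, spec: ModelSpec) -> RelationshipMatrix:
    """Build the relationship matrix the model spec calls for (G or K)."""
    if spec.algorithm == "GBLUP":
        return vanraden_grm(M)
    return gaussian_kernel(M, spec.h)


def _fit(y: pd.Series, X, R: RelationshipMatrix, spec: ModelSpec) -> FitResult:
    if spec.algorithm == "GBLUP":
        return fit_gblup(y, X, R)
    return fit_rkhs(y, X, R, spec)


def _prepare_response(
    tab: pd.DataFrame, spec: ModelSpec, train_ids: list[str]
) -> tuple[pd.Series, np.ndarray | None, pd.Series]:
    """Training response, fixed-effect design, and the observed values that
    predictions are scored against.

    Corrector mode fits the corrector OLS on training lines only and applies
    its coefficients to all lines, so validation phenotypes never enter
    training; the scored observation is then the corrected phenotype.
    """
    y_all = tab["y"]
    if not spec.covariates:
        return y_all.loc[train_ids], None, y_all
    missing = [c for c in spec.covariates if c not in tab.columns]
    if missing:
        raise ValueError(f"covariates absent from the phenotype table: {missing}")
    C = tab[list(spec.covariates)].astype(float)
    if C.isna().any().any():
        raise ValueError("covariate values missing for some lines")
    if spec.covariate_mode == "fixed":
        return y_all.loc[train_ids], C.loc[train_ids].to_numpy(), y_all
    # corrector: residualize on training lines, apply coefficients everywhere
    Xtr = np.column_stack([np.ones(len(train_ids)), C.loc[train_ids].to_numpy()])
    beta, *_ = np.linalg.lstsq(Xtr, y_all.loc[train_ids].to_numpy(), rcond=None)
    Xall = np.column_stack([np.ones(len(tab)), C.to_numpy()])
    corrected = pd.Series(y_all.to_numpy() - Xall @ beta, index=tab.index, name="y")
    return corrected.loc[train_ids], None, corrected


def _assemble_holdout(
    tab: pd.DataFrame, R: RelationshipMatrix, spec: ModelSpec, cv: CVConfig, rep: int
) -> tuple[pd.Series, pd.Series]:
    """One replicate of k-fold holdout prediction over every line.

    Returns (predicted score, observed response) aligned on the lines of
    ``tab``; every line is validated exactly once.
    """
    lines = list(tab.index)
    folds = make_folds(lines, cv, rep)
    min_fold = np.bincount(folds, minlength=cv.k).min()
    if min_fold < 3:
        raise ValueError(
            f"fold with {min_fold} validation lines: correlation would be unstable"
        )
    pred = pd.Series(np.nan, index=tab.index, dtype=float)
    obs = pd.Series(np.nan, index=tab.index, dtype=float)
    for f in range(cv.k):
        val_ids = [l for l, lab in zip(lines, folds) if lab == f]
        train_ids = [l for l, lab in zip(lines, folds) if lab != f]
        y_tr, X_tr, scored = _prepare_response(tab, spec, train_ids)
        fit = _fit(y_tr, X_tr, R, spec)
        score = fit.gebv.loc[val_ids].to_numpy().copy()
        if spec.covariates and spec.covariate_mode == "fixed":
            # prediction includes the fixed covariate contribution
            Xv = np.column_stack(
                [np.ones(len(val_ids)), tab.loc[val_ids, list(spec.covariates)].to_numpy()]
            )
            score = score + Xv @ fit.beta_hat
        pred.loc[val_ids] = score
        obs.loc[val_ids] = scored.loc[val_ids].to_numpy()
    return pred, obs


def run_within_year_cv(
    tab: pd.DataFrame,
    R: RelationshipMatrix,
    spec: ModelSpec,
    cv: CVConfig,
) -> PredictiveAbility:
    """Within-year predictive ability by k-fold x replicates holdout.

    ``tab`` is one year's per-line table (from :func:`year_table`).  Per
    replicate, holdout predictions are assembled for all lines and
    correlated with the observed response.
    """
    rs = []
    for rep in range(cv.reps):
        pred, obs = _assemble_holdout(tab, R, spec, cv, rep)
        rs.append(float(np.corrcoef(pred.to_numpy(), obs.to_numpy())[0, 1]))
    return PredictiveAbility.from_reps(rs)


def run_cross_year(
    train_tab: pd.DataFrame,
    test_tab: pd.DataFrame,
    R: RelationshipMatrix,
    spec: ModelSpec,
    cv: CVConfig,
    holdout: bool = True,
) -> PredictiveAbility:
    """Cross-year predictive ability: train on one year, score on the other.

    Holdout GEBVs are assembled on the training year by the same k-fold x
    replicates scheme, then correlated per replicate with the target year's
    observed phenotypes; with ``holdout=False`` a single whole-population
    fit supplies the predictions instead (one pseudo-replicate, se = 0).
    """
    common = [l for l in train_tab.index if l in set(test_tab.index)]
    if not common:
        raise ValueError("training and target years share no lines")
    obs_test = test_tab.loc[common, "y"].to_numpy()
    if not holdout:
        y_tr, X_tr, _ = _prepare_response(train_tab, spec, list(train_tab.index))
        fit = _fit(y_tr, X_tr, R, spec)
        pred = fit.gebv.loc[common].to_numpy().copy()
        if spec.covariates and spec.covariate_mode == "fixed":
            Xv = np.column_stack(
                [np.ones(len(common)), train_tab.loc[common, list(spec.covariates)].to_numpy()]
            )
            pred = pred + Xv @ fit.beta_hat
        r = float(np.corrcoef(pred, obs_test)[0, 1])
        return PredictiveAbility(mean_r=r, se=0.0, per_rep_r=np.array([r]))
    rs = []
    for rep in range(cv.reps):
        pred, _ = _assemble_holdout(train_tab, spec=spec, R=R, cv=cv, rep=rep)
        rs.append(float(np.corrcoef(pred.loc[common].to_numpy(), obs_test)[0, 1]))
    return PredictiveAbility.from_reps(rs)


def grid_search_bandwidth(
    tab: pd.DataFrame,
    M: MarkerMatrix,
    spec: ModelSpec,
    h_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0),
    cv: CVConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Within-year CV profile over the Gaussian-kernel bandwidth grid.

    Returns the bandwidth maximizing mean predictive ability (ties broken
    toward the smaller h) and the full profile.  The default grid spans the
    0.1-1 region where the kernel typically performs best, plus flatter and
    steeper extremes.
    """
    if spec.algorithm != "RKHS":
        raise ValueError("bandwidth search applies to the RKHS model only")
    if len(h_grid) == 0:
        raise ValueError("empty bandwidth grid")
    cv = cv or CVConfig()
    rows = []
    for h in h_grid:
        K = gaussian_kernel(M, h)
        pa = run_within_year_cv(tab, K, ModelSpec(**{**spec.__dict__, "h": h}), cv)
        rows.append({"h": h, "mean_r": pa.mean_r, "se": pa.se})
    profile = pd.DataFrame(rows)
    # ties toward smaller h: stable argmax over the profile sorted by h
    profile = profile.sort_values("h", kind="stable").reset_index(drop=True)
    best = float(profile.loc[profile["mean_r"].idxmax(), "h"])
    return best, profile


def preselect_covariate(
    tab: pd.DataFrame,
    R: RelationshipMatrix,
    spec: ModelSpec,
    candidates: tuple[str, ...] = DEFAULT_RUST_CANDIDATES,
    cv: CVConfig | None = None,
    max_missing: float = 0.1,
) -> tuple[str, pd.DataFrame]:
    """Screen candidate covariates one at a time by within-year CV.

    Each candidate is added singly as a fixed covariate to the base model
    and scored by mean predictive ability; the winner and the full ranking
    are returned.  Ties are broken by candidate order.  Candidates missing
    for more than ``max_missing`` of lines are skipped with a warning.
    """
    cv = cv or CVConfig()
    rows = []
    for c in candidates:
        if c not in tab.columns or tab[c].isna().mean() > max_missing:
            warnings.warn(f"covariate {c!r} unavailable for too many lines; skipped")
            continue
        cand_spec = ModelSpec(
            **{**spec.__dict__, "covariates": (c,), "covariate_mode": "fixed"}
        )
        sub = tab.dropna(subset=[c])
        pa = run_within_year_cv(sub, R, cand_spec, cv)
        rows.append({"covariate": c, "mean_r": pa.mean_r, "se": pa.se})
    if not rows:
        raise ValueError("no usable candidate covariates")
    ranking = pd.DataFrame(rows)
    best = str(ranking.loc[ranking["mean_r"].idxmax(), "covariate"])
    return best, ranking.sort_values("mean_r", ascending=False, kind="stable").reset_index(
        drop=True
    )
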