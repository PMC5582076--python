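"""Correlation-threshold marker thinning and the thinning experiment.

Redundant markers (in high linkage disequilibrium) carry little extra
information for genomic prediction.  Thinning removes markers whose absolute
pairwise Pearson correlation with an already-retained marker reaches a
threshold t, scanning markers greedily in stored order (keep-first):
deterministic, and at t = 1.0 it still removes exact duplicates because the
removal condition is |r| >= t, not a strict inequality.

In the experiment, thinning is decided inside each training fold using the
training lines' genotypes only — validation lines never contribute to the
correlation matrix — and the relationship matrix is rebuilt on the retained
markers before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import CVConfig, PredictiveAbility, make_folds
from .genotypes import MarkerMatrix, RelationshipMatrix, gaussian_kernel, vanraden_grm
from .predictors import ModelSpec, fit_gblup, fit_rkhs

__all__ = ["ThinningResult", "correlation_filter", "run_thinning_experiment"]

DEFAULT_T_GRID = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)


@dataclass
class ThinningResult:
    """Aggregate outcome of the thinning experiment at one threshold."""

    t: float
    n_retained: float  # mean over folds/replicates
    predictive: PredictiveAbility
    flagged: bool = False  # fewer than 10 markers survived in some fold


def correlation_filter(
    M_train: MarkerMatrix | np.ndarray, t: float, corr: np.ndarray | None = None
) -> np.ndarray:
    """Greedy keep-first thinning at absolute-correlation cutoff ``t``.

    Returns the integer indices of retained markers: a marker survives iff
    its absolute Pearson correlation with every earlier-retained marker is
    below ``t`` (removal at |r| >= t).  Zero-variance markers are dropped
    with a warning before correlations are computed.  A precomputed
    correlation matrix may be passed to amortize cost across thresholds.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError(f"threshold t must lie in (0, 1], got {t}")
    V = M_train.values if isinstance(M_train, MarkerMatrix) else np.asarray(M_train, float)
    if np.isnan(V).any():
        raise ValueError("thinning requires a complete (imputed) matrix")
    sd = V.std(axis=0)
    usable = sd > 0
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} zero-variance markers dropped before thinning")
    if corr is None:
        corr = marker_correlations(V[:, usable])
        cols = np.flatnonzero(usable)
    else:
        cols = np.flatnonzero(usable)
        corr = corr[np.ix_(cols, cols)]
    retained: list[int] = []
    # removal at |r| >= t, with a tolerance so that numerically computed
    # perfect correlations (1 - eps) are still removed at t = 1.0
    cut = t - 1e-9
    for j in range(corr.shape[0]):
        if not retained or np.all(np.abs(corr[j, retained]) < cut):
            retained.append(j)
    return cols[retained]


def marker_correlations(V: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix among marker columns (zero-SD safe)."""
    Vc = V - V.mean(axis=0)
    sd = Vc.std(axis=0)
    sd[sd == 0] = 1.0
    Vn = Vc / sd
    return (Vn.T @ Vn) / V.shape[0]


def run_thinning_experiment(
    tab: pd.DataFrame,
    M: MarkerMatrix,
    spec: ModelSpec,
    cv: CVConfig,
    t_grid: tuple[float, ...] = DEFAULT_T_GRID,
) -> list[ThinningResult]:
    """Thinning-versus-predictive-ability profile over a threshold grid.

    For each replicate and fold: compute the training-line correlation
    matrix once, thin at each t, rebuild the relationship matrix on the
    retained markers, fit the model on the training lines, and predict the
    holdout fold.  Per threshold, per-replicate assembled correlations give
    the predictive ability; thresholds leaving fewer than 10 markers in any
    fold are flagged (not an error).
    """
    if not t_grid:
        raise ValueError("empty threshold grid")
    if any(not 0 < t <= 1 for t in t_grid):
        raise ValueError("thresholds must lie in (0, 1]")
    if not M.is_complete():
        raise ValueError("thinning experiment requires imputed genotypes")
    lines = list(tab.index)
    y_all = tab["y"]
    line_pos = {l: i for i, l in enumerate(M.line_ids)}
    per_t_r: dict[float, list[float]] = {t: [] for t in t_grid}
    per_t_n: dict[float, list[int]] = {t: [] for t in t_grid}
    flagged = {t: False for t in t_grid}
    for rep in range(cv.reps):
        folds = make_folds(lines, cv, rep)
        preds: dict[float, pd.Series] = {t: pd.Series(np.nan, index=tab.index) for t in t_grid}
        for f in range(cv.k):
            val_ids = [l for l, lab in zip(lines, folds) if lab == f]
            train_ids = [l for l, lab in zip(lines, folds) if lab != f]
            Vtr = M.values[[line_pos[l] for l in train_ids], :]
            sd = Vtr.std(axis=0)
            usable = np.flatnonzero(sd > 0)
            corr = marker_correlations(Vtr[:, usable])
            y_tr = y_all.loc[train_ids]
            for t in t_grid:
                local = []
                cut = t - 1e-9
                for j in range(corr.shape[0]):
                    if not local or np.all(np.abs(corr[j, local]) < cut):
                        local.append(j)
                keep = usable[local]
                per_t_n[t].append(keep.size)
                if keep.size < 10:
                    flagged[t] = True
                Msub = M.subset_markers(keep)
                R = (
                    vanraden_grm(Msub)
                    if spec.algorithm == "GBLUP"
                    else gaussian_kernel(Msub, spec.h)
                )
                fit = (
                    fit_gblup(y_tr, None, R)
                    if spec.algorithm == "GBLUP"
                    else fit_rkhs(y_tr, None, R, spec)
                )
                preds[t].loc[val_ids] = fit.gebv.loc[val_ids].to_numpy()
        for t in t_grid:
            per_t_r[t].append(
                float(np.corrcoef(preds[t].to_numpy(), y_all.to_numpy())[0, 1])
            )
    return [
        ThinningResult(
            t=t,
            n_retained=float(np.mean(per_t_n[t])),
            predictive=PredictiveAbility.from_reps(per_t_r[t]),
            flagged=flagged[t],
        )
        for t in t_grid
    ]
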