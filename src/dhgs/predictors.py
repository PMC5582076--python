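"""Genomic prediction models: GBLUP by REML and Gaussian-kernel RKHS by Gibbs.

Both models share the linear mixed form ``y = X beta + g + eps`` with a
single genomic random effect.  GBLUP assumes ``g ~ N(0, G sigma2_A)`` with
the VanRaden realized relationship matrix; RKHS regression assumes
``u ~ N(0, K sigma2_u)`` with a Gaussian kernel, which lets the model pick
up non-additive signal.  GBLUP variance components are estimated by exact
restricted maximum likelihood: with a single random effect the restricted
likelihood profiles down to a one-dimensional function of the variance
ratio ``lambda = sigma2_eps / sigma2_A`` once the relationship matrix is
spectrally decomposed, so the optimum is found by scalar minimization (no
iterative mixed-model solver needed).  RKHS is fitted by a conjugate Gibbs
sampler (normal updates for beta and the kernel effects, scaled-inverse
chi-square updates for the variances), matching the Bayesian treatment
customary for kernel regression in genomic selection.

Genomic values for lines without phenotypes are obtained from the kernel
rows: ``g_new = R[new, train] (R[train, train] + lambda I)^(-1) (y - X beta)``
evaluated at the estimated (GBLUP) or posterior-mean (RKHS) variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotypes import RelationshipMatrix

__all__ = [
    "ChainConfig",
    "ModelSpec",
    "FitResult",
    "fit_gblup",
    "fit_rkhs",
    "correct_phenotype",
]

#: diagonal jitter permitted before factorizing a relationship matrix
DIAG_JITTER = 1e-8


@dataclass
class ChainConfig:
    """Gibbs sampler settings for the RKHS model.

    Priors are scaled-inverse-chi-square with ``prior_df`` degrees of
    freedom; the prior scales split the sample variance of the response
    equally between the kernel effect and the residual.  ``fix_variances``
    (sigma2_u, sigma2_eps) freezes the variance components — degenerate
    priors, used for closed-form validation.
    """

    iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    fix_variances: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelSpec:
    """What to fit: algorithm, covariate handling, kernel bandwidth, chain."""

    algorithm: str = "GBLUP"  # "GBLUP" | "RKHS"
    covariates: tuple[str, ...] = ()
    covariate_mode: str = "fixed"  # "fixed" | "corrector"
    h: float | None = None  # Gaussian-kernel bandwidth (RKHS only)
    chain: ChainConfig = field(default_factory=ChainConfig)

    def __post_init__(self) -> None:
        if self.algorithm not in ("GBLUP", "RKHS"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.covariate_mode not in ("fixed", "corrector"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")
        if self.algorithm == "RKHS" and self.h is None:
            raise ValueError("RKHS requires a bandwidth h")
        if self.algorithm == "GBLUP" and self.h is not None:
            raise ValueError("bandwidth h is meaningful only for RKHS")


@dataclass
class FitResult:
    """One model fit: fixed effects, variances, and per-line genomic values."""

    beta_hat: np.ndarray
    gebv: pd.Series  # indexed by line id, covers every line in R
    var_additive: float
    var_residual: float
    loglik_or_posterior: float
    converged: bool
    extras: dict = field(default_factory=dict)

    @property
    def heritability(self) -> float:
        """Realized heritability among the training lines.

        The genetic variance of the sampled lines under g ~ N(0, R s2_A) is
        s2_A * (mean diag R - mean R), not s2_A itself: for fully inbred DH
        material the VanRaden G diagonal is near 2 (inbreeding F = 1), so
        ignoring the scale would halve the apparent genetic variance.
        """
        scale = self.extras.get("g_scale", 1.0)
        var_g = self.var_additive * scale
        tot = var_g + self.var_residual
        return var_g / tot if tot > 0 else 0.0


def _as_series(y) -> pd.Series:
    if not isinstance(y, pd.Series):
        raise TypeError("phenotypes must be a pandas Series indexed by line id")
    return y.astype(float)


def _design(X, train_ids: Sequence[str]) -> np.ndarray:
    """Fixed-effect design for the training lines; None means intercept only."""
    if X is None:
        return np.ones((len(train_ids), 1))
    if isinstance(X, pd.DataFrame):
        Xm = X.loc[list(train_ids)].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
    if Xm.shape[0] != len(train_ids):
        raise ValueError("design matrix rows do not match training lines")
    if not np.all(np.isclose(Xm[:, 0], Xm[0, 0])) or Xm[0, 0] == 0:
        Xm = np.column_stack([np.ones(len(train_ids)), Xm])  # ensure intercept
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("fixed-effect design is singular (collinear columns)")
    return Xm


def _reml_profile(delta: float, d: np.ndarray, Uty: np.ndarray, UtX: np.ndarray):
    """Profiled restricted log-likelihood at variance ratio delta.

    Works in the eigenbasis of the relationship matrix: H = R + delta I has
    eigenvalues d + delta, so weighted least squares and the determinant
    terms are O(n p^2).  Returns (loglik, beta_hat, sigma2_A).
    """
    w = 1.0 / (d + delta)
    XtWX = UtX.T @ (w[:, None] * UtX)
    XtWy = UtX.T @ (w * Uty)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = Uty - UtX @ beta
    n, p = UtX.shape
    rss = float(resid @ (w * resid))
    sigma2_A = rss / (n - p)
    _, logdet_XtWX = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma2_A)
        + np.sum(np.log(d + delta))
        + logdet_XtWX
        + (n - p)
    )
    return ll, beta, sigma2_A


def fit_gblup(
    y: pd.Series,
    X: pd.DataFrame | np.ndarray | None,
    R: RelationshipMatrix,
    ratio_tol: float = 1e-8,
) -> FitResult:
    """Fit GBLUP by exact one-dimensional REML and predict all lines in R.

    ``y`` holds phenotypes for the training lines (its index); GEBVs are
    returned for every line in ``R``, with non-training lines predicted from
    their relationship to the training set.  The variance ratio
    ``delta = sigma2_eps / sigma2_A`` is optimized on a log grid followed by
    bounded scalar refinement, to ``ratio_tol`` on log10(delta).
    """
    y = _as_series(y)
    train_ids = list(y.index)
    missing = set(train_ids) - set(R.line_ids)
    if missing:
        raise ValueError(f"relationship matrix lacks training lines: {sorted(missing)[:5]}")
    idx = R.index_of(train_ids)
    Rtt = R.values[np.ix_(idx, idx)].copy()
    Rtt[np.diag_indices_from(Rtt)] += DIAG_JITTER
    Xm = _design(X, train_ids)
    n, p = Xm.shape
    if n <= p:
        raise ValueError("more fixed effects than training observations")

    d, U = np.linalg.eigh(Rtt)
    d = np.clip(d, 1e-12, None)
    Uty = U.T @ y.to_numpy()
    UtX = U.T @ Xm

    grid = np.linspace(-8.0, 8.0, 33)
    lls = np.array([_reml_profile(10.0**t, d, Uty, UtX)[0] for t in grid])
    if not np.all(np.isfinite(lls)):
        raise RuntimeError(f"REML likelihood non-finite on the search grid: {lls}")
    i = int(np.argmax(lls))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    opt = minimize_scalar(
        lambda t: -_reml_profile(10.0**t, d, Uty, UtX)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": ratio_tol},
    )
    if not opt.success:
        raise RuntimeError(f"REML refinement failed: {opt.message}")
    delta = float(10.0**opt.x)
    ll, beta, sigma2_A = _reml_profile(delta, d, Uty, UtX)
    sigma2_e = delta * sigma2_A

    # GEBVs: R[:, train] (Rtt + delta I)^(-1) (y - X beta); for training rows
    # this equals the mixed-model-equation solution
    resid = y.to_numpy() - Xm @ beta
    alpha = U @ ((U.T @ resid) / (d + delta))
    gebv_all = R.values[:, idx] @ alpha
    gebv = pd.Series(gebv_all, index=R.line_ids, name="gebv")
    return FitResult(
        beta_hat=beta,
        gebv=gebv,
        var_additive=sigma2_A,
        var_residual=sigma2_e,
        loglik_or_posterior=ll,
        converged=True,
        extras={
            "delta": delta,
            "train_ids": train_ids,
            "g_scale": float(np.mean(np.diag(Rtt)) - np.mean(Rtt)),
        },
    )


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def fit_rkhs(
    y: pd.Series,
    X: pd.DataFrame | np.ndarray | None,
    K: RelationshipMatrix,
    spec: ModelSpec | None = None,
) -> FitResult:
    """Fit the single-kernel RKHS model by Gibbs sampling.

    The kernel effect is sampled in the eigenbasis of ``K`` (components with
    negligible eigenvalues dropped), which makes every update conjugate and
    O(n) per sweep.  ``gebv`` holds the posterior mean of ``u`` for training
    lines; unphenotyped lines in ``K`` are extended through the kernel rows
    at the posterior-mean variance components.  Deterministic under
    ``spec.chain.seed``.
    """
    spec = spec or ModelSpec(algorithm="RKHS", h=0.5)
    chain = spec.chain
    y = _as_series(y)
    train_ids = list(y.index)
    missing = set(train_ids) - set(K.line_ids)
    if missing:
        raise ValueError(f"kernel matrix lacks training lines: {sorted(missing)[:5]}")
    idx = K.index_of(train_ids)
    Ktt = K.values[np.ix_(idx, idx)]
    Xm = _design(X, train_ids)
    n, p = Xm.shape
    yv = y.to_numpy()

    d, U = np.linalg.eigh((Ktt + Ktt.T) / 2.0)
    if d.min() < -1e-6 * max(d.max(), 1.0):
        raise ValueError(f"kernel matrix is not PSD (min eigenvalue {d.min():.3e})")
    keep = d > 1e-10 * d.max()
    d, U = d[keep], U[:, keep]
    r = d.size

    XtX = Xm.T @ Xm
    XtX_inv = np.linalg.inv(XtX)
    L_beta = np.linalg.cholesky(XtX_inv)
    UtY = U.T @ yv
    UtX = U.T @ Xm

    vy = float(np.var(yv, ddof=1))
    df0 = chain.prior_df
    S_u = S_e = vy / 2.0
    rng = np.random.default_rng(chain.seed)

    if chain.fix_variances is not None:
        s2u, s2e = map(float, chain.fix_variances)
        if s2u <= 0 or s2e <= 0:
            raise ValueError("fixed variances must be positive")
    else:
        s2u, s2e = S_u, S_e

    b = np.zeros(r)
    beta = XtX_inv @ (Xm.T @ yv)
    n_kept = 0
    total_kept = (chain.iterations - chain.burn_in + chain.thin - 1) // chain.thin
    n_batches = min(25, total_kept)
    batch_size = total_kept // n_batches
    u_batches = np.zeros((n_batches, n))  # batch-means MCSE (autocorrelation-aware)
    u_sum = np.zeros(n)
    u_sumsq = np.zeros(n)
    beta_sum = np.zeros(p)
    s2u_sum = s2e_sum = 0.0
    logpost_sum = 0.0
    for it in range(chain.iterations):
        # beta | b: GLS with iid residuals once the kernel effect is subtracted
        resid_b = yv - U @ b
        mean_beta = XtX_inv @ (Xm.T @ resid_b)
        beta = mean_beta + np.sqrt(s2e) * (L_beta @ rng.standard_normal(p))
        # b | beta: independent normals in the eigenbasis
        ytil = UtY - UtX @ beta
        v = 1.0 / (1.0 / s2e + 1.0 / (d * s2u))
        b = v * ytil / s2e + np.sqrt(v) * rng.standard_normal(r)
        if chain.fix_variances is None:
            s2u = _scaled_inv_chi2(
                rng, df0 + r, (float(b @ (b / d)) + df0 * S_u) / (df0 + r)
            )
            e = yv - Xm @ beta - U @ b
            s2e = _scaled_inv_chi2(
                rng, df0 + n, (float(e @ e) + df0 * S_e) / (df0 + n)
            )
        if not (np.isfinite(s2u) and np.isfinite(s2e) and np.all(np.isfinite(b))):
            raise RuntimeError(f"divergent Gibbs chain at iteration {it}")
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            u = U @ b
            u_batches[min(n_kept // batch_size, n_batches - 1)] += u
            n_kept += 1
            u_sum += u
            u_sumsq += u**2
            beta_sum += beta
            s2u_sum += s2u
            s2e_sum += s2e
            e = yv - Xm @ beta - u
            logpost_sum += -0.5 * (n * np.log(2 * np.pi * s2e) + float(e @ e) / s2e)

    u_mean = u_sum / n_kept
    u_sd = np.sqrt(np.maximum(u_sumsq / n_kept - u_mean**2, 0.0))
    # batch sizes: the last batch absorbs the remainder
    counts = np.full(n_batches, batch_size, dtype=float)
    counts[-1] = n_kept - batch_size * (n_batches - 1)
    bm = u_batches / counts[:, None]
    u_mcse = bm.std(axis=0, ddof=1) / np.sqrt(n_batches) if n_batches > 1 else u_sd
    beta_mean = beta_sum / n_kept
    s2u_hat, s2e_hat = s2u_sum / n_kept, s2e_sum / n_kept

    # extend to unphenotyped lines through the kernel rows at the posterior
    # mean variances (same BLUP formula as GBLUP)
    lam = s2e_hat / s2u_hat
    resid = yv - Xm @ beta_mean
    alpha = U @ ((U.T @ resid) / (d + lam))
    gebv_all = K.values[:, idx] @ alpha
    gebv = pd.Series(gebv_all, index=K.line_ids, name="gebv")
    gebv.loc[train_ids] = u_mean  # posterior mean where the chain sampled it
    return FitResult(
        beta_hat=beta_mean,
        gebv=gebv,
        var_additive=s2u_hat,
        var_residual=s2e_hat,
        loglik_or_posterior=logpost_sum / n_kept,
        converged=True,
        extras={
            "u_mcse": u_mcse,
            "u_sd": u_sd,
            "n_kept": n_kept,
            "g_scale": float(np.mean(np.diag(Ktt)) - np.mean(Ktt)),
            "train_ids": train_ids,
            "h": K.h,
        },
    )


def correct_phenotype(y: pd.Series, covariate: pd.Series) -> pd.Series:
    """Residualize phenotypes on a single covariate by ordinary least squares.

    The residuals (zero mean, zero sample covariance with the covariate)
    serve as corrected phenotypes for downstream genomic prediction.
    """
    y = _as_series(y)
    cov = covariate.reindex(y.index).astype(float)
    if cov.isna().any():
        raise ValueError("covariate missing for some phenotyped lines")
    c = cov.to_numpy()
    if np.ptp(c) == 0:
        raise ValueError("constant covariate is collinear with the intercept")
    Xm = np.column_stack([np.ones(len(c)), c])
    beta, *_ = np.linalg.lstsq(Xm, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - Xm @ beta
    return pd.Series(resid, index=y.index, name=y.name)
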