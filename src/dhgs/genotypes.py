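"""Genotype matrices, quality filtering, imputation, and relationship matrices.

Genotypes are coded -1 (one parental homozygote), 0 (heterozygote), +1 (the
other homozygote), with missing calls stored as NaN.  Doubled-haploid (DH)
material should contain no heterozygotes, but the 0 code is retained for
generality.  Two genomic similarity matrices are supported:

* the VanRaden realized relationship matrix
  ``G = Z Z' / (2 * sum_i p_i (1 - p_i))`` with ``Z = a - 2 (p_i - 0.5)``,
  where ``p_i`` is the frequency of the second allele at locus ``i``; and
* the Gaussian kernel
  ``K(x_j, x_k) = exp(-h * mean_l (x_jl - x_kl)^2)`` with bandwidth ``h``.

Imputed genotypes are kept real-valued on the -1..+1 scale (never re-rounded
to the three codes): both G and K operate on numeric marker values, and
rounding would discard information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "RelationshipMatrix",
    "filter_by_call_rate",
    "impute_mean",
    "impute_em",
    "vanraden_grm",
    "gaussian_kernel",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_vcf",
]


@dataclass
class MarkerMatrix:
    """Lines x markers genotype codes with missingness as NaN."""

    line_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray  # float (n, m); NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def call_rates(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.isnan(self.values).mean(axis=0)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def copy(self) -> "MarkerMatrix":
        return MarkerMatrix(list(self.line_ids), list(self.marker_ids), self.values.copy())

    def subset_markers(self, keep: Sequence[int] | np.ndarray) -> "MarkerMatrix":
        keep = np.asarray(keep)
        return MarkerMatrix(
            list(self.line_ids),
            [self.marker_ids[i] for i in keep],
            self.values[:, keep].copy(),
        )

    def subset_lines(self, ids: Sequence[str]) -> "MarkerMatrix":
        index = {l: i for i, l in enumerate(self.line_ids)}
        rows = np.array([index[l] for l in ids])
        return MarkerMatrix(list(ids), list(self.marker_ids), self.values[rows].copy())


@dataclass
class RelationshipMatrix:
    """n x n genomic similarity among lines (VanRaden G or Gaussian K)."""

    line_ids: list[str]
    values: np.ndarray
    kind: str  # "vanraden-G" | "gaussian-K"
    h: float | None = None  # bandwidth, Gaussian kernel only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square over line_ids")

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        index = {l: i for i, l in enumerate(self.line_ids)}
        return np.array([index[l] for l in ids])


def filter_by_call_rate(M: MarkerMatrix, min_rate: float) -> MarkerMatrix:
    """Retain markers whose call rate is strictly greater than ``min_rate``.

    The comparison is strict (">"), so ties at the threshold are excluded;
    a marker with call rate exactly 0.75 does not survive ``min_rate=0.75``.
    An empty result is allowed (logged, not an error).
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    keep = np.flatnonzero(M.call_rates() > min_rate)
    if keep.size == 0:
        logger.warning("call-rate filter at %.3f retained no markers", min_rate)
    return M.subset_markers(keep)


def impute_mean(M: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing entry by the observed mean of its marker column.

    Observed entries are untouched, so each marker's observed allele
    frequency is preserved exactly.
    """
    V = M.values.copy()
    miss = np.isnan(V)
    if not miss.any():
        return MarkerMatrix(list(M.line_ids), list(M.marker_ids), V)
    n_obs = (~miss).sum(axis=0)
    all_missing = np.flatnonzero(n_obs == 0)
    if all_missing.size:
        raise ValueError(
            f"markers with no observed genotypes: {[M.marker_ids[i] for i in all_missing[:5]]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_means = np.nanmean(V, axis=0)
    V[miss] = np.broadcast_to(col_means, V.shape)[miss]
    return MarkerMatrix(list(M.line_ids), list(M.marker_ids), V)


def impute_em(
    M: MarkerMatrix,
    tol: float = 1e-4,
    max_iter: int = 100,
    ridge: float = 1e-6,
) -> tuple[MarkerMatrix, bool, int]:
    """EM-style multivariate-normal imputation exploiting line relatedness.

    Each marker column is modelled as a draw from an n-variate normal with
    its own marker mean and a common line-by-line covariance (the approach
    taken by relationship-matrix-based EM imputation for GBS data, where
    markers vastly outnumber lines so the n x n covariance is the
    well-conditioned side of the matrix).  Starting from mean imputation,
    the algorithm alternates (i) re-estimating the line covariance from the
    completed matrix across markers with (ii) replacing every missing entry
    by its conditional expectation given the observed genotypes of the
    other lines at the same marker.  In a biparental DH population the line
    covariance encodes shared genome tracts, so close relatives inform each
    other's missing calls — the advantage over plain mean imputation.  A
    line duplicating a complete line is restored essentially exactly.

    Per sweep the n x n covariance is inverted once; each marker column
    then needs only the missing-block precision solve
    ``E[x_mis | x_obs] = mu - P_mm^{-1} P_mo (x_obs - mu)``.

    Returns ``(imputed, converged, n_iter)``.  Non-convergence at
    ``max_iter`` warns and returns the best iterate.
    """
    if M.n_lines < 2:
        raise ValueError("EM imputation needs at least 2 lines")
    miss = np.isnan(M.values)
    if not miss.any():
        return M.copy(), True, 0
    base = impute_mean(M)  # validates all-missing markers, sets start values
    V = base.values
    n, m = V.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(M.values, axis=0)  # fixed per-marker means (observed)
    miss_cols = np.flatnonzero(miss.any(axis=0))
    converged = False
    it = 0
    n_obs_mean = float((~miss).sum(axis=0).mean())
    for it in range(1, max_iter + 1):
        Xc = V - mu  # centered completed matrix
        Sigma = (Xc @ Xc.T) / m
        avg_var = max(float(np.trace(Sigma)) / n, 1e-12)
        # the observed entries of every centered column sum to zero exactly
        # (mu is their own mean), which plants an artificial null direction
        # along 1 that the conditional would exploit ("this line = minus the
        # sum of the others").  Modelling the sampling error of the column
        # means as a common random offset (variance ~ var / n_obs) restores
        # honest variance along that direction.
        Sigma += (avg_var / n_obs_mean) * np.ones((n, n))
        Sigma[np.diag_indices_from(Sigma)] += ridge * avg_var
        P = np.linalg.inv(Sigma)  # precision over lines
        delta = 0.0
        for j in miss_cols:
            mrow = miss[:, j]
            orow = ~mrow
            rhs = P[np.ix_(mrow, orow)] @ (V[orow, j] - mu[j])
            new = mu[j] - np.linalg.solve(P[np.ix_(mrow, mrow)], rhs)
            delta = max(delta, float(np.max(np.abs(new - V[mrow, j]))))
            V[mrow, j] = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM imputation did not converge in {max_iter} iterations "
            f"(returning best iterate)",
            RuntimeWarning,
        )
    return MarkerMatrix(list(M.line_ids), list(M.marker_ids), V), converged, it


def allele_frequencies(M: MarkerMatrix) -> np.ndarray:
    """Frequency p_i of the second (+1) allele at each locus.

    On the -1..+1 scale the mean genotype is 2 p_i - 1, so
    p_i = (mean + 1) / 2.  Works on imputed real-valued matrices.
    """
    if not M.is_complete():
        raise ValueError("allele frequencies require a complete (imputed) matrix")
    return (M.values.mean(axis=0) + 1.0) / 2.0


def vanraden_grm(M: MarkerMatrix, drop_monomorphic: bool = True) -> RelationshipMatrix:
    """VanRaden realized relationship matrix G = ZZ' / (2 sum p_i (1-p_i)).

    ``Z`` has elements ``a - 2 (p_i - 0.5)`` where ``a`` is the marker code
    and ``p_i`` the second-allele frequency computed from all lines in ``M``
    (training plus candidates: genotypes of selection candidates are known at
    prediction time, so no phenotype leakage occurs).  Monomorphic markers
    contribute zero to both numerator and denominator and are dropped.
    """
    if not M.is_complete():
        raise ValueError("G requires a complete (imputed) genotype matrix")
    p = allele_frequencies(M)
    het = 2.0 * p * (1.0 - p)
    if drop_monomorphic:
        poly = het > 0
        if not poly.any():
            raise ValueError("all markers are monomorphic; G undefined")
        p, het = p[poly], het[poly]
        V = M.values[:, poly]
    else:
        V = M.values
    Z = V - 2.0 * (p - 0.5)
    denom = het.sum()
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(list(M.line_ids), G, kind="vanraden-G")


def gaussian_kernel(M: MarkerMatrix, h: float) -> RelationshipMatrix:
    """Gaussian kernel K(j,k) = exp(-h * mean squared genotype difference)."""
    if h < 0:
        raise ValueError(f"bandwidth h must be >= 0, got {h}")
    if not M.is_complete():
        raise ValueError("K requires a complete (imputed) genotype matrix")
    V = M.values
    sq = (V**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
    np.maximum(D2, 0.0, out=D2)
    K = np.exp(-h * D2 / M.n_markers)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return RelationshipMatrix(list(M.line_ids), K, kind="gaussian-K", h=h)


# ---------------------------------------------------------------------------
# I/O: genotype TSV dialect (rows = lines, columns = markers, NA = missing)
# ---------------------------------------------------------------------------

def write_genotype_tsv(M: MarkerMatrix, path: str | Path) -> None:
    df = pd.DataFrame(M.values, index=M.line_ids, columns=M.marker_ids)
    df.index.name = "line"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_genotype_tsv(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return MarkerMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float)
    )


def read_vcf(path: str | Path) -> MarkerMatrix:
    """Read biallelic genotypes from a VCF: 0/0 -> -1, 0/1 -> 0, 1/1 -> +1.

    Requires ``cyvcf2`` (optional dependency).
    """
    from cyvcf2 import VCF  # lazy import: optional extra

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.where(gt == 0, -1.0, np.where(gt == 1, 0.0, np.where(gt == 3, 1.0, np.nan)))
        cols.append(col)
    values = np.column_stack(cols) if cols else np.empty((len(line_ids), 0))
    return MarkerMatrix(line_ids, marker_ids, values)
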