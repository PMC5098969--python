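"""Two-step maximum-likelihood polychoric correlation estimation.

Step 1 fixes per-variable thresholds at the inverse-normal transforms of the
marginal cumulative proportions; step 2 maximizes the multinomial likelihood
of the contingency table over the latent correlation rho, with cell
probabilities given by bivariate-normal rectangle probabilities.  Pairwise
matrices need not be positive semidefinite, so an eigenvalue-clipping repair
is provided and applied by the matrix estimator when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._bvn import bvn_cdf
from .datasets import MISSING, SurveyDataset

__all__ = [
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_matrix",
    "nearest_psd",
    "PolychoricMatrix",
    "PolychoricCorrelation",
]

#: Absolute bound at which pair estimates are clamped and flagged.
RHO_CLAMP = 0.999


def estimate_thresholds(category_counts) -> np.ndarray:
    """Thresholds tau (length K-1) from marginal category counts.

    tau_k = Phi^{-1} of the cumulative proportion through category k; empty
    extreme categories yield -inf/+inf entries, interior empty categories
    repeated thresholds.
    """
    counts = np.asarray(category_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("category counts must have positive total")
    cum = np.cumsum(counts)[:-1] / total
    with np.errstate(divide="ignore"):
        return norm.ppf(cum)


def _table_nll_factory(table: np.ndarray):
    """Return (nll(rho), tau1, tau2) for a contingency table."""
    table = np.asarray(table, dtype=float)
    counts = table.ravel()
    obs = counts > 0
    counts = counts[obs]
    tau1 = estimate_thresholds(table.sum(axis=1))
    tau2 = estimate_thresholds(table.sum(axis=0))
    k1 = table.shape[0]
    k2 = table.shape[1]
    a = np.concatenate([[-np.inf], tau1, [np.inf]])
    b = np.concatenate([[-np.inf], tau2, [np.inf]])
    A = np.repeat(a, k2 + 1)
    B = np.tile(b, k1 + 1)

    def nll(rho: float) -> float:
        C = bvn_cdf(A, B, rho).reshape(k1 + 1, k2 + 1)
        P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
        P = np.clip(P.ravel()[obs], 1e-12, None)
        return -float(counts @ np.log(P))

    return nll, tau1, tau2


def polychoric_pair(table) -> tuple[float, dict]:
    """Two-step ML polychoric correlation from a K1 x K2 contingency table.

    Returns (rho, status) where status records convergence, clamping at
    +/-0.999 and the attained negative log-likelihood.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() <= 0:
        raise ValueError("contingency table is empty")
    if (table.sum(axis=1) > 0).sum() < 2 or (table.sum(axis=0) > 0).sum() < 2:
        raise ValueError(
            "degenerate margin: both variables need >= 2 non-empty categories"
        )
    nll, tau1, tau2 = _table_nll_factory(table)
    res = minimize_scalar(
        nll, bounds=(-RHO_CLAMP, RHO_CLAMP), method="bounded",
        options={"xatol": 1e-5},
    )
    rho = float(res.x)
    clamped = False
    if RHO_CLAMP - abs(rho) < 1e-3:
        # check the bound genuinely dominates before clamping
        if nll(np.sign(rho) * RHO_CLAMP) <= res.fun + 1e-9:
            rho = float(np.sign(rho) * RHO_CLAMP)
            clamped = True
    status = {
        "converged": bool(res.success),
        "clamped": clamped,
        "nll": float(res.fun),
        "tau1": tau1,
        "tau2": tau2,
    }
    return rho, status


@dataclass
class PolychoricMatrix:
    """Estimated latent correlation matrix with per-variable thresholds."""

    rho: np.ndarray
    tau: list
    labels: list[str]
    psd_adjusted: bool = False
    max_adjustment: float = 0.0
    convergence: list = field(default_factory=list)
    degenerate: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.rho.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.labels, columns=self.labels)


def nearest_psd(matrix: np.ndarray, eig_floor: float = 1e-6):
    """Eigenvalue-clipping PSD repair, rescaled to unit diagonal.

    Already-PSD inputs pass through unchanged.  Returns (repaired, max
    elementwise change).
    """
    M = np.asarray(matrix, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    vals, vecs = np.linalg.eigh(M)
    if vals[0] >= 0:
        return M.copy(), 0.0
    clipped = np.clip(vals, eig_floor, None)
    R = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    return R, float(np.abs(R - M).max())


class PolychoricCorrelation(BaseEstimator):
    """Polychoric correlation matrix estimator for ordinal data.

    Parameters
    ----------
    pairwise_complete : bool
        Drop, per pair, the rows where either variable is missing.  When
        False (post-imputation default) missing cells raise an error.
    categories : tuple (low, high)
        Inclusive range of ordinal codes.
    psd_repair : bool
        Apply eigenvalue-clipping repair when the pairwise matrix is
        indefinite.

    Attributes
    ----------
    rho_ : (p, p) latent correlation matrix, unit diagonal.
    tau_ : list of per-variable threshold vectors.
    psd_adjusted_, max_adjustment_ : repair diagnostics.
    convergence_ : per-pair optimizer status dicts keyed by (i, j).
    degenerate_ : list of (index, reason) for constant/degenerate variables.
    """

    def __init__(self, pairwise_complete: bool = False,
                 categories: tuple = (1, 5), psd_repair: bool = True):
        self.pairwise_complete = pairwise_complete
        self.categories = categories
        self.psd_repair = psd_repair

    def fit(self, X, y=None, labels: Optional[list] = None):
        X = np.asarray(X)
        if X.dtype.kind == "f":
            Xi = np.full(X.shape, MISSING, dtype=np.int64)
            obs = ~np.isnan(X)
            Xi[obs] = X[obs].astype(np.int64)
            X = Xi
        n, p = X.shape
        lo, hi = self.categories
        ncat = hi - lo + 1
        if not self.pairwise_complete and np.any(X == MISSING):
            raise ValueError(
                "missing cells present; impute first or use "
                "pairwise_complete=True"
            )
        obs_codes = X[X != MISSING]
        if obs_codes.size and (obs_codes.min() < lo or obs_codes.max() > hi):
            raise ValueError(
                f"observed codes outside categories {self.categories}; "
                "convert zero codes to missing before estimation"
            )
        rho = np.eye(p)
        conv: dict = {}
        degenerate = []
        taus = []
        for j in range(p):
            col = X[:, j]
            col = col[col != MISSING]
            counts = np.bincount(col - lo, minlength=ncat)
            if (counts > 0).sum() < 2:
                degenerate.append((j, "fewer than 2 observed categories"))
                taus.append(np.full(ncat - 1, np.nan))
            else:
                taus.append(estimate_thresholds(counts))
        bad = {j for j, _ in degenerate}
        for i in range(p):
            for j in range(i + 1, p):
                if i in bad or j in bad:
                    continue
                mask = (X[:, i] != MISSING) & (X[:, j] != MISSING)
                xi = X[mask, i] - lo
                xj = X[mask, j] - lo
                table = np.zeros((ncat, ncat))
                np.add.at(table, (xi, xj), 1.0)
                try:
                    r, status = polychoric_pair(table)
                except ValueError as exc:
                    conv[(i, j)] = {"converged": False, "error": str(exc)}
                    continue
                rho[i, j] = rho[j, i] = r
                conv[(i, j)] = status
        self.psd_adjusted_ = False
        self.max_adjustment_ = 0.0
        if self.psd_repair:
            repaired, change = nearest_psd(rho)
            if change > 0:
                rho = repaired
                self.psd_adjusted_ = True
                self.max_adjustment_ = change
        self.rho_ = rho
        self.tau_ = taus
        self.convergence_ = conv
        self.degenerate_ = degenerate
        self.labels_ = list(labels) if labels is not None else [
            f"v{j}" for j in range(p)
        ]
        self.n_samples_ = n
        return self

    def result_(self) -> PolychoricMatrix:
        return PolychoricMatrix(
            rho=self.rho_,
            tau=self.tau_,
            labels=self.labels_,
            psd_adjusted=self.psd_adjusted_,
            max_adjustment=self.max_adjustment_,
            convergence=self.convergence_,
            degenerate=self.degenerate_,
        )


def polychoric_matrix(
    data: SurveyDataset | np.ndarray,
    pairwise_complete: bool = False,
) -> PolychoricMatrix:
    """Polychoric correlation matrix of a survey dataset (or code matrix)."""
    if isinstance(data, SurveyDataset):
        X = data.responses
        labels = data.descriptor_labels
    else:
        X = np.asarray(data)
        labels = None
    est = PolychoricCorrelation(pairwise_complete=pairwise_complete)
    est.fit(X, labels=labels)
    return est.result_()
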