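"""Multiple imputation of ordinal responses via bootstrap EM.

Each of m imputations bootstraps the rows, fits a multivariate-normal
mean/covariance by EM on the resampled data (ordinal codes treated as
continuous, with numerically coded conditioning variables such as group and
rater appended), and draws the original dataset's missing cells from their
conditional normal distributions.  Pooling averages the m completed copies
cellwise, rounds half away from zero and clamps to the 1-5 scale; observed
cells pass through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .datasets import MISSING, SurveyDataset

__all__ = ["EMImputer", "ImputationResult", "em_impute", "pool_and_round"]

logger = logging.getLogger(__name__)


def _em_mvn(X: np.ndarray, tol: float = 1e-4, max_iter: int = 200,
            ridge: float = 1e-3):
    """EM estimate of (mu, Sigma) for MVN data with missing entries.

    Returns (mu, Sigma, n_iter, converged).
    """
    n, q = X.shape
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    Xc = np.where(obs, X, mu)
    sigma = np.cov(Xc, rowvar=False, bias=True) + ridge * np.eye(q)

    # group rows by missing pattern so each pattern solves one system
    keys = {}
    for i in range(n):
        keys.setdefault(obs[i].tobytes(), []).append(i)
    patterns = [
        (np.frombuffer(k, dtype=bool), np.array(idx))
        for k, idx in keys.items()
    ]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ex = np.where(obs, X, 0.0)
        exx = np.zeros((q, q))
        for o, idx in patterns:
            m = ~o
            xo = X[np.ix_(idx, np.flatnonzero(o))]
            if not m.any():
                continue
            so_oo = sigma[np.ix_(o, o)]
            so_om = sigma[np.ix_(o, m)]
            try:
                coef = np.linalg.solve(so_oo, so_om)  # (|o|, |m|)
            except np.linalg.LinAlgError:
                coef = np.linalg.solve(
                    so_oo + ridge * np.eye(o.sum()), so_om
                )
                logger.info("singular observed block; ridge repair applied")
            cond_mean = mu[m] + (xo - mu[o]) @ coef
            ex[np.ix_(idx, np.flatnonzero(m))] = cond_mean
            cond_cov = sigma[np.ix_(m, m)] - so_om.T @ coef
            exx[np.ix_(m, m)] += len(idx) * cond_cov
        mu_new = ex.mean(axis=0)
        d = ex - mu_new
        sigma_new = (d.T @ d + exx) / n
        if np.linalg.eigvalsh(sigma_new)[0] < 1e-10:
            sigma_new = sigma_new + ridge * np.eye(q)
            logger.info("singular covariance update; ridge repair applied")
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    return mu, sigma, it, converged


def _conditional_draw(X, mu, sigma, rng, ridge=1e-3):
    """Draw missing cells of X from their conditional normals (in place)."""
    out = X.copy()
    obs = ~np.isnan(X)
    for i in range(X.shape[0]):
        o = obs[i]
        m = ~o
        if not m.any():
            continue
        so_oo = sigma[np.ix_(o, o)]
        so_om = sigma[np.ix_(o, m)]
        try:
            coef = np.linalg.solve(so_oo, so_om)
        except np.linalg.LinAlgError:
            coef = np.linalg.solve(so_oo + ridge * np.eye(o.sum()), so_om)
        cond_mean = mu[m] + (X[i, o] - mu[o]) @ coef
        cond_cov = sigma[np.ix_(m, m)] - so_om.T @ coef
        cond_cov = (cond_cov + cond_cov.T) / 2
        vals, vecs = np.linalg.eigh(cond_cov)
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        out[i, m] = cond_mean + root @ rng.standard_normal(m.sum())
    return out


class EMImputer(BaseEstimator):
    """Bootstrap-EM multiple imputer for continuous-coded ordinal data.

    Parameters mirror the conventional EM-with-bootstrap imputers: m
    imputations, EM tolerance/iteration cap, a ridge used only to repair
    singular covariances, and a seed.

    Attributes
    ----------
    imputations_ : list of m completed (continuous) copies of X.
    em_iterations_ : per-imputation EM iteration counts.
    converged_ : per-imputation convergence flags.
    """

    def __init__(self, m: int = 15, tol: float = 1e-4, max_iter: int = 200,
                 ridge: float = 1e-3, random_state: Optional[int] = None):
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, y=None, conditioning: Optional[np.ndarray] = None):
        """Generate m completed copies of X (NaN marks missing cells).

        conditioning: optional (n, c) fully observed numeric covariates
        included in the EM model but not returned in the copies.
        """
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        for j in range(p):
            col = X[:, j]
            if np.unique(col[~np.isnan(col)]).size < 2:
                raise ValueError(
                    f"column {j} has fewer than 2 observed distinct values"
                )
        if conditioning is not None:
            conditioning = np.asarray(conditioning, dtype=float)
            if np.isnan(conditioning).any():
                raise ValueError("conditioning variables must be complete")
            full = np.hstack([X, conditioning])
        else:
            full = X
        rng = np.random.default_rng(self.random_state)
        copies, iters, flags = [], [], []
        for _ in range(self.m):
            rows = rng.integers(0, n, size=n)
            mu, sigma, it, ok = _em_mvn(
                full[rows], tol=self.tol, max_iter=self.max_iter,
                ridge=self.ridge,
            )
            if not ok:
                logger.warning(
                    "EM hit the %d-iteration cap without converging",
                    self.max_iter,
                )
            completed = _conditional_draw(full, mu, sigma, rng, self.ridge)
            copies.append(completed[:, :p])
            iters.append(it)
            flags.append(ok)
        self.imputations_ = copies
        self.em_iterations_ = iters
        self.converged_ = flags
        self.n_features_in_ = p
        return self

    def transform(self, X=None) -> np.ndarray:
        """Cellwise mean of the completed copies (continuous scale)."""
        return np.mean(self.imputations_, axis=0)

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).transform()


@dataclass
class ImputationResult:
    """Completed copies plus the pooled integer dataset."""

    completed: list
    m: int
    conditioning: list
    seed: Optional[int]
    em_iterations: list
    source: SurveyDataset = None
    pooled: SurveyDataset = None


def em_impute(
    data: SurveyDataset,
    conditioning: Sequence[str] = ("group", "rater"),
    m: int = 15,
    seed: Optional[int] = None,
    tol: float = 1e-4,
    max_iter: int = 200,
    ridge: float = 1e-3,
) -> ImputationResult:
    """Multiple imputation of a survey dataset's missing cells.

    Group labels and rater identifiers enter as single numeric codes, the
    convention of the original analysis.
    """
    X = data.responses.astype(float)
    X[data.responses == MISSING] = np.nan
    cond_cols = []
    names = []
    if "group" in conditioning:
        _, codes = np.unique(data.group, return_inverse=True)
        cond_cols.append(codes.astype(float))
        names.append("group")
    if "rater" in conditioning:
        _, codes = np.unique(data.rater_id, return_inverse=True)
        cond_cols.append(codes.astype(float))
        names.append("rater")
    C = np.column_stack(cond_cols) if cond_cols else None
    imp = EMImputer(m=m, tol=tol, max_iter=max_iter, ridge=ridge,
                    random_state=seed)
    imp.fit(X, conditioning=C)
    return ImputationResult(
        completed=imp.imputations_,
        m=m,
        conditioning=names,
        seed=seed,
        em_iterations=imp.em_iterations_,
        source=data,
    )


def pool_and_round(result: ImputationResult) -> SurveyDataset:
    """Average the copies, round half away from zero, clamp to [1, 5].

    Observed cells pass through unchanged as integers.
    """
    if result.m < 1 or not result.completed:
        raise ValueError("need at least one completed copy")
    mean = np.mean(result.completed, axis=0)
    rounded = np.sign(mean) * np.floor(np.abs(mean) + 0.5)
    pooled = np.clip(rounded, 1, 5).astype(np.int64)
    data = result.source
    out = data.copy()
    missing = data.responses == MISSING
    out.responses[missing] = pooled[missing]
    result.pooled = out
    return out
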