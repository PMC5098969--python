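"""Sparse Gaussian graphical model estimation with EBIC model selection.

The precision matrix is estimated by L1-penalized maximum likelihood
(graphical lasso, diagonal unpenalized) along a log-spaced lambda path; the
model minimizing the Extended Bayesian Information Criterion

    EBIC = -2 l + E log n + 4 E gamma log p,
    l = (n/2) (log det K - tr(S K)),

is returned as a partial-correlation weight matrix.  gamma in [0, 1] tunes
the extra penalty on edge count: gamma = 0 recovers the BIC, larger values
favour sparser, higher-specificity graphs.  The most conservative gamma is
the largest grid value at which every group's network is still non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._glasso import glasso, glasso_path

__all__ = [
    "NetworkModel",
    "glasso_fit",
    "lambda_grid",
    "ebic",
    "select_network",
    "select_gamma",
    "precision_to_partial",
    "edge_density",
    "edge_density_percent",
    "EBICGraphLasso",
]

#: Entries of the weight matrix below this magnitude count as absent edges.
EDGE_EPS = 1e-10


def _check_corr(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if np.linalg.eigvalsh(S)[0] < -1e-8:
        raise ValueError("S is not PSD; apply nearest_psd first")
    return (S + S.T) / 2


def glasso_fit(S, lam: float, tol: float = 1e-5, max_iter: int = 200):
    """Precision matrix maximizing the penalized likelihood at one lambda."""
    S = _check_corr(S)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        if np.linalg.eigvalsh(S)[0] <= 1e-12:
            raise ValueError("S singular: unpenalized MLE does not exist")
        return np.linalg.inv(S)
    _, K, info = glasso(S, lam, tol=tol, max_iter=max_iter)
    if not info["converged"]:
        res = np.abs(np.linalg.inv(K) - S).max()
        raise RuntimeError(
            f"glasso did not converge in {info['n_iter']} sweeps "
            f"(residual {res:.2e})"
        )
    return K


def lambda_grid(S, n_lambda: int = 100, min_ratio: float = 0.01):
    """Log-spaced decreasing penalty sequence from lambda_max = max|S_ij|."""
    S = np.asarray(S, dtype=float)
    off = S - np.diag(np.diag(S))
    lam_max = float(np.abs(off).max())
    if lam_max <= 0:
        import warnings

        warnings.warn("all off-diagonal entries are zero; degenerate grid")
        return np.array([0.0])
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def _edge_count(K: np.ndarray) -> int:
    iu = np.triu_indices(K.shape[0], 1)
    return int((np.abs(K[iu]) > EDGE_EPS).sum())


def ebic(K, S, n: int, gamma: float) -> float:
    """Extended BIC of a fitted precision matrix."""
    K = np.asarray(K, dtype=float)
    S = np.asarray(S, dtype=float)
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    ll = (n / 2.0) * (logdet - np.trace(S @ K))
    E = _edge_count(K)
    p = K.shape[0]
    return float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def precision_to_partial(K) -> np.ndarray:
    """Partial correlations W_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    K = np.asarray(K, dtype=float)
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2


@dataclass
class NetworkModel:
    """Selected sparse partial-correlation network."""

    W: np.ndarray
    K: np.ndarray
    lambda_: float
    gamma: float
    ebic: float
    n: int
    labels: list[str]
    lambda_path: Optional[np.ndarray] = None
    ebic_path: Optional[np.ndarray] = None

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def E(self) -> int:
        return _edge_count(self.W)

    def edge_list(self):
        """(i_label, j_label, weight) rows for every present edge."""
        iu, ju = np.triu_indices(self.p, 1)
        rows = []
        for i, j in zip(iu, ju):
            if abs(self.W[i, j]) > EDGE_EPS:
                rows.append((self.labels[i], self.labels[j], self.W[i, j]))
        return rows


def edge_density_percent(p: int, E: int) -> float:
    """Edge count as a percentage of the p(p-1)/2 possible edges."""
    if p < 2:
        raise ValueError("need at least 2 nodes")
    return 100.0 * E / (p * (p - 1) / 2.0)


def edge_density(model: NetworkModel) -> float:
    return edge_density_percent(model.p, model.E)


def select_network(
    S,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    min_ratio: float = 0.01,
    labels: Optional[Sequence[str]] = None,
    tol: float = 1e-5,
    refit: bool = False,
) -> NetworkModel:
    """EBIC-minimizing graphical lasso along the lambda path.

    With refit=False (the common software shortcut) the EBIC uses the
    penalized estimate's likelihood; with refit=True each candidate support
    is scored (and the winner returned) as its support-restricted maximum-
    likelihood fit, the form in which the criterion's selection consistency
    holds.  Ties in EBIC break toward larger lambda (the sparser model).
    """
    S = _check_corr(S)
    p = S.shape[0]
    lams = lambda_grid(S, n_lambda=n_lambda, min_ratio=min_ratio)
    if lams[0] == 0.0:
        K = np.diag(1.0 / np.diag(S))
        score = ebic(K, S, n, gamma)
        return NetworkModel(
            W=np.zeros_like(S), K=K, lambda_=0.0, gamma=gamma, ebic=score,
            n=n, labels=_labels(labels, p),
            lambda_path=lams, ebic_path=np.array([score]),
        )
    Ks, _, _, ok = glasso_path(S, lams, tol=tol)
    if refit:
        from ._glasso import covsel

        cache: dict = {}
        refit_Ks = list(Ks)
        for i in range(lams.size):
            if not ok[i]:
                continue
            support = np.abs(Ks[i]) > EDGE_EPS
            np.fill_diagonal(support, True)
            key = support.tobytes()
            if key not in cache:
                Kr, conv = covsel(S, support)
                cache[key] = (Kr, conv)
            Kr, conv = cache[key]
            refit_Ks[i] = Kr
            ok[i] = ok[i] and conv
        Ks = refit_Ks
    scores = np.full(lams.size, np.inf)
    for i in range(lams.size):
        if not ok[i]:
            continue
        try:
            scores[i] = ebic(Ks[i], S, n, gamma)
        except ValueError:
            continue
    if not np.isfinite(scores).any():
        raise RuntimeError("no lambda on the grid produced a valid fit")
    best = 0
    for i in range(1, lams.size):
        if scores[i] < scores[best]:  # strict: ties keep larger lambda
            best = i
    K = Ks[best]
    return NetworkModel(
        W=precision_to_partial(K), K=K, lambda_=float(lams[best]),
        gamma=gamma, ebic=float(scores[best]), n=n,
        labels=_labels(labels, p), lambda_path=lams, ebic_path=scores,
    )


def _labels(labels, p):
    return list(labels) if labels is not None else [f"v{j}" for j in range(p)]


def select_gamma(
    S_list: Sequence[np.ndarray],
    n_list: Sequence[int],
    gamma_grid: Optional[np.ndarray] = None,
    **select_kwargs,
) -> float:
    """Most conservative EBIC hyperparameter.

    Returns the largest gamma on the grid (default 0 to 1 by 0.05) at which
    every supplied correlation matrix still yields a non-empty network.
    """
    if gamma_grid is None:
        gamma_grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    if len(S_list) != len(n_list) or len(S_list) == 0:
        raise ValueError("need matching, non-empty S_list and n_list")
    for g in sorted(gamma_grid, reverse=True):
        models = [
            select_network(S, n, gamma=float(g), **select_kwargs)
            for S, n in zip(S_list, n_list)
        ]
        if all(m.E > 0 for m in models):
            return float(g)
    raise ValueError("networks are empty at every gamma on the grid")


class EBICGraphLasso(BaseEstimator):
    """Regularized partial-correlation network estimator.

    Parameters
    ----------
    gamma : EBIC hyperparameter in [0, 1].
    n_lambda, min_ratio : penalty-path resolution.
    correlation : "polychoric" (ordinal data), "pearson", or "precomputed"
        (X is then a correlation matrix and n_samples must be given to fit).

    Attributes
    ----------
    weights_ : partial-correlation weight matrix (zero diagonal).
    precision_ : selected precision matrix.
    lambda_, ebic_, n_edges_ : selection diagnostics.
    network_ : the full NetworkModel.
    """

    def __init__(self, gamma: float = 0.5, n_lambda: int = 100,
                 min_ratio: float = 0.01, correlation: str = "polychoric"):
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.min_ratio = min_ratio
        self.correlation = correlation

    def fit(self, X, y=None, n_samples: Optional[int] = None,
            labels: Optional[Sequence[str]] = None):
        X = np.asarray(X, dtype=float)
        if self.correlation == "precomputed":
            if n_samples is None:
                raise ValueError("precomputed mode requires n_samples")
            S, n = X, int(n_samples)
        elif self.correlation == "pearson":
            S, n = np.corrcoef(X, rowvar=False), X.shape[0]
        elif self.correlation == "polychoric":
            from .polychoric import polychoric_matrix

            S, n = polychoric_matrix(X.astype(np.int64)).rho, X.shape[0]
        else:
            raise ValueError(f"unknown correlation mode {self.correlation!r}")
        model = select_network(
            S, n, gamma=self.gamma, n_lambda=self.n_lambda,
            min_ratio=self.min_ratio, labels=labels,
        )
        self.network_ = model
        self.weights_ = model.W
        self.precision_ = model.K
        self.lambda_ = model.lambda_
        self.ebic_ = model.ebic
        self.n_edges_ = model.E
        self.labels_ = model.labels
        return self
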