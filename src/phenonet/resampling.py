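"""Bootstrap machinery: network bootstraps, Cliff's delta, stability curves.

Three resampling schemes support the group comparison and the robustness
checks: (i) a non-parametric bootstrap (subjects resampled with replacement,
network re-estimated, centralities recorded) feeding the Cliff's-delta
comparison of two groups; (ii) node-wise stability (networks re-estimated on
random node subsets); (iii) subject-wise, case-dropping stability (networks
re-estimated on random subject subsets drawn without replacement).  Stability
is summarized as the mean correlation - product-moment and rank - between
bootstrapped and original centrality values per sampling level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .centrality import betweenness, strength
from .datasets import SurveyDataset
from .ggm import select_network
from .polychoric import polychoric_matrix

__all__ = [
    "BootstrapDistributions",
    "StabilityCurves",
    "bootstrap_networks",
    "cliff_delta",
    "cliff_delta_ci",
    "compare_groups",
    "node_wise_stability",
    "subject_wise_stability",
]

logger = logging.getLogger(__name__)

#: |delta| below this is conventionally a negligible effect.
NEGLIGIBLE_DELTA = 0.25


# -- Cliff's delta --------------------------------------------------------

def _dominance_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d_i. = mean_j sign(x_i - y_j), via sorted counting (O(n log n))."""
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left")
    less = y.size - np.searchsorted(ys, x, side="right")
    return (greater - less) / y.size


def cliff_delta(x, y) -> float:
    """Dominance effect size: [#(x_i > y_j) - #(x_i < y_j)] / (n_x n_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(_dominance_rows(x, y).mean())


def cliff_delta_ci(x, y, alpha: float = 0.05):
    """(delta, lo, hi): normal CI from the consistent variance estimator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    di = _dominance_rows(x, y)
    dj = -_dominance_rows(y, x)
    d = float(di.mean())
    if nx < 2 or ny < 2:
        return d, -1.0, 1.0
    # sum over pairs of (d_ij - d)^2; d_ij in {-1,0,1} so sum d_ij^2 counts
    # non-ties, obtained from the row dominance counts
    ys = np.sort(y)
    non_tie = (
        np.searchsorted(ys, x, side="left")
        + (ny - np.searchsorted(ys, x, side="right"))
    ).sum()
    ss_pair = non_tie - 2 * d * (di.sum() * ny) + nx * ny * d * d
    var = (
        ny**2 * ((di - d) ** 2).sum()
        + nx**2 * ((dj - d) ** 2).sum()
        - ss_pair
    ) / (nx * ny * (nx - 1) * (ny - 1))
    var = max(var, 0.0)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return d, max(d - half, -1.0), min(d + half, 1.0)


# -- non-parametric network bootstrap -------------------------------------

@dataclass
class BootstrapDistributions:
    """Per-replicate centrality values and edge counts for one group."""

    labels: list[str]
    betweenness: np.ndarray  # (successes, p)
    strength: np.ndarray
    edge_counts: np.ndarray
    B: int
    failures: int
    seed: Optional[int]
    gamma: float

    @property
    def n_success(self) -> int:
        return self.betweenness.shape[0]

    def edge_count_sd(self) -> float:
        """Spread of the edge count across bootstrap networks."""
        return float(np.std(self.edge_counts, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """Long-format replicate-level export (for audit)."""
        rows = []
        for r in range(self.n_success):
            for v, label in enumerate(self.labels):
                rows.append(
                    {
                        "replicate": r,
                        "node": label,
                        "betweenness": self.betweenness[r, v],
                        "strength": self.strength[r, v],
                        "edge_count": self.edge_counts[r],
                    }
                )
        return pd.DataFrame(rows)


def _estimate_once(X, n, gamma, labels, n_lambda, min_ratio):
    pm = polychoric_matrix(X)
    if pm.degenerate:
        raise ValueError(
            f"degenerate descriptors in resample: {pm.degenerate}"
        )
    model = select_network(
        pm.rho, n, gamma=gamma, labels=labels,
        n_lambda=n_lambda, min_ratio=min_ratio,
    )
    return model


def bootstrap_networks(
    data: SurveyDataset,
    B: int = 2000,
    gamma: float = 0.65,
    seed: Optional[int] = None,
    n_lambda: int = 100,
    min_ratio: float = 0.01,
    min_n: int = 20,
    max_failure_rate: float = 0.2,
) -> BootstrapDistributions:
    """Non-parametric bootstrap of one group's network.

    Each replicate resamples subjects with replacement, re-estimates the
    polychoric matrix and the EBIC-selected network at fixed gamma, and
    records both centrality metrics and the edge count.  Failed replicates
    are logged and excluded; more than `max_failure_rate` failures aborts.
    """
    n = data.n_subjects
    if n < min_n:
        raise ValueError(f"need at least {min_n} subjects for stable "
                         "polychoric estimation")
    rng = np.random.default_rng(seed)
    p = data.n_descriptors
    bet, stren, edges = [], [], []
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            model = _estimate_once(
                data.responses[idx], n, gamma, data.descriptor_labels,
                n_lambda, min_ratio,
            )
            bet.append(betweenness(model.W))
            stren.append(strength(model.W))
            edges.append(model.E)
        except Exception as exc:  # noqa: BLE001 - replicate-level guard
            failures += 1
            logger.info("bootstrap replicate %d failed: %s", b, exc)
        if (b + 1) % 100 == 0:
            logger.info("bootstrap: %d/%d replicates", b + 1, B)
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed "
            f"(> {max_failure_rate:.0%}); data too degenerate"
        )
    return BootstrapDistributions(
        labels=list(data.descriptor_labels),
        betweenness=(
            np.array(bet) if bet else np.empty((0, p))
        ),
        strength=np.array(stren) if stren else np.empty((0, p)),
        edge_counts=np.array(edges, dtype=float),
        B=B,
        failures=failures,
        seed=seed,
        gamma=gamma,
    )


def _combined(boot: BootstrapDistributions, standardize: bool) -> np.ndarray:
    b, s = boot.betweenness, boot.strength
    if standardize:
        def z(a):
            sd = a.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            return (a - a.mean(axis=1, keepdims=True)) / sd

        b, s = z(b), z(s)
    return (b + s) / 2.0


def compare_groups(
    bootA: BootstrapDistributions,
    bootB: BootstrapDistributions,
    standardize: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cliff's delta per descriptor between two groups' bootstrap centralities.

    The per-replicate combined centrality is the mean of betweenness and
    strength (optionally z-standardized within replicate).  Positive delta
    means the first group's values dominate.  |delta| < 0.25 is labelled
    negligible.
    """
    if bootA.labels != bootB.labels:
        raise ValueError("node labels differ between the two groups")
    xa = _combined(bootA, standardize)
    xb = _combined(bootB, standardize)
    rows = []
    for v, label in enumerate(bootA.labels):
        d, lo, hi = cliff_delta_ci(xa[:, v], xb[:, v], alpha=alpha)
        rows.append(
            {
                "descriptor": label,
                "delta": d,
                "ci_low": lo,
                "ci_high": hi,
                "negligible": abs(d) < NEGLIGIBLE_DELTA,
            }
        )
    return pd.DataFrame(rows)


# -- stability ------------------------------------------------------------

@dataclass
class StabilityCurves:
    """Mean bootstrapped-vs-original centrality correlation per level."""

    kind: str  # "node" or "subject"
    table: pd.DataFrame  # level, metric, pearson, spearman, n_success
    B: int
    gamma: float
    seed: Optional[int]

    def mean_correlation(self, level, metric: str = "betweenness",
                         which: str = "pearson") -> float:
        t = self.table
        row = t[(t["level"] == level) & (t["metric"] == metric)]
        return float(row[which].iloc[0])


def _safe_corrs(a: np.ndarray, b: np.ndarray):
    """(pearson, spearman) or None when either vector is constant."""
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    pr = float(np.corrcoef(a, b)[0, 1])
    ra, rb = rankdata(a), rankdata(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        return None
    sr = float(np.corrcoef(ra, rb)[0, 1])
    return pr, sr


def _accumulate(rows, kind, level, metric, vals):
    arr = np.array([v for v in vals if v is not None])
    rows.append(
        {
            "level": level,
            "metric": metric,
            "pearson": float(arr[:, 0].mean()) if arr.size else np.nan,
            "spearman": float(arr[:, 1].mean()) if arr.size else np.nan,
            "n_success": int(arr.shape[0]),
        }
    )


def node_wise_stability(
    data: SurveyDataset,
    sizes: Optional[Sequence[int]] = None,
    B: int = 2000,
    gamma: float = 0.65,
    seed: Optional[int] = None,
    n_lambda: int = 100,
    min_ratio: float = 0.01,
) -> StabilityCurves:
    """Re-estimate the network on random node subsets of each size.

    All subjects are retained, so the polychoric matrix of a node subset is
    the full-data matrix restricted to those nodes; only the network
    selection and centralities are recomputed.  Correlations use only the
    nodes present in the replicate.
    """
    p = data.n_descriptors
    if sizes is None:
        sizes = range(3, p)
    sizes = sorted(int(k) for k in sizes)
    if any(k < 3 or k > p for k in sizes):
        raise ValueError("node subset sizes must lie in [3, p]")
    S = polychoric_matrix(data).rho
    n = data.n_subjects
    orig = select_network(S, n, gamma=gamma, labels=data.descriptor_labels,
                          n_lambda=n_lambda, min_ratio=min_ratio)
    ob, os_ = betweenness(orig.W), strength(orig.W)
    rng = np.random.default_rng(seed)
    rows = []
    for k in sizes:
        got_b, got_s = [], []
        for _ in range(B):
            nodes = np.sort(rng.choice(p, size=k, replace=False))
            try:
                sub = select_network(
                    S[np.ix_(nodes, nodes)], n, gamma=gamma,
                    n_lambda=n_lambda, min_ratio=min_ratio,
                )
            except Exception as exc:  # noqa: BLE001
                logger.info("node-wise replicate failed: %s", exc)
                continue
            got_b.append(_safe_corrs(betweenness(sub.W), ob[nodes]))
            got_s.append(_safe_corrs(strength(sub.W), os_[nodes]))
        _accumulate(rows, "node", k, "betweenness", got_b)
        _accumulate(rows, "node", k, "strength", got_s)
    return StabilityCurves(
        kind="node", table=pd.DataFrame(rows), B=B, gamma=gamma, seed=seed
    )


def subject_wise_stability(
    data: SurveyDataset,
    fractions: Optional[Sequence[float]] = None,
    B: int = 2000,
    gamma: float = 0.65,
    seed: Optional[int] = None,
    n_lambda: int = 100,
    min_ratio: float = 0.01,
) -> StabilityCurves:
    """Case-dropping stability: re-estimate on subject subsets.

    Subjects are drawn without replacement at each retention fraction
    (default ten levels spanning 25% to 95%); the full network is
    re-estimated and its centralities correlated with the original values.
    """
    if fractions is None:
        fractions = np.linspace(0.25, 0.95, 10)
    fractions = sorted(float(f) for f in fractions)
    n = data.n_subjects
    if min(fractions) * n < 10:
        raise ValueError("smallest fraction retains fewer than 10 subjects")
    S = polychoric_matrix(data).rho
    orig = select_network(S, n, gamma=gamma, labels=data.descriptor_labels,
                          n_lambda=n_lambda, min_ratio=min_ratio)
    ob, os_ = betweenness(orig.W), strength(orig.W)
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        k = int(round(f * n))
        got_b, got_s = [], []
        for _ in range(B):
            idx = rng.choice(n, size=k, replace=False)
            try:
                model = _estimate_once(
                    data.responses[idx], k, gamma, data.descriptor_labels,
                    n_lambda, min_ratio,
                )
            except Exception as exc:  # noqa: BLE001
                logger.info("subject-wise replicate failed: %s", exc)
                continue
            got_b.append(_safe_corrs(betweenness(model.W), ob))
            got_s.append(_safe_corrs(strength(model.W), os_))
        _accumulate(rows, "subject", f, "betweenness", got_b)
        _accumulate(rows, "subject", f, "strength", got_s)
    return StabilityCurves(
        kind="subject", table=pd.DataFrame(rows), B=B, gamma=gamma, seed=seed
    )
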