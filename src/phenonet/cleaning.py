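"""Descriptor- and subject-level screening filters for raw survey data.

The cleaning sequence removes descriptors dominated by "not relevant" zero
codes, drops subjects with implausibly many zeros, recodes remaining zeros
as missing, removes descriptors too incomplete to impute, collapses
redundant descriptor pairs (near-duplicate polychoric correlations), screens
out descriptors whose repeated ratings by the same rater lack independence,
and finally drops near-constant descriptors with very low variation ratios.
Every removal is logged in a CleaningReport.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import MISSING, SurveyDataset

__all__ = [
    "CleaningStep",
    "CleaningReport",
    "variation_ratio",
    "filter_zero_heavy",
    "filter_zero_heavy_subjects",
    "zeros_to_missing",
    "filter_missing_heavy",
    "filter_redundant_pairs",
    "rater_variance_ratio",
    "filter_rater_dependent",
    "filter_low_variation",
]

logger = logging.getLogger(__name__)


@dataclass
class CleaningStep:
    name: str
    threshold: float
    removed: list
    stats: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


@dataclass
class CleaningReport:
    steps: list = field(default_factory=list)

    def add(self, step: CleaningStep) -> None:
        for d in step.removed:
            logger.info("cleaning/%s removed %r", step.name, d)
        self.steps.append(step)

    def removed_descriptors(self) -> dict:
        out = {}
        for s in self.steps:
            if s.name == "zero_heavy_subjects":
                continue
            for d in s.removed:
                out.setdefault(d, s.name)
        return out

    def to_text(self) -> str:
        lines = []
        for s in self.steps:
            lines.append(f"[{s.name}] threshold={s.threshold}")
            lines.append(f"  removed: {s.removed if s.removed else 'none'}")
            for k, v in s.stats.items():
                lines.append(f"  {k}: {v}")
            for w in s.warnings:
                lines.append(f"  warning: {w}")
        return "\n".join(lines)


def variation_ratio(responses) -> float:
    """Proportion of non-missing responses that differ from the mode.

    Ties in the mode do not matter: the ratio uses the maximal count.
    """
    x = np.asarray(responses)
    x = x[x != MISSING]
    if x.size == 0:
        raise ValueError("no non-missing responses")
    counts = np.bincount(x - x.min())
    return 1.0 - counts.max() / x.size


def filter_zero_heavy(
    data: SurveyDataset, threshold: float = 0.10
) -> tuple[SurveyDataset, CleaningStep]:
    """Remove descriptors with at least `threshold` zero responses.

    The boundary is inclusive ("at least 10%").
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    frac = data.zero_mask().mean(axis=0)
    keep = frac < threshold
    step = CleaningStep(
        name="zero_heavy_descriptors",
        threshold=threshold,
        removed=[data.descriptor_labels[j] for j in np.flatnonzero(~keep)],
        stats={
            "zero_fraction": dict(
                zip(data.descriptor_labels, np.round(frac, 4))
            )
        },
    )
    if not keep.any():
        step.warnings.append("all descriptors removed")
    return data.select_descriptors(keep), step


def filter_zero_heavy_subjects(
    data: SurveyDataset, threshold: float = 0.15
) -> tuple[SurveyDataset, CleaningStep]:
    """Drop subjects whose zero-code fraction exceeds the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    frac = data.zero_mask().mean(axis=1)
    keep = frac <= threshold
    step = CleaningStep(
        name="zero_heavy_subjects",
        threshold=threshold,
        removed=[str(data.subject_id[i]) for i in np.flatnonzero(~keep)],
        stats={"max_zero_fraction": float(frac.max()) if frac.size else 0.0},
    )
    return data.select_subjects(keep), step


def zeros_to_missing(data: SurveyDataset) -> SurveyDataset:
    """Convert every remaining zero code into the missing sentinel."""
    out = data.copy()
    out.responses[out.responses == 0] = MISSING
    return out


def filter_missing_heavy(
    data: SurveyDataset, threshold: float = 0.05
) -> tuple[SurveyDataset, CleaningStep]:
    """Remove descriptors with strictly more than `threshold` missing.

    The boundary is exclusive ("greater than 5%"): exactly 5% is retained.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    frac = data.missing_mask().mean(axis=0)
    keep = frac <= threshold
    step = CleaningStep(
        name="missing_heavy_descriptors",
        threshold=threshold,
        removed=[data.descriptor_labels[j] for j in np.flatnonzero(~keep)],
        stats={
            "missing_fraction": dict(
                zip(data.descriptor_labels, np.round(frac, 4))
            )
        },
    )
    return data.select_descriptors(keep), step


def filter_redundant_pairs(
    data: SurveyDataset,
    corr_threshold: float = 0.8,
    keep: Optional[Sequence[str]] = None,
) -> tuple[SurveyDataset, CleaningStep]:
    """Collapse descriptor pairs with |polychoric| above the threshold.

    Pairwise-complete polychoric correlations are estimated on the
    pre-imputation data; for each offending pair, the member with the larger
    mean absolute correlation to all other descriptors is dropped (a
    user-supplied keep-list overrides).  Ties and cascades resolve greedily
    from the strongest pair down.
    """
    from .polychoric import polychoric_matrix

    if data.n_descriptors < 2:
        raise ValueError("need at least 2 descriptors")
    keep = set(keep or ())
    pm = polychoric_matrix(data, pairwise_complete=True)
    rho = pm.rho.copy()
    labels = list(data.descriptor_labels)
    warnings = [
        f"pair {labels[i]}/{labels[j]} skipped: {st['error']}"
        for (i, j), st in pm.convergence.items()
        if not st.get("converged", True) and "error" in st
    ]
    p = len(labels)
    active = np.ones(p, dtype=bool)
    removed = []
    while True:
        A = np.abs(rho) * np.outer(active, active)
        np.fill_diagonal(A, 0.0)
        i, j = np.unravel_index(np.argmax(A), A.shape)
        if A[i, j] <= corr_threshold:
            break
        # drop the member with the larger mean |rho| to the rest
        others = active.copy()
        others[[i, j]] = False
        if labels[i] in keep and labels[j] not in keep:
            drop = j
        elif labels[j] in keep and labels[i] not in keep:
            drop = i
        elif others.any():
            mi = np.abs(rho[i, others]).mean()
            mj = np.abs(rho[j, others]).mean()
            drop = i if mi >= mj else j
        else:
            drop = j
        removed.append(
            (labels[i], labels[j], float(rho[i, j]), labels[drop])
        )
        active[drop] = False
    step = CleaningStep(
        name="redundant_pairs",
        threshold=corr_threshold,
        removed=[r[3] for r in removed],
        stats={"pairs": removed},
        warnings=warnings,
    )
    return data.select_descriptors(active), step


def _rater_groups(data: SurveyDataset):
    """Indices of subjects for each rater contributing >= 2 subjects."""
    raters, inv = np.unique(data.rater_id, return_inverse=True)
    groups = []
    for r in range(len(raters)):
        idx = np.flatnonzero(inv == r)
        if idx.size >= 2:
            groups.append(idx)
    return groups


def rater_variance_ratio(data: SurveyDataset, descriptor: int | str) -> float:
    """Between- over within-rater mean square of one descriptor.

    Computed over raters with at least two subjects.  Zero within-rater
    variance with rater differences gives +inf; the fully constant case is
    reported as 1 by convention (not flagged).
    """
    j = (
        data.descriptor_labels.index(descriptor)
        if isinstance(descriptor, str)
        else descriptor
    )
    groups = _rater_groups(data)
    if len(groups) < 2:
        raise ValueError("need >= 2 raters with >= 2 subjects each")
    vals = []
    for idx in groups:
        y = data.responses[idx, j]
        y = y[y != MISSING]
        if y.size >= 2:
            vals.append(y.astype(float))
    if len(vals) < 2:
        raise ValueError("insufficient replication after missing removal")
    grand = np.concatenate(vals).mean()
    n_tot = sum(v.size for v in vals)
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in vals)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
    ms_between = ss_between / (len(vals) - 1)
    ms_within = ss_within / (n_tot - len(vals))
    if ms_within == 0.0:
        return 1.0 if ms_between == 0.0 else np.inf
    return float(ms_between / ms_within)


def filter_rater_dependent(
    data: SurveyDataset,
    n_permutations: int = 500,
    percentile: float = 99.0,
    seed: int = 0,
) -> tuple[SurveyDataset, CleaningStep]:
    """Remove descriptors whose ratings depend on the rater.

    A descriptor is flagged when its between/within-rater variance ratio
    exceeds the given percentile of a permutation null built by shuffling
    its responses across subjects within each group.
    """
    rng = np.random.default_rng(seed)
    p = data.n_descriptors
    observed = np.empty(p)
    for j in range(p):
        observed[j] = rater_variance_ratio(data, j)
    group_idx = [
        np.flatnonzero(data.group == g) for g in data.group_names
    ]
    null = np.empty((n_permutations, p))
    for b in range(n_permutations):
        shuf = data.copy()
        for idx in group_idx:
            perm = rng.permutation(idx)
            shuf.responses[idx] = data.responses[perm]
        for j in range(p):
            null[b, j] = rater_variance_ratio(shuf, j)
    cut = np.percentile(null, percentile, axis=0)
    flagged = (observed > cut) | np.isposinf(observed)
    step = CleaningStep(
        name="rater_dependent",
        threshold=percentile,
        removed=[data.descriptor_labels[j] for j in np.flatnonzero(flagged)],
        stats={
            "variance_ratio": dict(
                zip(data.descriptor_labels, np.round(observed, 3))
            ),
            "null_cut": dict(zip(data.descriptor_labels, np.round(cut, 3))),
        },
    )
    return data.select_descriptors(~flagged), step


def filter_low_variation(
    data: SurveyDataset, floor: float = 0.15
) -> tuple[SurveyDataset, CleaningStep]:
    """Remove near-constant descriptors with variation ratio below `floor`."""
    vr = np.array(
        [variation_ratio(data.responses[:, j]) for j in
         range(data.n_descriptors)]
    )
    keep = vr >= floor
    step = CleaningStep(
        name="low_variation",
        threshold=floor,
        removed=[data.descriptor_labels[j] for j in np.flatnonzero(~keep)],
        stats={
            "variation_ratio": dict(
                zip(data.descriptor_labels, np.round(vr, 3))
            )
        },
    )
    return data.select_descriptors(keep), step
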