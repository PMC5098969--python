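"""Ordinal survey data container and delimited-text I/O.

A survey table holds one row per subject (dog) and one column per
behavioural descriptor, coded on a 1-5 agreement scale with 0 meaning
"not relevant / don't know" and a dedicated sentinel for truly missing
cells.  Per-subject metadata carries the group label (e.g. patrol vs
detection) and the rater (handler) identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Optional

import numpy as np
import pandas as pd

__all__ = ["MISSING", "SurveyDataset", "read_survey", "write_survey"]

#: Sentinel for a missing cell in the integer response matrix.  Distinct
#: from the 0 code, which is a real response ("not relevant/don't know").
MISSING: int = -1

_VALID_CODES = frozenset({MISSING, 0, 1, 2, 3, 4, 5})


@dataclass
class SurveyDataset:
    """Subjects x descriptors ordinal response matrix with metadata.

    Attributes
    ----------
    responses : (n, p) int array with codes {MISSING, 0, 1..5}.
    group : (n,) array of group labels.
    rater_id : (n,) array of rater identifiers.
    descriptor_labels : list of p unique descriptor names.
    subject_id : optional (n,) array of subject identifiers.
    truth : optional generating specification, set by the simulator.
    """

    responses: np.ndarray
    group: np.ndarray
    rater_id: np.ndarray
    descriptor_labels: list[str]
    subject_id: Optional[np.ndarray] = None
    truth: Any = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        self.group = np.asarray(self.group)
        self.rater_id = np.asarray(self.rater_id)
        self.descriptor_labels = list(self.descriptor_labels)
        if self.subject_id is None:
            self.subject_id = np.array(
                [f"s{i:04d}" for i in range(self.responses.shape[0])]
            )
        self.validate()

    def validate(self) -> None:
        n, p = self.responses.shape
        if len(self.group) != n or len(self.rater_id) != n:
            raise ValueError("metadata length does not match subject count")
        if len(self.descriptor_labels) != p:
            raise ValueError("descriptor label count does not match columns")
        if len(set(self.descriptor_labels)) != p:
            raise ValueError("descriptor labels must be unique")
        if any(len(str(r)) == 0 for r in self.rater_id):
            raise ValueError("rater identifiers must be non-empty")
        bad = set(np.unique(self.responses)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid response codes present: {sorted(bad)}")

    # -- basic properties -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.responses.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.responses.shape[1]

    @property
    def group_names(self) -> list:
        seen: dict = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        return self.responses == MISSING

    def zero_mask(self) -> np.ndarray:
        return self.responses == 0

    # -- subsetting -------------------------------------------------------
    def copy(self) -> "SurveyDataset":
        return replace(
            self,
            responses=self.responses.copy(),
            group=self.group.copy(),
            rater_id=self.rater_id.copy(),
            descriptor_labels=list(self.descriptor_labels),
            subject_id=self.subject_id.copy(),
        )

    def select_descriptors(self, index) -> "SurveyDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        labels = [self.descriptor_labels[i] for i in index]
        return replace(
            self, responses=self.responses[:, index], descriptor_labels=labels
        )

    def select_subjects(self, index) -> "SurveyDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            responses=self.responses[index],
            group=self.group[index],
            rater_id=self.rater_id[index],
            subject_id=self.subject_id[index],
        )

    def subset_group(self, name) -> "SurveyDataset":
        return self.select_subjects(self.group == name)

    # -- frame conversion -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.responses.astype(float), columns=self.descriptor_labels
        )
        df[self.responses == MISSING] = np.nan
        df.insert(0, "rater", self.rater_id)
        df.insert(0, "group", self.group)
        df.insert(0, "subject", self.subject_id)
        return df


def write_survey(data: SurveyDataset, path) -> None:
    """Write one row per subject; missing cells are left blank."""
    df = data.to_frame()
    for c in data.descriptor_labels:
        df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False)


def read_survey(
    path,
    group_column: str = "group",
    rater_column: str = "rater",
    subject_column: str = "subject",
) -> SurveyDataset:
    """Read a delimited survey table, validating every response code.

    Blank cells become the missing sentinel; any code outside {0..5} is an
    error naming the offending cells.
    """
    df = pd.read_csv(path)
    for col in (group_column, rater_column):
        if col not in df.columns:
            raise ValueError(f"required metadata column {col!r} not found")
    meta_cols = [c for c in (subject_column, group_column, rater_column)
                 if c in df.columns]
    desc_cols = [c for c in df.columns if c not in meta_cols]
    values = df[desc_cols].to_numpy(dtype=float)
    resp = np.full(values.shape, MISSING, dtype=np.int64)
    obs = ~np.isnan(values)
    resp[obs] = values[obs].astype(np.int64)
    bad = obs & ((values < 0) | (values > 5) | (values != np.round(values)))
    if np.any(bad):
        cells = [
            f"row {i + 2}, column {desc_cols[j]!r}: {values[i, j]:g}"
            for i, j in zip(*np.nonzero(bad))
        ][:20]
        raise ValueError("invalid response codes: " + "; ".join(cells))
    subject = (
        df[subject_column].astype(str).to_numpy()
        if subject_column in df.columns
        else None
    )
    return SurveyDataset(
        responses=resp,
        group=df[group_column].to_numpy(),
        rater_id=df[rater_column].astype(str).to_numpy(),
        descriptor_labels=desc_cols,
        subject_id=subject,
    )
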