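"""Feature-matrix assembly.

Joins the per-family feature tables (spectral, nonlinear, connectivity)
into a single labelled matrix whose rows are epochs (or subjects, in
whole-signal mode).  Rows with more than a configurable fraction of
missing features are dropped; remaining missing values stay as NaN and
are imputed later, inside each cross-validation fold, from training-fold
medians only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "assemble_features"]

POSITIVE_LABEL = "PMCI"
NEGATIVE_LABEL = "SMCI"


@dataclass
class FeatureMatrix:
    """Named feature values with per-row subject IDs and group labels."""

    values: pd.DataFrame  # index (subject_id, epoch_index)
    labels: pd.Series  # per row, 'SMCI' or 'PMCI'

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels must align with rows")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate feature names: {sorted(set(dupes))}")
        per_subject = self.labels.groupby(self.subject_ids).nunique()
        mixed = per_subject[per_subject > 1]
        if len(mixed):
            raise ValueError(f"subjects with conflicting labels: {list(mixed.index)}")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.values.index.get_level_values("subject_id").to_numpy()

    @property
    def y(self) -> np.ndarray:
        """Binary labels: PMCI (positive class) = 1, SMCI = 0."""
        return (self.labels.to_numpy() == POSITIVE_LABEL).astype(int)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return len(self.values)

    def rows_for(self, subjects: Sequence[str]) -> np.ndarray:
        """Boolean row mask for a set of subject IDs."""
        wanted = set(subjects)
        return np.fromiter(
            (s in wanted for s in self.subject_ids), bool, len(self)
        )


def assemble_features(
    tables: Sequence[pd.DataFrame],
    group_of: Mapping[str, str],
    max_missing_fraction: float = 0.2,
) -> FeatureMatrix:
    """Column-wise join of feature tables sharing the same row keys.

    Every table must be indexed by ``(subject_id, epoch_index)`` with
    exactly the same key set; a mismatch raises with the offending keys.
    Rows whose fraction of missing features exceeds
    ``max_missing_fraction`` are dropped and logged.
    """
    if not tables:
        raise ValueError("no feature tables given")
    base = set(tables[0].index)
    for i, table in enumerate(tables[1:], start=2):
        keys = set(table.index)
        if keys != base:
            extra = sorted(keys - base)[:5]
            missing = sorted(base - keys)[:5]
            raise ValueError(
                f"feature table {i} keys differ from table 1: "
                f"missing {missing}, unexpected {extra}"
            )
    joined = pd.concat([t.sort_index() for t in tables], axis=1)

    missing_frac = joined.isna().mean(axis=1)
    bad = missing_frac > max_missing_fraction
    if bad.any():
        logger.warning(
            "dropping %d rows with > %.0f%% missing features: %s",
            int(bad.sum()), 100 * max_missing_fraction,
            list(joined.index[bad][:10]),
        )
        joined = joined[~bad]

    subjects = joined.index.get_level_values("subject_id")
    unknown = sorted(set(subjects) - set(group_of))
    if unknown:
        raise ValueError(f"no group label for subjects: {unknown[:10]}")
    labels = pd.Series([group_of[s] for s in subjects], index=joined.index, name="group")
    return FeatureMatrix(values=joined, labels=labels)
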