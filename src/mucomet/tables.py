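"""Core containers: the metabolite feature table and sample metadata.

A :class:`FeatureTable` is a samples x metabolites abundance matrix that
moves through four states during preprocessing: ``raw`` -> ``normalized``
-> ``logged`` -> ``scaled``.  State transitions are performed by the
functions in :mod:`mucomet.preprocess`; each transition returns a new
table and validates the contract of its input state.

Sample metadata travels as a plain :class:`pandas.DataFrame` with one row
per sample; :func:`validate_metadata` checks the minimal contract (a
``sample_id`` column unique and aligned with the table, and a two-level
group column).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

STATES = ("raw", "normalized", "logged", "scaled")

#: canonical metadata column names
SAMPLE_ID = "sample_id"
GROUP = "group"
SUBTYPE = "subtype"


class TableValidationError(ValueError):
    """A feature table or metadata frame violates its invariants."""


@dataclass(frozen=True)
class FeatureTable:
    """Samples x metabolites abundance matrix with a processing state.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id, one column per metabolite.
    state:
        One of ``raw``, ``normalized``, ``logged``, ``scaled``.
    zero_variance:
        Metabolite names whose column had zero variance when the table
        was autoscaled (those columns are centred only).
    """

    data: pd.DataFrame
    state: str = "raw"
    zero_variance: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise TableValidationError(
                f"unknown state {self.state!r}; expected one of {STATES}"
            )
        if self.data.ndim != 2 or self.data.empty:
            raise TableValidationError("feature table must be a non-empty 2-D frame")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate metabolite names: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TableValidationError("feature table contains non-finite values")
        if self.state in ("raw", "normalized") and (values < 0).any():
            row, col = map(int, np.argwhere(values < 0)[0])
            raise TableValidationError(
                f"negative abundance at sample {self.data.index[row]!r}, "
                f"metabolite {self.data.columns[col]!r} in state {self.state!r}"
            )
        if self.state == "scaled":
            means = values.mean(axis=0)
            if np.abs(means).max() > 1e-9:
                raise TableValidationError("scaled table columns must have mean 0")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def metabolite_names(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, state: str, **kwargs) -> "FeatureTable":
        """Return a new table with replaced data and state."""
        return replace(self, data=data, state=state, **kwargs)


def validate_metadata(
    metadata: pd.DataFrame,
    table: FeatureTable | None = None,
    group_col: str = GROUP,
    require_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Check metadata invariants and (optionally) alignment with a table.

    Returns the metadata indexed by ``sample_id`` and ordered like the
    table when one is given.
    """
    if SAMPLE_ID in metadata.columns:
        metadata = metadata.set_index(SAMPLE_ID)
    if metadata.index.has_duplicates:
        dupes = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate sample ids in metadata: {dupes}")
    if group_col not in metadata.columns:
        raise TableValidationError(f"metadata lacks the {group_col!r} column")
    if table is not None:
        missing = table.sample_ids.difference(metadata.index)
        if len(missing):
            raise TableValidationError(
                f"metadata missing samples: {missing.tolist()[:5]}"
            )
        metadata = metadata.loc[table.sample_ids]
    if require_groups is not None:
        present = set(metadata[group_col].dropna().unique())
        absent = [g for g in require_groups if g not in present]
        if absent:
            raise TableValidationError(
                f"metadata group column lacks required level(s) {absent}"
            )
    return metadata
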