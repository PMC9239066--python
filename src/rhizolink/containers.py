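"""Core in-memory containers shared across the pipeline.

A :class:`CountTable` couples a samples x features matrix of integer read
counts with per-sample metadata (pot, treatment, spatial block, day of
growth, harvest time, growth stage).  Growth measurements travel as plain
pandas DataFrames with documented column names (see
:mod:`rhizolink.growth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every CountTable must carry
METADATA_COLUMNS = ("pot_id", "treatment", "block", "day", "harvest_time", "stage")

TREATMENTS = ("inoculated", "disrupted")
STAGES = ("early", "mid", "late")

#: name of the pooled low-abundance column in CLR feature matrices
REMAINDER = "__remainder__"


def stage_of_day(day: float) -> str:
    """Growth stage as a pure function of days after germination.

    Early rhizospheres are those harvested at 3-4 days of growth, late ones
    at 13-14 days; everything else (including the day-2 baseline) is "mid".
    """
    if 3 <= day <= 4:
        return "early"
    if 13 <= day <= 14:
        return "late"
    return "mid"


@dataclass
class CountTable:
    """Samples x features integer read counts with aligned sample metadata.

    Parameters
    ----------
    counts:
        DataFrame indexed by sample id, one column per feature (ASV or
        module), non-negative integer cells.
    metadata:
        DataFrame indexed by sample id with at least the columns in
        :data:`METADATA_COLUMNS`.
    taxonomy:
        Optional per-feature labels (index = feature id).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count table contains negative values")
        if not self.counts.index.equals(self.metadata.index):
            # allow same set, different order
            if set(self.counts.index) != set(self.metadata.index):
                raise ValueError("sample ids in counts and metadata do not match")
            self.metadata = self.metadata.loc[self.counts.index]
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample depth."""
        depths = self.depths()
        if (depths == 0).any():
            raise ValueError("cannot compute relative abundance for all-zero samples")
        return self.counts.div(depths, axis=0)

    # -- subsetting ------------------------------------------------------
    def select_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        return CountTable(
            self.counts.loc[sample_ids],
            self.metadata.loc[sample_ids],
            self.taxonomy,
        )

    def select_features(self, feature_ids) -> "CountTable":
        feature_ids = list(feature_ids)
        tax = self.taxonomy.loc[feature_ids] if self.taxonomy is not None else None
        return CountTable(self.counts[feature_ids], self.metadata, tax)

    def group_samples(self, treatment: str, stage: str) -> list[str]:
        """Sample ids of one sample group (treatment x time stage).

        stage "all" means every sample grown more than 2 days.
        """
        meta = self.metadata
        mask = meta["treatment"] == treatment
        if stage == "all":
            mask &= meta["day"] > 2
        else:
            mask &= meta["stage"] == stage
        return list(meta.index[mask])


def validate_group(metadata: pd.DataFrame, sample_ids, treatment: str) -> None:
    treatments = set(metadata.loc[list(sample_ids), "treatment"])
    if treatments - {treatment}:
        raise ValueError(f"sample group mixes treatments: {treatments}")
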