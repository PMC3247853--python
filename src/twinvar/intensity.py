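"""Aliquot-by-antibody intensity matrices with a processing-stage tag."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["IntensityTable", "STAGES"]

STAGES = ("raw", "normalized", "transformed")
_ORDER = {s: i for i, s in enumerate(STAGES)}


@dataclass
class IntensityTable:
    """A matrix of per-aliquot antibody intensities.

    ``values`` is indexed by aliquot ID with one column per antibody.
    ``stage`` tracks where the table sits in the pipeline: raw fluorescence,
    PQN-normalised, or Box-Cox transformed. Raw and normalised intensities
    must be strictly positive; stage transitions only move forward.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated aliquot IDs: {dupes}")
        if self.stage in ("raw", "normalized"):
            bad = (self.values <= 0) | self.values.isna()
            if bad.any().any():
                col = bad.any(axis=0).idxmax()
                row = bad[col].idxmax()
                raise ValueError(
                    f"non-positive intensity at aliquot {row!r}, antibody {col!r} "
                    f"in {self.stage} table"
                )

    @property
    def aliquot_ids(self) -> pd.Index:
        return self.values.index

    @property
    def antibodies(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_stage(self, values: pd.DataFrame, stage: str) -> "IntensityTable":
        """Return a new table at a later pipeline stage."""
        if _ORDER[stage] < _ORDER[self.stage]:
            raise ValueError(f"cannot move from stage {self.stage!r} back to {stage!r}")
        return IntensityTable(values=values, stage=stage)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="aliquot_id")

    @classmethod
    def from_csv(cls, path, stage: str = "raw") -> "IntensityTable":
        values = pd.read_csv(path, index_col="aliquot_id")
        return cls(values=values, stage=stage)
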