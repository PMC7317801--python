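"""Dated, geolocated, deme-assigned samples."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demes import DemeGraph

#: Samples younger than this (ky BP) count as modern.
MODERN_AGE_THRESHOLD_KY = 0.5


@dataclass(frozen=True)
class SampleSet:
    """A table of samples with columns id, deme, age_ky and optional lat/lon.

    Ages are in ky BP (0 for modern samples); deme labels must exist in the
    deme graph the set is used with; ids are unique.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("id", "deme", "age_ky"):
            if col not in t.columns:
                raise ValueError(f"missing column {col!r}")
        dup = t["id"][t["id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id(s): {sorted(set(dup))}")
        ages = pd.to_numeric(t["age_ky"], errors="raise")
        if (ages < 0).any():
            bad = t["id"][ages < 0].tolist()
            raise ValueError(f"negative age for sample(s) {bad}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def ages(self) -> np.ndarray:
        return self.table["age_ky"].to_numpy(dtype=float)

    @property
    def demes(self) -> list[str]:
        return self.table["deme"].tolist()

    @property
    def has_coordinates(self) -> bool:
        return {"lat", "lon"}.issubset(self.table.columns)

    def is_modern(self) -> np.ndarray:
        return self.ages < MODERN_AGE_THRESHOLD_KY

    def validate_against(self, graph: DemeGraph) -> None:
        unknown = set(self.demes) - set(graph.demes)
        if unknown:
            raise ValueError(f"unknown deme(s) in sample table: {sorted(unknown)}")

    def deme_indices(self, graph: DemeGraph) -> np.ndarray:
        self.validate_against(graph)
        return np.array([graph.index(d) for d in self.demes], dtype=np.int64)

    def group_indices(self, graph: DemeGraph) -> np.ndarray:
        self.validate_against(graph)
        return np.array([graph.group_index(d) for d in self.demes], dtype=np.int64)

    @classmethod
    def from_records(cls, records) -> "SampleSet":
        return cls(pd.DataFrame.from_records(records))
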