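"""Cases x raters category assignments for one assessment tool.

The long on-disk format is a UTF-8 comma-delimited file with header
``case_id,rater_id,tool,outcome`` (one row per case per rater); in memory the
matrix is wide (cases as rows, raters as columns) with category identifiers
as values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scales import Scale, scale_for


class RatingDataError(ValueError):
    """Raised when rating records are structurally invalid."""


@dataclass
class RatingMatrix:
    """Complete ordinal category assignments for n cases by r raters.

    Every cell must hold a category id belonging to ``scale``; missing cells
    are rejected.  Two raters is the common case (the validation study used a
    pharmacist and a paediatrician) but r >= 2 is accepted.
    """

    scale: Scale
    assignments: pd.DataFrame  # index: case ids, columns: rater ids, values: category ids

    def __post_init__(self) -> None:
        df = self.assignments
        if df.columns.duplicated().any() or df.index.duplicated().any():
            raise RatingDataError("duplicate case or rater identifiers")
        if len(df.columns) < 2:
            raise RatingDataError(f"need at least 2 raters, got {len(df.columns)}")
        if df.isna().any().any():
            missing = df.stack(dropna=False)
            cell = missing[missing.isna()].index[0]
            raise RatingDataError(f"missing rating for case {cell[0]!r}, rater {cell[1]!r}")
        known = set(self.scale.ids)
        bad = sorted(set(df.to_numpy().ravel().tolist()) - known)
        if bad:
            raise RatingDataError(
                f"unknown categories {bad} for tool {self.scale.tool_id!r}; known: {self.scale.ids}"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def tool_id(self) -> str:
        return self.scale.tool_id

    @property
    def case_ids(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def rater_ids(self) -> list[str]:
        return list(self.assignments.columns)

    @property
    def n_cases(self) -> int:
        return len(self.assignments)

    @property
    def n_raters(self) -> int:
        return len(self.assignments.columns)

    def scores(self) -> pd.DataFrame:
        """Ordinal scores (ints) in the same cases x raters layout."""
        mapping = {c.id: c.score for c in self.scale}
        return self.assignments.apply(lambda col: col.map(mapping)).astype(int)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_pairs(
        cls,
        scale: Scale,
        pairs: Iterable[tuple[str, str]],
        case_ids: Sequence[str] | None = None,
        rater_ids: Sequence[str] = ("rater1", "rater2"),
    ) -> "RatingMatrix":
        """Build a two-rater matrix from (rater1, rater2) category id pairs."""
        pairs = list(pairs)
        if case_ids is None:
            width = max(4, len(str(len(pairs))))
            case_ids = [f"case_{i + 1:0{width}d}" for i in range(len(pairs))]
        df = pd.DataFrame(pairs, index=list(case_ids), columns=list(rater_ids), dtype=object)
        return cls(scale, df)

    @classmethod
    def from_records(cls, records: pd.DataFrame, scale: Scale | None = None) -> "RatingMatrix":
        """Build from a long table with columns case_id, rater_id, tool, outcome."""
        required = {"case_id", "rater_id", "tool", "outcome"}
        missing = required - set(records.columns)
        if missing:
            raise RatingDataError(f"rating records missing columns: {sorted(missing)}")
        tools = records["tool"].unique().tolist()
        if len(tools) != 1:
            raise RatingDataError(f"rating records must concern a single tool, got {tools}")
        if scale is None:
            scale = scale_for(str(tools[0]))
        elif str(tools[0]) != scale.tool_id:
            raise RatingDataError(f"records are for tool {tools[0]!r}, expected {scale.tool_id!r}")
        dup = records.duplicated(subset=["case_id", "rater_id"])
        if dup.any():
            row = records[dup].iloc[0]
            raise RatingDataError(
                f"duplicate rating for case {row['case_id']!r}, rater {row['rater_id']!r}"
            )
        wide = records.pivot(index="case_id", columns="rater_id", values="outcome")
        wide = wide.reindex(index=records["case_id"].unique(), columns=sorted(wide.columns))
        wide.index.name = None
        wide.columns.name = None
        return cls(scale, wide)

    @classmethod
    def read_csv(cls, path: str | Path, scale: Scale | None = None) -> "RatingMatrix":
        return cls.from_records(pd.read_csv(path, dtype=str), scale=scale)

    # -- serialization -----------------------------------------------------
    def to_records(self) -> pd.DataFrame:
        long = self.assignments.stack().rename("outcome").reset_index()
        long.columns = ["case_id", "rater_id", "outcome"]
        long.insert(2, "tool", self.tool_id)
        return long

    def to_csv(self, path: str | Path) -> None:
        self.to_records().to_csv(path, index=False)

    def category_counts(self, rater_id: str) -> np.ndarray:
        """Per-category counts for one rater, in ascending score order."""
        col = self.assignments[rater_id]
        return np.array([(col == c).sum() for c in self.scale.ids], dtype=int)
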