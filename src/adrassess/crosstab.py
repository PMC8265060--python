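"""Inter-rater contingency tables and constrained table enumeration.

A :class:`CrossTab` is a k x k table of paired category counts; by convention
rows are the second rater and columns the first (the layout used in the
published per-category agreement tables).  All agreement statistics are
symmetric in the two raters, so the orientation only matters for display and
for reconstruction bookkeeping.

:func:`feasible_tables` enumerates every non-negative integer table with
prescribed row marginals, column marginals and diagonal.  This is the engine
used to reconstruct a full k x k rating table from published one-vs-rest 2x2
agreement tables, which fix exactly those three constraint sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .scales import Scale

if TYPE_CHECKING:  # pragma: no cover
    from .agreement import WeightScheme
    from .ratings import RatingMatrix


class AmbiguousSelectionError(ValueError):
    """Raised when minimum-disagreement selection is tied between tables."""

    def __init__(self, message: str, candidates: list["CrossTab"]):
        super().__init__(message)
        self.candidates = candidates


@dataclass(frozen=True)
class CrossTab:
    """k x k paired-count table; rows = second rater, columns = first rater."""

    scale: Scale
    counts: np.ndarray
    row_rater: str = "rater2"
    col_rater: str = "rater1"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.scale)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} does not match {k} categories")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(int)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        counts = counts.astype(int)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.scale)

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossTab):
            return NotImplemented
        return self.scale == other.scale and np.array_equal(self.counts, other.counts)

    def __hash__(self) -> int:
        return hash((self.scale, self.counts.tobytes()))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "tool": self.scale.tool_id,
            "categories": self.scale.ids,
            "row_rater": self.row_rater,
            "col_rater": self.col_rater,
            "counts": self.counts.tolist(),
        }

    def to_text(self) -> str:
        """Aligned plain-text rendering (rows rater 2, columns rater 1)."""
        ids = self.scale.ids
        width = max(len(i) for i in ids + ["Total"]) + 2
        head = " " * width + "".join(f"{i:>{width}}" for i in ids) + f"{'Total':>{width}}"
        lines = [f"{self.row_rater} \\ {self.col_rater}", head]
        for i, cid in enumerate(ids):
            row = self.counts[i]
            lines.append(
                f"{cid:<{width}}"
                + "".join(f"{v:>{width}d}" for v in row)
                + f"{int(row.sum()):>{width}d}"
            )
        lines.append(
            f"{'Total':<{width}}"
            + "".join(f"{int(v):>{width}d}" for v in self.col_marginals)
            + f"{self.n:>{width}d}"
        )
        return "\n".join(lines)

    # -- conversions -------------------------------------------------------
    def expand_to_ratings(
        self, rater_ids: Sequence[str] = ("rater1", "rater2")
    ) -> "RatingMatrix":
        """Expand the table into one rating pair per counted case.

        Cases are emitted in row-major (lexicographic) cell order, i.e. by
        ascending rater-2 score then ascending rater-1 score, and numbered
        sequentially.  All agreement statistics are permutation-invariant, so
        the order is a pure bookkeeping convention.
        """
        from .ratings import RatingMatrix

        ids = self.scale.ids
        pairs: list[tuple[str, str]] = []
        for i, r2_cat in enumerate(ids):
            for j, r1_cat in enumerate(ids):
                pairs.extend([(r1_cat, r2_cat)] * int(self.counts[i, j]))
        return RatingMatrix.from_pairs(self.scale, pairs, rater_ids=rater_ids)


def crosstab_from_ratings(ratings: "RatingMatrix") -> CrossTab:
    """Tabulate a two-rater matrix: counts[i, j] = #cases rated category i by
    the second rater and category j by the first."""
    if ratings.n_raters != 2:
        raise ValueError(f"crosstab requires exactly 2 raters, got {ratings.n_raters}")
    r1, r2 = ratings.rater_ids
    k = len(ratings.scale)
    idx = {c: i for i, c in enumerate(ratings.scale.ids)}
    i2 = ratings.assignments[r2].map(idx).to_numpy(dtype=int)
    i1 = ratings.assignments[r1].map(idx).to_numpy(dtype=int)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (i2, i1), 1)
    return CrossTab(ratings.scale, counts, row_rater=r2, col_rater=r1)


@dataclass
class EnumerationResult:
    """Outcome of constrained enumeration: the tables, or a diagnosis of why
    the constraints are infeasible (empty table list)."""

    tables: list[CrossTab] = field(default_factory=list)
    diagnosis: str | None = None

    def __iter__(self):
        return iter(self.tables)

    def __len__(self) -> int:
        return len(self.tables)


def _check_constraints(rows: np.ndarray, cols: np.ndarray, diag: np.ndarray) -> str | None:
    if (rows < 0).any() or (cols < 0).any() or (diag < 0).any():
        return "negative constraint value"
    if rows.sum() != cols.sum():
        return f"marginal sums differ: rows total {int(rows.sum())}, columns total {int(cols.sum())}"
    for i, d in enumerate(diag):
        if d > rows[i]:
            return f"diagonal[{i}] = {int(d)} exceeds row marginal {int(rows[i])}"
        if d > cols[i]:
            return f"diagonal[{i}] = {int(d)} exceeds column marginal {int(cols[i])}"
    return None


def feasible_tables(
    row_marginals: Sequence[int],
    col_marginals: Sequence[int],
    diagonal: Sequence[int],
    scale: Scale,
) -> EnumerationResult:
    """Enumerate all non-negative integer k x k tables with the given row
    marginals, column marginals and diagonal.

    Backtracks over the off-diagonal cells in row-major order, so the result
    list is in lexicographic order of the flattened table.  Infeasible
    constraints yield an empty list plus a diagnosis naming the violated
    constraint.
    """
    rows = np.asarray(row_marginals, dtype=int)
    cols = np.asarray(col_marginals, dtype=int)
    diag = np.asarray(diagonal, dtype=int)
    k = len(scale)
    if not (len(rows) == len(cols) == len(diag) == k):
        raise ValueError(f"constraint vectors must have length {k}")
    problem = _check_constraints(rows, cols, diag)
    if problem is not None:
        return EnumerationResult([], problem)

    row_rem = rows - diag
    col_rem = cols - diag
    cells = [(i, j) for i in range(k) for j in range(k) if i != j]
    table = np.diag(diag).astype(int)
    found: list[CrossTab] = []

    def last_in_row(pos: int) -> bool:
        i, _ = cells[pos]
        return pos + 1 == len(cells) or cells[pos + 1][0] != i

    def backtrack(pos: int) -> None:
        if pos == len(cells):
            if not row_rem.any() and not col_rem.any():
                found.append(CrossTab(scale, table.copy()))
            return
        i, j = cells[pos]
        hi = min(row_rem[i], col_rem[j])
        lo = row_rem[i] if last_in_row(pos) else 0
        if lo > hi:
            return
        for v in range(int(lo), int(hi) + 1):
            table[i, j] = v
            row_rem[i] -= v
            col_rem[j] -= v
            backtrack(pos + 1)
            row_rem[i] += v
            col_rem[j] += v
            table[i, j] = 0

    backtrack(0)
    if not found:
        return EnumerationResult([], "no integer table satisfies the joint constraints")
    return EnumerationResult(found, None)


def select_min_disagreement(
    tables: Sequence[CrossTab], scheme: "WeightScheme | None" = None
) -> CrossTab:
    """Pick the table minimizing total weighted off-diagonal disagreement.

    The default weight scheme is linear (|score_i - score_j|).  Selection is
    value-blind: it looks only at the tables, never at any statistic one
    hopes to reproduce.  A tie is an error carrying all tied candidates.
    """
    from .agreement import linear_weights

    tables = list(tables)
    if not tables:
        raise ValueError("select_min_disagreement requires a non-empty table list")
    if scheme is None:
        scheme = linear_weights()

    def cost(t: CrossTab) -> float:
        w = scheme.matrix(np.asarray(t.scale.scores))
        off = t.counts * (1 - np.eye(t.k, dtype=int))
        return float((w * off).sum())

    costs = [cost(t) for t in tables]
    best = min(costs)
    winners = [t for t, c in zip(tables, costs) if c == best]
    if len(winners) > 1:
        raise AmbiguousSelectionError(
            f"{len(winners)} tables tie at total {scheme.name} disagreement {best}",
            winners,
        )
    return winners[0]
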