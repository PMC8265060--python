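"""Ordered outcome scales for ADR assessment tools.

Both Liverpool tools classify a suspected adverse drug reaction into one of
four ordered categories.  Causality (LCAT): unlikely < possible < probable <
definite, scored 0..3.  Avoidability (LAAT): unassessable < not avoidable <
possibly avoidable < definitely avoidable, scored 0..3.  The ordinal scores
drive the weighted-kappa and extreme-disagreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Category:
    """One outcome category with its ordinal score and display label."""

    id: str
    score: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.id.replace("_", " "))


@dataclass(frozen=True)
class Scale:
    """An ordered set of outcome categories for one tool.

    Scores must be unique and form a contiguous run starting at 0; the
    categories are stored in ascending score order regardless of input order.
    """

    tool_id: str
    categories: tuple[Category, ...] = field(default=())

    def __post_init__(self) -> None:
        cats = tuple(sorted(self.categories, key=lambda c: c.score))
        object.__setattr__(self, "categories", cats)
        scores = [c.score for c in cats]
        if sorted(set(scores)) != scores:
            raise ValueError(f"duplicate ordinal scores in scale {self.tool_id!r}: {scores}")
        if scores != list(range(len(scores))):
            raise ValueError(
                f"ordinal scores of scale {self.tool_id!r} must be contiguous from 0, got {scores}"
            )
        ids = [c.id for c in cats]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate category ids in scale {self.tool_id!r}: {ids}")

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.categories]

    @property
    def scores(self) -> list[int]:
        return [c.score for c in self.categories]

    def category(self, cat_id: str) -> Category:
        for c in self.categories:
            if c.id == cat_id:
                return c
        raise KeyError(f"unknown category {cat_id!r} for tool {self.tool_id!r}; known: {self.ids}")

    def score_of(self, cat_id: str) -> int:
        return self.category(cat_id).score

    def index(self, cat_id: str) -> int:
        # Index in ascending-score order; equals the ordinal score by construction.
        return self.score_of(cat_id)


LCAT_SCALE = Scale(
    "LCAT",
    (
        Category("unlikely", 0, "Unlikely"),
        Category("possible", 1, "Possible"),
        Category("probable", 2, "Probable"),
        Category("definite", 3, "Definite"),
    ),
)

LAAT_SCALE = Scale(
    "LAAT",
    (
        Category("unassessable", 0, "Unassessable"),
        Category("not_avoidable", 1, "Not avoidable"),
        Category("possibly_avoidable", 2, "Possibly avoidable"),
        Category("definitely_avoidable", 3, "Definitely avoidable"),
    ),
)

_BUILTIN = {s.tool_id: s for s in (LCAT_SCALE, LAAT_SCALE)}


def scale_for(tool_id: str) -> Scale:
    """Return the bundled scale for ``tool_id`` ("LCAT" or "LAAT")."""
    try:
        return _BUILTIN[tool_id]
    except KeyError:
        raise KeyError(f"no bundled scale for tool {tool_id!r}; known: {sorted(_BUILTIN)}") from None
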