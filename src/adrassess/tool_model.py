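"""Config-driven binary decision-flow engine for ADR assessment tools.

The Liverpool causality and avoidability tools are flow diagrams of yes/no
questions ending in one of four ordered outcome categories.  The engine here
is tool-agnostic: a tool is a declarative YAML/JSON document (decision graph
plus bilingual question bank) validated on load, and evaluation is a
deterministic traversal of the graph over explicit clinical answers.

Bundled definitions for LCAT (causality) and LAAT (avoidability) live under
``adrassess/data`` with both the original English wording and the
Brazilian-Portuguese v1/v2 translations.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .scales import Category, Scale

ANSWERS = ("yes", "no")


class ToolConfigError(ValueError):
    """Structural problem in a tool definition; the message names the node."""


class MissingAnswerError(KeyError):
    """An on-path question was left unanswered."""

    def __init__(self, question_id: str):
        super().__init__(question_id)
        self.question_id = question_id

    def __str__(self) -> str:
        return f"no answer supplied for question {self.question_id!r} on the active path"


class UnusedAnswerWarning(UserWarning):
    """An answer was supplied for a question not on the traversed path."""


class OutcomeCategory(BaseModel):
    """An outcome leaf: identifier, ordinal score, display labels by language."""

    model_config = ConfigDict(frozen=True)

    id: str
    score: int = Field(ge=0)
    labels: dict[str, str] = Field(default_factory=dict)

    def label(self, language: str = "en") -> str:
        return self.labels.get(language, self.id.replace("_", " "))


class Question(BaseModel):
    """A yes/no question node with its bilingual, versioned text bank.

    ``texts`` maps language tag -> version tag -> sentence ("en"/"original"
    for the source wording; "pt-BR" carries "v1" and "v2").  ``footnote``
    holds the explanation attached to asterisked items, keyed by language.
    """

    model_config = ConfigDict(frozen=True, populate_by_name=True)

    id: str
    yes: str
    no: str
    texts: dict[str, dict[str, str]] = Field(default_factory=dict)
    footnote: dict[str, str] | None = None

    @field_validator("texts")
    @classmethod
    def _non_empty_texts(cls, v: dict) -> dict:
        for lang, versions in v.items():
            for tag, text in versions.items():
                if not str(text).strip():
                    raise ValueError(f"empty text for ({lang}, {tag})")
        return v

    def text(self, language: str, version: str) -> str:
        try:
            versions = self.texts[language]
        except KeyError:
            raise KeyError(
                f"question {self.id!r} has no {language!r} text; "
                f"available languages: {sorted(self.texts)}"
            ) from None
        try:
            return versions[version]
        except KeyError:
            raise KeyError(
                f"question {self.id!r} has no ({language!r}, {version!r}) text; "
                f"available versions: {sorted(versions)}"
            ) from None


class ToolDefinition(BaseModel):
    """A validated, acyclic binary decision graph with ordinal outcome leaves."""

    model_config = ConfigDict(frozen=True)

    id: str
    start: str
    questions: tuple[Question, ...]
    outcomes: tuple[OutcomeCategory, ...]

    # -- lookups -----------------------------------------------------------
    def question(self, question_id: str) -> Question:
        for q in self.questions:
            if q.id == question_id:
                return q
        raise KeyError(
            f"unknown question {question_id!r} in tool {self.id!r}; "
            f"known: {[q.id for q in self.questions]}"
        )

    def outcome(self, outcome_id: str) -> OutcomeCategory:
        for o in self.outcomes:
            if o.id == outcome_id:
                return o
        raise KeyError(f"unknown outcome {outcome_id!r} in tool {self.id!r}")

    @property
    def question_ids(self) -> list[str]:
        return [q.id for q in self.questions]

    @property
    def outcome_ids(self) -> list[str]:
        return [o.id for o in self.outcomes]

    def target(self, question_id: str, answer: str) -> str:
        q = self.question(question_id)
        if answer not in ANSWERS:
            raise ValueError(f"answer must be one of {ANSWERS}, got {answer!r}")
        return q.yes if answer == "yes" else q.no

    def scale(self) -> Scale:
        return Scale(
            self.id,
            tuple(Category(o.id, o.score, o.label("en")) for o in self.outcomes),
        )


class Assessment(BaseModel):
    """One rater's traversal result for one case: the trail and the outcome."""

    case_id: Optional[str] = None
    rater_id: Optional[str] = None
    tool_id: str
    trail: tuple[tuple[str, str], ...]
    outcome: OutcomeCategory


class DoseRecord(BaseModel):
    drug: str
    dose: Optional[str] = None
    route: Optional[str] = None
    notes: Optional[str] = None


class CaseReport(BaseModel):
    """Structured ADR case report, as assembled from ward records.

    Carries the information the tools' questions draw on: patient
    characterization, suspected medicines with doses, the event and its
    timeline, dechallenge/rechallenge observations, allergy history and
    prevention notes.
    """

    case_id: str
    patient_id: Optional[str] = None
    age_years: int = Field(ge=0, le=17)
    sex: str
    diagnosis: str
    suspected_drugs: list[DoseRecord]
    event_description: str
    onset_day: Optional[int] = None
    administration_day: Optional[int] = None
    dechallenge: Optional[bool] = None
    dechallenge_notes: Optional[str] = None
    rechallenge: Optional[bool] = None
    rechallenge_notes: Optional[str] = None
    allergy_history: Optional[str] = None
    prevention_notes: Optional[str] = None


# ---------------------------------------------------------------------------
# Loading and validation


def _validate_graph(tool: ToolDefinition) -> None:
    qids = tool.question_ids
    oids = tool.outcome_ids
    if len(set(qids)) != len(qids):
        dup = sorted({q for q in qids if qids.count(q) > 1})
        raise ToolConfigError(f"duplicate question ids {dup} in tool {tool.id!r}")
    if len(set(oids)) != len(oids):
        raise ToolConfigError(f"duplicate outcome ids in tool {tool.id!r}")
    overlap = set(qids) & set(oids)
    if overlap:
        raise ToolConfigError(f"ids used as both question and outcome: {sorted(overlap)}")

    scores = sorted(o.score for o in tool.outcomes)
    if len(set(scores)) != len(scores):
        dup_score = next(s for s in scores if scores.count(s) > 1)
        holders = [o.id for o in tool.outcomes if o.score == dup_score]
        raise ToolConfigError(
            f"duplicate ordinal score {dup_score} shared by outcomes {holders} in tool {tool.id!r}"
        )
    if scores != list(range(len(scores))):
        raise ToolConfigError(
            f"outcome scores of tool {tool.id!r} must be contiguous from 0, got {scores}"
        )

    if tool.start not in qids:
        raise ToolConfigError(f"start node {tool.start!r} is not a question of tool {tool.id!r}")
    nodes = set(qids) | set(oids)
    for q in tool.questions:
        for ans in ANSWERS:
            tgt = q.yes if ans == "yes" else q.no
            if tgt is None or tgt == "":
                raise ToolConfigError(f"question {q.id!r} is missing its {ans!r} branch")
            if tgt not in nodes:
                raise ToolConfigError(
                    f"dangling edge: question {q.id!r}/{ans} targets unknown node {tgt!r}"
                )

    # acyclicity by DFS over question nodes
    WHITE, GREY, BLACK = 0, 1, 2
    color = {q: WHITE for q in qids}

    def dfs(node: str, path: list[str]) -> None:
        color[node] = GREY
        q = tool.question(node)
        for tgt in (q.yes, q.no):
            if tgt in color:
                if color[tgt] == GREY:
                    cycle = path[path.index(tgt):] + [tgt] if tgt in path else [node, tgt]
                    raise ToolConfigError(
                        f"cycle detected in tool {tool.id!r} involving questions {cycle}"
                    )
                if color[tgt] == WHITE:
                    dfs(tgt, path + [tgt])
        color[node] = BLACK

    for q in qids:
        if color[q] == WHITE:
            dfs(q, [q])

    # reachability of every outcome (and every question) from start
    reached_q: set[str] = set()
    reached_o: set[str] = set()
    stack = [tool.start]
    while stack:
        node = stack.pop()
        if node in reached_q:
            continue
        if node in set(oids):
            reached_o.add(node)
            continue
        reached_q.add(node)
        q = tool.question(node)
        stack.extend([q.yes, q.no])
    unreachable = set(oids) - reached_o
    if unreachable:
        raise ToolConfigError(
            f"outcomes {sorted(unreachable)} unreachable from start node {tool.start!r} "
            f"in tool {tool.id!r}"
        )
    orphan_q = set(qids) - reached_q
    if orphan_q:
        raise ToolConfigError(
            f"questions {sorted(orphan_q)} unreachable from start node {tool.start!r} "
            f"in tool {tool.id!r}"
        )


def load_tool_definition(source: str | Path | Mapping) -> ToolDefinition:
    """Load and validate a tool definition from a YAML/JSON file or a dict.

    Raises :class:`ToolConfigError` (naming the offending node) on any
    structural defect: cycles, dangling edge targets, missing branches,
    duplicate or non-contiguous ordinal scores, unreachable outcomes.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        doc = yaml.safe_load(text)  # YAML is a JSON superset, covers both
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ToolConfigError("tool definition document must be a mapping")
    data = dict(doc)
    if "tool" in data and "id" not in data:
        data["id"] = data.pop("tool")
    for key in ("id", "start", "questions", "outcomes"):
        if key not in data:
            raise ToolConfigError(f"tool definition missing required key {key!r}")
    outcomes = [
        {"id": o["id"], "score": o.get("score", o.get("ordinal_score")), "labels": o.get("labels", {})}
        for o in data["outcomes"]
    ]
    # YAML 1.1 readers may parse unquoted yes/no keys as booleans; normalize.
    questions = [
        {("yes" if k is True else "no" if k is False else k): v for k, v in q.items()}
        for q in data["questions"]
    ]
    try:
        tool = ToolDefinition(
            id=data["id"],
            start=data["start"],
            questions=tuple(Question(**q) for q in questions),
            outcomes=tuple(OutcomeCategory(**o) for o in outcomes),
        )
    except (ValidationError, TypeError) as exc:
        raise ToolConfigError(f"invalid tool definition: {exc}") from exc
    _validate_graph(tool)
    return tool


def load_bundled_tool(tool_id: str) -> ToolDefinition:
    """Load one of the packaged tool definitions ("LCAT" or "LAAT")."""
    name = {"LCAT": "lcat.yaml", "LAAT": "laat.yaml"}.get(tool_id)
    if name is None:
        raise KeyError(f"no bundled tool {tool_id!r}; known: ['LAAT', 'LCAT']")
    ref = resources.files("adrassess.data").joinpath(name)
    with resources.as_file(ref) as path:
        return load_tool_definition(path)


# ---------------------------------------------------------------------------
# Evaluation


def _normalize_answers(answers: Mapping[str, object]) -> dict[str, str]:
    out: dict[str, str] = {}
    for qid, raw in answers.items():
        if isinstance(raw, bool):
            val = "yes" if raw else "no"
        else:
            val = str(raw).strip().lower()
        if val not in ANSWERS:
            raise ValueError(f"answer for {qid!r} must be yes/no (or bool), got {raw!r}")
        out[str(qid)] = val
    return out


def evaluate(
    tool: ToolDefinition,
    answers: Mapping[str, object],
    case_id: str | None = None,
    rater_id: str | None = None,
) -> Assessment:
    """Traverse the tool's graph under the given yes/no answers.

    Answers may be "yes"/"no" strings or booleans.  A question on the active
    path without an answer raises :class:`MissingAnswerError`; answers for
    questions off the traversed path are ignored with an
    :class:`UnusedAnswerWarning`.
    """
    ans = _normalize_answers(answers)
    trail: list[tuple[str, str]] = []
    node = tool.start
    outcome_ids = set(tool.outcome_ids)
    while node not in outcome_ids:
        if node not in ans:
            raise MissingAnswerError(node)
        a = ans[node]
        trail.append((node, a))
        node = tool.target(node, a)
    unused = set(ans) - {q for q, _ in trail}
    if unused:
        warnings.warn(
            f"answers for questions not on the traversed path ignored: {sorted(unused)}",
            UnusedAnswerWarning,
            stacklevel=2,
        )
    return Assessment(
        case_id=case_id,
        rater_id=rater_id,
        tool_id=tool.id,
        trail=tuple(trail),
        outcome=tool.outcome(node),
    )


def replay(tool: ToolDefinition, assessment: Assessment) -> Assessment:
    """Re-run a stored assessment's trail; must reproduce its outcome."""
    return evaluate(
        tool,
        dict(assessment.trail),
        case_id=assessment.case_id,
        rater_id=assessment.rater_id,
    )


def question_text(
    tool: ToolDefinition, question_id: str, language: str, version: str
) -> str:
    """Exact stored sentence for (question, language tag, version tag)."""
    return tool.question(question_id).text(language, version)


def enumerate_paths(tool: ToolDefinition) -> Iterator[tuple[tuple[tuple[str, str], ...], str]]:
    """Yield every (trail, outcome id) pair reachable from the start node."""
    outcome_ids = set(tool.outcome_ids)

    def walk(node: str, trail: tuple[tuple[str, str], ...]):
        if node in outcome_ids:
            yield trail, node
            return
        q = tool.question(node)
        yield from walk(q.yes, trail + ((node, "yes"),))
        yield from walk(q.no, trail + ((node, "no"),))

    yield from walk(tool.start, ())


def load_case_reports(path: str | Path) -> list[CaseReport]:
    """Read a JSON file holding a list of case-report records."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(raw, Mapping):
        raw = raw.get("cases", [raw])
    reports = [CaseReport(**rec) for rec in raw]
    ids = [r.case_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids in case-report collection")
    return reports
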