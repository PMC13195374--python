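"""Question bank: the pool of predefined triage questions, the documentation
topic hierarchy, and the critical symptom combinations.

A bank is the static clinical content a triage prototype runs on: every
question an operator can ask (binary confirm/negate prompts), a two-level
topic hierarchy that fixes the order of the structured call documentation,
and the critical symptom combinations — sets of questions whose joint
confirmation mandates the highest urgency and drives the pink/red
highlighting in the session engine.

Banks are serialized as a single self-describing JSON file (keys
``questions``, ``hierarchy``, ``critical_combinations``, ``schema_version``)
so that fixtures are diff-able and round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

SCHEMA_VERSION = "1"

ANSWER_CONFIRMED = "confirmed"
ANSWER_NEGATED = "negated"
ANSWERS = (ANSWER_CONFIRMED, ANSWER_NEGATED)


class BankError(ValueError):
    """Base class for bank problems."""


class BankFormatError(BankError):
    """The bank file does not parse under the documented schema."""


class BankIntegrityError(BankError):
    """Cross-references inside the bank are inconsistent."""


@dataclass(frozen=True)
class Question:
    """One predefined binary question.

    ``topic_path`` is the ordered path of topic labels from the hierarchy
    root down to the node the question documents under.
    """

    id: int
    text: str
    topic_path: tuple[str, ...]
    answer_domain: str = "binary"
    is_faq_eligible: bool = True

    def __post_init__(self) -> None:
        if self.id < 0:
            raise BankIntegrityError(f"question id must be non-negative, got {self.id}")
        if not self.text:
            raise BankIntegrityError(f"question {self.id} has empty text")
        if self.answer_domain != "binary":
            raise BankIntegrityError(
                f"question {self.id}: unsupported answer domain {self.answer_domain!r}"
            )
        object.__setattr__(self, "topic_path", tuple(self.topic_path))


class TopicHierarchy:
    """Ordered tree of topic labels with a deterministic total display order.

    The display rank of a topic path is its position in a preorder traversal,
    which makes document ordering a pure function of the hierarchy.
    """

    def __init__(self, tree: Sequence[tuple[str, Sequence]] | Sequence) -> None:
        self._tree = [self._normalize(node) for node in tree]
        self._ranks: dict[tuple[str, ...], int] = {}
        for rank, path in enumerate(self._preorder(self._tree, ())):
            self._ranks[path] = rank
        self._check_siblings(self._tree, ())

    @staticmethod
    def _normalize(node) -> tuple[str, list]:
        if isinstance(node, str):
            return (node, [])
        label, children = node
        return (str(label), [TopicHierarchy._normalize(c) for c in children])

    @classmethod
    def _preorder(cls, nodes, prefix) -> Iterator[tuple[str, ...]]:
        for label, children in nodes:
            path = prefix + (label,)
            yield path
            yield from cls._preorder(children, path)

    def _check_siblings(self, nodes, prefix) -> None:
        labels = [label for label, _ in nodes]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise BankIntegrityError(
                f"duplicate sibling topic labels {dup} under {'/'.join(prefix) or '<root>'}"
            )
        for label, children in nodes:
            self._check_siblings(children, prefix + (label,))

    def resolves(self, path: Sequence[str]) -> bool:
        return tuple(path) in self._ranks

    def rank(self, path: Sequence[str]) -> int:
        """Preorder position of ``path``; raises on unknown paths."""
        try:
            return self._ranks[tuple(path)]
        except KeyError:
            raise BankIntegrityError(f"topic path {tuple(path)} not in hierarchy") from None

    def paths(self) -> list[tuple[str, ...]]:
        return sorted(self._ranks, key=self._ranks.__getitem__)

    def to_jsonable(self) -> list:
        def conv(nodes):
            return [[label, conv(children)] for label, children in nodes]

        return conv(self._tree)

    @classmethod
    def from_jsonable(cls, data) -> "TopicHierarchy":
        return cls(data)

    def __eq__(self, other) -> bool:
        return isinstance(other, TopicHierarchy) and self.to_jsonable() == other.to_jsonable()


@dataclass(frozen=True)
class CriticalCombination:
    """A set of questions whose joint confirmation forms a highest-urgency
    constellation; ``members`` all require the answer "confirmed"."""

    id: int
    members: frozenset[int]
    urgency_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(int(m) for m in self.members))
        if not self.members:
            raise BankIntegrityError(f"combination {self.id} has no members")


@dataclass
class QuestionBank:
    questions: dict[int, Question] = field(default_factory=dict)
    hierarchy: TopicHierarchy = field(default_factory=lambda: TopicHierarchy([]))
    critical_combinations: list[CriticalCombination] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for qid, q in self.questions.items():
            if qid != q.id:
                raise BankIntegrityError(f"question keyed {qid} carries id {q.id}")
            if not self.hierarchy.resolves(q.topic_path):
                raise BankIntegrityError(
                    f"question {qid}: topic path {q.topic_path} does not resolve"
                )
        seen_members: set[frozenset[int]] = set()
        for comb in self.critical_combinations:
            dangling = sorted(m for m in comb.members if m not in self.questions)
            if dangling:
                raise BankIntegrityError(
                    f"combination {comb.id} references unknown question ids {dangling}"
                )
            if comb.members in seen_members:
                raise BankIntegrityError(
                    f"combination {comb.id} duplicates another combination's member set"
                )
            seen_members.add(comb.members)

    # -- accessors --------------------------------------------------------

    def question(self, qid: int) -> Question:
        try:
            return self.questions[qid]
        except KeyError:
            raise LookupError(f"unknown question id {qid}") from None

    def question_ids(self) -> list[int]:
        return sorted(self.questions)

    def __len__(self) -> int:
        return len(self.questions)

    # -- serialization ----------------------------------------------------

    def to_jsonable(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "questions": [
                {
                    "id": q.id,
                    "text": q.text,
                    "topic_path": list(q.topic_path),
                    "answer_domain": q.answer_domain,
                    "is_faq_eligible": q.is_faq_eligible,
                }
                for q in (self.questions[k] for k in sorted(self.questions))
            ],
            "hierarchy": self.hierarchy.to_jsonable(),
            "critical_combinations": [
                {
                    "id": c.id,
                    "members": sorted(c.members),
                    "urgency_label": c.urgency_label,
                }
                for c in self.critical_combinations
            ],
        }

    @classmethod
    def from_jsonable(cls, data: Mapping) -> "QuestionBank":
        try:
            raw_questions = data["questions"]
            raw_hierarchy = data["hierarchy"]
            raw_combs = data["critical_combinations"]
            version = str(data["schema_version"])
        except (KeyError, TypeError) as exc:
            raise BankFormatError(f"bank file missing top-level key: {exc}") from exc
        questions: dict[int, Question] = {}
        for rec in raw_questions:
            try:
                q = Question(
                    id=int(rec["id"]),
                    text=rec["text"],
                    topic_path=tuple(rec["topic_path"]),
                    answer_domain=rec.get("answer_domain", "binary"),
                    is_faq_eligible=bool(rec.get("is_faq_eligible", True)),
                )
            except (KeyError, TypeError) as exc:
                raise BankFormatError(f"malformed question record {rec!r}") from exc
            if q.id in questions:
                raise BankIntegrityError(f"duplicate question id {q.id}")
            questions[q.id] = q
        combs = []
        for rec in raw_combs:
            try:
                combs.append(
                    CriticalCombination(
                        id=int(rec["id"]),
                        members=frozenset(int(m) for m in rec["members"]),
                        urgency_label=rec["urgency_label"],
                    )
                )
            except (KeyError, TypeError) as exc:
                raise BankFormatError(f"malformed combination record {rec!r}") from exc
        return cls(
            questions=questions,
            hierarchy=TopicHierarchy.from_jsonable(raw_hierarchy),
            critical_combinations=combs,
            schema_version=version,
        )


def load_bank(path: str | Path) -> QuestionBank:
    """Load and validate a question bank from its JSON file."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise BankFormatError(f"{path}: not valid JSON ({exc})") from exc
    return QuestionBank.from_jsonable(data)


def save_bank(bank: QuestionBank, path: str | Path) -> None:
    """Write a bank to disk; ``load_bank`` of the result is the identity."""
    Path(path).write_text(json.dumps(bank.to_jsonable(), indent=1, sort_keys=True))


def search_questions(bank: QuestionBank, query: str) -> list[Question]:
    """Case-insensitive token-AND search over question texts.

    Every whitespace token of ``query`` must occur as a substring of the
    question text.  Results are ordered by (matched token count desc, id asc);
    with AND semantics the first key is constant, so ordering is by id.
    """
    tokens = [t.lower() for t in query.split()]
    if not tokens:
        raise ValueError("query is empty after trimming")
    hits: list[tuple[int, int, Question]] = []
    for qid in sorted(bank.questions):
        text = bank.questions[qid].text.lower()
        matched = sum(1 for t in tokens if t in text)
        if matched == len(tokens):
            hits.append((-matched, qid, bank.questions[qid]))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [q for _, _, q in hits]


def combinations_for(bank: QuestionBank, question_id: int) -> list[CriticalCombination]:
    """All critical combinations containing ``question_id``, ascending id.

    This is what the interface shows when an operator clicks a highlighted
    symptom: which constellations the symptom could complete.
    """
    bank.question(question_id)
    return sorted(
        (c for c in bank.critical_combinations if question_id in c.members),
        key=lambda c: c.id,
    )
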