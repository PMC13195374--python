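"""Live state of one triage call and its structured documentation.

A :class:`CallSession` accumulates the operator's confirmed/negated answers
in order, the patient header, and the final disposition.  From that state
two derived views are computed:

* :func:`compute_highlights` — the pink/red alerting rule over critical
  symptom combinations.  A combination whose members are all confirmed turns
  ``critical`` (red); a combination exactly one unanswered member short,
  with none of its members negated, turns every member — including the
  missing one — ``near_critical`` (pink).  A negated member kills a
  combination's highlight: a denied symptom cannot complete a constellation.
* :func:`render_document` — the structured documentation: answered
  questions grouped by the bank's hierarchy traversal order, then by the
  order in which they were answered within a topic.

Both are pure functions of (bank, answer log), so they can be recomputed
from scratch at any point and compared with incremental updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .question_bank import ANSWER_CONFIRMED, ANSWER_NEGATED, ANSWERS, QuestionBank

DEFAULT_URGENCY_LEVELS = ("acute", "urgent", "routine", "advice_only")
DEFAULT_RESPONSE_MENU = (
    "ambulance",
    "clinic_appointment",
    "doctor_callback",
    "home_visit",
    "self_care_advice",
)

UNKNOWN = "unknown"
CALLER_RELATIONS = ("self", "relative", "bystander", "professional", "other", UNKNOWN)
SEXES = ("female", "male", UNKNOWN)


class SessionStateError(RuntimeError):
    """An operation conflicts with the session's current state."""


class Highlight(str, Enum):
    NONE = "none"
    NEAR_CRITICAL = "near_critical"
    CRITICAL = "critical"


@dataclass
class PatientHeader:
    age: int | str = UNKNOWN
    sex: str = UNKNOWN
    caller_relation: str = UNKNOWN
    note: str = ""

    def __post_init__(self) -> None:
        if self.age != UNKNOWN and (not isinstance(self.age, int) or self.age < 0):
            raise ValueError(f"age must be a non-negative integer or 'unknown', got {self.age!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.caller_relation not in CALLER_RELATIONS:
            raise ValueError(f"caller_relation must be one of {CALLER_RELATIONS}")


@dataclass(frozen=True)
class AnswerEntry:
    question_id: int
    answer: str
    index: int


@dataclass(frozen=True)
class Disposition:
    urgency: str
    response: str
    set_at: int


@dataclass(frozen=True)
class DocumentEntry:
    topic_path: tuple[str, ...]
    question_text: str
    answer: str


@dataclass
class StructuredDocument:
    entries: list[DocumentEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


class CallSession:
    """One call in progress: answers are append-only, the disposition is
    last-write-wins with an audit trail."""

    def __init__(
        self,
        bank: QuestionBank,
        header: PatientHeader | None = None,
        urgency_levels: Sequence[str] = DEFAULT_URGENCY_LEVELS,
        response_menu: Sequence[str] = DEFAULT_RESPONSE_MENU,
    ) -> None:
        self.bank = bank
        self.header = header or PatientHeader()
        self.urgency_levels = tuple(urgency_levels)
        self.response_menu = tuple(response_menu)
        self.answers: list[AnswerEntry] = []
        self._answered: dict[int, str] = {}
        self.disposition: Disposition | None = None
        self.disposition_audit: list[Disposition] = []

    # -- answers ----------------------------------------------------------

    def record_answer(self, question_id: int, answer: str) -> "CallSession":
        if answer not in ANSWERS:
            raise ValueError(f"answer must be one of {ANSWERS}, got {answer!r}")
        self.bank.question(question_id)
        if question_id in self._answered:
            raise SessionStateError(f"question {question_id} already answered")
        self.answers.append(AnswerEntry(question_id, answer, len(self.answers)))
        self._answered[question_id] = answer
        return self

    def answer_for(self, question_id: int) -> str | None:
        return self._answered.get(question_id)

    @property
    def answered_ids(self) -> set[int]:
        return set(self._answered)

    # -- disposition ------------------------------------------------------

    def set_disposition(self, urgency: str, response: str) -> "CallSession":
        if urgency not in self.urgency_levels:
            raise ValueError(f"urgency {urgency!r} not in menu {self.urgency_levels}")
        if response not in self.response_menu:
            raise ValueError(f"response {response!r} not in menu {self.response_menu}")
        disp = Disposition(urgency, response, set_at=len(self.answers))
        self.disposition = disp
        self.disposition_audit.append(disp)
        return self

    # -- export -----------------------------------------------------------

    def to_jsonable(self) -> dict:
        return {
            "header": {
                "age": self.header.age,
                "sex": self.header.sex,
                "caller_relation": self.header.caller_relation,
                "note": self.header.note,
            },
            "answers": [[e.question_id, e.answer] for e in self.answers],
            "disposition": None
            if self.disposition is None
            else {
                "urgency": self.disposition.urgency,
                "response": self.disposition.response,
                "set_at": self.disposition.set_at,
            },
        }

    def to_jsonl_line(self) -> str:
        return json.dumps(self.to_jsonable(), sort_keys=True)


def replay_session(bank: QuestionBank, answers: Iterable[tuple[int, str]]) -> CallSession:
    """Build a session by replaying an ordered (question id, answer) sequence."""
    session = CallSession(bank)
    for qid, answer in answers:
        session.record_answer(qid, answer)
    return session


def compute_highlights(session: CallSession, bank: QuestionBank | None = None) -> dict[int, Highlight]:
    """Highlight state per question id under the pink/red combination rule.

    For each critical combination:

    * every member confirmed → all members ``critical``;
    * exactly one member unanswered, the rest confirmed, none negated →
      all members including the unanswered one ``near_critical``;
    * any member negated, or more than one missing → no contribution.

    ``critical`` overrides ``near_critical`` per question; all other
    questions map to ``none``.
    """
    bank = bank or session.bank
    state: dict[int, Highlight] = {qid: Highlight.NONE for qid in bank.questions}
    for comb in bank.critical_combinations:
        answers = [session.answer_for(m) for m in sorted(comb.members)]
        if any(a == ANSWER_NEGATED for a in answers):
            continue
        n_confirmed = sum(a == ANSWER_CONFIRMED for a in answers)
        if n_confirmed == len(comb.members):
            for m in comb.members:
                state[m] = Highlight.CRITICAL
        elif n_confirmed == len(comb.members) - 1:
            for m in comb.members:
                if state[m] is not Highlight.CRITICAL:
                    state[m] = Highlight.NEAR_CRITICAL
    return state


def render_document(session: CallSession, bank: QuestionBank | None = None) -> StructuredDocument:
    """The hierarchy-ordered structured documentation of answered questions.

    Entries are sorted by (topic display rank, answer sequence index): the
    hierarchy fixes the between-topic order regardless of when questions
    were answered, and entry order breaks ties within a topic.
    """
    bank = bank or session.bank
    keyed = []
    for entry in session.answers:
        q = bank.question(entry.question_id)
        keyed.append((bank.hierarchy.rank(q.topic_path), entry.index, q, entry.answer))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return StructuredDocument(
        entries=[DocumentEntry(q.topic_path, q.text, answer) for _, _, q, answer in keyed]
    )
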