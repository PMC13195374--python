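"""Synthetic study data: question banks, archetype-driven call corpora,
scripted fine-tuning scenarios, and paired pre/post rating tables.

No real call data ships with this package.  The simulator stands in for it
by emulating the study conditions the analysis layer expects:

* a bank of 1200 predefined binary questions over a two-level topic
  hierarchy (organ system -> symptom group) with 25 critical symptom
  combinations of 2-4 members;
* call corpora drawn from a mixture of 15 case archetypes.  Each archetype
  has a prevalence weight, a preferred topic order, per-question ask
  affinities and confirm probabilities, and (for the high-urgency
  archetypes) an embedded critical combination that expresses with a fixed
  probability — giving the recommender learnable co-occurrence and
  sequence structure, and CART a planted critical-case rule;
* exactly ``n_cases`` scripted scenarios with a fixed opening topic and
  deterministic answers, labelled as the fine-tuning split;
* paired ratings for 22 operators x 15 cases x 2 phases in the quality
  assessment tool's structure (0-10 overall items, 1-5 Likert items with
  an NA category, a 7-category triage-accuracy item), generated from a
  crossed random-intercepts model with a planted treatment shift on
  overall medical quality.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .question_bank import (
    ANSWER_CONFIRMED,
    ANSWER_NEGATED,
    CriticalCombination,
    Question,
    QuestionBank,
    TopicHierarchy,
)
from .session_engine import DEFAULT_URGENCY_LEVELS

# two-level synthetic hierarchy: organ system -> symptom group.
# Labels are placeholders for ordering only, not clinical content.
ORGAN_SYSTEMS = (
    "airway", "breathing", "circulation", "neurology", "abdomen",
    "musculoskeletal", "skin", "mental_health", "ent", "general",
)
SYMPTOM_GROUPS = ("onset", "character", "severity", "associated")

_ADJECTIVES = (
    "sudden", "severe", "persistent", "intermittent", "worsening", "radiating",
    "localized", "diffuse", "recurrent", "new",
)
_FINDINGS = (
    "pain", "swelling", "bleeding", "rash", "fever", "dizziness", "weakness",
    "numbness", "shortness of breath", "nausea", "confusion", "palpitations",
)

# planted rating-model defaults.  The treatment shift and variance
# components are chosen jointly so that the planted overall-medical
# configuration has ICC_op = 0.17, ICC_case = 0.42 and paired effect size
# dz = delta / (sigma_e * sqrt(2)) = 0.16 at delta = 0.34.
DELTA_MEDICAL = 0.34
SIGMA_E = 0.34 / (0.16 * np.sqrt(2.0))  # 1.5026
_TOTAL_VAR = SIGMA_E**2 / (1.0 - 0.17 - 0.42)
SIGMA_OP = float(np.sqrt(0.17 * _TOTAL_VAR))  # 0.9674
SIGMA_CASE = float(np.sqrt(0.42 * _TOTAL_VAR))  # 1.5206

# per-item (pretest mean, pre->post shift) for the four 0-10 overall items
OVERALL_ITEMS = {
    "overall_medical": (6.83, DELTA_MEDICAL),
    "overall_communication": (7.06, -0.09),
    "overall_safety": (7.92, 0.07),
    "overall_efficiency": (6.67, 0.17),
}
MEDICAL_LIKERT_ITEMS = tuple(f"medical_{i}" for i in range(1, 10))
COMMUNICATION_LIKERT_ITEMS = tuple(f"communication_{i}" for i in range(1, 10))
TRIAGE_ITEM = "triage_accuracy"

SCALE_OVERALL = "overall10"
SCALE_LIKERT = "likert5"
SCALE_TRIAGE = "triage7"

# default 7x7 joint pre/post kernel for the triage-accuracy item: mass
# concentrated on optimal triage with mild categories adjacent, matching
# the transition structure observed in paired simulated-call studies.
DEFAULT_TRIAGE_KERNEL = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, 5, 0, 0, 0],
        [0, 1, 15, 24, 2, 1, 0],
        [0, 2, 10, 189, 16, 5, 0],
        [0, 0, 1, 17, 10, 2, 0],
        [0, 0, 0, 5, 5, 7, 0],
        [0, 0, 0, 0, 0, 1, 1],
    ],
    dtype=float,
)
DEFAULT_TRIAGE_KERNEL /= DEFAULT_TRIAGE_KERNEL.sum()


@dataclass
class SimConfig:
    """All simulator knobs, with defaults at the emulated study conditions."""

    seed: int
    n_questions: int = 1200
    n_archetypes: int = 15
    n_calls: int = 2000
    n_operators: int = 22
    n_cases: int = 15
    n_combinations: int = 25
    combination_sizes: tuple[int, int] = (2, 4)
    seq_len_range: tuple[int, int] = (6, 18)
    epsilon: float = 0.2  # probability of an adjacent-order swap
    embed_prob: float = 0.7  # chance a critical archetype expresses its combination
    # rating-model parameters
    delta_medical: float = DELTA_MEDICAL
    sigma_op: float = SIGMA_OP
    sigma_case: float = SIGMA_CASE
    sigma_e: float = SIGMA_E
    likert_mu: float = 3.6
    likert_sigma_scale: float = 0.5
    likert_cutpoints: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5)
    na_prob: float = 0.1
    triage_kernel: np.ndarray = field(default_factory=lambda: DEFAULT_TRIAGE_KERNEL.copy())

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("sigma_op", "sigma_case", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        kernel = np.asarray(self.triage_kernel, dtype=float)
        if kernel.shape != (7, 7) or (kernel < 0).any():
            raise ValueError("triage_kernel must be a non-negative 7x7 array")
        self.triage_kernel = kernel / kernel.sum()

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items() if k != "triage_kernel"}
        data["triage_kernel"] = np.asarray(self.triage_kernel).tolist()
        for key in ("combination_sizes", "seq_len_range", "likert_cutpoints"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("combination_sizes", "seq_len_range", "likert_cutpoints"):
            if key in data:
                data[key] = tuple(data[key])
        if "triage_kernel" in data:
            data["triage_kernel"] = np.asarray(data["triage_kernel"], dtype=float)
        return cls(**data)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent substreams per generator so corpora and ratings decouple
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# bank generation
# ---------------------------------------------------------------------------


def generate_bank(config: SimConfig) -> QuestionBank:
    """Deterministic synthetic bank: ``n_questions`` binary questions over
    the two-level hierarchy plus ``n_combinations`` critical combinations
    of 2-4 members.  Texts are placeholders, not clinical content."""
    if config.n_questions < 1:
        raise ValueError("n_questions must be >= 1")
    rng = _rng(config, 1)
    leaves = [(s, g) for s in ORGAN_SYSTEMS for g in SYMPTOM_GROUPS]
    hierarchy = TopicHierarchy(
        [(s, [(g, []) for g in SYMPTOM_GROUPS]) for s in ORGAN_SYSTEMS]
    )
    questions: dict[int, Question] = {}
    for qid in range(config.n_questions):
        system, group = leaves[qid % len(leaves)]
        adj = _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))]
        finding = _FINDINGS[int(rng.integers(len(_FINDINGS)))]
        questions[qid] = Question(
            id=qid,
            text=f"Does the patient have {adj} {finding} ({system} {group}, item {qid})?",
            topic_path=(system, group),
            is_faq_eligible=True,
        )
    combs: list[CriticalCombination] = []
    seen: set[frozenset[int]] = set()
    lo, hi = config.combination_sizes
    max_size = min(hi, config.n_questions)
    cid = 0
    while len(combs) < config.n_combinations and max_size >= max(lo, 1):
        size = int(rng.integers(max(min(lo, max_size), 1), max_size + 1))
        members = frozenset(int(q) for q in rng.choice(config.n_questions, size=size, replace=False))
        if members in seen:
            continue
        seen.add(members)
        combs.append(CriticalCombination(id=cid, members=members, urgency_label="acute"))
        cid += 1
    return QuestionBank(questions=questions, hierarchy=hierarchy, critical_combinations=combs)


# ---------------------------------------------------------------------------
# archetypes and call corpora
# ---------------------------------------------------------------------------


@dataclass
class Archetype:
    """One synthetic case profile in the mixture that generates calls."""

    id: int
    prevalence: float
    urgency_label: str
    confirm_probs: np.ndarray  # per bank question, in question-id order
    ask_weights: np.ndarray  # sampling affinity per question
    topic_order: tuple[str, ...]  # preferred order of top-level topics
    embedded_combination_id: int | None = None


def default_archetypes(bank: QuestionBank, config: SimConfig) -> list[Archetype]:
    """The archetype mixture: each archetype prefers ~3 organ systems,
    confirms its characteristic questions often, and the first third of
    archetypes embed a critical combination (urgency 'acute')."""
    rng = _rng(config, 2)
    qids = bank.question_ids()
    n = len(qids)
    raw = rng.dirichlet(np.full(config.n_archetypes, 5.0))
    archetypes: list[Archetype] = []
    n_critical = max(1, config.n_archetypes // 3)
    for a in range(config.n_archetypes):
        order = tuple(rng.permutation(ORGAN_SYSTEMS))
        preferred = set(order[:3])
        weights = np.ones(n)
        confirm = rng.uniform(0.05, 0.40, size=n)
        for i, qid in enumerate(qids):
            if bank.question(qid).topic_path[0] in preferred:
                weights[i] = 20.0
                confirm[i] = rng.uniform(0.55, 0.95)
        embedded = None
        urgency = str(rng.choice(("routine", "urgent", "advice_only")))
        if a < n_critical and bank.critical_combinations:
            embedded = bank.critical_combinations[a % len(bank.critical_combinations)].id
            urgency = "acute"
        archetypes.append(
            Archetype(
                id=a,
                prevalence=float(raw[a]),
                urgency_label=urgency,
                confirm_probs=confirm,
                ask_weights=weights,
                topic_order=order,
                embedded_combination_id=embedded,
            )
        )
    total = sum(at.prevalence for at in archetypes)
    for at in archetypes:
        at.prevalence /= total
    return archetypes


@dataclass
class CallRecord:
    call_id: str
    archetype_id: int
    operator_id: int
    phase: str  # "pre" | "post"
    sequence: list[tuple[int, str]]
    urgency: str
    critical: bool
    split: str = "train"

    def to_jsonable(self) -> dict:
        return {
            "call_id": self.call_id,
            "archetype_id": self.archetype_id,
            "operator_id": self.operator_id,
            "phase": self.phase,
            "sequence": [[qid, a] for qid, a in self.sequence],
            "urgency": self.urgency,
            "critical": self.critical,
            "split": self.split,
        }

    @classmethod
    def from_jsonable(cls, data: dict) -> "CallRecord":
        return cls(
            call_id=data["call_id"],
            archetype_id=int(data["archetype_id"]),
            operator_id=int(data["operator_id"]),
            phase=data["phase"],
            sequence=[(int(q), a) for q, a in data["sequence"]],
            urgency=data["urgency"],
            critical=bool(data["critical"]),
            split=data.get("split", "train"),
        )


@dataclass
class CallCorpus:
    bank: QuestionBank
    records: list[CallRecord] = field(default_factory=list)

    def subset(self, split: str) -> "CallCorpus":
        return CallCorpus(self.bank, [r for r in self.records if r.split == split])

    @property
    def splits(self) -> set[str]:
        return {r.split for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


def save_corpus(corpus: CallCorpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in corpus.records:
            fh.write(json.dumps(rec.to_jsonable(), sort_keys=True) + "\n")


def load_corpus(path: str | Path, bank: QuestionBank) -> CallCorpus:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(CallRecord.from_jsonable(json.loads(line)))
    return CallCorpus(bank, records)


def _is_critical(sequence: Sequence[tuple[int, str]], bank: QuestionBank) -> bool:
    confirmed = {qid for qid, a in sequence if a == ANSWER_CONFIRMED}
    return any(c.members <= confirmed for c in bank.critical_combinations)


def _canonical_order(
    asked: Sequence[int], bank: QuestionBank, archetype: Archetype
) -> list[int]:
    topic_rank = {t: i for i, t in enumerate(archetype.topic_order)}
    return sorted(
        asked,
        key=lambda qid: (topic_rank.get(bank.question(qid).topic_path[0], len(topic_rank)), qid),
    )


def _epsilon_swaps(order: list[int], epsilon: float, rng: np.random.Generator) -> list[int]:
    order = list(order)
    for i in range(len(order) - 1):
        if epsilon > 0 and rng.random() < epsilon:
            order[i], order[i + 1] = order[i + 1], order[i]
    return order


def generate_corpus(
    bank: QuestionBank,
    archetypes: Sequence[Archetype],
    config: SimConfig,
    n_calls: int | None = None,
    split: str = "train",
    phase: str = "pre",
    stream: int = 3,
) -> CallCorpus:
    """Draw ``n_calls`` archetype-mixture calls.

    Per call: archetype by prevalence; asked set sampled without
    replacement by the archetype's affinities (its embedded combination is
    forced in and confirmed with probability ``embed_prob``); asked order
    is the archetype's preferred topic order perturbed by epsilon-random
    adjacent swaps; remaining answers are independent Bernoulli draws with
    the archetype's per-question confirm probability.
    """
    prevalences = np.array([a.prevalence for a in archetypes])
    if not np.isclose(prevalences.sum(), 1.0):
        raise ValueError("archetype prevalences must be normalized")
    n_calls = n_calls if n_calls is not None else config.n_calls
    rng = _rng(config, stream)
    qids = bank.question_ids()
    qpos = {qid: i for i, qid in enumerate(qids)}
    qarr = np.array(qids)
    records: list[CallRecord] = []
    comb_by_id = {c.id: c for c in bank.critical_combinations}
    lo, hi = config.seq_len_range
    for c in range(n_calls):
        a = archetypes[int(rng.choice(len(archetypes), p=prevalences))]
        operator = int(rng.integers(config.n_operators))
        length = int(rng.integers(lo, hi + 1))
        forced: list[int] = []
        if a.embedded_combination_id is not None and rng.random() < config.embed_prob:
            forced = sorted(comb_by_id[a.embedded_combination_id].members)
        weights = a.ask_weights.copy()
        for qid in forced:
            weights[qpos[qid]] = 0.0
        n_free = max(length - len(forced), 0)
        n_free = min(n_free, int((weights > 0).sum()))
        free = rng.choice(qarr, size=n_free, replace=False, p=weights / weights.sum()) if n_free else []
        asked = forced + [int(q) for q in free]
        order = _epsilon_swaps(_canonical_order(asked, bank, a), config.epsilon, rng)
        forced_set = set(forced)
        sequence = []
        for qid in order:
            if qid in forced_set:
                answer = ANSWER_CONFIRMED
            else:
                p = a.confirm_probs[qpos[qid]]
                answer = ANSWER_CONFIRMED if rng.random() < p else ANSWER_NEGATED
            sequence.append((qid, answer))
        records.append(
            CallRecord(
                call_id=f"{split}-{c:06d}",
                archetype_id=a.id,
                operator_id=operator,
                phase=phase,
                sequence=sequence,
                urgency=a.urgency_label,
                critical=_is_critical(sequence, bank),
                split=split,
            )
        )
    return CallCorpus(bank, records)


def generate_scenarios(bank: QuestionBank, config: SimConfig) -> CallCorpus:
    """Exactly ``n_cases`` scripted scenarios for fine-tuning.

    Each scenario opens on a fixed topic (the archetype's first preferred
    organ system, emulating a predefined opening line), asks its
    archetype's most characteristic questions in canonical order with no
    swap noise, and answers deterministically (confirmed iff the confirm
    probability is at least 0.5; embedded combinations always confirmed).
    """
    if config.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    archetypes = default_archetypes(bank, config)
    qids = bank.question_ids()
    qpos = {qid: i for i, qid in enumerate(qids)}
    comb_by_id = {c.id: c for c in bank.critical_combinations}
    length = (config.seq_len_range[0] + config.seq_len_range[1]) // 2
    records = []
    for j in range(config.n_cases):
        a = archetypes[j % len(archetypes)]
        forced = (
            sorted(comb_by_id[a.embedded_combination_id].members)
            if a.embedded_combination_id is not None
            else []
        )
        opening_topic = a.topic_order[0]
        # most characteristic questions, opening-topic questions first
        ranked = sorted(
            (q for q in qids if q not in forced),
            key=lambda q: (
                bank.question(q).topic_path[0] != opening_topic,
                -a.ask_weights[qpos[q]],
                q,
            ),
        )
        asked = forced + ranked[: max(length - len(forced), 1)]
        order = _canonical_order(asked, bank, a)
        # the scripted opening line: the scenario starts on the opening topic
        order.sort(key=lambda q: bank.question(q).topic_path[0] != opening_topic)
        sequence = []
        for qid in order:
            if qid in forced:
                answer = ANSWER_CONFIRMED
            else:
                answer = (
                    ANSWER_CONFIRMED
                    if a.confirm_probs[qpos[qid]] >= 0.5
                    else ANSWER_NEGATED
                )
            sequence.append((qid, answer))
        records.append(
            CallRecord(
                call_id=f"scenario-{j:02d}",
                archetype_id=a.id,
                operator_id=-1,
                phase="pre",
                sequence=sequence,
                urgency=a.urgency_label,
                critical=_is_critical(sequence, bank),
                split="finetune",
            )
        )
    return CallCorpus(bank, records)


# ---------------------------------------------------------------------------
# paired pre/post ratings
# ---------------------------------------------------------------------------

RATING_COLUMNS = ["call_id", "operator_id", "case_id", "phase", "item_id", "scale", "value"]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _clipped_normal_mean(a: np.ndarray, sigma: float, lo: float = 0.0, hi: float = 10.0):
    """E[clip(X, lo, hi)] for X ~ Normal(a, sigma^2), elementwise in a."""
    from scipy.stats import norm

    if sigma == 0:
        return np.clip(a, lo, hi)
    alpha = (lo - a) / sigma
    beta = (hi - a) / sigma
    return (
        a
        + sigma * (norm.pdf(alpha) - norm.pdf(beta))
        + (lo - a) * norm.cdf(alpha)
        + (hi - a) * (1.0 - norm.cdf(beta))
    )


def _observed_mean(mu: float, sigma_u: float, sigma_e: float) -> float:
    """Expected clipped rating when the latent is mu + u + e with
    u ~ Normal(0, sigma_u^2) (combined random intercepts) and
    e ~ Normal(0, sigma_e^2); Gauss-Hermite over u."""
    u = _GH_NODES * sigma_u
    return float(np.sum(_GH_WEIGHTS * _clipped_normal_mean(mu + u, sigma_e)))


def _latent_mean_for(target: float, sigma_u: float, sigma_e: float) -> float:
    """The latent mean whose observed (clipped) mean equals ``target``.

    Ceiling clipping on a bounded 0-10 scale attenuates means and shifts;
    solving for the latent mean makes the generated data's observed-scale
    statistics — the quantities the analysis layer recovers — equal the
    planted targets exactly in expectation.
    """
    from scipy.optimize import brentq

    if sigma_u == 0 and sigma_e == 0:
        return target
    lo, hi = target - 1.0, target + 6.0 * (sigma_u + sigma_e)
    return float(brentq(lambda m: _observed_mean(m, sigma_u, sigma_e) - target, lo, hi))


def generate_ratings(config: SimConfig) -> pd.DataFrame:
    """Paired pre/post rating table for n_operators x n_cases calls.

    Overall items follow mu_phase + b_op + c_case + e with independent
    normal random intercepts per item, clipped to [0, 10]; the planted
    pre->post shift on overall medical quality is ``delta_medical``.
    Likert items threshold a latent normal into categories 1-5 with NA
    probability ``na_prob``; the triage item draws the (pre, post) pair
    jointly from ``triage_kernel``.
    """
    rng = _rng(config, 4)
    rows: list[tuple] = []
    n_op, n_case = config.n_operators, config.n_cases
    likert_sigmas = (
        config.sigma_op * config.likert_sigma_scale,
        config.sigma_case * config.likert_sigma_scale,
        config.sigma_e * config.likert_sigma_scale,
    )

    def add(op, case, phase, item, scale, value):
        rows.append((f"c{op:02d}-{case:02d}-{phase}", op, case, phase, item, scale, value))

    sigma_u = float(np.hypot(config.sigma_op, config.sigma_case))
    for item, (mu_pre, delta) in OVERALL_ITEMS.items():
        b = rng.normal(0.0, config.sigma_op, size=n_op)
        c = rng.normal(0.0, config.sigma_case, size=n_case)
        if item == "overall_medical":
            delta = config.delta_medical
        # latent means calibrated so the observed (ceiling-clipped) means
        # equal the planted pre/post targets in expectation
        latent = {
            "pre": _latent_mean_for(mu_pre, sigma_u, config.sigma_e),
            "post": _latent_mean_for(mu_pre + delta, sigma_u, config.sigma_e),
        }
        for op in range(n_op):
            for case in range(n_case):
                for phase in ("pre", "post"):
                    value = latent[phase] + b[op] + c[case] + rng.normal(0.0, config.sigma_e)
                    add(op, case, phase, item, SCALE_OVERALL, float(np.clip(value, 0.0, 10.0)))

    s_op, s_case, s_e = likert_sigmas
    for item in MEDICAL_LIKERT_ITEMS + COMMUNICATION_LIKERT_ITEMS:
        b = rng.normal(0.0, s_op, size=n_op)
        c = rng.normal(0.0, s_case, size=n_case)
        for op in range(n_op):
            for case in range(n_case):
                for phase in ("pre", "post"):
                    if rng.random() < config.na_prob:
                        add(op, case, phase, item, SCALE_LIKERT, np.nan)
                        continue
                    latent = config.likert_mu + b[op] + c[case] + rng.normal(0.0, s_e)
                    category = 1 + int(np.searchsorted(config.likert_cutpoints, latent))
                    add(op, case, phase, item, SCALE_LIKERT, float(np.clip(category, 1, 5)))

    kernel = config.triage_kernel.ravel()
    for op in range(n_op):
        for case in range(n_case):
            cell = int(rng.choice(49, p=kernel))
            pre_cat, post_cat = divmod(cell, 7)
            add(op, case, "pre", TRIAGE_ITEM, SCALE_TRIAGE, float(pre_cat + 1))
            add(op, case, "post", TRIAGE_ITEM, SCALE_TRIAGE, float(post_cat + 1))

    return pd.DataFrame(rows, columns=RATING_COLUMNS)


def save_ratings(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="NA")


def load_ratings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"])


def generate_manifest(
    config: SimConfig, n_unavailable: int = 4, n_missing_audio: int = 6
) -> pd.DataFrame:
    """Planned-call manifest for the pairing filter: one row per
    (operator, case, phase) with availability and audio-retrieval flags.
    Defaults flag 4 pairs unavailable and 6 with missing audio, disjointly."""
    rng = _rng(config, 5)
    pairs = [(op, case) for op in range(config.n_operators) for case in range(config.n_cases)]
    flagged = rng.choice(len(pairs), size=n_unavailable + n_missing_audio, replace=False)
    unavailable = {pairs[i] for i in flagged[:n_unavailable]}
    missing_audio = {pairs[i] for i in flagged[n_unavailable:]}
    rows = []
    for op, case in pairs:
        for phase in ("pre", "post"):
            # the flag hits one phase of the pair; either phase failing drops it
            hit = phase == ("pre" if (op + case) % 2 == 0 else "post")
            rows.append(
                {
                    "operator_id": op,
                    "case_id": case,
                    "phase": phase,
                    "available": not ((op, case) in unavailable and hit),
                    "audio_ok": not ((op, case) in missing_audio and hit),
                }
            )
    return pd.DataFrame(rows)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of the config with a different seed (for replications)."""
    return replace(config, triage_kernel=config.triage_kernel.copy(), seed=seed)
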