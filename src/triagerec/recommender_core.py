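"""The hybrid 8-slot next-question recommender.

Four prediction strategies fill a dynamically updated list of 8 questions:

* **slot 1** — a CART classifier trained on question combinations specific
  to critical cases; the slot proposes the first unanswered split question
  on the session's active decision path (the maximally informative
  unresolved feature), falling back to the question that would complete the
  most near-critical symptom combinations.
* **slots 2–4** — alternating least squares (ALS) matrix factorization over
  the call × question interaction matrix; candidates are unanswered
  questions in topics already introduced in the conversation, ranked by the
  projected session factor's score.
* **slots 5–7** — similar calls: top-m training calls by cosine similarity
  to the session vector contribute a candidate pool, blended with a small
  recurrent network's next-question distribution by a convex weight alpha.
* **slot 8** — the most frequently asked question not already featured
  higher in the list (no prediction applied).

Sessions are encoded as signed vectors over the bank (+1 confirmed, -1
negated, 0 unasked) so that negation is distinguishable from absence.
All tie-breaks are by lowest question id, making composition deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import yaml
from sklearn.tree import DecisionTreeClassifier

from .question_bank import ANSWER_CONFIRMED, ANSWER_NEGATED, QuestionBank
from .session_engine import CallSession, Highlight, compute_highlights

if TYPE_CHECKING:  # pragma: no cover
    from .call_simulator import CallCorpus


class TrainingError(RuntimeError):
    """A model cannot be trained on the given corpus."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RecommenderConfig:
    """All tunables of the recommender, surfaced in one place.

    ALS: rank ``k``, ridge penalty ``lam``, ``als_iterations``.
    Similar-calls blend: ``m`` retrieved neighbours, convex weight ``alpha``
    on the similarity-pool term (1 - alpha goes to the RNN probability).
    CART: ``cart_max_depth`` / ``cart_min_leaf``.  RNN: Elman network with
    ``rnn_hidden`` units trained for ``rnn_epochs`` epochs at ``rnn_lr``.
    """

    k: int = 16
    lam: float = 0.1
    als_iterations: int = 15
    m: int = 20
    alpha: float = 0.5
    cart_max_depth: int = 6
    cart_min_leaf: int = 5
    rnn_hidden: int = 32
    rnn_epochs: int = 3
    rnn_lr: float = 0.1
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)

    @classmethod
    def from_yaml(cls, path) -> "RecommenderConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# session encoding and the interaction matrix
# ---------------------------------------------------------------------------


def _answer_sign(answer: str) -> int:
    return 1 if answer == ANSWER_CONFIRMED else -1


def session_vector(
    session_or_answers: CallSession | Sequence[tuple[int, str]],
    bank: QuestionBank,
    index: dict[int, int] | None = None,
) -> np.ndarray:
    """Signed encoding of a session over the bank's question axis:
    +1 confirmed, -1 negated, 0 unasked."""
    index = index if index is not None else question_index(bank)
    v = np.zeros(len(index))
    if isinstance(session_or_answers, CallSession):
        pairs: Iterable[tuple[int, str]] = (
            (e.question_id, e.answer) for e in session_or_answers.answers
        )
    else:
        pairs = session_or_answers
    for qid, answer in pairs:
        v[index[qid]] = _answer_sign(answer)
    return v


def question_index(bank: QuestionBank) -> dict[int, int]:
    return {qid: i for i, qid in enumerate(bank.question_ids())}


@dataclass
class InteractionMatrix:
    """Calls x questions matrix of signed session vectors."""

    matrix: np.ndarray
    call_ids: list
    question_ids: list[int]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.call_ids), len(self.question_ids)):
            raise ValueError("matrix shape inconsistent with id lists")
        if not np.isin(self.matrix, (-1.0, 0.0, 1.0)).all():
            raise ValueError("interaction entries must be in {-1, 0, +1}")


def interaction_matrix(corpus: "CallCorpus", bank: QuestionBank) -> InteractionMatrix:
    qids = bank.question_ids()
    idx = {qid: i for i, qid in enumerate(qids)}
    rows = np.zeros((len(corpus.records), len(qids)))
    call_ids = []
    for r, rec in enumerate(corpus.records):
        call_ids.append(rec.call_id)
        for qid, answer in rec.sequence:
            rows[r, idx[qid]] = _answer_sign(answer)
    return InteractionMatrix(rows, call_ids, qids)


# ---------------------------------------------------------------------------
# slot 1: CART over critical cases
# ---------------------------------------------------------------------------


@dataclass
class CartModel:
    """Decision tree flagging likely critical calls; exposes the fitted
    sklearn tree plus the question-id axis so the slot-1 walk can map
    split features back to bank questions."""

    tree: DecisionTreeClassifier
    question_ids: list[int]

    def predict_proba_critical(self, vector: np.ndarray) -> float:
        proba = self.tree.predict_proba(vector.reshape(1, -1))[0]
        classes = list(self.tree.classes_)
        return float(proba[classes.index(True)]) if True in classes else 0.0


def train_cart(
    corpus: "CallCorpus",
    bank: QuestionBank,
    config: RecommenderConfig | None = None,
) -> CartModel:
    """Fit the critical-case tree on full-call signed vectors vs the
    critical flag.  Requires both classes present."""
    config = config or RecommenderConfig()
    mat = interaction_matrix(corpus, bank)
    y = np.array([rec.critical for rec in corpus.records], dtype=bool)
    if len(set(y.tolist())) < 2:
        raise TrainingError("corpus has a single criticality class; tree is undefined")
    tree = DecisionTreeClassifier(
        max_depth=config.cart_max_depth,
        min_samples_leaf=config.cart_min_leaf,
        random_state=config.seed,
    )
    tree.fit(mat.matrix, y)
    return CartModel(tree=tree, question_ids=mat.question_ids)


def _near_critical_completion_candidate(session: CallSession, bank: QuestionBank) -> int | None:
    """The unanswered question whose confirmation would complete the most
    near-critical combinations; ties by lowest id."""
    answered = session.answered_ids
    completions: Counter[int] = Counter()
    for comb in bank.critical_combinations:
        answers = [session.answer_for(m) for m in comb.members]
        if any(a == ANSWER_NEGATED for a in answers):
            continue
        missing = [m for m in comb.members if session.answer_for(m) is None]
        if len(missing) == 1:
            completions[missing[0]] += 1
    candidates = [(qid, n) for qid, n in completions.items() if qid not in answered]
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[0][0]


def slot1_question(session: CallSession, cart: CartModel, bank: QuestionBank) -> int | None:
    """Walk the tree along the session's known answers; return the first
    unanswered split question on the active path, else the near-critical
    completion fallback, else None."""
    t = cart.tree.tree_
    node = 0
    while t.children_left[node] != -1:  # not a leaf
        qid = cart.question_ids[t.feature[node]]
        answer = session.answer_for(qid)
        if answer is None:
            return qid
        value = float(_answer_sign(answer))
        node = t.children_left[node] if value <= t.threshold[node] else t.children_right[node]
    return _near_critical_completion_candidate(session, bank)


# ---------------------------------------------------------------------------
# slots 2-4: alternating least squares
# ---------------------------------------------------------------------------


@dataclass
class AlsModel:
    U: np.ndarray  # calls x k
    V: np.ndarray  # questions x k
    lam: float
    k: int
    iterations: int
    seed: int
    question_ids: list[int]
    objective_history: list[float] = field(default_factory=list)

    def project_session(self, vector: np.ndarray) -> np.ndarray:
        """Ridge-solve a session factor against V over the session's
        observed (non-zero) cells — the cold-start projection."""
        obs = np.nonzero(vector)[0]
        if obs.size == 0:
            return np.zeros(self.k)
        Vo = self.V[obs]
        A = Vo.T @ Vo + self.lam * np.eye(self.k)
        return np.linalg.solve(A, Vo.T @ vector[obs])

    def score(self, vector: np.ndarray) -> np.ndarray:
        """Predicted affinity of the session for every bank question."""
        return self.V @ self.project_session(vector)


def als_objective(matrix: np.ndarray, U: np.ndarray, V: np.ndarray, lam: float) -> float:
    """Regularized squared reconstruction error over observed cells."""
    mask = matrix != 0
    resid = (matrix - U @ V.T)[mask]
    return float(resid @ resid + lam * ((U * U).sum() + (V * V).sum()))


def train_als(
    matrix: InteractionMatrix,
    k: int = 16,
    lam: float = 0.1,
    iterations: int = 15,
    seed: int = 0,
) -> AlsModel:
    """Alternating ridge solves for U (call factors) and V (question
    factors) over the observed cells.  Each half-step solves its ridge
    problem exactly, so the objective is non-increasing per iteration."""
    if k < 1:
        raise ValueError("rank k must be >= 1")
    if lam <= 0:
        raise ValueError("regularization lam must be > 0")
    R = matrix.matrix
    if R.size == 0 or not np.any(R):
        raise TrainingError("interaction matrix has no observed cells")
    n_calls, n_questions = R.shape
    rng = np.random.default_rng(seed)
    U = rng.normal(scale=0.1, size=(n_calls, k))
    V = rng.normal(scale=0.1, size=(n_questions, k))
    eye = lam * np.eye(k)
    history = [als_objective(R, U, V, lam)]
    for _ in range(iterations):
        for i in range(n_calls):
            obs = np.nonzero(R[i])[0]
            if obs.size:
                Vo = V[obs]
                U[i] = np.linalg.solve(Vo.T @ Vo + eye, Vo.T @ R[i, obs])
            else:
                U[i] = 0.0
        for j in range(n_questions):
            obs = np.nonzero(R[:, j])[0]
            if obs.size:
                Uo = U[obs]
                V[j] = np.linalg.solve(Uo.T @ Uo + eye, Uo.T @ R[obs, j])
            else:
                V[j] = 0.0
        history.append(als_objective(R, U, V, lam))
    return AlsModel(
        U=U, V=V, lam=lam, k=k, iterations=iterations, seed=seed,
        question_ids=list(matrix.question_ids), objective_history=history,
    )


def slots234_questions(
    session: CallSession, als: AlsModel, bank: QuestionBank, exclude: set[int] | None = None
) -> list[int]:
    """Up to 3 unanswered questions from topics already introduced in the
    conversation, ranked by ALS score descending, ties by id."""
    exclude = exclude or set()
    answered = session.answered_ids
    introduced = {
        bank.question(qid).topic_path[0] for qid in answered if bank.question(qid).topic_path
    }
    if not introduced:
        return []
    idx = {qid: i for i, qid in enumerate(als.question_ids)}
    vec = session_vector(session, bank, idx)
    scores = als.score(vec)
    candidates = [
        qid
        for qid in als.question_ids
        if qid not in answered
        and qid not in exclude
        and bank.question(qid).topic_path
        and bank.question(qid).topic_path[0] in introduced
    ]
    candidates.sort(key=lambda qid: (-scores[idx[qid]], qid))
    return candidates[:3]


# ---------------------------------------------------------------------------
# slots 5-7: similar calls (cosine retrieval + RNN blend)
# ---------------------------------------------------------------------------


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two session vectors; defined as 0 when
    either vector is all-zero."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass
class SimilarityIndex:
    vectors: np.ndarray  # training calls x questions
    sequences: list[list[tuple[int, str]]]
    question_ids: list[int]

    def __post_init__(self) -> None:
        if len(self.sequences) != self.vectors.shape[0]:
            raise ValueError("one stored sequence required per stored vector")

    def top_m(self, vector: np.ndarray, m: int) -> list[tuple[int, float]]:
        """Indices and similarities of the m most similar training calls."""
        norms = np.linalg.norm(self.vectors, axis=1)
        vnorm = np.linalg.norm(vector)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.where(
                (norms > 0) & (vnorm > 0), self.vectors @ vector / (norms * vnorm + (norms == 0)), 0.0
            )
        if vnorm == 0:
            sims = np.zeros_like(sims)
        order = np.lexsort((np.arange(len(sims)), -sims))[:m]
        return [(int(i), float(sims[i])) for i in order]


def build_similarity_index(corpus: "CallCorpus", bank: QuestionBank) -> SimilarityIndex:
    mat = interaction_matrix(corpus, bank)
    return SimilarityIndex(
        vectors=mat.matrix,
        sequences=[list(rec.sequence) for rec in corpus.records],
        question_ids=mat.question_ids,
    )


class RnnModel:
    """Small Elman network predicting the next question id from the prefix
    of (question, answer) tokens.

    Input tokens are one per (question, answer) pair plus a start token;
    the output layer is a softmax over question ids, so every prediction is
    a point on the probability simplex.  Trained by truncated BPTT with
    plain SGD and gradient clipping — deliberately modest, sized for desk
    corpora rather than production traffic.
    """

    def __init__(self, question_ids: list[int], hidden: int = 32, seed: int = 0) -> None:
        self.question_ids = list(question_ids)
        self.qindex = {qid: i for i, qid in enumerate(self.question_ids)}
        self.n_questions = len(self.question_ids)
        self.hidden = hidden
        self.seed = seed
        self.epochs_trained = 0
        n_tokens = 2 * self.n_questions + 1  # start token is index 0
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(hidden)
        self.E = rng.normal(scale=scale, size=(n_tokens, hidden))  # token embedding
        self.W = rng.normal(scale=scale, size=(hidden, hidden))  # recurrence
        self.b = np.zeros(hidden)
        self.Out = rng.normal(scale=scale, size=(hidden, self.n_questions))
        self.c = np.zeros(self.n_questions)

    # token 0 = start; (q, confirmed) -> 1 + 2*idx; (q, negated) -> 2 + 2*idx
    def _token(self, qid: int, answer: str) -> int:
        base = 1 + 2 * self.qindex[qid]
        return base if answer == ANSWER_CONFIRMED else base + 1

    def _forward(self, tokens: list[int]) -> tuple[np.ndarray, list[np.ndarray]]:
        h = np.zeros(self.hidden)
        states = []
        for tok in tokens:
            h = np.tanh(self.E[tok] + self.W @ h + self.b)
            states.append(h)
        return h, states

    def predict_next(self, prefix: Sequence[tuple[int, str]]) -> np.ndarray:
        """Probability distribution over next question ids given the prefix
        (the empty prefix yields the global first-question distribution)."""
        tokens = [0] + [self._token(qid, a) for qid, a in prefix]
        h, _ = self._forward(tokens)
        logits = h @ self.Out + self.c
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()

    def _train_sequence(self, seq: list[tuple[int, str]], lr: float) -> float:
        tokens = [0] + [self._token(qid, a) for qid, a in seq[:-1]]
        targets = [self.qindex[qid] for qid, _ in seq]
        _, states = self._forward(tokens)
        T = len(tokens)
        dE = np.zeros_like(self.E)
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dOut = np.zeros_like(self.Out)
        dc = np.zeros_like(self.c)
        dh_next = np.zeros(self.hidden)
        loss = 0.0
        # backward through time; each state t emits a prediction for targets[t]
        probs = []
        for t in range(T):
            logits = states[t] @ self.Out + self.c
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            probs.append(p)
            loss -= float(np.log(max(p[targets[t]], 1e-12)))
        for t in range(T - 1, -1, -1):
            dlogits = probs[t].copy()
            dlogits[targets[t]] -= 1.0
            dOut += np.outer(states[t], dlogits)
            dc += dlogits
            dh = self.Out @ dlogits + dh_next
            dz = dh * (1.0 - states[t] ** 2)
            dE[tokens[t]] += dz
            db += dz
            if t > 0:
                dW += np.outer(dz, states[t - 1])
            dh_next = self.W.T @ dz
        for g in (dE, dW, db, dOut, dc):
            np.clip(g, -5.0, 5.0, out=g)
        self.E -= lr * dE
        self.W -= lr * dW
        self.b -= lr * db
        self.Out -= lr * dOut
        self.c -= lr * dc
        return loss / T


def train_rnn(
    corpus: "CallCorpus",
    bank: QuestionBank,
    hidden: int = 32,
    epochs: int = 3,
    lr: float = 0.1,
    seed: int = 0,
) -> RnnModel:
    """Train the next-question network on the corpus question sequences."""
    sequences = [list(rec.sequence) for rec in corpus.records if rec.sequence]
    if not sequences:
        raise TrainingError("corpus has no non-empty sequences")
    model = RnnModel(bank.question_ids(), hidden=hidden, seed=seed)
    rng = np.random.default_rng(seed + 1)
    order = np.arange(len(sequences))
    for _ in range(epochs):
        rng.shuffle(order)
        for i in order:
            model._train_sequence(sequences[i], lr)
        model.epochs_trained += 1
    return model


def slots567_questions(
    session: CallSession,
    index: SimilarityIndex,
    rnn: RnnModel,
    m: int = 20,
    alpha: float = 0.5,
    exclude: set[int] | None = None,
) -> list[int]:
    """Up to 3 questions from similar calls: candidate pool from the top-m
    cosine neighbours (or all unanswered questions when the session vector
    is all-zero), scored alpha * similarity-weighted pool frequency +
    (1 - alpha) * RNN next-question probability."""
    exclude = exclude or set()
    answered = session.answered_ids
    idx = {qid: i for i, qid in enumerate(index.question_ids)}
    vec = _vector_from_session(session, idx)
    prefix = [(e.question_id, e.answer) for e in session.answers]
    rnn_probs = rnn.predict_next(prefix)

    if not np.any(vec):
        # no answers yet: cosine is 0 everywhere; fall back to the global
        # RNN distribution over all eligible questions
        pool = [q for q in index.question_ids if q not in answered and q not in exclude]
        pool.sort(key=lambda q: (-rnn_probs[rnn.qindex[q]], q))
        return pool[:3]

    neighbours = index.top_m(vec, m)
    weights: Counter[int] = Counter()
    total_w = 0.0
    for call_i, sim in neighbours:
        w = max(sim, 0.0)
        total_w += w
        for qid, _ in index.sequences[call_i]:
            weights[qid] += w
    pool = sorted(q for q in weights if q not in answered and q not in exclude)
    if not pool:
        return []
    scores = {}
    for q in pool:
        pool_freq = weights[q] / total_w if total_w > 0 else 0.0
        scores[q] = alpha * pool_freq + (1.0 - alpha) * float(rnn_probs[rnn.qindex[q]])
    pool.sort(key=lambda q: (-scores[q], q))
    return pool[:3]


def _vector_from_session(session: CallSession, idx: dict[int, int]) -> np.ndarray:
    v = np.zeros(len(idx))
    for e in session.answers:
        if e.question_id in idx:
            v[idx[e.question_id]] = _answer_sign(e.answer)
    return v


# ---------------------------------------------------------------------------
# slot 8: frequently asked questions
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    counts: Counter[int] = field(default_factory=Counter)

    @classmethod
    def from_corpus(cls, corpus: "CallCorpus") -> "FrequencyTable":
        counts: Counter[int] = Counter()
        for rec in corpus.records:
            for qid, _ in rec.sequence:
                counts[qid] += 1
        return cls(counts)

    def ranking(self, bank: QuestionBank) -> list[int]:
        """All FAQ-eligible bank questions by asked-count desc, id asc."""
        qids = [q for q in bank.question_ids() if bank.question(q).is_faq_eligible]
        return sorted(qids, key=lambda q: (-self.counts.get(q, 0), q))


def slot8_question(
    freq: FrequencyTable,
    session: CallSession,
    already_listed: set[int],
    bank: QuestionBank,
) -> int | None:
    """The most frequently asked question neither answered nor already in
    slots 1-7; ties by lowest id; None when exhausted."""
    answered = session.answered_ids
    for qid in freq.ranking(bank):
        if qid not in answered and qid not in already_listed:
            return qid
    return None


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

SOURCE_CART = "cart"
SOURCE_ALS = "als"
SOURCE_SIMILAR = "similar"
SOURCE_FAQ = "faq"
SOURCE_BACKFILL = "backfill"


@dataclass(frozen=True)
class SlotEntry:
    slot: int
    question_id: int
    source: str
    score: float


@dataclass
class RecommendationList:
    entries: list[SlotEntry] = field(default_factory=list)

    @property
    def question_ids(self) -> list[int]:
        return [e.question_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, qid: int) -> bool:
        return qid in set(self.question_ids)


@dataclass
class RecommenderBundle:
    """The trained prediction components plus composition parameters.

    Any of cart / als / (index, rnn) may be None — the composer then skips
    those slots and backfills from the frequency ranking, which is also the
    untrained-models fallback mode.
    """

    bank: QuestionBank
    freq: FrequencyTable
    cart: CartModel | None = None
    als: AlsModel | None = None
    index: SimilarityIndex | None = None
    rnn: RnnModel | None = None
    config: RecommenderConfig = field(default_factory=RecommenderConfig)
    training_call_ids: set = field(default_factory=set)

    def recommend(self, session: CallSession) -> RecommendationList:
        return compose(session, self, self.bank)


def train_bundle(
    corpus: "CallCorpus", bank: QuestionBank, config: RecommenderConfig | None = None
) -> RecommenderBundle:
    """Train all four components on a corpus and assemble the bundle."""
    config = config or RecommenderConfig()
    mat = interaction_matrix(corpus, bank)
    try:
        cart = train_cart(corpus, bank, config)
    except TrainingError:
        cart = None
    als = train_als(mat, k=config.k, lam=config.lam, iterations=config.als_iterations,
                    seed=config.seed)
    index = build_similarity_index(corpus, bank)
    rnn = train_rnn(corpus, bank, hidden=config.rnn_hidden, epochs=config.rnn_epochs,
                    lr=config.rnn_lr, seed=config.seed)
    return RecommenderBundle(
        bank=bank, freq=FrequencyTable.from_corpus(corpus),
        cart=cart, als=als, index=index, rnn=rnn, config=config,
        training_call_ids={rec.call_id for rec in corpus.records},
    )


def frequency_baseline(corpus: "CallCorpus", bank: QuestionBank) -> RecommenderBundle:
    """Prediction-free baseline: all 8 slots fall through to the frequency
    ranking.  The full bundle must beat this to be worth its training."""
    return RecommenderBundle(
        bank=bank,
        freq=FrequencyTable.from_corpus(corpus),
        training_call_ids={rec.call_id for rec in corpus.records},
    )


def compose(session: CallSession, bundle: RecommenderBundle, bank: QuestionBank) -> RecommendationList:
    """Fill slot 1, then 2-4, then 5-7, then 8; skip questions already
    placed or answered; backfill any remaining slots from the frequency
    ranking.  Pure function of (session, bundle, bank)."""
    placed: list[tuple[int, str, float]] = []
    placed_ids: set[int] = set()
    answered = session.answered_ids

    def _add(qid: int, source: str, score: float) -> None:
        if qid not in placed_ids and qid not in answered and len(placed) < 8:
            placed.append((qid, source, score))
            placed_ids.add(qid)

    if bundle.cart is not None:
        q1 = slot1_question(session, bundle.cart, bank)
        if q1 is not None:
            _add(q1, SOURCE_CART, 1.0)
    if bundle.als is not None:
        for qid in slots234_questions(session, bundle.als, bank, exclude=placed_ids):
            _add(qid, SOURCE_ALS, 0.0)
    if bundle.index is not None and bundle.rnn is not None:
        for qid in slots567_questions(
            session, bundle.index, bundle.rnn,
            m=bundle.config.m, alpha=bundle.config.alpha, exclude=placed_ids,
        ):
            _add(qid, SOURCE_SIMILAR, 0.0)
    q8 = slot8_question(bundle.freq, session, placed_ids, bank)
    if q8 is not None:
        _add(q8, SOURCE_FAQ, float(bundle.freq.counts.get(q8, 0)))
    for qid in bundle.freq.ranking(bank):
        if len(placed) >= 8:
            break
        _add(qid, SOURCE_BACKFILL, float(bundle.freq.counts.get(qid, 0)))

    return RecommendationList(
        entries=[SlotEntry(slot=i + 1, question_id=q, source=s, score=sc)
                 for i, (q, s, sc) in enumerate(placed)]
    )


# ---------------------------------------------------------------------------
# bundle persistence: versioned directory, one file per component + manifest
# ---------------------------------------------------------------------------

BUNDLE_FORMAT_VERSION = "1"


def save_bundle(bundle: RecommenderBundle, directory) -> None:
    import json
    import pickle
    from pathlib import Path

    from .question_bank import save_bank

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    components = []
    save_bank(bundle.bank, directory / "bank.json")
    (directory / "freq.json").write_text(
        json.dumps({str(k): v for k, v in bundle.freq.counts.items()}, sort_keys=True)
    )
    if bundle.cart is not None:
        with open(directory / "cart.pkl", "wb") as fh:
            pickle.dump({"tree": bundle.cart.tree, "question_ids": bundle.cart.question_ids}, fh)
        components.append("cart")
    if bundle.als is not None:
        np.savez(
            directory / "als.npz",
            U=bundle.als.U, V=bundle.als.V,
            lam=bundle.als.lam, k=bundle.als.k,
            iterations=bundle.als.iterations, seed=bundle.als.seed,
            question_ids=np.array(bundle.als.question_ids),
            objective_history=np.array(bundle.als.objective_history),
        )
        components.append("als")
    if bundle.index is not None:
        np.savez(directory / "index.npz", vectors=bundle.index.vectors,
                 question_ids=np.array(bundle.index.question_ids))
        (directory / "index_sequences.json").write_text(
            json.dumps([[[q, a] for q, a in seq] for seq in bundle.index.sequences])
        )
        components.append("index")
    if bundle.rnn is not None:
        np.savez(
            directory / "rnn.npz",
            E=bundle.rnn.E, W=bundle.rnn.W, b=bundle.rnn.b,
            Out=bundle.rnn.Out, c=bundle.rnn.c,
            question_ids=np.array(bundle.rnn.question_ids),
            hidden=bundle.rnn.hidden, seed=bundle.rnn.seed,
            epochs_trained=bundle.rnn.epochs_trained,
        )
        components.append("rnn")
    bundle.config.to_yaml(directory / "config.yaml")
    (directory / "manifest.json").write_text(
        json.dumps(
            {
                "format_version": BUNDLE_FORMAT_VERSION,
                "components": components,
                "training_call_ids": sorted(bundle.training_call_ids),
            },
            indent=1,
        )
    )


def load_bundle(directory) -> RecommenderBundle:
    import json
    import pickle
    from pathlib import Path

    from .question_bank import load_bank

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported bundle format {manifest.get('format_version')!r}")
    bank = load_bank(directory / "bank.json")
    freq = FrequencyTable(
        Counter({int(k): int(v) for k, v in json.loads((directory / "freq.json").read_text()).items()})
    )
    config = RecommenderConfig.from_yaml(directory / "config.yaml")
    components = set(manifest["components"])
    cart = als = index = rnn = None
    if "cart" in components:
        with open(directory / "cart.pkl", "rb") as fh:
            data = pickle.load(fh)
        cart = CartModel(tree=data["tree"], question_ids=list(data["question_ids"]))
    if "als" in components:
        z = np.load(directory / "als.npz")
        als = AlsModel(
            U=z["U"], V=z["V"], lam=float(z["lam"]), k=int(z["k"]),
            iterations=int(z["iterations"]), seed=int(z["seed"]),
            question_ids=[int(q) for q in z["question_ids"]],
            objective_history=[float(x) for x in z["objective_history"]],
        )
    if "index" in components:
        z = np.load(directory / "index.npz")
        sequences = [
            [(int(q), a) for q, a in seq]
            for seq in json.loads((directory / "index_sequences.json").read_text())
        ]
        index = SimilarityIndex(vectors=z["vectors"], sequences=sequences,
                                question_ids=[int(q) for q in z["question_ids"]])
    if "rnn" in components:
        z = np.load(directory / "rnn.npz")
        rnn = RnnModel([int(q) for q in z["question_ids"]], hidden=int(z["hidden"]),
                       seed=int(z["seed"]))
        rnn.E, rnn.W, rnn.b = z["E"], z["W"], z["b"]
        rnn.Out, rnn.c = z["Out"], z["c"]
        rnn.epochs_trained = int(z["epochs_trained"])
    return RecommenderBundle(
        bank=bank, freq=freq, cart=cart, als=als, index=index, rnn=rnn, config=config,
        training_call_ids=set(manifest.get("training_call_ids", [])),
    )
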