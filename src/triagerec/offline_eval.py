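"""Offline replay evaluation of the 8-slot recommender.

The recommender's quality is measured by sequential replay against held-out
call transcripts: at every step the list is computed from the answered
prefix only, and a hit is scored when the question actually asked next
appears in the list.  Metrics are hit-rate@k (k = 1, 4, 8), mean
reciprocal rank, catalog coverage (fraction of the bank ever recommended),
and per-slot-source attribution counts.  Differences between two runs on
the same corpus get percentile bootstrap confidence intervals resampled
over calls.

The replay prefix never includes the step being predicted; steps start at
prefix length 1, since three of the four slot strategies are vacuous on an
empty session.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .call_simulator import CallCorpus
from .session_engine import CallSession


class EvalValidationError(ValueError):
    """Evaluation inputs are inconsistent (e.g. train/test overlap)."""


@dataclass
class EvalReport:
    hit_rate_at_k: dict[int, float]
    mrr: float
    coverage: float
    source_counts: dict[str, int]
    corpus_id: str
    bundle_id: str
    seed: int
    n_calls: int
    n_steps: int
    per_call: dict[str, dict] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "hit_rate_at_k": {str(k): v for k, v in self.hit_rate_at_k.items()},
            "mrr": self.mrr,
            "coverage": self.coverage,
            "source_counts": dict(self.source_counts),
            "corpus_id": self.corpus_id,
            "bundle_id": self.bundle_id,
            "seed": self.seed,
            "n_calls": self.n_calls,
            "n_steps": self.n_steps,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_jsonable(), fh, indent=1)


def evaluate(
    bundle,
    corpus: CallCorpus,
    ks: tuple[int, ...] = (1, 4, 8),
    corpus_id: str = "",
    bundle_id: str = "",
    seed: int = 0,
    training_call_ids: set[str] | None = None,
) -> EvalReport:
    """Replay every corpus call and score the recommender step by step.

    ``bundle`` is anything with a ``recommend(session) -> RecommendationList``
    method (normally a trained :class:`RecommenderBundle`).  If the bundle
    carries (or the caller passes) training call ids, an overlap with the
    evaluation corpus is a validation error — replay on training calls
    would inflate every metric.
    """
    train_ids = set(training_call_ids or getattr(bundle, "training_call_ids", set()) or set())
    overlap = train_ids & {rec.call_id for rec in corpus.records}
    if overlap:
        raise EvalValidationError(f"corpus overlaps training split: {sorted(overlap)[:5]}")
    bank = corpus.bank
    hits = {k: 0 for k in ks}
    rr_total = 0.0
    n_steps = 0
    recommended_ever: set[int] = set()
    source_counts: Counter[str] = Counter()
    per_call: dict[str, dict] = {}
    for rec in corpus.records:
        seq = rec.sequence
        call_hits = {k: 0 for k in ks}
        call_rr = 0.0
        call_steps = 0
        session = CallSession(bank)
        if seq:
            session.record_answer(*seq[0])
        for t in range(1, len(seq)):
            target = seq[t][0]
            rec_list = bundle.recommend(session)
            listed = rec_list.question_ids
            recommended_ever.update(listed)
            for entry in rec_list.entries:
                source_counts[entry.source] += 1
            if target in listed:
                rank = listed.index(target) + 1
                call_rr += 1.0 / rank
                for k in ks:
                    if rank <= k:
                        call_hits[k] += 1
            call_steps += 1
            session.record_answer(*seq[t])
        if call_steps:
            n_steps += call_steps
            rr_total += call_rr
            for k in ks:
                hits[k] += call_hits[k]
            per_call[rec.call_id] = {
                "steps": call_steps,
                "rr": call_rr,
                **{f"hits{k}": call_hits[k] for k in ks},
            }
    if n_steps == 0:
        raise EvalValidationError("corpus contains no scorable steps")
    return EvalReport(
        hit_rate_at_k={k: hits[k] / n_steps for k in ks},
        mrr=rr_total / n_steps,
        coverage=len(recommended_ever) / len(bank) if len(bank) else 0.0,
        source_counts=dict(source_counts),
        corpus_id=corpus_id,
        bundle_id=bundle_id,
        seed=seed,
        n_calls=len(per_call),
        n_steps=n_steps,
        per_call=per_call,
    )


@dataclass(frozen=True)
class MetricDelta:
    metric: str
    delta: float
    ci_low: float
    ci_high: float


def compare(
    report_a: EvalReport,
    report_b: EvalReport,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MetricDelta]:
    """Per-metric differences (A - B) with percentile bootstrap CIs
    resampled over calls.  Both reports must come from the same corpus."""
    if report_a.corpus_id != report_b.corpus_id:
        raise EvalValidationError(
            f"corpus mismatch: {report_a.corpus_id!r} vs {report_b.corpus_id!r}"
        )
    calls = sorted(set(report_a.per_call) & set(report_b.per_call))
    if not calls:
        raise EvalValidationError("reports share no calls")
    ks = sorted(report_a.hit_rate_at_k)
    metrics = [f"hits{k}" for k in ks] + ["rr"]
    names = [f"hit_rate_at_{k}" for k in ks] + ["mrr"]
    a = np.array([[report_a.per_call[c][m] for m in metrics] + [report_a.per_call[c]["steps"]] for c in calls])
    b = np.array([[report_b.per_call[c][m] for m in metrics] + [report_b.per_call[c]["steps"]] for c in calls])
    rng = np.random.default_rng(seed)

    def rates(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
        sub = data[idx]
        return sub[:, :-1].sum(axis=0) / sub[:, -1].sum()

    all_idx = np.arange(len(calls))
    point = rates(a, all_idx) - rates(b, all_idx)
    boots = np.empty((n_boot, len(metrics)))
    for i in range(n_boot):
        idx = rng.integers(0, len(calls), size=len(calls))
        boots[i] = rates(a, idx) - rates(b, idx)
    lo = np.percentile(boots, 2.5, axis=0)
    hi = np.percentile(boots, 97.5, axis=0)
    return [
        MetricDelta(metric=name, delta=float(point[i]), ci_low=float(lo[i]), ci_high=float(hi[i]))
        for i, name in enumerate(names)
    ]
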