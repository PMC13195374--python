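# Methods

This note documents the models and procedures `triagerec` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## The session model

A call session is an append-only log of (question id, answer) entries over
a bank of predefined binary questions, plus a patient header and a
disposition (urgency + response from configured menus, last-write-wins with
an audit trail). Two derived views are pure functions of (bank, answer
log), so they can always be recomputed from scratch and compared against
incremental updates:

* **Structured documentation** sorts answered questions by (topic display
  rank, answer sequence index). The topic hierarchy's display rank is its
  preorder traversal position, which makes the between-topic order total
  and reproducible; entry order breaks ties within a topic.
* **Highlighting.** For each critical symptom combination (a set of
  questions whose joint confirmation mandates the highest urgency): all
  members confirmed → all members *critical*; exactly one member
  unanswered with the rest confirmed and none negated → all members,
  including the unanswered one, *near-critical*; *critical* overrides
  *near-critical* per question. Three choices here were open and are fixed
  as follows. "Nearly complete" means exactly one unanswered member — the
  minimal reading of an alert that precedes completion. The missing member
  is itself highlighted, because the interface marks predicted questions
  as well as confirmed symptoms. A negated member kills a combination's
  highlight entirely: a denied symptom cannot complete a constellation.
  The kill rule is a modeling decision, not an observed behavior, and is
  exercised directly by the truth-table tests.

## The 8-slot recommender

Sessions are encoded as signed vectors (+1 confirmed, −1 negated,
0 unasked); the signed encoding distinguishes negation from absence, which
matters for both factorization and retrieval.

**Slot 1 (critical-case CART).** A decision tree (scikit-learn,
`max_depth` 6, `min_samples_leaf` 5, seeded) is fit on full-call signed
vectors against the critical flag. At recommendation time the tree is
walked along the session's known answers; the first *unanswered* split
question on the active path is proposed — the maximally informative
unresolved feature. If the active path is fully answered, the fallback is
the unanswered question whose confirmation would complete the most
near-critical combinations (ties by lowest id); if no candidate exists the
slot is empty.

**Slots 2–4 (ALS).** `train_als` alternates exact ridge solves for call
factors U and question factors V over the observed (non-zero) cells of the
interaction matrix; because each half-step solves its subproblem exactly,
the regularized objective is non-increasing per iteration — an invariant
the tests check against an independent recomputation. Defaults: rank
k = 16, λ = 0.1, 15 iterations. Sessions not in the training matrix are
cold-start projected by a ridge solve of the session vector against V;
this is one reasonable choice among several, and is surfaced as
`AlsModel.project_session` so alternatives can be swapped in. Candidates
are unanswered questions whose top-level topic has already been introduced
by an answered question — with a two-level hierarchy the top level is the
only available notion of "topic".

**Slots 5–7 (similar calls).** The top-m (default 20) training calls by
cosine similarity (defined as 0 when either vector is all-zero) contribute
a pool of questions they asked; each candidate is scored
α · (similarity-weighted pool frequency) + (1−α) · (RNN next-question
probability), α default 0.5. The RNN is a deliberately small Elman network
(hidden 32 by default): one token per (question, answer) pair plus a start
token, tanh recurrence, softmax output over question ids, trained by
backpropagation through time with plain SGD (lr 0.1), gradient clipping at
±5, and ≤5 epochs on desk corpora. Its outputs are verified to lie on the
probability simplex. With no answers yet, cosine retrieval is undefined
(all similarities 0) and the slots fall back to the RNN's global
first-question distribution.

**Slot 8 (FAQ) and backfill.** The most frequently asked question not
already listed or answered; if the four strategies under-produce, the
remaining slots are backfilled from the same frequency ranking, which
keeps the list behavior consistent with the slot-8 philosophy. All
tie-breaks everywhere are by lowest question id, so composition is a
deterministic function of (session, bundle, bank, config).

## Offline evaluation

Replay evaluation walks each held-out transcript: at prefix length
t = 1 … L−1 the 8-slot list is computed from the prefix alone and scored
against the question actually asked next. The empty prefix is excluded
because three of the four strategies are vacuous there; including it would
only dilute every recommender equally. Hits are counted against the *next*
asked question — the strictest sequential criterion. Metrics: hit-rate@k
(k = 1, 4, 8), mean reciprocal rank, catalog coverage, per-source slot
counts. Differences between two runs on the same corpus get percentile
bootstrap CIs (default 1000 resamples, seeded) over calls. The evaluator
refuses corpora that overlap the bundle's training call ids, and a
corrupted-oracle test (a recommender that only emits already-answered
questions) pins the no-leak property: any nonzero score would prove the
target leaked into the prefix.

## The synthetic-data generator

The generator stands in for all real study data; its defaults are the
study conditions the analysis layer expects.

**Banks.** 1200 binary questions over a two-level hierarchy (10 organ
systems × 4 symptom groups; labels are ordering placeholders, not clinical
content), 25 critical combinations of 2–4 members. How real question pools
distribute over topics, and how many critical combinations exist in
practice, is unknown; these fixtures must not be read as clinically
meaningful.

**Corpora.** Calls are drawn from a mixture of 15 archetypes. Each
archetype prefers ~3 organ systems (ask-affinity 20:1, confirm
probabilities 0.55–0.95 on characteristic questions vs 0.05–0.40
elsewhere), has a preferred topic order, and — for the first third of
archetypes — an embedded critical combination expressed with probability
0.7. Sequence length is uniform on 6–18. Question order follows the
archetype's topic order perturbed by ε-random adjacent swaps (ε default
0.2): real operators' question choices are unobservable, and this policy
produces learnable but noisy sequential structure. The critical flag is
recomputed from the sequence and is checked, cross-module, against the
session engine's red-highlight detection. Scripted scenarios (default 15)
fix the opening topic — emulating a predefined opening line — and answer
deterministically.

**Ratings.** For each of 22 operators × 15 cases × 2 phases, overall
items on the 0–10 scale follow μ_phase + b_op + c_case + e with
independent normal intercepts per item; Likert items threshold a latent
normal into categories 1–5 with a configurable NA probability (default
0.1); the triage item draws its (pre, post) pair jointly from a 7×7
kernel whose default concentrates mass on optimal triage with mild
categories adjacent. The planted configuration on overall medical quality
is: shift δ = 0.34, and variance components solved jointly from the
target intraclass correlations (ICC_op = 0.17, ICC_case = 0.42) and the
target paired effect size (dz = 0.16 = δ/(σ_e√2)): σ_e = 1.503,
σ_op = 0.967, σ_case = 1.521. As a consistency check, the implied Wald CI
halfwidth 1.96·σ_e·√(2/330) = 0.23 matches the width of the planted
configuration's reported interval.

**Ceiling calibration.** Ratings are clipped to [0, 10] rather than
truncated-resampled (truncation biases unit means more, not less, at
these variances). Clipping at the ceiling attenuates observed means and
shifts: at the planted configuration about 9% of the mass sits above 10,
which would shrink the recovered difference by ≈0.07 — outside the
recovery tolerance the generator is meant to support. The generator
therefore solves, per item and phase, for the *latent* mean whose
observed (clipped) mean equals the planted target: the clipped-normal
mean has a closed form, the random-intercept mixture is integrated by
Gauss–Hermite quadrature (61 nodes), and the scalar equation is solved by
Brent's method. The calibration is deterministic, is verified in the
tests against a large Monte-Carlo oracle, and makes the observed-scale
statistics — the quantities the analysis layer estimates — equal the
planted targets in expectation. Residual small-sample wobble remains
because 22 operators and 15 cases give variance components with large
sampling variance; the recovery tests therefore average over 20
replications.

**What passing tests do and do not show.** The simulator produces binary
answer profiles, archetype co-occurrence, mild sequential structure, and
crossed-random-effects ratings. It does not model natural language, caller
emotion, operator learning between calls, item correlations within a call,
or realistic call-length distributions (no distributional facts about real
calls are available; the defaults are engineering choices, not estimates).
Recommender improvements demonstrated on these corpora show that the
pipeline learns planted structure — not that it would help on real calls.

## Study analysis

* **Pairing filter:** a pair is retained iff both phases exist, are
  available, and have retrievable audio. Exclusion reasons are tallied
  with precedence unavailability > missing audio > missing phase, so a
  doubly flagged pair is counted once.
* **NA handling:** NA on a Likert item means the aspect was *correctly*
  left out, i.e. best-possible performance, and is recoded to 5; the
  sensitivity variant instead drops the affected (operator, case) pair for
  that item. With no NA present both modes provably coincide.
* **Bowker test:** degrees of freedom count only informative pairs
  (n_ij + n_ji > 0). The alternative convention — always k(k−1)/2 — would
  change the P value on sparse tables such as the packaged 7×7 example
  (which has 9 informative of 21 possible pairs). With no informative pair
  the test is reported as undefined rather than silently P = 1.
* **Mixed model:** value ~ phase with crossed random intercepts for
  operator and case, fit by REML (statsmodels variance components); the
  phase coefficient with a 95% Wald CI is the pre/post difference.
  Negative variance estimates are truncated at 0 before ICCs are formed,
  preserving ICC ∈ [0, 1]. Estimation criterion and CI method are declared
  choices; a study might use different software defaults.
* **Thresholds:** α = .05 for primary outcomes, Bonferroni-adjusted
  α = .002 for secondary outcomes, exposed as configuration constants.
* **Display rounding:** percentages round half away from zero to integers.

## Problem sizes used by the test suite

The suite trains and evaluates at sizes chosen to exercise every code path
while staying desk-scale: unit tests use banks of 3–80 questions and
corpora of 40–700 calls; the uniqueness property runs 1000 randomized
sessions; Bowker equivalence runs 500 random matrices; parameter recovery
runs 20 replications of the full 22×15×2 rating table; and the end-to-end
learning check trains the full bundle on 2000 calls over the 1200-question
bank and replays 200 held-out calls.

## Known limitations

* The CART→question mapping (first unanswered split on the active path) is
  one defensible reading of "a slot for identifying highly urgent cases";
  the original interface may have used another.
* Cold-start ALS projection and the cosine/RNN blend weight are declared
  defaults, not estimated quantities.
* The mixed model assumes no operator × case interaction and homoscedastic
  residuals; the generator satisfies both by construction, real ratings
  need not.
* Whether highlighting should consider negated answers at all is a design
  decision (the kill rule); sensitivity to it can be probed by swapping the
  rule in `compute_highlights`.
* Human-rated quality outcomes are not computationally reproducible; the
  planted-parameter recovery tests validate the *machinery*, not the
  published human-subject estimates.
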