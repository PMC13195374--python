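"""Paired pre/post quality analysis for simulated-call studies.

Implements the evaluation machinery of a pre/post feasibility design in
which the same operators handle the same cases in two phases and every
call is rated on a structured quality instrument:

* pairing and exclusion of planned calls (both phases must be available
  with retrievable audio);
* NA handling for 5-point Likert items, where NA means "correctly left
  out" and is recoded to the highest category (5), with an exclusion-based
  sensitivity variant;
* 7x7 triage-accuracy transition matrices (severe undertriage ... optimal
  ... severe overtriage) and their band summaries;
* the Bowker test of table symmetry, the multi-category generalization of
  McNemar's test, with degrees of freedom counted over informative
  category pairs only (pairs with at least one discordant observation);
* paired continuous summaries from a linear mixed model with crossed
  operator and case random intercepts (REML), intraclass correlations from
  the variance components, and the paired effect size Cohen dz.

Significance thresholds are configuration, not policy baked into the
functions: ``ALPHA_PRIMARY`` (0.05) for primary outcomes and
``ALPHA_SECONDARY`` (0.002, Bonferroni-adjusted) for secondary outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_PRIMARY = 0.05
ALPHA_SECONDARY = 0.002

TRIAGE_LABELS = (
    "severe_undertriage",
    "moderate_undertriage",
    "mild_undertriage",
    "optimal",
    "mild_overtriage",
    "moderate_overtriage",
    "severe_overtriage",
)
SCALE_LIKERT = "likert5"
SCALE_TRIAGE = "triage7"
SCALE_OVERALL = "overall10"

REASON_UNAVAILABLE = "unavailable"
REASON_MISSING_AUDIO = "missing_audio"
REASON_MISSING_PHASE = "missing_phase"


class AnalysisError(ValueError):
    """Invalid input to an analysis operation."""


class UndefinedTestError(AnalysisError):
    """The requested statistic is undefined on this input."""


# ---------------------------------------------------------------------------
# pairing and exclusions
# ---------------------------------------------------------------------------


@dataclass
class PairedCallSet:
    """Retained (operator, case) pairs and the exclusion tally."""

    pairs: list[tuple[int, int]]
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def pair_and_filter(manifest: pd.DataFrame) -> PairedCallSet:
    """Apply the pairing filter to a planned-call manifest.

    ``manifest`` has one row per (operator_id, case_id, phase) with boolean
    ``available`` and ``audio_ok`` columns.  A pair is retained iff both of
    its phases exist, are available, and have retrievable audio.  Excluded
    pairs are tallied by reason with precedence unavailability > missing
    audio > missing phase, so a pair failing on several grounds is counted
    once under the highest-precedence reason.
    """
    required = {"operator_id", "case_id", "phase", "available", "audio_ok"}
    missing = required - set(manifest.columns)
    if missing:
        raise AnalysisError(f"manifest missing columns {sorted(missing)}")
    dup = manifest.duplicated(subset=["operator_id", "case_id", "phase"])
    if dup.any():
        rows = manifest[dup][["operator_id", "case_id", "phase"]].values.tolist()
        raise AnalysisError(f"duplicate manifest rows for {rows}")
    pairs: list[tuple[int, int]] = []
    exclusions: dict[str, int] = {}
    for (op, case), grp in manifest.groupby(["operator_id", "case_id"], sort=True):
        phases = set(grp["phase"])
        if not grp["available"].all():
            reason = REASON_UNAVAILABLE
        elif not grp["audio_ok"].all():
            reason = REASON_MISSING_AUDIO
        elif phases < {"pre", "post"}:
            reason = REASON_MISSING_PHASE
        else:
            pairs.append((int(op), int(case)))
            continue
        exclusions[reason] = exclusions.get(reason, 0) + 1
    return PairedCallSet(pairs=pairs, exclusions=exclusions)


# ---------------------------------------------------------------------------
# NA handling
# ---------------------------------------------------------------------------


def recode_na(records: pd.DataFrame, mode: str = "recode") -> pd.DataFrame:
    """Handle NA values on Likert items.

    NA marks an aspect that was *correctly* left out, i.e. best-possible
    performance: ``mode="recode"`` maps NA to the highest category (5).
    ``mode="exclude"`` is the sensitivity variant: for each item, any
    (operator, case) pair with an NA in either phase is dropped for that
    item.  NA on a non-Likert scale is a validation error.
    """
    if mode not in ("recode", "exclude"):
        raise AnalysisError(f"mode must be 'recode' or 'exclude', got {mode!r}")
    df = records.copy()
    na_mask = df["value"].isna()
    bad = na_mask & (df["scale"] != SCALE_LIKERT)
    if bad.any():
        items = sorted(df.loc[bad, "item_id"].unique())
        raise AnalysisError(f"NA on non-Likert items {items}")
    if mode == "recode":
        df.loc[na_mask, "value"] = 5.0
        return df
    na_keys = df.loc[na_mask, ["operator_id", "case_id", "item_id"]].drop_duplicates()
    merged = df.merge(na_keys, on=["operator_id", "case_id", "item_id"], how="left", indicator=True)
    return merged[merged["_merge"] == "left_only"].drop(columns="_merge").reset_index(drop=True)


# ---------------------------------------------------------------------------
# transition matrices and triage summaries
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """Square pre (rows) x post (columns) count matrix over ordered categories."""

    counts: np.ndarray
    labels: tuple[str, ...] = TRIAGE_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise AnalysisError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise AnalysisError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def load_reference_transitions() -> TransitionMatrix:
    """The packaged published 7x7 pre/post triage-accuracy transition table
    of 320 paired simulated triage calls (the in-package worked example)."""
    with resources.files("triagerec.data").joinpath("reference_triage_transitions.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return TransitionMatrix(df.values, labels=tuple(df.columns))


def build_transition_matrix(ratings: pd.DataFrame, item_id: str = "triage_accuracy") -> TransitionMatrix:
    """Count pre -> post category transitions for one 7-category item over
    all (operator, case) pairs; every pair must carry both phases."""
    sub = ratings[ratings["item_id"] == item_id]
    if sub.empty:
        raise AnalysisError(f"no records for item {item_id!r}")
    if sub["value"].isna().any():
        raise AnalysisError("transition matrix input must not contain NA")
    wide = sub.pivot_table(
        index=["operator_id", "case_id"], columns="phase", values="value", aggfunc="first"
    )
    if "pre" not in wide.columns or "post" not in wide.columns or wide[["pre", "post"]].isna().any().any():
        missing = wide.index[wide.reindex(columns=["pre", "post"]).isna().any(axis=1)].tolist()
        raise AnalysisError(f"pairs missing a phase value: {missing}")
    counts = np.zeros((7, 7), dtype=int)
    for pre, post in wide[["pre", "post"]].itertuples(index=False):
        counts[int(pre) - 1, int(post) - 1] += 1
    return TransitionMatrix(counts)


def summarize_triage(matrix: TransitionMatrix) -> pd.DataFrame:
    """Collapse the 7 categories into undertriage (1-3), optimal (4) and
    overtriage (5-7) bands per phase, with integer display percentages
    (rounded half away from zero)."""
    counts = matrix.counts
    pre = counts.sum(axis=1)
    post = counts.sum(axis=0)
    total = counts.sum()
    bands = {"undertriage": slice(0, 3), "optimal": slice(3, 4), "overtriage": slice(4, 7)}

    def pct(x: float) -> int:
        return int(np.floor(100.0 * x / total + 0.5)) if total else 0

    rows = []
    for band, sl in bands.items():
        rows.append(
            {
                "band": band,
                "pre_count": int(pre[sl].sum()),
                "pre_percent": pct(pre[sl].sum()),
                "post_count": int(post[sl].sum()),
                "post_percent": pct(post[sl].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bowker test of symmetry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BowkerResult:
    statistic: float
    df: int
    p_value: float


def bowker_symmetry(matrix: TransitionMatrix | np.ndarray) -> BowkerResult:
    """Bowker's chi-square test that a square paired table is symmetric.

    statistic = sum over unordered category pairs {i, j}, i != j, with
    n_ij + n_ji > 0 of (n_ij - n_ji)^2 / (n_ij + n_ji); df = the number of
    such informative pairs; p = upper chi-square tail.  Pairs with no
    discordant observations carry no information about asymmetry and are
    excluded from both the statistic and the degrees of freedom.
    """
    counts = matrix.counts if isinstance(matrix, TransitionMatrix) else np.asarray(matrix)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise AnalysisError("Bowker test requires a square matrix")
    k = counts.shape[0]
    if k < 2:
        raise AnalysisError("Bowker test requires at least 2 categories")
    statistic = 0.0
    df = 0
    for i in range(k):
        for j in range(i + 1, k):
            s = counts[i, j] + counts[j, i]
            if s > 0:
                statistic += (counts[i, j] - counts[j, i]) ** 2 / s
                df += 1
    if df == 0:
        raise UndefinedTestError("no informative category pair; symmetry test undefined")
    return BowkerResult(float(statistic), df, float(stats.chi2.sf(statistic, df)))


# ---------------------------------------------------------------------------
# paired continuous summaries
# ---------------------------------------------------------------------------


def cohen_dz(pre: np.ndarray, post: np.ndarray) -> float:
    """Paired effect size: mean of the paired differences divided by their
    standard deviation (n - 1 denominator)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise AnalysisError("pre and post must have equal length")
    if pre.size < 2:
        raise AnalysisError("need at least 2 pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        raise UndefinedTestError("zero variance of paired differences; dz undefined")
    return float(diff.mean() / sd)


@dataclass(frozen=True)
class PairedSummary:
    pre_mean: float
    post_mean: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    icc_operator: float
    icc_case: float
    cohen_dz: float
    n_pairs: int


def paired_mixed_summary(values: pd.DataFrame, value_col: str = "value") -> PairedSummary:
    """Pre/post comparison from a crossed random-intercepts mixed model.

    ``values`` holds one row per (operator_id, case_id, phase) observation.
    The model is value ~ phase with random intercepts for operator and case
    (REML).  The phase fixed effect is the post - pre difference with a 95%
    Wald CI; intraclass correlations are each grouping factor's variance
    share of (operator + case + residual), negative estimates truncated at
    zero.  Cohen dz is computed on the paired per-(operator, case) values.
    """
    import statsmodels.formula.api as smf

    df = values[["operator_id", "case_id", "phase", value_col]].rename(
        columns={value_col: "value"}
    ).dropna()
    if df["operator_id"].nunique() < 2 or df["case_id"].nunique() < 2:
        raise AnalysisError("model unidentifiable: need at least 2 operators and 2 cases")
    if set(df["phase"]) != {"pre", "post"}:
        raise AnalysisError("both phases required")
    df = df.assign(post=(df["phase"] == "post").astype(float))
    model = smf.mixedlm(
        "value ~ post",
        df,
        groups=np.ones(len(df)),
        re_formula="0",
        vc_formula={"operator": "0 + C(operator_id)", "case": "0 + C(case_id)"},
    )
    import warnings

    with warnings.catch_warnings():
        # boundary fits (variance component at 0) are legitimate outcomes
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    coef = float(fit.params["post"])
    ci = fit.conf_int().loc["post"]
    p = float(fit.pvalues["post"])
    vc = dict(zip(model.exog_vc.names, np.maximum(fit.vcomp, 0.0)))
    var_op, var_case = vc.get("operator", 0.0), vc.get("case", 0.0)
    var_e = float(fit.scale)
    total = var_op + var_case + var_e
    wide = df.pivot_table(index=["operator_id", "case_id"], columns="phase", values="value",
                          aggfunc="mean").dropna()
    try:
        dz = cohen_dz(wide["pre"].values, wide["post"].values)
    except UndefinedTestError:
        dz = 0.0
    return PairedSummary(
        pre_mean=float(df.loc[df["phase"] == "pre", "value"].mean()),
        post_mean=float(df.loc[df["phase"] == "post", "value"].mean()),
        difference=coef,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=p,
        icc_operator=float(var_op / total) if total > 0 else 0.0,
        icc_case=float(var_case / total) if total > 0 else 0.0,
        cohen_dz=dz,
        n_pairs=len(wide),
    )
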