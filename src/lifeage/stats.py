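"""Pre/post evaluation machinery for a single-arm repeated-measures design.

Covers the paired t-test, the Wilcoxon signed-rank test (exact by sign-flip
enumeration for small samples, normal approximation with tie and continuity
corrections otherwise), the paired sample-size calculation with dropout
inflation, and cohort summaries in the baseline/follow-up table style used
for intervention feasibility studies.

The Wilcoxon test is implemented in-package rather than delegated: the
contract here fixes a specific policy — zero differences dropped, mid-ranks
for tied absolute differences, exact two-sided p by the full sign-flip null
distribution up to m = 12 — which library implementations do not offer in
combination (exact modes typically refuse ties).

The variable-to-test assignment for the standard report is fixed:
paired t for diet score, life satisfaction and combined mood; Wilcoxon for
the Life Age delta, BMI, weight, activity, stress and sleep.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Any, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import LifestyleOffsetsConfig, PopulationNorms
from .errors import InputError, LifeAgeError
from .questionnaires import combined_mood

__all__ = [
    "TestResult",
    "SampleSizeSpec",
    "SampleSize",
    "PairedCohort",
    "paired_t_test",
    "wilcoxon_signed_rank",
    "required_sample_size",
    "percent",
    "summarize_frame",
    "summarize_cohort",
    "evaluate_pre_post",
    "EvaluationReport",
    "TEST_ASSIGNMENT",
    "analysis_frame",
]

ALPHA_DEFAULT = 0.05

#: Analysis variable -> test, as used in the standard pre/post report.
TEST_ASSIGNMENT: dict[str, str] = {
    "diet_score": "paired_t",
    "life_satisfaction": "paired_t",
    "combined_mood": "paired_t",
    "life_age_delta": "wilcoxon",
    "bmi": "wilcoxon",
    "weight_kg": "wilcoxon",
    "met_hours": "wilcoxon",
    "stress": "wilcoxon",
    "sleep_hours": "wilcoxon",
}

#: Display bands for BMI in cohort summaries (reporting only; the scoring
#: bands in the lifestyle config are finer).
_BMI_DISPLAY_BANDS = (("<25", -np.inf, 25.0), ("25-29.9", 25.0, 30.0), (">=30", 30.0, np.inf))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one paired test on one variable."""

    variable: str
    test: str
    n_pairs: int
    estimate: float  # mean difference (t) or median difference (Wilcoxon)
    statistic: float
    p_value: float
    significant: bool
    alpha: float = ALPHA_DEFAULT


class SampleSize(NamedTuple):
    """Participants to enrol, and complete pairs needed before dropout."""

    enrolled: int
    complete: int


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design inputs for the paired sample-size calculation.

    ``delta`` is the anticipated mean paired change (years), ``sd`` the SD of
    the paired change, ``dropout`` the anticipated fraction lost to follow-up.
    """

    delta: float = 0.5
    sd: float = 0.75
    alpha: float = 0.05
    power: float = 0.90
    dropout: float = 0.20

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise InputError("delta must be nonzero (zero effect needs infinite n)")
        if self.sd <= 0:
            raise InputError(f"sd must be > 0, got {self.sd}")
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise InputError(f"power must be in (0, 1), got {self.power}")
        if not 0 <= self.dropout < 1:
            raise InputError(f"dropout must be in [0, 1), got {self.dropout}")


def _clean_pairs(pre: Sequence[float], post: Sequence[float]) -> np.ndarray:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InputError("pre and post must be equal-length 1-D arrays of paired values")
    keep = ~(np.isnan(pre) | np.isnan(post))
    return (post - pre)[keep]


def paired_t_test(
    pre: Sequence[float], post: Sequence[float], variable: str = "", alpha: float = ALPHA_DEFAULT
) -> TestResult:
    """Two-sided paired t-test on differences d = post - pre.

    t = mean(d) / (sd(d)/sqrt(n)) with n-1 degrees of freedom.  Degenerate
    cases are defined rather than errors: zero variance with zero mean gives
    t = 0, p = 1; zero variance with nonzero mean gives an infinite statistic
    and p = 0.
    """
    d = _clean_pairs(pre, post)
    n = d.size
    if n < 2:
        raise InputError(f"paired t-test needs at least 2 complete pairs, got {n}")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / (sd / math.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(
        variable=variable,
        test="paired_t",
        n_pairs=int(n),
        estimate=float(mean),
        statistic=float(t),
        p_value=float(p),
        significant=bool(p <= alpha),
        alpha=alpha,
    )


def _signed_rank_sums(d: np.ndarray) -> tuple[np.ndarray, float, float]:
    ranks = sps.rankdata(np.abs(d))  # mid-ranks for tied |d|
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return ranks, w_plus, w_minus


def _exact_sign_flip_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p from the sign-flip null distribution of W+.

    Each |d| keeps its (mid-)rank and receives an independent ± sign under
    the null; the distribution of W+ over all 2^m assignments is built by
    convolution on doubled ranks (integers even with mid-ranks).
    p = min(1, 2·min(P(W+ <= obs), P(W+ >= obs))).
    """
    r2 = [int(round(2.0 * r)) for r in ranks]
    counts: dict[int, int] = {0: 1}
    for r in r2:
        nxt: dict[int, int] = defaultdict(int)
        for s, c in counts.items():
            nxt[s] += c
            nxt[s + r] += c
        counts = dict(nxt)
    total = 2 ** len(r2)
    w2 = int(round(2.0 * w_plus))
    p_le = sum(c for s, c in counts.items() if s <= w2) / total
    p_ge = sum(c for s, c in counts.items() if s >= w2) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _approx_sign_flip_p(d: np.ndarray, ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    m = d.size
    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        return 1.0
    num = w_plus - mean
    if num != 0.0:
        num -= 0.5 * math.copysign(1.0, num)  # continuity correction toward the mean
    z = num / math.sqrt(var)
    return min(1.0, 2.0 * sps.norm.sf(abs(z)))


#: Largest number of nonzero differences for which "auto" uses the exact null.
EXACT_WILCOXON_MAX_M = 12


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    mode: Literal["exact", "approximate", "auto"] = "auto",
    variable: str = "",
    alpha: float = ALPHA_DEFAULT,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on differences d = post - pre.

    Zero differences are dropped (classic Wilcoxon policy); tied |d| receive
    mid-ranks.  In ``auto`` mode the exact sign-flip null is enumerated when
    at most 12 nonzero differences remain, otherwise the normal approximation
    with tie and continuity corrections is used.  All differences zero is a
    defined degenerate case: p = 1 with the statistic at the null centre.

    The reported statistic is min(W+, W-); the effect estimate is the median
    of the nonzero differences.
    """
    d = _clean_pairs(pre, post)
    if d.size == 0:
        raise InputError("Wilcoxon signed-rank needs at least one pair")
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return TestResult(
            variable=variable, test="wilcoxon", n_pairs=0, estimate=0.0,
            statistic=0.0, p_value=1.0, significant=False, alpha=alpha,
        )
    ranks, w_plus, w_minus = _signed_rank_sums(d)
    if mode == "exact" or (mode == "auto" and m <= EXACT_WILCOXON_MAX_M):
        p = _exact_sign_flip_p(ranks, w_plus)
    elif mode in ("approximate", "auto"):
        p = _approx_sign_flip_p(d, ranks, w_plus)
    else:
        raise InputError(f"unknown mode {mode!r}; use 'exact', 'approximate' or 'auto'")
    return TestResult(
        variable=variable,
        test="wilcoxon",
        n_pairs=int(m),
        estimate=float(np.median(d)),
        statistic=float(min(w_plus, w_minus)),
        p_value=float(p),
        significant=bool(p <= alpha),
        alpha=alpha,
    )


def required_sample_size(spec: SampleSizeSpec) -> SampleSize:
    """Paired sample size by the normal-quantile formula, inflated for dropout.

    complete = ceil(((z_{1-alpha/2} + z_{power}) · sd / delta)²);
    enrolled = ceil(complete / (1 - dropout)).

    At the design point delta 0.5, SD 0.75, two-sided alpha 0.05, power 0.90
    this gives 24 complete pairs and 30 enrolled at 20% anticipated dropout.
    """
    z_a = sps.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = sps.norm.ppf(spec.power)
    complete = math.ceil(((z_a + z_b) * spec.sd / abs(spec.delta)) ** 2)
    enrolled = math.ceil(complete / (1.0 - spec.dropout))
    return SampleSize(enrolled=enrolled, complete=complete)


def percent(count: int, total: int) -> int:
    """Integer percentage with half-up rounding (10 of 16 -> 63)."""
    if total <= 0:
        return 0
    return int(math.floor(count / total * 100.0 + 0.5))


# ---------------------------------------------------------------------------
# Cohorts and reports


@dataclass(frozen=True)
class PairedCohort:
    """Baseline and follow-up records, one row per participant per frame.

    Both frames carry an ``id`` column; a participant missing from the
    follow-up frame is a dropout.  Paired analyses use complete cases only.
    """

    baseline: pd.DataFrame
    followup: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("baseline", self.baseline), ("followup", self.followup)):
            if len(df) and "id" not in df.columns:
                raise InputError(f"{name} frame must have an 'id' column")
            if len(df) and df["id"].duplicated().any():
                dups = df.loc[df["id"].duplicated(), "id"].tolist()
                raise InputError(f"duplicate participant ids in {name} frame: {dups}")

    @property
    def n_enrolled(self) -> int:
        return len(self.baseline)

    def completer_ids(self) -> list[Any]:
        if not len(self.baseline) or not len(self.followup):
            return []
        fu = set(self.followup["id"])
        return [pid for pid in self.baseline["id"] if pid in fu]

    @property
    def n_completers(self) -> int:
        return len(self.completer_ids())


def analysis_frame(
    df: pd.DataFrame,
    config: LifestyleOffsetsConfig | None = None,
    norms: PopulationNorms | None = None,
) -> pd.DataFrame:
    """Derive the analysis variables from a raw cohort frame.

    Produces (where the inputs allow): diet_score, life_satisfaction,
    combined_mood, bmi, weight_kg, met_hours, stress, sleep_hours, and
    life_age_delta computed through the scoring engine.  Rows that cannot be
    scored get NaN for life_age_delta; variables whose columns are absent are
    omitted entirely.
    """
    if not len(df):
        return pd.DataFrame(columns=["id"])
    out = pd.DataFrame({"id": df["id"].to_numpy()})
    for col in ("diet_score", "life_satisfaction", "stress", "sleep_hours", "weight_kg", "bmi", "met_hours"):
        if col in df.columns:
            out[col] = pd.to_numeric(df[col], errors="coerce").to_numpy()
    if "positive_mood" in df.columns and "negative_mood" in df.columns:
        out["combined_mood"] = [
            combined_mood(p, n)
            for p, n in zip(
                pd.to_numeric(df["positive_mood"], errors="coerce"),
                pd.to_numeric(df["negative_mood"], errors="coerce"),
            )
        ]
    try:
        from .engine import compute_cohort
        from .io import profiles_from_frame

        profiles = profiles_from_frame(df)
        results, _errors = compute_cohort(profiles, config, norms)
        deltas = {r.id: r.delta for r in results}
        out["life_age_delta"] = [deltas.get(pid, np.nan) for pid in out["id"]]
    except (KeyError, LifeAgeError):
        pass  # profile columns insufficient: life_age_delta omitted
    return out


def summarize_frame(df: pd.DataFrame, config=None, norms=None) -> dict[str, Any]:
    """Table-style summary of one timepoint.

    Numeric variables report mean, SD, median, IQR *and* full range, each
    labelled (so displays can choose "median (IQR)" or "median (range)"
    explicitly); categorical variables report counts with integer
    percentages.
    """
    n = len(df)
    summary: dict[str, Any] = {"n": n, "variables": {}, "categorical": {}}
    if n == 0:
        return summary
    derived = analysis_frame(df, config, norms)
    for name in derived.columns:
        if name == "id":
            continue
        x = derived[name].dropna().to_numpy(dtype=float)
        if not x.size:
            continue
        summary["variables"][name] = {
            "n": int(x.size),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "median": float(np.median(x)),
            "iqr": (float(np.percentile(x, 25)), float(np.percentile(x, 75))),
            "range": (float(x.min()), float(x.max())),
        }
    if "sex" in df.columns:
        k = int((df["sex"] == "female").sum())
        summary["categorical"]["female_sex"] = {"count": k, "total": n, "percent": percent(k, n)}
    if "smoking" in df.columns:
        for cat in ("never", "ex", "current"):
            k = int((df["smoking"] == cat).sum())
            summary["categorical"][f"smoking_{cat}"] = {
                "count": k, "total": n, "percent": percent(k, n),
            }
    if "bmi" in derived.columns:
        bmi = derived["bmi"].dropna()
        for label, lo, hi in _BMI_DISPLAY_BANDS:
            k = int(((bmi >= lo) & (bmi < hi)).sum())
            summary["categorical"][f"bmi_{label}"] = {
                "count": k, "total": n, "percent": percent(k, n),
            }
    return summary


def summarize_cohort(cohort: PairedCohort, config=None, norms=None) -> dict[str, Any]:
    """Baseline and follow-up summaries side by side (empty cohort -> zero counts)."""
    return {
        "baseline": summarize_frame(cohort.baseline, config, norms),
        "followup": summarize_frame(cohort.followup, config, norms),
    }


@dataclass(frozen=True)
class EvaluationReport:
    """Full pre/post report: enrolment, completion, summaries, per-variable tests."""

    n_enrolled: int
    n_completers: int
    summary: dict[str, Any]
    tests: dict[str, TestResult] = field(default_factory=dict)
    alpha: float = ALPHA_DEFAULT

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_enrolled": self.n_enrolled,
            "n_completers": self.n_completers,
            "alpha": self.alpha,
            "summary": self.summary,
            "tests": {
                k: {
                    "variable": t.variable,
                    "test": t.test,
                    "n_pairs": t.n_pairs,
                    "estimate": t.estimate,
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "significant": t.significant,
                }
                for k, t in self.tests.items()
            },
        }


def evaluate_pre_post(
    cohort: PairedCohort,
    config: LifestyleOffsetsConfig | None = None,
    norms: PopulationNorms | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> EvaluationReport:
    """Complete-case pre/post analysis of a paired cohort.

    Each analysis variable present at both timepoints is tested with its
    assigned test (see :data:`TEST_ASSIGNMENT`) on participants observed at
    both timepoints; p <= alpha flags significance.  A cohort with no
    follow-ups yields a report with zero completers and no tests.
    """
    completers = cohort.completer_ids()
    summary = summarize_cohort(cohort, config, norms)
    tests: dict[str, TestResult] = {}
    if completers:
        base = analysis_frame(cohort.baseline, config, norms).set_index("id").loc[completers]
        fu = analysis_frame(cohort.followup, config, norms).set_index("id").loc[completers]
        for variable, test in TEST_ASSIGNMENT.items():
            if variable not in base.columns or variable not in fu.columns:
                continue
            pre = base[variable].to_numpy(dtype=float)
            post = fu[variable].to_numpy(dtype=float)
            keep = ~(np.isnan(pre) | np.isnan(post))
            if keep.sum() < 2:
                continue
            if test == "paired_t":
                tests[variable] = paired_t_test(pre[keep], post[keep], variable=variable, alpha=alpha)
            else:
                tests[variable] = wilcoxon_signed_rank(
                    pre[keep], post[keep], variable=variable, alpha=alpha
                )
    return EvaluationReport(
        n_enrolled=cohort.n_enrolled,
        n_completers=len(completers),
        summary=summary,
        tests=tests,
        alpha=alpha,
    )
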