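"""Day-level hypoxia/hyperoxia calling against pooled time-matched controls.

The unit of inference is one EAE mouse-day: that day's 60 within-session
ΔPO2 samples (the trace minus the animal's own pre-induction baseline)
are compared with the concatenated ΔPO2 samples of every control mouse
measured on the matched day, using a two-sample t-test (Welch by
default) at a Bonferroni-corrected threshold. A day significantly below
the controls is hypoxic, significantly above is hyperoxic, otherwise
normoxic. Direction comes from the sign of the mean difference, which
allows a hyperoxic label with a negative ΔPO2 when the controls dropped
further.

The 60 samples within a session are treated as exchangeable replicates;
within-session autocorrelation and the shared baseline-estimation error
per mouse are not modeled by the test (see the package methods note for
the consequences under the null).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import compute_baseline, delta_series
from .model import MouseRecord, MouseSummary, StudyDataset


class TestVariant(str, Enum):
    WELCH = "welch"
    STUDENT = "student"


class Family(str, Enum):
    PER_MOUSE = "per_mouse"
    GLOBAL = "global"


class CallLabel(str, Enum):
    HYPOXIC = "hypoxic"
    HYPEROXIC = "hyperoxic"
    NORMOXIC = "normoxic"


@dataclass(frozen=True)
class CallingParams:
    """Classification settings.

    ``family`` chooses the Bonferroni denominator: each mouse's own
    number of post-induction measurement days (default) or all EAE
    mouse-days in the study. ``day_match_tolerance`` is how far (in
    days) a control session may sit from the queried day and still join
    the pooled control dataset. ``session_means`` switches the test
    unit to control session means (sensitivity-analysis variant).
    """

    alpha: float = 0.05
    test_variant: TestVariant = TestVariant.WELCH
    family: Family = Family.PER_MOUSE
    day_match_tolerance: int = 1
    session_means: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.day_match_tolerance < 0:
            raise ValueError("day_match_tolerance must be >= 0")
        object.__setattr__(self, "test_variant", TestVariant(self.test_variant))
        object.__setattr__(self, "family", Family(self.family))


@dataclass
class DayCall:
    """Classification of one EAE mouse-day with its test statistics."""

    mouse_id: str
    day: int
    mean_delta_eae: float
    mean_delta_control: float
    t_stat: float
    p_raw: float
    alpha_corrected: float
    n_eae: int
    n_control: int
    label: CallLabel


@dataclass
class CohortSummary:
    """Study-level totals in the layout of the published table captions."""

    total_hypoxic_days: int
    total_hyperoxic_days: int
    total_measurement_days: int
    n_mice_any_hypoxic: int
    n_mice_any_hyperoxic: int
    mean_delta_hypoxic: Optional[float]
    sd_delta_hypoxic: Optional[float]
    mean_delta_hyperoxic: Optional[float]
    sd_delta_hyperoxic: Optional[float]
    asymmetry_t: Optional[float]
    asymmetry_p: Optional[float]


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha/m for a family of m comparisons."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def pooled_control_deltas(
    dataset: StudyDataset, day: int, params: CallingParams | None = None
) -> np.ndarray:
    """Concatenated control ΔPO2 samples time-matched to ``day``.

    Each control mouse contributes its session nearest to ``day``
    within ``day_match_tolerance`` (exact match preferred; ties go to
    the earlier day), with that mouse's own baseline subtracted.
    """
    params = params or CallingParams()
    pools: list[np.ndarray] = []
    for mouse in dataset.control_mice:
        candidates = [s for s in mouse.post_sessions
                      if abs(s.day - day) <= params.day_match_tolerance]
        if not candidates:
            continue
        best = min(candidates, key=lambda s: (abs(s.day - day), s.day))
        deltas = delta_series(best, compute_baseline(mouse))
        if params.session_means:
            pools.append(np.array([float(np.mean(deltas))]))
        else:
            pools.append(deltas)
    if not pools:
        raise ValueError(
            f"no control session within +/-{params.day_match_tolerance} "
            f"day(s) of day {day}"
        )
    return np.concatenate(pools)


def classify_day(
    eae_deltas: Sequence[float],
    control_pool: Sequence[float],
    alpha_corrected: float,
    test_variant: TestVariant | str = TestVariant.WELCH,
) -> tuple[float, float, CallLabel]:
    """Two-sample t-test of one day's EAE ΔPO2 samples vs the control pool.

    Returns (t, p, label). Degenerate inputs with zero variance in both
    groups and equal means give t = 0, p = 1 (normoxic); zero variance
    with unequal means gives an infinite t and p = 0.
    """
    x = np.asarray(eae_deltas, dtype=float)
    y = np.asarray(control_pool, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need >= 2 values for a t-test")
    variant = TestVariant(test_variant)
    diff = float(np.mean(x) - np.mean(y))
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if diff == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, diff), 0.0
    else:
        res = stats.ttest_ind(x, y, equal_var=(variant is TestVariant.STUDENT))
        t, p = float(res.statistic), float(res.pvalue)
    if p < alpha_corrected:
        label = CallLabel.HYPOXIC if diff < 0 else CallLabel.HYPEROXIC
    else:
        label = CallLabel.NORMOXIC
    return t, p, label


def summarize_mouse(
    calls: Sequence[DayCall], behavior: Sequence[tuple[int, float]]
) -> MouseSummary:
    """Collapse one mouse's day calls and scores into a summary-table row."""
    ids = {c.mouse_id for c in calls}
    if len(ids) > 1:
        raise ValueError(f"calls span multiple mice: {sorted(ids)}")
    mouse_id = ids.pop() if ids else ""

    def _label_stats(label: CallLabel) -> tuple[int, Optional[float], Optional[float]]:
        deltas = [c.mean_delta_eae for c in calls if c.label is label]
        if not deltas:
            return 0, None, None
        mean = float(np.mean(deltas))
        sd = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0
        return len(deltas), mean, sd

    n_hypo, mean_hypo, sd_hypo = _label_stats(CallLabel.HYPOXIC)
    n_hyper, mean_hyper, sd_hyper = _label_stats(CallLabel.HYPEROXIC)
    day_largest = (
        max(calls, key=lambda c: abs(c.mean_delta_eae)).day if calls else None
    )
    peak = max((s for _, s in behavior), default=0.0)
    if peak > 0:
        peak_day: Optional[int] = min(d for d, s in behavior if s == peak)
    else:
        peak, peak_day = 0.0, None
    return MouseSummary(
        mouse_id=mouse_id,
        n_hypoxic_days=n_hypo,
        n_hyperoxic_days=n_hyper,
        mean_delta_hypoxic=mean_hypo,
        sd_delta_hypoxic=sd_hypo,
        mean_delta_hyperoxic=mean_hyper,
        sd_delta_hyperoxic=sd_hyper,
        day_largest_abs_delta=day_largest,
        peak_behavior=float(peak),
        day_peak_behavior=peak_day,
    )


def asymmetry_test(calls: Sequence[DayCall]) -> Optional[tuple[float, float]]:
    """Are hypoxic excursions larger than hyperoxic ones?

    Two-sample (pooled-variance) t-test on |mean ΔPO2| of hypoxic vs
    hyperoxic days. Returns None, with a warning, when either class has
    fewer than 2 days.
    """
    hypo = [abs(c.mean_delta_eae) for c in calls if c.label is CallLabel.HYPOXIC]
    hyper = [abs(c.mean_delta_eae) for c in calls if c.label is CallLabel.HYPEROXIC]
    if len(hypo) < 2 or len(hyper) < 2:
        warnings.warn(
            "asymmetry test skipped: need >=2 hypoxic and >=2 hyperoxic days",
            stacklevel=2,
        )
        return None
    if np.var(hypo, ddof=1) == 0.0 and np.var(hyper, ddof=1) == 0.0:
        if np.mean(hypo) == np.mean(hyper):
            return 0.0, 1.0
        return math.copysign(math.inf, np.mean(hypo) - np.mean(hyper)), 0.0
    res = stats.ttest_ind(hypo, hyper, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def call_study(
    dataset: StudyDataset, params: CallingParams | None = None
) -> tuple[list[DayCall], list[MouseSummary], CohortSummary]:
    """Run the full day-calling procedure on one region's cohort.

    One :class:`DayCall` per EAE post-induction session that has a
    matchable control pool (unmatchable days are skipped with a
    warning); per-mouse summaries in the published table layout; and
    cohort totals with the hypoxia/hyperoxia magnitude-asymmetry test.
    """
    params = params or CallingParams()
    if not dataset.control_mice or not dataset.eae_mice:
        raise ValueError("calling requires >=1 control and >=1 EAE mouse")

    if params.family is Family.GLOBAL:
        m_global = sum(len(m.post_sessions) for m in dataset.eae_mice)

    calls: list[DayCall] = []
    summaries: list[MouseSummary] = []
    for mouse in dataset.eae_mice:
        baseline = compute_baseline(mouse)
        post = mouse.post_sessions
        if params.family is Family.PER_MOUSE:
            m = max(len(post), 1)
        else:
            m = max(m_global, 1)
        alpha_corr = bonferroni_alpha(params.alpha, m)
        mouse_calls: list[DayCall] = []
        for session in post:
            try:
                pool = pooled_control_deltas(dataset, session.day, params)
            except ValueError as exc:
                warnings.warn(f"{mouse.mouse_id} day {session.day}: {exc}", stacklevel=2)
                continue
            deltas = delta_series(session, baseline)
            t, p, label = classify_day(deltas, pool, alpha_corr, params.test_variant)
            mouse_calls.append(
                DayCall(
                    mouse_id=mouse.mouse_id,
                    day=session.day,
                    mean_delta_eae=float(np.mean(deltas)),
                    mean_delta_control=float(np.mean(pool)),
                    t_stat=t,
                    p_raw=p,
                    alpha_corrected=alpha_corr,
                    n_eae=int(deltas.size),
                    n_control=int(pool.size),
                    label=label,
                )
            )
        calls.extend(mouse_calls)
        summaries.append(summarize_mouse(mouse_calls, mouse.behavior))

    cohort = summarize_cohort(calls, summaries)
    return calls, summaries, cohort


def summarize_cohort(
    calls: Sequence[DayCall], summaries: Sequence[MouseSummary]
) -> CohortSummary:
    hypo = [c.mean_delta_eae for c in calls if c.label is CallLabel.HYPOXIC]
    hyper = [c.mean_delta_eae for c in calls if c.label is CallLabel.HYPEROXIC]

    def _ms(vals: list[float]) -> tuple[Optional[float], Optional[float]]:
        if not vals:
            return None, None
        return (
            float(np.mean(vals)),
            float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        )

    mean_hypo, sd_hypo = _ms(hypo)
    mean_hyper, sd_hyper = _ms(hyper)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        asym = asymmetry_test(calls)
    return CohortSummary(
        total_hypoxic_days=len(hypo),
        total_hyperoxic_days=len(hyper),
        total_measurement_days=len(calls),
        n_mice_any_hypoxic=sum(1 for s in summaries if s.n_hypoxic_days > 0),
        n_mice_any_hyperoxic=sum(1 for s in summaries if s.n_hyperoxic_days > 0),
        mean_delta_hypoxic=mean_hypo,
        sd_delta_hypoxic=sd_hypo,
        mean_delta_hyperoxic=mean_hyper,
        sd_delta_hyperoxic=sd_hyper,
        asymmetry_t=asym[0] if asym else None,
        asymmetry_p=asym[1] if asym else None,
    )


def summary_totals(summaries: Sequence[MouseSummary]) -> dict[str, int]:
    """Aggregate per-mouse summary rows (e.g. the packaged fixtures)."""
    return {
        "n_mice": len(summaries),
        "total_hypoxic_days": sum(s.n_hypoxic_days for s in summaries),
        "total_hyperoxic_days": sum(s.n_hyperoxic_days for s in summaries),
        "n_mice_any_hypoxic": sum(1 for s in summaries if s.n_hypoxic_days > 0),
        "n_mice_any_hyperoxic": sum(1 for s in summaries if s.n_hyperoxic_days > 0),
    }
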