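"""Windowed event probabilities and behavior-score statistics.

Covers the time-resolved half of the analysis: the probability of a
hypoxic or hyperoxic call per 4-day window of the disease course, the
grouping of |ΔPO2| by behavior-deficit bin with one-way ANOVA and
Games-Howell post-hoc comparisons (unequal variances), the linear
deficit-vs-|ΔPO2| regression with its F-test against y = 0, and the
per-bin absolute-PO2 t-tests against controls with Bonferroni
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .calling import CallingParams, CallLabel, DayCall, TestVariant, bonferroni_alpha
from .core import compute_baseline, session_stats
from .model import StudyDataset

#: Maximum day gap when pairing a PO2 measurement with a behavior score.
SCORE_PAIRING_TOLERANCE = 2


@dataclass(frozen=True)
class WindowSpec:
    """Half-open day windows [a, a + width) tiling [start, end)."""

    width: int = 4
    start: int = 0
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("window width must be >= 1")

    def windows(self, last_day: int) -> list[tuple[int, int]]:
        end = self.end if self.end is not None else last_day + 1
        out = []
        a = self.start
        while a < end:
            out.append((a, min(a + self.width, end)))
            a += self.width
        return out


@dataclass(frozen=True)
class BehaviorBins:
    """Deficit-score bins; half-open on interior edges.

    The default edges (0, 4, 8, 12) give low [0, 4), medium [4, 8) and
    high [8, 12] bins; at 0.5-point granularity these match the
    published "0-3.9 / 4-7.9 / 8.0-12" grouping. Scores above the last
    edge (possible just before humane-endpoint censoring) fall into the
    top bin with a warning.
    """

    edges: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    labels: tuple[str, ...] = ("low", "medium", "high")

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or any(
            b <= a for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("need one label per bin")
        if self.edges[0] > 0:
            raise ValueError("bins must cover score 0")

    def bin_of(self, score: float) -> str:
        if score < self.edges[0]:
            raise ValueError(f"score {score} below first edge {self.edges[0]}")
        if score > self.edges[-1]:
            warnings.warn(
                f"score {score} above last bin edge {self.edges[-1]}; "
                "assigned to the top bin",
                stacklevel=2,
            )
            return self.labels[-1]
        for (a, b), lab in zip(zip(self.edges, self.edges[1:]), self.labels):
            if a <= score < b:
                return lab
        return self.labels[-1]  # score == last edge (closed top bin)


def window_probabilities(
    calls: Sequence[DayCall], spec: WindowSpec | None = None
):
    """Per-window hypoxia/hyperoxia probabilities.

    Each window's probability is the count of calls with that label
    divided by the number of calls in the window; empty windows report
    NaN probabilities with n = 0. Returns a pandas DataFrame with
    columns window_start, window_end, n_measurements, p_hypoxia,
    p_hyperoxia.
    """
    import pandas as pd

    if not calls:
        raise ValueError("no day calls to window")
    spec = spec or WindowSpec()
    last_day = max(c.day for c in calls)
    rows = []
    for a, b in spec.windows(last_day):
        in_win = [c for c in calls if a <= c.day < b]
        n = len(in_win)
        if n == 0:
            p_hypo = p_hyper = math.nan
        else:
            p_hypo = sum(c.label is CallLabel.HYPOXIC for c in in_win) / n
            p_hyper = sum(c.label is CallLabel.HYPEROXIC for c in in_win) / n
        rows.append((a, b, n, p_hypo, p_hyper))
    return pd.DataFrame(
        rows,
        columns=["window_start", "window_end", "n_measurements", "p_hypoxia", "p_hyperoxia"],
    )


def pair_score(
    behavior: Sequence[tuple[int, float]],
    day: int,
    tolerance: int = SCORE_PAIRING_TOLERANCE,
) -> Optional[float]:
    """Behavior score paired with a measurement day.

    Same-day score preferred (scoring happened an hour after the PO2
    recording); otherwise the nearest score within ``tolerance`` days,
    ties to the earlier day; otherwise None.
    """
    if not behavior:
        return None
    best = min(behavior, key=lambda t: (abs(t[0] - day), t[0]))
    return best[1] if abs(best[0] - day) <= tolerance else None


def group_abs_delta_by_behavior(
    calls: Sequence[DayCall],
    behavior_by_mouse: Mapping[str, Sequence[tuple[int, float]]],
    bins: BehaviorBins | None = None,
) -> tuple[dict[str, list[float]], list[DayCall]]:
    """|mean ΔPO2| per mouse-day, partitioned by the paired score's bin.

    Returns (groups keyed by bin label, list of unpaired calls). Raises
    if no call at all can be paired with a score.
    """
    bins = bins or BehaviorBins()
    groups: dict[str, list[float]] = {lab: [] for lab in bins.labels}
    unpaired: list[DayCall] = []
    for c in calls:
        score = pair_score(behavior_by_mouse.get(c.mouse_id, ()), c.day)
        if score is None:
            unpaired.append(c)
        else:
            groups[bins.bin_of(score)].append(abs(c.mean_delta_eae))
    if not any(groups.values()):
        raise ValueError("no call could be paired with a behavior score")
    return groups, unpaired


def _welch_df(s1sq: float, n1: int, s2sq: float, n2: int) -> float:
    num = (s1sq / n1 + s2sq / n2) ** 2
    den = (s1sq / n1) ** 2 / (n1 - 1) + (s2sq / n2) ** 2 / (n2 - 1)
    return num / den if den > 0 else float(n1 + n2 - 2)


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    mean_diff: float
    q_stat: float
    df: float
    p_value: float


def anova_games_howell(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, float, list[PairwiseComparison]]:
    """One-way ANOVA plus Games-Howell post-hoc comparisons.

    Games-Howell handles unequal variances and group sizes: for groups
    i, j the statistic q = |mi - mj| / sqrt((si²/ni + sj²/nj)/2) is
    referred to the studentized-range distribution with k groups and
    Welch–Satterthwaite degrees of freedom. Groups with fewer than 2
    values are excluded with a warning. Returns (F, p_anova, pairwise);
    with all groups constant the ANOVA F is NaN (flagged) and pairwise
    comparisons degenerate to q = 0, p = 1 (or p = 0 when means differ).
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    dropped = set(groups) - set(usable)
    if dropped:
        warnings.warn(
            f"excluding group(s) with <2 values: {sorted(dropped)}", stacklevel=2
        )
    if len(usable) < 2:
        raise ValueError("need >=2 groups with >=2 values each")

    k = len(usable)
    arrays = list(usable.values())
    if all(np.var(a, ddof=1) == 0.0 for a in arrays):
        f_stat, p_anova = math.nan, math.nan
        warnings.warn("all groups constant: ANOVA F undefined", stacklevel=2)
    else:
        f_stat, p_anova = (float(x) for x in stats.f_oneway(*arrays))

    names = list(usable)
    pairwise: list[PairwiseComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = usable[names[i]], usable[names[j]]
            ni, nj = len(xi), len(xj)
            vi, vj = float(np.var(xi, ddof=1)), float(np.var(xj, ddof=1))
            diff = float(np.mean(xi) - np.mean(xj))
            se = math.sqrt((vi / ni + vj / nj) / 2.0)
            if se == 0.0:
                q = 0.0 if diff == 0.0 else math.inf
                p = 1.0 if diff == 0.0 else 0.0
                df = float(ni + nj - 2)
            else:
                q = abs(diff) / se
                df = _welch_df(vi, ni, vj, nj)
                p = float(stats.studentized_range.sf(q, k, df))
            pairwise.append(
                PairwiseComparison((names[i], names[j]), diff, q, df, p)
            )
    return f_stat, p_anova, pairwise


def regression_ftest(
    scores: Sequence[float], abs_deltas: Sequence[float]
) -> tuple[float, float, float, float, float]:
    """OLS of |ΔPO2| on behavior score, F-tested against a flat line.

    Returns (slope, intercept, r_squared, F, p) with
    F = (n − 2)·R²/(1 − R²) on (1, n − 2) degrees of freedom. Intended
    for mouse-days from animals that showed symptoms (max score > 0).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(abs_deltas, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 paired observations")
    if np.var(x) == 0.0:
        raise ValueError("degenerate predictor: scores have zero variance")
    n = x.size
    if np.var(y) == 0.0:
        return 0.0, float(np.mean(y)), 0.0, 0.0, 1.0
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        return float(res.slope), float(res.intercept), 1.0, math.inf, 0.0
    f_stat = (n - 2) * r2 / (1.0 - r2)
    p = float(stats.f.sf(f_stat, 1, n - 2))
    return float(res.slope), float(res.intercept), r2, float(f_stat), p


@dataclass
class BinTestResult:
    bin_label: str
    n_eae_sessions: int
    n_control_sessions: int
    mean_po2_eae: float
    mean_po2_control: float
    t_stat: float
    p_raw: float
    alpha_corrected: float
    significant: bool
    direction: str  # "lower" / "higher" relative to controls


def behavior_absolute_po2_tests(
    dataset: StudyDataset,
    bins: BehaviorBins | None = None,
    alpha: float = 0.05,
    params: CallingParams | None = None,
) -> list[BinTestResult]:
    """Absolute session-mean PO2 per behavior bin vs pooled controls.

    EAE post-induction session means (not ΔPO2) are grouped by the
    paired behavior score's bin and each non-empty bin is compared to
    the pooled control post-induction session means with a two-sample
    t-test; the Bonferroni family is the number of bins tested.
    """
    bins = bins or BehaviorBins()
    params = params or CallingParams(alpha=alpha)

    control_means = [
        session_stats(s)[0]
        for m in dataset.control_mice
        for s in m.post_sessions
    ]
    if len(control_means) < 2:
        raise ValueError("empty (or singleton) control pool of session means")

    by_bin: dict[str, list[float]] = {lab: [] for lab in bins.labels}
    for mouse in dataset.eae_mice:
        for s in mouse.post_sessions:
            score = pair_score(mouse.behavior, s.day)
            if score is None:
                continue
            by_bin[bins.bin_of(score)].append(session_stats(s)[0])
    tested = {lab: v for lab, v in by_bin.items() if len(v) >= 2}
    if not tested:
        raise ValueError("no behavior bin has >=2 EAE sessions")

    m = len(tested)
    alpha_corr = bonferroni_alpha(alpha, m)
    welch = params.test_variant is not TestVariant.STUDENT
    results = []
    for lab, vals in tested.items():
        res = stats.ttest_ind(vals, control_means, equal_var=not welch)
        diff = float(np.mean(vals) - np.mean(control_means))
        results.append(
            BinTestResult(
                bin_label=lab,
                n_eae_sessions=len(vals),
                n_control_sessions=len(control_means),
                mean_po2_eae=float(np.mean(vals)),
                mean_po2_control=float(np.mean(control_means)),
                t_stat=float(res.statistic),
                p_raw=float(res.pvalue),
                alpha_corrected=alpha_corr,
                significant=bool(res.pvalue < alpha_corr),
                direction="lower" if diff < 0 else "higher",
            )
        )
    return results
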