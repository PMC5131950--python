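"""Domain model for longitudinal brain-oximetry studies.

A study follows implanted-probe mice through EAE induction: each mouse
contributes one 10-minute PO2 recording session per measurement day
(nominally 60 samples at 0.1 Hz, in mmHg) plus behavior-deficit scores on
a 15-point paralysis scale (tail max 2, each limb max 3, 15 = death).
Days are counted relative to induction; negative days are the
pre-induction baseline period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

NOMINAL_SAMPLES_PER_SESSION = 60
MAX_BEHAVIOR_SCORE = 15.0
SCORE_STEP = 0.5


class Group(str, Enum):
    EAE = "EAE"
    CONTROL = "CONTROL"


class Region(str, Enum):
    CEREBELLUM = "cerebellum"
    CORTEX = "cortex"


@dataclass
class PO2Session:
    """One day's PO2 trace for one mouse (samples in mmHg)."""

    mouse_id: str
    day: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError(
                f"session {self.mouse_id} day {self.day}: samples must be a "
                "nonempty 1-D array"
            )
        self.day = int(self.day)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class MouseRecord:
    """All sessions and behavior scores for one animal.

    ``behavior`` is a list of (day, score) pairs, at most one per day.
    """

    mouse_id: str
    group: Group
    region: Region
    sessions: list[PO2Session] = field(default_factory=list)
    behavior: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.region = Region(self.region)
        self.sessions = sorted(self.sessions, key=lambda s: s.day)
        self.behavior = sorted(
            [(int(d), float(s)) for d, s in self.behavior], key=lambda t: t[0]
        )

    @property
    def baseline_sessions(self) -> list[PO2Session]:
        return [s for s in self.sessions if s.day < 0]

    @property
    def post_sessions(self) -> list[PO2Session]:
        return [s for s in self.sessions if s.day >= 0]

    def session_on(self, day: int) -> Optional[PO2Session]:
        for s in self.sessions:
            if s.day == day:
                return s
        return None

    def peak_behavior(self) -> tuple[float, Optional[int]]:
        """Peak score and the first day it was reached (day None if peak 0)."""
        if not self.behavior:
            return 0.0, None
        peak = max(score for _, score in self.behavior)
        if peak <= 0:
            return 0.0, None
        day = min(d for d, score in self.behavior if score == peak)
        return peak, day


@dataclass
class StudyDataset:
    """One region's cohort: EAE mice plus time-matched CFA controls."""

    mice: list[MouseRecord]
    region: Region

    def __post_init__(self) -> None:
        self.region = Region(self.region)

    @property
    def eae_mice(self) -> list[MouseRecord]:
        return [m for m in self.mice if m.group is Group.EAE]

    @property
    def control_mice(self) -> list[MouseRecord]:
        return [m for m in self.mice if m.group is Group.CONTROL]

    def get_mouse(self, mouse_id: str) -> MouseRecord:
        for m in self.mice:
            if m.mouse_id == mouse_id:
                return m
        raise KeyError(f"unknown mouse {mouse_id!r}")


@dataclass
class MouseSummary:
    """Per-mouse aggregate in the layout of the study's summary tables.

    Mean/sd fields are ``None`` when the mouse has no days of that class
    (printed as N/A); ``day_peak_behavior`` is ``None`` when the peak
    score is 0.
    """

    mouse_id: str
    n_hypoxic_days: int
    n_hyperoxic_days: int
    mean_delta_hypoxic: Optional[float]
    sd_delta_hypoxic: Optional[float]
    mean_delta_hyperoxic: Optional[float]
    sd_delta_hyperoxic: Optional[float]
    day_largest_abs_delta: Optional[int]
    peak_behavior: float
    day_peak_behavior: Optional[int]


def _is_half_step(score: float, tol: float = 1e-9) -> bool:
    return abs(score / SCORE_STEP - round(score / SCORE_STEP)) <= tol


def validate_study(dataset: StudyDataset) -> list[str]:
    """Check every model invariant; return human-readable violations.

    Reports rather than raises so callers can surface all problems at
    once. An empty list means the dataset is fully valid.
    """
    violations: list[str] = []
    seen_ids: set[str] = set()
    for mouse in dataset.mice:
        mid = mouse.mouse_id
        if mid in seen_ids:
            violations.append(f"{mid}: duplicate mouse_id")
        seen_ids.add(mid)
        if mouse.region is not dataset.region:
            violations.append(
                f"{mid}: region {mouse.region.value} differs from dataset "
                f"region {dataset.region.value}"
            )
        days = [s.day for s in mouse.sessions]
        if len(days) != len(set(days)):
            violations.append(f"{mid}: duplicate session day")
        if not any(d < 0 for d in days):
            violations.append(f"{mid}: no baseline (no session with day < 0)")
        for s in mouse.sessions:
            if not np.all(np.isfinite(s.samples)):
                violations.append(f"{mid} day {s.day}: non-finite PO2 sample")
            elif np.any(s.samples < 0):
                violations.append(f"{mid} day {s.day}: negative PO2 sample")
        score_days = [d for d, _ in mouse.behavior]
        if len(score_days) != len(set(score_days)):
            violations.append(f"{mid}: more than one behavior score on a day")
        for d, score in mouse.behavior:
            if not (0.0 <= score <= MAX_BEHAVIOR_SCORE):
                violations.append(
                    f"{mid} day {d}: behavior score {score} outside [0, 15]"
                )
            elif not _is_half_step(score):
                violations.append(
                    f"{mid} day {d}: score granularity ({score} is not a "
                    "0.5 multiple)"
                )
    return violations


def warn_nonstandard_sessions(dataset: StudyDataset) -> None:
    """Warn (once per mouse-day) about sessions that are not 60 samples."""
    for mouse in dataset.mice:
        for s in mouse.sessions:
            if s.n_samples != NOMINAL_SAMPLES_PER_SESSION:
                warnings.warn(
                    f"{mouse.mouse_id} day {s.day}: {s.n_samples} samples "
                    f"(nominal {NOMINAL_SAMPLES_PER_SESSION})",
                    stacklevel=2,
                )


def datasets_equal(a: StudyDataset, b: StudyDataset) -> bool:
    """Structural equality on the data model (exact float comparison)."""
    if a.region is not b.region or len(a.mice) != len(b.mice):
        return False
    for ma, mb in zip(
        sorted(a.mice, key=lambda m: m.mouse_id),
        sorted(b.mice, key=lambda m: m.mouse_id),
    ):
        if (
            ma.mouse_id != mb.mouse_id
            or ma.group is not mb.group
            or ma.region is not mb.region
            or ma.behavior != mb.behavior
            or len(ma.sessions) != len(mb.sessions)
        ):
            return False
        for sa, sb in zip(ma.sessions, mb.sessions):
            if sa.day != sb.day or not np.array_equal(sa.samples, sb.samples):
                return False
    return True
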