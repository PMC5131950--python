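"""Synthetic preclinical cohort generator with a ground-truth channel.

The study's raw PO2 traces were never deposited, so analyses are
exercised on synthetic cohorts that reproduce the statistical structure
the pipeline assumes: strong per-animal baseline heterogeneity, a
measurement schedule that densifies around disease peak, day-level
hypoxic/hyperoxic shifts drawn per mouse-day from region-specific
distributions and time-windowed event probabilities, behavior
trajectories on the 15-point deficit scale, and humane-endpoint
censoring at score >= 13.

Every injected mouse-day label (hypoxic / hyperoxic / normoxic) and its
shift in mmHg is recorded in a :class:`GroundTruth` table so that the
day-calling pipeline can be scored against the truth it was fed.

Reproducibility: one root seed; each mouse draws from its own
``SeedSequence`` substream, so enlarging the cohort never perturbs the
mice already generated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .model import (
    Group,
    MouseRecord,
    PO2Session,
    Region,
    StudyDataset,
)

Label = Literal["hypoxic", "hyperoxic", "normoxic"]

# (window_start, window_end, probability) with half-open [start, end) days.
ProbCurve = tuple[tuple[int, int, float], ...]

#: Measurement cadence: every 2-3 days through the disease peak
#: (days 10-18), every 5 days afterwards, ending near sacrifice.
DEFAULT_POST_SCHEDULE = (3, 5, 7, 10, 12, 14, 16, 18, 23, 28, 33)
DEFAULT_BASELINE_DAYS = (-3, -2, -1)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters for one region's synthetic cohort.

    Units: PO2 quantities in mmHg, days relative to induction, behavior
    in score points. The probability curves give, per day window, the
    chance that an EAE measurement day carries a hypoxic (resp.
    hyperoxic) shift; within each window the two must sum to <= 1.
    """

    region: Region
    n_eae: int
    n_control: int
    baseline_mu: float
    baseline_sd: float
    hypoxic_shift_mu: float
    hypoxic_shift_sd: float
    hyperoxic_shift_mu: float
    hyperoxic_shift_sd: float
    hypoxia_prob_curve: ProbCurve
    hyperoxia_prob_curve: ProbCurve
    behavior_onset_day: float
    behavior_peak_day: float
    behavior_peak_mu: float
    behavior_peak_sd: float
    within_session_sd: float = 2.5
    baseline_days: tuple[int, ...] = DEFAULT_BASELINE_DAYS
    post_schedule: tuple[int, ...] = DEFAULT_POST_SCHEDULE
    censor_threshold: float = 13.0
    samples_per_session: int = 60
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))

    def validate(self) -> None:
        if self.n_eae < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.baseline_mu <= 0:
            raise ValueError("baseline_mu must be positive")
        for name in ("baseline_sd", "within_session_sd", "hypoxic_shift_sd",
                     "hyperoxic_shift_sd", "behavior_peak_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hypoxic_shift_mu >= 0:
            raise ValueError("hypoxic_shift_mu must be negative")
        if self.hyperoxic_shift_mu <= 0:
            raise ValueError("hyperoxic_shift_mu must be positive")
        if self.samples_per_session < 2:
            raise ValueError("samples_per_session must be >= 2")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in (-1, 1)")
        if any(d >= 0 for d in self.baseline_days):
            raise ValueError("baseline days must be negative")
        for sched in (self.baseline_days, self.post_schedule):
            if any(b <= a for a, b in zip(sched, sched[1:])):
                raise ValueError("schedule days must be strictly increasing")
        for curve in (self.hypoxia_prob_curve, self.hyperoxia_prob_curve):
            for a, b, p in curve:
                if b <= a:
                    raise ValueError(f"empty probability window [{a}, {b})")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"window [{a}, {b}): probability {p} outside [0, 1]")
        for day in self.post_schedule:
            total = _curve_prob(self.hypoxia_prob_curve, day) + _curve_prob(
                self.hyperoxia_prob_curve, day
            )
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"day {day}: hypoxia + hyperoxia probability {total} > 1"
                )

    # -- JSON round trip (CLI config files) --------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["region"] = self.region.value
        d["baseline_days"] = list(self.baseline_days)
        d["post_schedule"] = list(self.post_schedule)
        d["hypoxia_prob_curve"] = [list(w) for w in self.hypoxia_prob_curve]
        d["hyperoxia_prob_curve"] = [list(w) for w in self.hyperoxia_prob_curve]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("baseline_days", "post_schedule"):
            if key in d:
                d[key] = tuple(int(x) for x in d[key])
        for key in ("hypoxia_prob_curve", "hyperoxia_prob_curve"):
            if key in d:
                d[key] = tuple((int(a), int(b), float(p)) for a, b, p in d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TruthRecord:
    mouse_id: str
    day: int
    label: Label
    shift: float


@dataclass
class GroundTruth:
    """Injected per mouse-day labels and shifts for recovery scoring."""

    records: list[TruthRecord] = field(default_factory=list)

    def label_of(self, mouse_id: str, day: int) -> Label:
        for r in self.records:
            if r.mouse_id == mouse_id and r.day == day:
                return r.label
        raise KeyError(f"no ground truth for ({mouse_id}, {day})")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.mouse_id, r.day, r.label, r.shift) for r in self.records],
            columns=["mouse_id", "day", "label", "shift_mmhg"],
        )

    def validate(self) -> None:
        for r in self.records:
            ok = (
                (r.label == "hypoxic" and r.shift < 0)
                or (r.label == "hyperoxic" and r.shift > 0)
                or (r.label == "normoxic" and r.shift == 0)
            )
            if not ok:
                raise ValueError(
                    f"({r.mouse_id}, {r.day}): label {r.label} inconsistent "
                    f"with shift {r.shift}"
                )


# ---------------------------------------------------------------------------
# Region presets

_PRESETS: dict[Region, dict] = {
    # Cerebellar cohort: 8 EAE / 5 CFA controls; baseline 29.9 +/- 6.8 mmHg;
    # hypoxic-day shift -8.8 +/- 6.0, hyperoxic-day +3.2 +/- 2.8. Hypoxia
    # probability peaks in days 4-8 (0.67), hyperoxia in days 8-12 (0.46),
    # with off-peak levels set so simulated cohorts carry roughly half
    # hypoxic and a quarter hyperoxic days, as observed for this region.
    Region.CEREBELLUM: dict(
        n_eae=8,
        n_control=5,
        baseline_mu=29.9,
        baseline_sd=6.8,
        hypoxic_shift_mu=-8.8,
        hypoxic_shift_sd=6.0,
        hyperoxic_shift_mu=3.2,
        hyperoxic_shift_sd=2.8,
        hypoxia_prob_curve=(
            (0, 4, 0.40), (4, 8, 0.67), (8, 12, 0.50), (12, 16, 0.50),
            (16, 20, 0.50), (20, 24, 0.45), (24, 34, 0.35),
        ),
        hyperoxia_prob_curve=(
            (0, 4, 0.10), (4, 8, 0.15), (8, 12, 0.46), (12, 16, 0.30),
            (16, 20, 0.25), (20, 24, 0.25), (24, 34, 0.20),
        ),
        behavior_onset_day=10.0,
        behavior_peak_day=17.0,
        behavior_peak_mu=6.0,
        behavior_peak_sd=3.3,
    ),
    # Cortical cohort: 16 EAE / 8 controls; baseline 23.6 +/- 4.8 mmHg;
    # shifts -8.0 +/- 4.6 and +0.8 +/- 2.1. Hypoxia probability peaks in
    # days 8-12 (0.86); hyperoxia peaks later, days 16-20 (0.29). Deficits
    # appear earlier (day ~7) than in the cerebellar cohort.
    Region.CORTEX: dict(
        n_eae=16,
        n_control=8,
        baseline_mu=23.6,
        baseline_sd=4.8,
        hypoxic_shift_mu=-8.0,
        hypoxic_shift_sd=4.6,
        hyperoxic_shift_mu=0.8,
        hyperoxic_shift_sd=2.1,
        hypoxia_prob_curve=(
            (0, 4, 0.50), (4, 8, 0.70), (8, 12, 0.86), (12, 16, 0.78),
            (16, 20, 0.70), (20, 24, 0.75), (24, 34, 0.70),
        ),
        hyperoxia_prob_curve=(
            (0, 4, 0.10), (4, 8, 0.10), (8, 12, 0.10), (12, 16, 0.20),
            (16, 20, 0.29), (20, 24, 0.20), (24, 34, 0.15),
        ),
        behavior_onset_day=7.0,
        behavior_peak_day=18.0,
        behavior_peak_mu=6.1,
        behavior_peak_sd=3.5,
    ),
}


def default_config(region: Region | str, seed: int = 0) -> SimulationConfig:
    """Region preset mirroring the published cohort structure."""
    region = Region(region)
    cfg = SimulationConfig(region=region, seed=seed, **_PRESETS[region])
    cfg.validate()
    return cfg


def null_config(region: Region | str, seed: int = 0) -> SimulationConfig:
    """Default preset with all event probabilities zeroed.

    Under this configuration EAE and control sessions are identically
    distributed; every injected label is normoxic.
    """
    cfg = default_config(region, seed=seed)
    zero = tuple((a, b, 0.0) for a, b, _ in cfg.hypoxia_prob_curve)
    zero2 = tuple((a, b, 0.0) for a, b, _ in cfg.hyperoxia_prob_curve)
    return replace(cfg, hypoxia_prob_curve=zero, hyperoxia_prob_curve=zero2)


# ---------------------------------------------------------------------------
# Generation

def _curve_prob(curve: ProbCurve, day: int) -> float:
    for a, b, p in curve:
        if a <= day < b:
            return p
    return 0.0


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      low: float = 0.0, max_tries: int = 10000) -> float:
    """Rejection-sample Normal(mu, sd) conditioned on value > low."""
    if sd == 0:
        if mu <= low:
            raise ValueError(f"degenerate truncated normal: mu {mu} <= {low}")
        return mu
    for _ in range(max_tries):
        x = rng.normal(mu, sd)
        if x > low:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def _signed_shift(rng: np.random.Generator, mu: float, sd: float) -> float:
    """Draw a shift with the sign of mu enforced (rejection sampling)."""
    sign = 1.0 if mu > 0 else -1.0
    return sign * _truncated_normal(rng, abs(mu), sd, low=0.0)


def _session_samples(
    rng: np.random.Generator, mean: float, cfg: SimulationConfig
) -> np.ndarray:
    n = cfg.samples_per_session
    if cfg.ar1_rho == 0.0:
        noise = rng.normal(0.0, cfg.within_session_sd, size=n)
    else:
        # AR(1) with the configured marginal sd
        rho = cfg.ar1_rho
        innov_sd = cfg.within_session_sd * np.sqrt(1 - rho**2)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, cfg.within_session_sd)
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + rng.normal(0.0, innov_sd)
    return np.maximum(mean + noise, 0.0)  # physical floor at 0 mmHg


def _round_half(x: float) -> float:
    return round(x * 2.0) / 2.0


def _behavior_scores(
    rng: np.random.Generator, days: tuple[int, ...], cfg: SimulationConfig
) -> list[tuple[int, float]]:
    """Piecewise-linear onset -> peak -> plateau trajectory with noise.

    A peak drawn below half a point produces an asymptomatic mouse
    (all-zero scores), mirroring the occasional EAE mouse that never
    shows deficits.
    """
    peak = rng.normal(cfg.behavior_peak_mu, cfg.behavior_peak_sd)
    onset = max(1.0, rng.normal(cfg.behavior_onset_day, 2.0))
    peak_day = max(onset + 1.0, rng.normal(cfg.behavior_peak_day, 2.0))
    scores: list[tuple[int, float]] = []
    for d in days:
        if peak < 0.5 or d < onset:
            base = 0.0
        elif d <= peak_day:
            base = peak * (d - onset) / (peak_day - onset)
        else:
            base = 0.85 * peak  # deficits persist near peak until sacrifice
        if base > 0:
            base += rng.normal(0.0, 0.5)
        score = min(max(_round_half(base), 0.0), 15.0)
        scores.append((int(d), score))
    return scores


def _simulate_mouse(
    mouse_id: str,
    group: Group,
    cfg: SimulationConfig,
    seed_seq: np.random.SeedSequence,
) -> tuple[MouseRecord, list[TruthRecord]]:
    rng = np.random.default_rng(seed_seq)
    baseline = _truncated_normal(rng, cfg.baseline_mu, cfg.baseline_sd)

    sessions: list[PO2Session] = []
    truths: list[TruthRecord] = []
    for day in cfg.baseline_days:
        sessions.append(
            PO2Session(mouse_id, day, _session_samples(rng, baseline, cfg))
        )

    for day in cfg.post_schedule:
        label: Label = "normoxic"
        shift = 0.0
        if group is Group.EAE:
            u = rng.random()
            p_hypo = _curve_prob(cfg.hypoxia_prob_curve, day)
            p_hyper = _curve_prob(cfg.hyperoxia_prob_curve, day)
            if u < p_hypo:
                label = "hypoxic"
                shift = _signed_shift(rng, cfg.hypoxic_shift_mu, cfg.hypoxic_shift_sd)
            elif u < p_hypo + p_hyper:
                label = "hyperoxic"
                shift = _signed_shift(rng, cfg.hyperoxic_shift_mu, cfg.hyperoxic_shift_sd)
        sessions.append(
            PO2Session(mouse_id, day, _session_samples(rng, baseline + shift, cfg))
        )
        truths.append(TruthRecord(mouse_id, int(day), label, shift))

    if group is Group.EAE:
        behavior = _behavior_scores(rng, cfg.post_schedule, cfg)
    else:
        behavior = [(int(d), 0.0) for d in cfg.post_schedule]

    # Humane-endpoint censoring: measurements stop after the first day the
    # deficit score reaches the threshold.
    censor_day: Optional[int] = None
    for d, s in behavior:
        if s >= cfg.censor_threshold:
            censor_day = d
            break
    if censor_day is not None:
        sessions = [s for s in sessions if s.day <= censor_day]
        behavior = [(d, s) for d, s in behavior if d <= censor_day]
        truths = [t for t in truths if t.day <= censor_day]

    record = MouseRecord(
        mouse_id=mouse_id,
        group=group,
        region=cfg.region,
        sessions=sessions,
        behavior=behavior,
    )
    return record, truths


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """Generate a synthetic cohort and its injected ground truth.

    Deterministic for a fixed config (including seed). Controls are
    generated first (C01, C02, ...), then EAE mice (E01, ...); each
    mouse consumes an independent RNG substream.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_control + config.n_eae)
    mice: list[MouseRecord] = []
    truth = GroundTruth()
    for i in range(config.n_control):
        rec, t = _simulate_mouse(f"C{i + 1:02d}", Group.CONTROL, config, children[i])
        mice.append(rec)
        truth.records.extend(t)
    for j in range(config.n_eae):
        rec, t = _simulate_mouse(
            f"E{j + 1:02d}", Group.EAE, config, children[config.n_control + j]
        )
        mice.append(rec)
        truth.records.extend(t)
    truth.validate()
    return StudyDataset(mice=mice, region=config.region), truth
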