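"""One-command orchestration: simulate/load → call → timecourse → behavior → kinetics.

``run_pipeline`` produces a flat bundle of plain CSV/JSON files plus a
manifest (config echo, seed, package version) sufficient to rerun the
analysis and reproduce every output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calling import CallingParams, call_study, summary_totals
from .core import KineticsParams, phd_rate_drop, po2_to_concentration
from .io import load_summary_fixture, read_study, summaries_to_frame, write_study
from .model import StudyDataset, validate_study
from .simulate import SimulationConfig, simulate_study
from .timecourse import (
    BehaviorBins,
    WindowSpec,
    anova_games_howell,
    behavior_absolute_po2_tests,
    group_abs_delta_by_behavior,
    regression_ftest,
    window_probabilities,
)


@dataclass
class RunConfig:
    """Pipeline inputs: exactly one of simulation / CSV paths / fixture."""

    out_dir: Path
    simulation: Optional[SimulationConfig] = None
    sessions_path: Optional[Path] = None
    behavior_path: Optional[Path] = None
    fixture: Optional[str] = None
    calling: CallingParams = dataclasses.field(default_factory=CallingParams)
    windows: WindowSpec = dataclasses.field(default_factory=WindowSpec)
    bins: BehaviorBins = dataclasses.field(default_factory=BehaviorBins)
    kinetics: KineticsParams = dataclasses.field(default_factory=KineticsParams)

    def validate(self) -> None:
        modes = [
            self.simulation is not None,
            self.sessions_path is not None,
            self.fixture is not None,
        ]
        if sum(modes) != 1:
            raise ValueError(
                "exactly one input mode required: simulation config, "
                "sessions CSV, or fixture name"
            )


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mouse_id": c.mouse_id,
                "day": c.day,
                "mean_delta_eae": c.mean_delta_eae,
                "mean_delta_control": c.mean_delta_control,
                "t_stat": c.t_stat,
                "p_raw": c.p_raw,
                "alpha_corrected": c.alpha_corrected,
                "n_eae": c.n_eae,
                "n_control": c.n_control,
                "label": c.label.value,
            }
            for c in calls
        ]
    )


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; return the paths written.

    Fixture mode only aggregates the packaged per-mouse summary table;
    the other modes run day-calling and all downstream statistics.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    manifest: dict = {
        "package": "eaeox",
        "version": __version__,
        "calling": dataclasses.asdict(cfg.calling),
        "windows": dataclasses.asdict(cfg.windows),
        "bins": dataclasses.asdict(cfg.bins),
        "kinetics": dataclasses.asdict(cfg.kinetics),
    }
    for key in ("calling", "windows", "bins"):
        manifest[key] = {
            k: (v.value if hasattr(v, "value") else v) for k, v in manifest[key].items()
        }

    if cfg.fixture is not None:
        try:
            summaries = load_summary_fixture(cfg.fixture)
        except Exception as exc:
            raise StageError("fixture", exc)
        manifest["input"] = {"fixture": cfg.fixture}
        written["mouse_summary"] = out / "mouse_summary.csv"
        summaries_to_frame(summaries).to_csv(written["mouse_summary"], index=False)
        written["cohort_summary"] = out / "cohort_summary.json"
        _write_json(written["cohort_summary"], summary_totals(summaries))
        written["manifest"] = out / "manifest.json"
        _write_json(written["manifest"], manifest)
        return written

    # ---- acquire dataset -------------------------------------------------
    truth = None
    if cfg.simulation is not None:
        try:
            dataset, truth = simulate_study(cfg.simulation)
        except Exception as exc:
            raise StageError("simulate", exc)
        manifest["input"] = {"simulation": cfg.simulation.to_dict(),
                             "seed": cfg.simulation.seed}
        s_path, b_path = write_study(dataset, out / "sessions.csv", out / "behavior.csv")
        written["sessions"], written["behavior"] = s_path, b_path
        written["ground_truth"] = out / "ground_truth.csv"
        truth.as_frame().to_csv(written["ground_truth"], index=False)
    else:
        try:
            dataset = read_study(cfg.sessions_path, cfg.behavior_path)
        except Exception as exc:
            raise StageError("read", exc)
        manifest["input"] = {
            "sessions_path": str(cfg.sessions_path),
            "behavior_path": str(cfg.behavior_path) if cfg.behavior_path else None,
        }

    problems = validate_study(dataset)
    if problems:
        raise StageError("validate", ValueError("; ".join(problems)))

    # ---- day calling -----------------------------------------------------
    try:
        calls, summaries, cohort = call_study(dataset, cfg.calling)
    except Exception as exc:
        raise StageError("call", exc)
    written["calls"] = out / "calls.csv"
    _calls_frame(calls).to_csv(written["calls"], index=False)
    written["mouse_summary"] = out / "mouse_summary.csv"
    summaries_to_frame(summaries).to_csv(written["mouse_summary"], index=False)
    written["cohort_summary"] = out / "cohort_summary.json"
    _write_json(written["cohort_summary"], dataclasses.asdict(cohort))
    manifest["alpha_corrected_by_mouse"] = {
        s.mouse_id: next(
            (c.alpha_corrected for c in calls if c.mouse_id == s.mouse_id), None
        )
        for s in summaries
    }

    # ---- windowed probabilities -----------------------------------------
    try:
        probs = window_probabilities(calls, cfg.windows)
    except Exception as exc:
        raise StageError("timecourse", exc)
    written["window_probabilities"] = out / "window_probabilities.csv"
    probs.to_csv(written["window_probabilities"], index=False)

    # ---- behavior statistics --------------------------------------------
    behavior_by_mouse = {m.mouse_id: m.behavior for m in dataset.eae_mice}
    anova_payload: dict
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups, unpaired = group_abs_delta_by_behavior(
                calls, behavior_by_mouse, cfg.bins
            )
            f_stat, p_anova, pairwise = anova_games_howell(groups)
        anova_payload = {
            "group_sizes": {k: len(v) for k, v in groups.items()},
            "n_unpaired_calls": len(unpaired),
            "anova_f": f_stat,
            "anova_p": p_anova,
            "games_howell": [
                {
                    "pair": list(c.pair),
                    "mean_diff": c.mean_diff,
                    "q": c.q_stat,
                    "df": c.df,
                    "p": c.p_value,
                }
                for c in pairwise
            ],
        }
    except ValueError as exc:  # degenerate grouping is data, not a bug
        anova_payload = {"skipped": str(exc)}
    written["behavior_anova"] = out / "behavior_anova.json"
    _write_json(written["behavior_anova"], anova_payload)

    symptomatic = {
        m.mouse_id for m in dataset.eae_mice if m.peak_behavior()[0] > 0
    }
    pairs = [
        (score, abs(c.mean_delta_eae))
        for c in calls
        if c.mouse_id in symptomatic
        and (score := _paired_score(behavior_by_mouse, c)) is not None
    ]
    try:
        slope, intercept, r2, f_reg, p_reg = regression_ftest(
            [s for s, _ in pairs], [d for _, d in pairs]
        )
        reg_payload = {
            "n": len(pairs),
            "slope": slope,
            "intercept": intercept,
            "r_squared": r2,
            "f_stat": f_reg,
            "p": p_reg,
        }
    except ValueError as exc:
        reg_payload = {"skipped": str(exc)}
    written["regression"] = out / "regression.json"
    _write_json(written["regression"], reg_payload)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bin_tests = behavior_absolute_po2_tests(
                dataset, cfg.bins, cfg.calling.alpha, cfg.calling
            )
        bt_frame = pd.DataFrame([dataclasses.asdict(b) for b in bin_tests])
    except ValueError as exc:
        bt_frame = pd.DataFrame([{"skipped": str(exc)}])
    written["behavior_bin_tests"] = out / "behavior_bin_tests.csv"
    bt_frame.to_csv(written["behavior_bin_tests"], index=False)

    # ---- PHD kinetics from this cohort's numbers -------------------------
    from .core import compute_baseline

    baselines = [compute_baseline(m) for m in dataset.mice]
    mean_baseline = float(np.mean(baselines))
    kin_payload: dict = {
        "mean_baseline_po2_mmhg": mean_baseline,
        "alpha_solubility_um_per_mmhg": cfg.kinetics.alpha_solubility,
    }
    if cohort.mean_delta_hypoxic is not None:
        c1 = po2_to_concentration(mean_baseline, cfg.kinetics)
        c2 = po2_to_concentration(
            max(mean_baseline + cohort.mean_delta_hypoxic, 0.0), cfg.kinetics
        )
        drop_min, drop_max = phd_rate_drop(c1, c2, cfg.kinetics)
        kin_payload.update(
            {
                "mean_hypoxic_delta_mmhg": cohort.mean_delta_hypoxic,
                "c1_um": c1,
                "c2_um": c2,
                "km_range_um": [cfg.kinetics.km_low, cfg.kinetics.km_high],
                "phd_rate_drop_pct_min": drop_min,
                "phd_rate_drop_pct_max": drop_max,
            }
        )
    else:
        kin_payload["skipped"] = "no hypoxic days called"
    written["kinetics"] = out / "kinetics.json"
    _write_json(written["kinetics"], kin_payload)

    written["manifest"] = out / "manifest.json"
    _write_json(written["manifest"], manifest)
    return written


def _paired_score(behavior_by_mouse, call):
    from .timecourse import pair_score

    return pair_score(behavior_by_mouse.get(call.mouse_id, ()), call.day)
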