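"""CSV readers/writers and packaged summary-table fixtures.

Sessions travel in long format (one row per PO2 sample)::

    mouse_id,group,region,day,sample_index,po2_mmhg

and behavior scores in a separate file::

    mouse_id,day,score

The two published per-mouse summary tables (cerebellar and cortical EAE
cohorts) ship inside the package as CSV and load as ``MouseSummary``
rows.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model import (
    Group,
    MouseRecord,
    MouseSummary,
    PO2Session,
    Region,
    StudyDataset,
    _is_half_step,
)

SESSION_COLUMNS = ["mouse_id", "group", "region", "day", "sample_index", "po2_mmhg"]
BEHAVIOR_COLUMNS = ["mouse_id", "day", "score"]

FIXTURE_NAMES = ("cerebellum_table1", "cortex_table2")

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def read_study(sessions_path: PathLike, behavior_path: PathLike | None = None) -> StudyDataset:
    """Load a study from long-format sessions CSV plus behavior CSV.

    Raises ``ValueError`` on schema problems: missing columns, empty
    file, non-numeric PO2, duplicate (mouse, day, sample_index), or
    behavior scores off the 0–15 half-point grid.
    """
    # round_trip parsing: shortest-repr floats must come back bit-identical
    sess = pd.read_csv(sessions_path, float_precision="round_trip")
    _require_columns(sess, SESSION_COLUMNS, "sessions CSV")
    if len(sess) == 0:
        raise ValueError("sessions CSV: no sessions")

    po2 = pd.to_numeric(sess["po2_mmhg"], errors="coerce")
    if po2.isna().any():
        bad = sess.loc[po2.isna()].iloc[0]
        raise ValueError(
            f"sessions CSV: non-numeric PO2 for mouse {bad['mouse_id']} "
            f"day {bad['day']} sample {bad['sample_index']}"
        )
    sess = sess.assign(po2_mmhg=po2)
    if sess.duplicated(subset=["mouse_id", "day", "sample_index"]).any():
        bad = sess.loc[
            sess.duplicated(subset=["mouse_id", "day", "sample_index"])
        ].iloc[0]
        raise ValueError(
            f"sessions CSV: duplicate (mouse, day, sample index) = "
            f"({bad['mouse_id']}, {bad['day']}, {bad['sample_index']})"
        )

    regions = set(sess["region"].astype(str))
    if len(regions) != 1:
        raise ValueError(f"sessions CSV: expected a single region, got {sorted(regions)}")
    region = Region(regions.pop())

    behavior_by_mouse: dict[str, list[tuple[int, float]]] = {}
    if behavior_path is not None:
        beh = pd.read_csv(behavior_path)
        _require_columns(beh, BEHAVIOR_COLUMNS, "behavior CSV")
        for row in beh.itertuples(index=False):
            score = float(row.score)
            if not (0.0 <= score <= 15.0) or not _is_half_step(score):
                raise ValueError(
                    f"behavior CSV: score {score} for mouse {row.mouse_id} "
                    f"day {row.day} outside [0, 15] or not a 0.5 multiple"
                )
            behavior_by_mouse.setdefault(str(row.mouse_id), []).append(
                (int(row.day), score)
            )

    mice: list[MouseRecord] = []
    for (mouse_id, group), mdf in sess.groupby(["mouse_id", "group"], sort=True):
        sessions = []
        for day, ddf in mdf.groupby("day", sort=True):
            ddf = ddf.sort_values("sample_index")
            sessions.append(
                PO2Session(
                    mouse_id=str(mouse_id),
                    day=int(day),
                    samples=ddf["po2_mmhg"].to_numpy(),
                )
            )
        mice.append(
            MouseRecord(
                mouse_id=str(mouse_id),
                group=Group(str(group)),
                region=region,
                sessions=sessions,
                behavior=behavior_by_mouse.pop(str(mouse_id), []),
            )
        )
    if behavior_by_mouse:
        raise ValueError(
            "behavior CSV: scores for mice absent from sessions CSV: "
            f"{sorted(behavior_by_mouse)}"
        )
    return StudyDataset(mice=mice, region=region)


def write_study(
    dataset: StudyDataset, sessions_path: PathLike, behavior_path: PathLike
) -> tuple[Path, Path]:
    """Write a dataset to the two CSVs; inverse of :func:`read_study`.

    Floats are written at full (shortest-repr) precision so the
    read/write round trip is lossless.
    """
    srows = []
    brows = []
    for mouse in dataset.mice:
        for s in mouse.sessions:
            for i, v in enumerate(s.samples):
                srows.append(
                    (
                        mouse.mouse_id,
                        mouse.group.value,
                        mouse.region.value,
                        s.day,
                        i,
                        repr(float(v)),
                    )
                )
        for day, score in mouse.behavior:
            brows.append((mouse.mouse_id, day, score))
    sessions_path, behavior_path = Path(sessions_path), Path(behavior_path)
    pd.DataFrame(srows, columns=SESSION_COLUMNS).to_csv(sessions_path, index=False)
    pd.DataFrame(brows, columns=BEHAVIOR_COLUMNS).to_csv(behavior_path, index=False)
    return sessions_path, behavior_path


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(v)


def load_summary_fixture(name: str) -> list[MouseSummary]:
    """Load a packaged per-mouse summary table verbatim.

    ``name`` is ``"cerebellum_table1"`` (8 cerebellar EAE mice) or
    ``"cortex_table2"`` (16 cortical EAE mice).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    with resources.files("eaeox.data").joinpath(f"{name}.csv").open("r") as fh:
        df = pd.read_csv(fh)
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            MouseSummary(
                mouse_id=str(r.mouse_id),
                n_hypoxic_days=int(r.n_hypoxic_days),
                n_hyperoxic_days=int(r.n_hyperoxic_days),
                mean_delta_hypoxic=_opt_float(r.mean_delta_hypoxic),
                sd_delta_hypoxic=_opt_float(r.sd_delta_hypoxic),
                mean_delta_hyperoxic=_opt_float(r.mean_delta_hyperoxic),
                sd_delta_hyperoxic=_opt_float(r.sd_delta_hyperoxic),
                day_largest_abs_delta=_opt_int(r.day_largest_abs_delta),
                peak_behavior=float(r.peak_behavior),
                day_peak_behavior=_opt_int(r.day_peak_behavior),
            )
        )
    return rows


def summaries_to_frame(summaries: list[MouseSummary]) -> pd.DataFrame:
    """Tabulate ``MouseSummary`` rows (None → NaN) for CSV export."""
    return pd.DataFrame(
        [
            {
                "mouse_id": s.mouse_id,
                "n_hypoxic_days": s.n_hypoxic_days,
                "n_hyperoxic_days": s.n_hyperoxic_days,
                "mean_delta_hypoxic": np.nan if s.mean_delta_hypoxic is None else s.mean_delta_hypoxic,
                "sd_delta_hypoxic": np.nan if s.sd_delta_hypoxic is None else s.sd_delta_hypoxic,
                "mean_delta_hyperoxic": np.nan if s.mean_delta_hyperoxic is None else s.mean_delta_hyperoxic,
                "sd_delta_hyperoxic": np.nan if s.sd_delta_hyperoxic is None else s.sd_delta_hyperoxic,
                "day_largest_abs_delta": np.nan if s.day_largest_abs_delta is None else s.day_largest_abs_delta,
                "peak_behavior": s.peak_behavior,
                "day_peak_behavior": np.nan if s.day_peak_behavior is None else s.day_peak_behavior,
            }
            for s in summaries
        ]
    )
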