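"""Session statistics, baseline-normalized ΔPO2, and PHD oxygen kinetics.

The kinetics half converts tissue PO2 (mmHg) to dissolved-O2
concentration (μM) with a linear solubility coefficient and evaluates
how much a PO2 decline slows prolyl hydroxylase (PHD), the cell's
oxygen sensor, through the Michaelis–Menten law v/Vmax = c/(Km + c).
Reported Km values for PHD1–3 span 85–240 μM, far above brain-tissue
dissolved O2 (~30–45 μM), so PHD flux sits on the steep part of the
curve and small PO2 drops translate into sizeable rate drops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import MouseRecord, PO2Session

#: Default O2 solubility in brain tissue at 37 °C, μM per mmHg.
DEFAULT_ALPHA_UM_PER_MMHG = 1.39


@dataclass(frozen=True)
class KineticsParams:
    """PHD Michaelis–Menten parameters.

    ``vmax`` is normalized to 1; it cancels in every rate ratio the
    package computes. ``km_low``/``km_high`` bracket the published
    PHD1–3 Km range (μM).
    """

    alpha_solubility: float = DEFAULT_ALPHA_UM_PER_MMHG
    km_low: float = 85.0
    km_high: float = 240.0
    vmax: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha_solubility > 0 and self.vmax > 0):
            raise ValueError("alpha_solubility and vmax must be positive")
        if not (0 < self.km_low <= self.km_high):
            raise ValueError("require 0 < km_low <= km_high")


def session_stats(session: PO2Session) -> tuple[float, float]:
    """Mean and sample standard deviation (n−1) of one session's trace."""
    x = session.samples
    if x.size < 2:
        raise ValueError(
            f"session {session.mouse_id} day {session.day}: need >=2 samples "
            "for descriptive statistics"
        )
    return float(np.mean(x)), float(np.std(x, ddof=1))


def compute_baseline(mouse: MouseRecord) -> float:
    """Pre-induction baseline PO2: grand mean over all baseline samples.

    Pools every sample from every session with day < 0 (the average of
    the days before induction). Equals the mean of session means when
    sessions have equal length, and stays well-defined when they do
    not.
    """
    base = mouse.baseline_sessions
    if not base:
        raise ValueError(f"{mouse.mouse_id}: no pre-induction sessions")
    if len(base) == 1:
        warnings.warn(
            f"{mouse.mouse_id}: baseline from a single pre-induction session",
            stacklevel=2,
        )
    return float(np.mean(np.concatenate([s.samples for s in base])))


def delta_series(session: PO2Session, baseline: float) -> np.ndarray:
    """ΔPO2 samples: the session trace minus the animal's own baseline."""
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    return session.samples - float(baseline)


def po2_to_concentration(
    po2_mmhg: float | np.ndarray, params: KineticsParams | None = None
) -> float | np.ndarray:
    """Dissolved O2 concentration (μM) from partial pressure (mmHg)."""
    params = params or KineticsParams()
    arr = np.asarray(po2_mmhg, dtype=float)
    if np.any(arr < 0):
        raise ValueError("PO2 must be >= 0")
    out = params.alpha_solubility * arr
    return float(out) if np.isscalar(po2_mmhg) else out


def phd_relative_rate(conc_um: float, km_um: float) -> float:
    """Michaelis–Menten fractional rate v/Vmax = c/(Km + c), in [0, 1)."""
    if km_um <= 0:
        raise ValueError("Km must be positive")
    if conc_um < 0:
        raise ValueError("concentration must be >= 0")
    return conc_um / (km_um + conc_um)


def phd_rate_drop(
    c1_um: float, c2_um: float, params: KineticsParams | None = None
) -> tuple[float, float]:
    """Percent drop in PHD initial rate when O2 falls from c1 to c2.

    Evaluates 100·(1 − rate(c2)/rate(c1)) at ``km_low`` and ``km_high``
    and returns (smaller, larger). The drop is monotone increasing in
    Km (as Km → ∞ it tends to the first-order limit 100·(1 − c2/c1)),
    so the two Km endpoints bound the drop over the whole Km range.
    """
    params = params or KineticsParams()
    if c1_um <= 0:
        raise ValueError("initial concentration c1 must be > 0")
    if c2_um < 0:
        raise ValueError("final concentration c2 must be >= 0")
    drops = [
        100.0 * (1.0 - phd_relative_rate(c2_um, km) / phd_relative_rate(c1_um, km))
        for km in (params.km_low, params.km_high)
    ]
    return min(drops), max(drops)
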