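"""Behavioral and structural covariates: median RT, sRT slope, d_L, nWBV."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import LOADS, TrialEvent


@dataclass
class BehaviorSummary:
    """Per-subject behavioral measures across memory loads."""

    median_rt: dict[int, float]
    srt: float
    d_l: dict[int, float]


@dataclass
class TissueVolumes:
    gm_mm3: float
    wm_mm3: float
    csf_mm3: float

    @property
    def nwbv(self) -> float:
        return nwbv(self.gm_mm3, self.wm_mm3, self.csf_mm3)


def median_rt(trials: list[TrialEvent], load: int) -> float:
    """Median RT over correct, responded trials at one load; NaN if none."""
    rts = [
        t.rt_s for t in trials
        if t.load == load and t.correct and not t.timeout and t.rt_s is not None
    ]
    if not rts:
        return float("nan")
    return float(np.median(rts))


def srt_slope(medians: dict[int, float] | list[float]) -> float:
    """OLS slope of median RT against memory load (1, 3, 6), s per letter."""
    if isinstance(medians, dict):
        y = np.array([medians.get(l, np.nan) for l in LOADS], dtype=float)
    else:
        y = np.asarray(medians, dtype=float)
    if len(y) != 3 or not np.isfinite(y).all():
        return float("nan")
    x = np.array(LOADS, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def d_l(hits: int, misses: int, false_alarms: int, correct_rejections: int) -> float:
    """Logistic discrimination index, independent of response bias.

    d_L = ln{ [H (1 - FA)] / [(1 - H) FA] } with the log-linear correction
    H = (hits + 0.5) / (hits + misses + 1), FA = (fa + 0.5) / (fa + cr + 1),
    which keeps the index finite for perfect scores.
    """
    if hits + misses < 1 or false_alarms + correct_rejections < 1:
        raise ValueError("need at least one target and one lure trial")
    H = (hits + 0.5) / (hits + misses + 1.0)
    FA = (false_alarms + 0.5) / (false_alarms + correct_rejections + 1.0)
    return math.log((H * (1.0 - FA)) / ((1.0 - H) * FA))


def nwbv(gm_mm3: float, wm_mm3: float, csf_mm3: float) -> float:
    """Normalized whole brain volume: (GM + WM) / (GM + WM + CSF).

    The fraction of intracranial volume occupied by brain tissue; a global
    atrophy proxy that falls with advancing age.
    """
    if gm_mm3 <= 0 or wm_mm3 <= 0 or csf_mm3 <= 0:
        raise ValueError("all tissue volumes must be positive")
    return (gm_mm3 + wm_mm3) / (gm_mm3 + wm_mm3 + csf_mm3)


def summarize_behavior(
    trials: list[TrialEvent], match: dict[int, np.ndarray] | None = None
) -> BehaviorSummary:
    """Median RT per load, the sRT slope, and d_L per load.

    ``match`` optionally gives, per load, a boolean array aligned with that
    load's trials marking match (target-present) probes; without it d_L is
    computed treating correct responses on match trials as hits and errors
    on non-match trials as false alarms, using an alternating assignment
    when match status is unavailable.
    """
    medians = {l: median_rt(trials, l) for l in LOADS}
    dls: dict[int, float] = {}
    for l in LOADS:
        sub = [t for t in trials if t.load == l]
        if match is not None and l in match:
            is_match = np.asarray(match[l], dtype=bool)
        else:
            is_match = np.arange(len(sub)) % 2 == 0
        hits = sum(1 for t, m in zip(sub, is_match) if m and t.correct)
        misses = sum(1 for t, m in zip(sub, is_match) if m and not t.correct)
        fas = sum(1 for t, m in zip(sub, is_match) if not m and not t.correct)
        crs = sum(1 for t, m in zip(sub, is_match) if not m and t.correct)
        dls[l] = d_l(hits, misses, fas, crs) if (hits + misses) and (fas + crs) else float("nan")
    return BehaviorSummary(median_rt=medians, srt=srt_slope(medians), d_l=dls)


def covariate_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble the subject-level covariate table written by the pipeline."""
    return pd.DataFrame(rows)
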