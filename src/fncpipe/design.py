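"""Task design: events, canonical HRF, convolved design matrix, contrasts.

The experiment is a verbal delayed item recognition (DIR) task. Each trial
presents a set of 1, 3 or 6 letters (stimulus, 3 s), holds them in working
memory (retention, 7 s) and probes recognition with a single letter
(probe, lasting until the subject's response, up to a 3 s window).
Crossing memory load {1, 3, 6} with task phase {stimulus, retention, probe}
yields nine regressors of interest; error/timeout trials are modelled by a
single separate nuisance regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOADS = (1, 3, 6)
PHASES = ("stimulus", "retention", "probe")

STIM_DUR_S = 3.0
RETENTION_DUR_S = 7.0
RESPONSE_WINDOW_S = 3.0

#: support of the canonical double-gamma HRF, seconds
HRF_LENGTH_S = 32.0

#: default microtime bins per TR for boxcar construction
DEFAULT_MICROTIME = 16


@dataclass(frozen=True)
class TrialEvent:
    """One DIR trial.

    ``rt_s`` is None for timeout trials (no response within the 3 s window).
    ``probe_onset_s`` is always onset + stimulus + retention duration.
    """

    onset_s: float
    load: int
    rt_s: float | None
    correct: bool
    timeout: bool = False
    stim_dur_s: float = STIM_DUR_S
    retention_dur_s: float = RETENTION_DUR_S

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.load not in LOADS:
            raise ValueError(f"load must be one of {LOADS}, got {self.load}")
        if self.timeout and self.rt_s is not None:
            raise ValueError("timeout trials carry no RT")
        if self.rt_s is not None and not 0 < self.rt_s <= RESPONSE_WINDOW_S:
            raise ValueError(
                f"rt_s must lie in (0, {RESPONSE_WINDOW_S}], got {self.rt_s}"
            )

    @property
    def probe_onset_s(self) -> float:
        return self.onset_s + self.stim_dur_s + self.retention_dur_s

    @property
    def probe_dur_s(self) -> float:
        """Probe epoch length: the trial's RT, or the full window on timeout."""
        if self.rt_s is None:
            return RESPONSE_WINDOW_S
        return self.rt_s

    @property
    def end_s(self) -> float:
        return self.probe_onset_s + self.probe_dur_s


def task_regressor_names() -> list[str]:
    """The nine load-by-phase regressors, phase-major order."""
    return [f"{phase}_load{load}" for phase in PHASES for load in LOADS]


@dataclass(frozen=True)
class HRFKernel:
    """Double-gamma HRF sampled on a regular grid starting at t = 0."""

    dt_s: float
    samples: np.ndarray

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_s

    @property
    def peak_time_s(self) -> float:
        return float(np.argmax(self.samples) * self.dt_s)


def canonical_hrf(dt_s: float) -> HRFKernel:
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities: a response gamma (shape 6, scale 1)
    peaking near 5 s and an undershoot gamma (shape 16, scale 1) weighted
    1/6, evaluated on ``[0, 32]`` s and scaled to unit peak.

    Parameters
    ----------
    dt_s:
        Sampling interval in seconds, 0 < dt_s <= 3.0.
    """
    if not 0 < dt_s <= 3.0:
        raise ValueError(f"dt_s must lie in (0, 3.0], got {dt_s}")
    from scipy import stats

    t = np.arange(0.0, HRF_LENGTH_S + dt_s / 2, dt_s)
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(
        t, a=16.0, scale=1.0
    ) / 6.0
    h = h / h.max()
    return HRFKernel(dt_s=dt_s, samples=h)


@dataclass
class DesignMatrix:
    """Scans-by-regressors convolved design with named contrasts.

    The first nine columns are the task regressors of interest
    (phase-major load-by-phase grid), followed by one error/timeout
    regressor and one intercept per run.
    """

    matrix: np.ndarray
    regressor_names: list[str]
    TR_s: float
    run_lengths: list[int]
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_task_regressors(self) -> int:
        return len(task_regressor_names())

    @property
    def task_columns(self) -> np.ndarray:
        return self.matrix[:, : self.n_task_regressors]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.regressor_names)


def events_from_frame(frame: pd.DataFrame) -> list[list[TrialEvent]]:
    """Parse a trial table (one row per trial) into per-run event lists.

    Expected columns: onset_s, load, rt_s (empty/NaN for timeouts),
    correct, timeout, run. Runs are ordered by their sorted labels.
    """
    runs = []
    for _, sub in frame.groupby("run", sort=True):
        events = []
        for row in sub.itertuples():
            rt = None if pd.isna(row.rt_s) else float(row.rt_s)
            events.append(
                TrialEvent(
                    onset_s=float(row.onset_s),
                    load=int(row.load),
                    rt_s=rt,
                    correct=bool(row.correct),
                    timeout=bool(row.timeout),
                )
            )
        runs.append(events)
    return runs


def _epochs_for_event(ev: TrialEvent) -> list[tuple[str, float, float]]:
    """(column label, onset, duration) triples for one trial.

    Correct trials load their three phases onto the load-by-phase grid;
    error and timeout trials put all three phases on the error regressor.
    """
    phases = [
        (f"stimulus_load{ev.load}", ev.onset_s, ev.stim_dur_s),
        (f"retention_load{ev.load}", ev.onset_s + ev.stim_dur_s, ev.retention_dur_s),
        (f"probe_load{ev.load}", ev.probe_onset_s, ev.probe_dur_s),
    ]
    if ev.correct and not ev.timeout:
        return phases
    return [("error", onset, dur) for _, onset, dur in phases]


def _convolve_run(
    events: list[TrialEvent],
    n_scans: int,
    TR_s: float,
    hrf: HRFKernel,
    microtime: int,
) -> np.ndarray:
    """Boxcars on the microtime grid, convolved with the HRF, sampled at scans."""
    dt = TR_s / microtime
    n_fine = n_scans * microtime
    names = task_regressor_names() + ["error"]
    col_index = {name: i for i, name in enumerate(names)}
    box = np.zeros((n_fine, len(names)))
    for ev in events:
        if ev.end_s > n_scans * TR_s:
            raise ValueError(
                f"event at {ev.onset_s:.1f}s extends past run end "
                f"({n_scans * TR_s:.1f}s)"
            )
        for name, onset, dur in _epochs_for_event(ev):
            i0 = int(round(onset / dt))
            i1 = int(round((onset + dur) / dt))
            box[i0:i1, col_index[name]] = 1.0
    # HRF resampled onto the microtime grid by pointwise evaluation
    kernel = canonical_hrf(dt).samples if abs(hrf.dt_s - dt) > 1e-12 else hrf.samples
    cols = np.empty((n_scans, len(names)))
    for j in range(len(names)):
        conv = np.convolve(box[:, j], kernel)[:n_fine]
        cols[:, j] = conv[::microtime]
    return cols


def build_design_matrix(
    runs: list[list[TrialEvent]],
    n_scans: int,
    TR_s: float,
    hrf: HRFKernel | None = None,
    microtime: int = DEFAULT_MICROTIME,
) -> DesignMatrix:
    """Convolved design matrix over one or more runs.

    Task columns are mean-centered within each run so the per-run
    intercepts absorb baseline; the error regressor and intercepts are
    nuisance columns carrying zero contrast weight.

    Parameters
    ----------
    runs:
        Event lists, one per run, in acquisition order. A single flat list
        of events is treated as one run.
    n_scans:
        Scans per run (each run has the same length).
    TR_s:
        Repetition time in seconds.
    hrf:
        HRF kernel; defaults to the canonical double-gamma evaluated on
        the microtime grid.
    microtime:
        Boxcar grid resolution, bins per TR (>= 1).
    """
    if microtime < 1:
        raise ValueError("microtime must be >= 1")
    if runs and isinstance(runs[0], TrialEvent):
        runs = [runs]  # type: ignore[list-item]
    n_runs = max(len(runs), 1)
    runs = list(runs) or [[]]
    if hrf is None:
        hrf = canonical_hrf(TR_s / microtime)

    task_names = task_regressor_names()
    names = task_names + ["error"] + [f"intercept_run{r}" for r in range(n_runs)]
    n_task = len(task_names)
    mat = np.zeros((n_scans * n_runs, len(names)))
    for r, events in enumerate(runs):
        sl = slice(r * n_scans, (r + 1) * n_scans)
        cols = _convolve_run(events, n_scans, TR_s, hrf, microtime)
        cols[:, :n_task] -= cols[:, :n_task].mean(axis=0)
        mat[sl, : n_task + 1] = cols
        mat[sl, n_task + 1 + r] = 1.0

    dm = DesignMatrix(
        matrix=mat,
        regressor_names=names,
        TR_s=TR_s,
        run_lengths=[n_scans] * n_runs,
    )
    dm.contrasts = contrasts_of_interest(names)
    return dm


def contrasts_of_interest(
    regressor_names: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Six contrasts: load-dependent and load-independent per task phase.

    Load-dependent weights are the centered load values (1, 3, 6 minus
    their mean: -7/3, -1/3, 8/3) scaled to unit norm — a linear-in-load
    "slope" coding. Load-independent weights average the three loads
    (1/3 each). Nuisance columns get zero weight.
    """
    if regressor_names is None:
        regressor_names = task_regressor_names()
    loads = np.array(LOADS, dtype=float)
    dep = loads - loads.mean()
    dep = dep / np.linalg.norm(dep)
    indep = np.full(3, 1.0 / 3.0)

    contrasts: dict[str, np.ndarray] = {}
    for kind, weights in (("load_dependent", dep), ("load_independent", indep)):
        for phase in PHASES:
            w = np.zeros(len(regressor_names))
            for load, wt in zip(LOADS, weights):
                w[regressor_names.index(f"{phase}_load{load}")] = wt
            contrasts[f"{kind}_{phase}"] = w
    return contrasts
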