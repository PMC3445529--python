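"""Synthetic delayed-item-recognition fMRI study with known ground truth.

Generates everything the pipeline consumes — 4D runs, a brain mask, trial
event tables, demographics, tissue volumes — from a parametric model whose
every downstream estimate is known:

* spatially compact, low-overlap source maps (super-Gaussian spatial
  amplitude distributions, so infomax separation is well-posed);
* per-subject component time courses carrying task-locked signal plus
  residuals with group-specific between-source correlations (the planted
  FNC structure; headline edges follow the young/old group means of the
  study this generator emulates: r = 0.514 vs 0.059 and 0.448 vs 0.113);
* response times whose load slope (sRT) is partially transmitted through
  one planted FNC edge (the age -> FNC -> performance mediation), and
* tissue volumes that differ by age group but are conditionally
  independent of FNC given group (so the age -> volume -> FNC path
  carries no indirect effect).

Run length vs trial count: a 69-scan run at TR 3 s lasts 207 s, which
holds nine ~21 s trials (3 s stimulus + 7 s retention + up to 3 s probe +
jittered ITI). The generator therefore defaults to 3 trials per load per
run; the emulated study's 10-per-load count is available by lengthening
``scans_per_run``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import LOADS, RESPONSE_WINDOW_S, RETENTION_DUR_S, STIM_DUR_S, TrialEvent
from .fnc import fisher_z, inverse_fisher_z

#: headline planted edges (source index pairs) and their group-mean r
PLANTED_EDGES = {
    (0, 1): {"young": 0.514, "old": 0.059},  # SMA/mid-cingulate analogue
    (2, 3): {"young": 0.448, "old": 0.113},  # precuneus/frontal analogue
}
BACKGROUND_R = {"young": 0.25, "old": 0.10}

#: RT model fit to the emulated study's per-load group medians
RT_MODEL = {
    "young": {"intercept": 0.824, "slope": 0.0597},
    "old": {"intercept": 0.814, "slope": 0.0897},
}
#: FNC-edge -> sRT coupling, s per letter per unit Fisher z (negative:
#: weaker connectivity -> steeper RT/load slope)
EDGE_COUPLING = -0.04
SLOPE_NOISE_SD = 0.018
RT_TRIAL_NOISE_SD = 0.18
Z_BETWEEN_SD = 0.25  # between-subject sd of a planted edge's Fisher z

HIT_RATE = 0.78
FA_RATE = 0.22
TIMEOUT_RATE = 0.01

VOLUME_MODEL = {
    "young": {"gm": 700e3, "wm": 500e3, "csf": 150e3},
    "old": {"gm": 620e3, "wm": 470e3, "csf": 260e3},
    "lognorm_sigma": 0.05,
}


@dataclass
class SynthConfig:
    """Study-level parameters; defaults emulate the target study's design."""

    n_young: int = 75
    n_old: int = 37
    runs: int = 3
    scans_per_run: int = 69
    TR_s: float = 3.0
    grid: tuple[int, int, int] = (12, 12, 12)
    mask_radius: float = 5.5
    n_sources: int = 6
    trials_per_load_per_run: int = 3
    task_amplitude: float = 0.2
    noise_sd: float = 1.0
    edge_coupling: float = EDGE_COUPLING
    slope_noise_sd: float = SLOPE_NOISE_SD
    z_between_sd: float = Z_BETWEEN_SD
    blob_sigma: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_young, self.n_old) < 3:
            raise ValueError("need at least 3 subjects per group")

    def fnc_matrix(self, group: str) -> np.ndarray:
        """Group-level between-source correlation target (unit diagonal, PD)."""
        k = self.n_sources
        R = np.full((k, k), BACKGROUND_R[group])
        np.fill_diagonal(R, 1.0)
        for (i, j), means in PLANTED_EDGES.items():
            if i < k and j < k:
                R[i, j] = R[j, i] = means[group]
        return _nearest_pd(R)

    @classmethod
    def reduced(cls, n_young: int = 12, n_old: int = 12, **kw) -> "SynthConfig":
        """Scaled-down benchmark study sized for reliable recovery.

        The edge->sRT coupling is inflated by sqrt(n_full / n_reduced),
        which preserves the mediator->outcome noncentrality of the
        full-size design, times a 1.3 detectability margin: the full-size
        coupling is deliberately marginal (the emulated study's indirect
        effect was itself borderline-significant), whereas a reduced smoke
        study must detect the planted mediation reliably to be informative
        about pipeline correctness rather than about borderline power.
        """
        full = cls.n_young + cls.n_old
        scale = 1.3 * np.sqrt(full / (n_young + n_old))
        kw.setdefault("grid", (10, 10, 10))
        kw.setdefault("mask_radius", 4.5)
        kw.setdefault("blob_sigma", 1.0)  # narrower blobs on the small grid
        kw.setdefault("edge_coupling", EDGE_COUPLING * scale)
        return cls(n_young=n_young, n_old=n_old, **kw)


def _nearest_pd(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues below ``floor`` and restore the unit diagonal."""
    evals, evecs = np.linalg.eigh(R)
    if evals.min() >= floor:
        return R
    evals = np.clip(evals, floor, None)
    R = evecs @ np.diag(evals) @ evecs.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def ball_mask(grid: tuple[int, int, int], radius: float) -> np.ndarray:
    """Boolean spherical mask centered on the grid."""
    coords = np.indices(grid, dtype=float)
    center = (np.array(grid) - 1.0) / 2.0
    dist2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
    return dist2 <= radius**2


# ---------------------------------------------------------------------------
# sources


def make_sources(cfg: SynthConfig, rng: np.random.Generator | None = None):
    """Compact Gaussian blobs inside the mask with low pairwise overlap.

    Returns (maps, mask): maps is n_sources x n_mask_voxels with unit
    variance rows and max pairwise |spatial correlation| < 0.2.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    from scipy.ndimage import binary_erosion

    mask = ball_mask(cfg.grid, cfg.mask_radius)
    vox_all = np.argwhere(mask).astype(float)
    n_vox = len(vox_all)
    if cfg.n_sources > n_vox / 20:
        raise ValueError(
            f"cannot pack {cfg.n_sources} sources into {n_vox} mask voxels"
        )
    # centers stay inside the eroded interior: brain-like sources do not
    # peak on the mask rim (the rim is where artifact components live)
    interior = binary_erosion(mask, iterations=1)
    vox = np.argwhere(interior if interior.any() else mask).astype(float)
    # farthest-point sampling packs the centers as far apart as the mask
    # allows; the blob width then shrinks (if needed) until overlap is low
    start = int(rng.integers(len(vox)))
    centers = [vox[start]]
    d2min = np.sum((vox - centers[0]) ** 2, axis=1)
    for _ in range(cfg.n_sources - 1):
        nxt = int(np.argmax(d2min))
        centers.append(vox[nxt])
        d2min = np.minimum(d2min, np.sum((vox - vox[nxt]) ** 2, axis=1))
    sigma = cfg.blob_sigma
    for _shrink in range(6):
        maps = np.empty((cfg.n_sources, n_vox))
        for s, c in enumerate(centers):
            d2 = np.sum((vox_all - c) ** 2, axis=1)
            maps[s] = np.exp(-d2 / (2.0 * sigma**2))
        # unit variance without spatial centering: disjoint positive blobs
        # are then near-orthogonal in the raw inner product the
        # PCA/ICA chain uses, avoiding cross-talk in back-reconstruction
        maps = maps / maps.std(axis=1, keepdims=True)
        cc = np.corrcoef(maps)
        if np.max(np.abs(cc - np.eye(cfg.n_sources))) < 0.2:
            return maps, mask
        sigma *= 0.85
    raise ValueError("infeasible packing: could not place low-overlap sources")


def default_task_betas(n_sources: int, rng: np.random.Generator) -> np.ndarray:
    """Per-source loadings on the 9 task regressors (phase-major grid).

    Each source prefers one phase with a linear load profile whose sign
    alternates (task-positive vs task-deactivating components), mimicking
    the mixture of load-dependent activations and deactivations seen in
    working-memory data. Laplace jitter keeps loadings super-Gaussian.
    """
    base = np.zeros((n_sources, 9))
    loads = np.array(LOADS, dtype=float)
    profile = loads / np.linalg.norm(loads)
    for s in range(n_sources):
        phase = s % 3
        sign = 1.0 if (s // 3) % 2 == 0 else -1.0
        base[s, phase * 3 : phase * 3 + 3] = sign * profile
    base += 0.15 * rng.laplace(size=base.shape)
    return base


# ---------------------------------------------------------------------------
# per-subject simulation


def subject_edge_z(cfg: SynthConfig, group: str, rng: np.random.Generator) -> dict:
    """Per-subject target Fisher z on each planted edge (group mean + jitter)."""
    out = {}
    for edge, means in PLANTED_EDGES.items():
        if max(edge) < cfg.n_sources:
            out[edge] = float(
                fisher_z(means[group]) + cfg.z_between_sd * rng.normal()
            )
    return out


def subject_fnc_target(cfg: SynthConfig, group: str, edge_z: dict) -> np.ndarray:
    """Subject-level correlation target: group matrix with jittered edges."""
    R = cfg.fnc_matrix(group).copy()
    for (i, j), z in edge_z.items():
        R[i, j] = R[j, i] = float(inverse_fisher_z(z))
    return _nearest_pd(R)


def sample_timecourses(
    cfg: SynthConfig,
    task_design: np.ndarray,
    task_betas: np.ndarray,
    R_target: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Component time courses: task signal plus correlated residual noise.

    ``tc = s + eps @ L.T`` where ``s`` is the task signal ``E @ betas.T``
    (E the scans x 9 convolved task design) rescaled so each source's
    task-locked sd equals ``cfg.task_amplitude``, and L factors the
    residual covariance chosen so that the *total* time-course
    correlations converge to the planted target as scans grow: the
    residual target compensates for the covariance the shared task signal
    introduces between sources. With ``task_betas = 0`` the residual
    target is exactly ``R_target``.
    """
    evals = np.linalg.eigvalsh(R_target)
    if evals.min() <= 0:
        raise ValueError("target correlation matrix is not positive definite")
    n_scans = task_design.shape[0]
    signal = task_design @ task_betas.T
    sd = signal.std(axis=0)
    scale = np.where(sd > 0, cfg.task_amplitude / np.where(sd > 0, sd, 1.0), 0.0)
    signal = signal * scale
    sig_c = signal - signal.mean(axis=0, keepdims=True)
    cov_sig = sig_c.T @ sig_c / n_scans
    v = np.diag(cov_sig)  # task-locked variance per source
    total_sd = np.sqrt(1.0 + v)
    R_resid = R_target * np.outer(total_sd, total_sd) - cov_sig
    np.fill_diagonal(R_resid, 1.0)
    R_resid = _nearest_pd(R_resid)
    L = np.linalg.cholesky(R_resid)
    eps = rng.standard_normal((n_scans, cfg.n_sources))
    return signal + eps @ L.T


def mix_and_noise(
    sources: np.ndarray, tcs: np.ndarray, noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Voxel data (scans x voxels) = tcs @ sources + Gaussian noise."""
    data = tcs @ sources
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return data


def simulate_events(
    cfg: SynthConfig,
    group: str,
    slope_subject: float,
    rng: np.random.Generator,
) -> tuple[list[list[TrialEvent]], list[dict]]:
    """Per-run trial events with RTs from the subject's load-slope model.

    RT = intercept_group + slope_subject * load + trial noise, truncated
    to (0, 3]; accuracy from hit/false-alarm rates on alternating
    match/non-match probes; rare timeouts carry no RT.
    """
    intercept = RT_MODEL[group]["intercept"]
    run_dur = cfg.scans_per_run * cfg.TR_s
    runs: list[list[TrialEvent]] = []
    match_info: list[dict] = []
    for _run in range(cfg.runs):
        loads = np.repeat(LOADS, cfg.trials_per_load_per_run)
        rng.shuffle(loads)
        n_trials = len(loads)
        trial_len = STIM_DUR_S + RETENTION_DUR_S + RESPONSE_WINDOW_S
        slack = run_dur - n_trials * trial_len - 6.0  # 6 s lead-out
        itis = rng.dirichlet(np.ones(n_trials)) * max(slack, 0.0)
        events, onset = [], 3.0
        match_flags = {l: [] for l in LOADS}
        per_load_count = {l: 0 for l in LOADS}
        for trial, load in enumerate(loads):
            is_match = per_load_count[load] % 2 == 0
            per_load_count[load] += 1
            timeout = rng.random() < TIMEOUT_RATE
            p_correct = HIT_RATE if is_match else 1.0 - FA_RATE
            correct = (not timeout) and (rng.random() < p_correct)
            rt = None
            if not timeout:
                rt = intercept + slope_subject * load + RT_TRIAL_NOISE_SD * rng.normal()
                rt = float(np.clip(rt, 0.05, RESPONSE_WINDOW_S))
            events.append(
                TrialEvent(
                    onset_s=float(onset), load=int(load), rt_s=rt,
                    correct=bool(correct), timeout=bool(timeout),
                )
            )
            match_flags[load].append(is_match)
            onset += trial_len + itis[trial]
        runs.append(events)
        match_info.append(match_flags)
    return runs, match_info


def simulate_volumes(cfg: SynthConfig, group: str, rng: np.random.Generator) -> dict:
    """Lognormal GM/WM/CSF volumes with group-specific means.

    Old-group normalized whole brain volume is lower by construction, and
    volumes are drawn independently of the planted FNC within group (the
    volume path carries no indirect effect).
    """
    means = VOLUME_MODEL[group]
    sigma = VOLUME_MODEL["lognorm_sigma"]
    out = {}
    for tissue in ("gm", "wm", "csf"):
        mu = np.log(means[tissue]) - sigma**2 / 2.0
        out[tissue] = float(rng.lognormal(mean=mu, sigma=sigma))
    return out


# ---------------------------------------------------------------------------
# whole-study assembly


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    gender: str
    events: list[list[TrialEvent]]
    match_info: list[dict]
    runs: list[np.ndarray]  # scans x mask-voxels, per run
    true_timecourses: np.ndarray  # total scans x n_sources
    edge_z: dict
    true_slope: float
    volumes: dict


@dataclass
class GroundTruth:
    source_maps: np.ndarray
    mask: np.ndarray
    task_betas: np.ndarray
    fnc_young: np.ndarray
    fnc_old: np.ndarray
    rt_model: dict
    edge_coupling: float
    mediation_fig1a: dict  # planted a, b, c, c_prime for age->FNC->sRT
    mediation_fig1b: dict  # planted paths for age->nWBV->FNC (b = 0)
    subjects: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SyntheticStudy:
    config: SynthConfig
    subjects: list[SyntheticSubject]
    truth: GroundTruth

    @property
    def demographics(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"subject_id": s.subject_id, "group": s.group, "gender": s.gender}
                for s in self.subjects
            ]
        )


def _planted_mediation_paths(cfg: SynthConfig) -> tuple[dict, dict]:
    edge = next(iter(PLANTED_EDGES))
    z_young = float(fisher_z(PLANTED_EDGES[edge]["young"]))
    z_old = float(fisher_z(PLANTED_EDGES[edge]["old"]))
    a = z_old - z_young
    b = cfg.edge_coupling
    c = RT_MODEL["old"]["slope"] - RT_MODEL["young"]["slope"]
    fig1a = {"edge": list(edge), "a": a, "b": b, "c": c, "c_prime": c - a * b}
    v = VOLUME_MODEL
    nwbv_y = (v["young"]["gm"] + v["young"]["wm"]) / sum(v["young"].values())
    nwbv_o = (v["old"]["gm"] + v["old"]["wm"]) / sum(v["old"].values())
    fig1b = {
        "edge": list(edge),
        "a": nwbv_o - nwbv_y,  # age -> volume
        "b": 0.0,  # volume -> FNC given age: none planted
        "c": a,  # age -> FNC total
        "c_prime": a,
    }
    return fig1a, fig1b


def simulate_study(cfg: SynthConfig) -> SyntheticStudy:
    """Generate the full study in memory; reproducible from (cfg, seed)."""
    rng = np.random.default_rng(cfg.seed)
    maps, mask = make_sources(cfg, rng)
    task_betas = default_task_betas(cfg.n_sources, rng)

    # genders roughly follow the emulated study's ratios
    fig1a, fig1b = _planted_mediation_paths(cfg)
    mediation_edge = next(iter(PLANTED_EDGES))

    from .design import build_design_matrix

    subjects = []
    rows = []
    counts = [("young", cfg.n_young, 2 / 3), ("old", cfg.n_old, 15 / 37)]
    sid = 0
    for group, n_group, male_frac in counts:
        for _ in range(n_group):
            sid += 1
            subject_id = f"sub-{sid:03d}"
            gender = "M" if rng.random() < male_frac else "F"
            edge_z = subject_edge_z(cfg, group, rng)
            z_med = edge_z.get(mediation_edge, 0.0)
            group_mean_z = float(fisher_z(PLANTED_EDGES[mediation_edge][group]))
            slope = (
                RT_MODEL[group]["slope"]
                + cfg.edge_coupling * (z_med - group_mean_z)
                + cfg.slope_noise_sd * rng.normal()
            )
            events, match_info = simulate_events(cfg, group, slope, rng)
            R_subj = subject_fnc_target(cfg, group, edge_z)

            run_data, tc_all = [], []
            for run_events in events:
                dm = build_design_matrix(
                    [run_events], cfg.scans_per_run, cfg.TR_s, microtime=8
                )
                tc = sample_timecourses(
                    cfg, dm.task_columns, task_betas, R_subj, rng
                )
                run_data.append(mix_and_noise(maps, tc, cfg.noise_sd, rng))
                tc_all.append(tc)
            volumes = simulate_volumes(cfg, group, rng)
            subjects.append(
                SyntheticSubject(
                    subject_id=subject_id, group=group, gender=gender,
                    events=events, match_info=match_info, runs=run_data,
                    true_timecourses=np.vstack(tc_all),
                    edge_z=edge_z, true_slope=float(slope), volumes=volumes,
                )
            )
            rows.append(
                {
                    "subject_id": subject_id, "group": group, "gender": gender,
                    "true_slope": float(slope),
                    **{f"true_z_{i}_{j}": z for (i, j), z in edge_z.items()},
                    **{f"{t}_mm3": v for t, v in volumes.items()},
                }
            )

    truth = GroundTruth(
        source_maps=maps, mask=mask, task_betas=task_betas,
        fnc_young=cfg.fnc_matrix("young"), fnc_old=cfg.fnc_matrix("old"),
        rt_model=RT_MODEL, edge_coupling=cfg.edge_coupling,
        mediation_fig1a=fig1a, mediation_fig1b=fig1b,
        subjects=pd.DataFrame(rows),
    )
    return SyntheticStudy(config=cfg, subjects=subjects, truth=truth)


# ---------------------------------------------------------------------------
# file output


def events_frame(subject: SyntheticSubject) -> pd.DataFrame:
    rows = []
    for run_idx, run_events in enumerate(subject.events):
        for ev in run_events:
            rows.append(
                {
                    "onset_s": ev.onset_s, "load": ev.load,
                    "rt_s": np.nan if ev.rt_s is None else ev.rt_s,
                    "correct": int(ev.correct), "timeout": int(ev.timeout),
                    "run": run_idx,
                }
            )
    return pd.DataFrame(rows)


def generate_study(
    cfg: SynthConfig, outdir: str | Path, overwrite: bool = False
) -> SyntheticStudy:
    """Write the study tree: NIfTI runs, mask, event/participant tables.

    Layout: ``sub-XXX/run-R_bold.nii.gz``, ``sub-XXX/sub-XXX_events.tsv``,
    ``mask.nii.gz``, ``participants.tsv``, ``volumes.tsv`` and
    ``ground_truth.npz`` (+ ``ground_truth.json`` for scalars), all under
    one study root.
    """
    import nibabel as nib

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{outdir} exists and is not empty; pass overwrite=True"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    study = simulate_study(cfg)
    mask = study.truth.mask
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), outdir / "mask.nii.gz")

    mask_lin = np.flatnonzero(mask.ravel())
    vol_rows = []
    for s in study.subjects:
        sdir = outdir / s.subject_id
        sdir.mkdir(exist_ok=True)
        for r, data in enumerate(s.runs):
            img4d = np.zeros(cfg.grid + (data.shape[0],), dtype=np.float32)
            flat = img4d.reshape(-1, data.shape[0])
            flat[mask_lin] = data.T.astype(np.float32)
            nib.save(nib.Nifti1Image(img4d, affine), sdir / f"run-{r}_bold.nii.gz")
        events_frame(s).to_csv(sdir / f"{s.subject_id}_events.tsv",
                               sep="\t", index=False)
        vol_rows.append(
            {"subject_id": s.subject_id,
             "gm_mm3": s.volumes["gm"], "wm_mm3": s.volumes["wm"],
             "csf_mm3": s.volumes["csf"]}
        )
    study.demographics.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    pd.DataFrame(vol_rows).to_csv(outdir / "volumes.tsv", sep="\t", index=False)

    np.savez_compressed(
        outdir / "ground_truth.npz",
        source_maps=study.truth.source_maps,
        mask=mask.astype(np.uint8),
        task_betas=study.truth.task_betas,
        fnc_young=study.truth.fnc_young,
        fnc_old=study.truth.fnc_old,
    )
    study.truth.subjects.to_csv(outdir / "ground_truth_subjects.tsv",
                                sep="\t", index=False)
    scalars = {
        "mediation_fig1a": study.truth.mediation_fig1a,
        "mediation_fig1b": study.truth.mediation_fig1b,
        "rt_model": RT_MODEL,
        "edge_coupling": cfg.edge_coupling,
        "seed": cfg.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(scalars, indent=2))
    return study
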