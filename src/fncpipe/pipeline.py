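"""End-to-end orchestration: study -> ICA -> GLM -> FNC -> behavior -> mediation.

Works either on an in-memory :class:`~fncpipe.synth.SyntheticStudy` or on a
study tree on disk (NIfTI runs + TSV tables, the layout
:func:`fncpipe.synth.generate_study` writes). Each stage consumes only the
previous stage's outputs, mirroring the subcommands of the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import fnc as fnc_mod
from . import gica, mediation, tcglm
from .design import build_design_matrix, events_from_frame
from .synth import SyntheticStudy


@dataclass
class StudyData:
    """Masked per-subject-run matrices plus tables, ready for analysis."""

    runs: list[gica.RunData]
    events: dict[str, list[list]]  # subject -> per-run TrialEvent lists
    demographics: pd.DataFrame
    volumes: pd.DataFrame | None
    mask: np.ndarray
    mask_index: np.ndarray
    TR_s: float
    scans_per_run: int
    match_info: dict[str, list[dict]] | None = None


def study_from_memory(study: SyntheticStudy) -> StudyData:
    cfg = study.config
    mask_index = np.flatnonzero(study.truth.mask.ravel())
    runs = []
    events = {}
    match_info = {}
    vol_rows = []
    for s in study.subjects:
        for r, data in enumerate(s.runs):
            runs.append(gica.RunData.from_raw(data, s.subject_id, r, mask_index))
        events[s.subject_id] = s.events
        match_info[s.subject_id] = s.match_info
        vol_rows.append(
            {"subject_id": s.subject_id, "gm_mm3": s.volumes["gm"],
             "wm_mm3": s.volumes["wm"], "csf_mm3": s.volumes["csf"]}
        )
    return StudyData(
        runs=runs, events=events, demographics=study.demographics,
        volumes=pd.DataFrame(vol_rows), mask=study.truth.mask,
        mask_index=mask_index, TR_s=cfg.TR_s, scans_per_run=cfg.scans_per_run,
        match_info=match_info,
    )


def study_from_tree(root: str | Path, TR_s: float = 3.0) -> StudyData:
    """Load a study tree written by :func:`fncpipe.synth.generate_study`."""
    import nibabel as nib

    root = Path(root)
    mask_img = nib.load(root / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    mask_index = np.flatnonzero(mask.ravel())
    demo = pd.read_csv(root / "participants.tsv", sep="\t")
    vol_path = root / "volumes.tsv"
    volumes = pd.read_csv(vol_path, sep="\t") if vol_path.exists() else None

    runs: list[gica.RunData] = []
    events: dict[str, list[list]] = {}
    scans_per_run = 0
    for sid in demo["subject_id"]:
        sdir = root / sid
        run_paths = sorted(sdir.glob("run-*_bold.nii.gz"))
        if not run_paths:
            raise FileNotFoundError(f"no BOLD runs under {sdir}")
        for r, p in enumerate(run_paths):
            try:
                img = nib.load(p)
                data4d = np.asarray(img.dataobj, dtype=float)
            except Exception as exc:  # corrupt input: name file and stage
                raise RuntimeError(
                    f"ica stage: failed to read NIfTI {p}: {exc}"
                ) from exc
            flat = data4d.reshape(-1, data4d.shape[-1])[mask_index].T
            scans_per_run = flat.shape[0]
            runs.append(gica.RunData.from_raw(flat, sid, r, mask_index))
        ev_frame = pd.read_csv(sdir / f"{sid}_events.tsv", sep="\t")
        events[sid] = events_from_frame(ev_frame)
    return StudyData(
        runs=runs, events=events, demographics=demo, volumes=volumes,
        mask=mask, mask_index=mask_index, TR_s=TR_s,
        scans_per_run=scans_per_run,
    )


@dataclass
class PipelineResult:
    model: gica.GroupICAModel
    components: dict[str, gica.SubjectComponents]
    contrast_values: np.ndarray | None = None
    task_table: tcglm.TaskRelatednessTable | None = None
    task_related: list[int] = field(default_factory=list)
    fnc_matrices: dict[str, fnc_mod.FNCMatrix] = field(default_factory=dict)
    edge_table: fnc_mod.EdgeTestTable | None = None
    retained_components: list[int] = field(default_factory=list)
    behavior: pd.DataFrame | None = None
    performance: dict[tuple[int, int], dict] = field(default_factory=dict)
    mediation_fnc: dict[tuple[int, int], mediation.MediationResult] = field(
        default_factory=dict
    )
    mediation_volume: dict[tuple[int, int], mediation.MediationResult] = field(
        default_factory=dict
    )


def fit_ica_stage(
    data: StudyData,
    n_ic: int,
    run_pcs: int = 30,
    n_reps: int = 5,
    seed: int = 0,
    backrecon: str = "gica",
) -> tuple[gica.GroupICAModel, dict[str, gica.SubjectComponents]]:
    model = gica.fit_group_ica(
        data.runs, n_ic=n_ic, run_pcs=run_pcs, n_reps=n_reps, seed=seed
    )
    by_subject: dict[str, list[gica.RunData]] = {}
    for run in data.runs:
        by_subject.setdefault(run.subject_id, []).append(run)
    comps = {
        sid: gica.back_reconstruct(model, subject_runs, method=backrecon)
        for sid, subject_runs in by_subject.items()
    }
    return model, comps


def glm_stage(
    data: StudyData,
    comps: dict[str, gica.SubjectComponents],
    keep: list[int] | None = None,
    alpha: float = 0.05,
    family_size: int | None = None,
):
    """Per-subject GLM contrasts and group task-relatedness tests.

    ``keep`` restricts the tested components (e.g. after artifact
    removal); indices refer to the model's component order.
    """
    demo = data.demographics.set_index("subject_id")
    sids = list(comps)
    n_ic = next(iter(comps.values())).timecourses.shape[1]
    if keep is None:
        keep = list(range(n_ic))
    values = []
    contrast_names = None
    for sid in sids:
        dm = build_design_matrix(
            data.events[sid], data.scans_per_run, data.TR_s
        )
        if contrast_names is None:
            contrast_names = list(dm.contrasts)
        sub_vals = np.empty((len(keep), len(dm.contrasts)))
        for ci, comp in enumerate(keep):
            res = tcglm.fit_component_glm(
                comps[sid].timecourses[:, comp], dm
            )
            cv = tcglm.contrast_values(res.betas, dm)
            sub_vals[ci] = [cv[name] for name in contrast_names]
        values.append(sub_vals)
    values = np.stack(values)  # subjects x comps x contrasts
    group = demo.loc[sids, "group"].to_numpy()
    gender = demo.loc[sids, "gender"].to_numpy()
    table = tcglm.component_group_tests(
        values, group, gender, components=keep,
        contrast_names=contrast_names, family_size=family_size, alpha=alpha,
    )
    retained, _ = tcglm.classify_task_related(table)
    return values, table, retained


def fnc_stage(
    data: StudyData,
    comps: dict[str, gica.SubjectComponents],
    components: list[int],
    alpha: float = 0.05,
):
    demo = data.demographics.set_index("subject_id")
    sids = list(comps)
    fncs = []
    for sid in sids:
        sc = comps[sid]
        mat = fnc_mod.compute_fnc(
            sc.timecourses[:, components], sc.run_lengths, subject_id=sid
        )
        fncs.append(mat)
    group = demo.loc[sids, "group"].to_numpy()
    gender = demo.loc[sids, "gender"].to_numpy()
    table = fnc_mod.edge_group_tests(
        fncs, group, gender, components=components, alpha=alpha
    )
    retained, _ = fnc_mod.prune_unconnected(table)
    return dict(zip(sids, fncs)), table, retained


def behavior_stage(data: StudyData) -> pd.DataFrame:
    rows = []
    for sid, runs in data.events.items():
        trials = [ev for run in runs for ev in run]
        match = None
        if data.match_info and sid in data.match_info:
            merged: dict[int, list] = {}
            for run_flags in data.match_info[sid]:
                for load, flags in run_flags.items():
                    merged.setdefault(load, []).extend(flags)
            match = {l: np.asarray(v) for l, v in merged.items()}
        summary = beh.summarize_behavior(trials, match=match)
        row = {"subject_id": sid, "srt": summary.srt}
        row.update({f"median_rt_{l}": m for l, m in summary.median_rt.items()})
        row.update({f"d_l_{l}": d for l, d in summary.d_l.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    if data.volumes is not None:
        table = table.merge(data.volumes, on="subject_id")
        table["nwbv"] = [
            beh.nwbv(r.gm_mm3, r.wm_mm3, r.csf_mm3)
            for r in table.itertuples()
        ]
    return table.merge(data.demographics, on="subject_id")


def mediation_stage(
    data: StudyData,
    fncs: dict[str, fnc_mod.FNCMatrix],
    behavior_table: pd.DataFrame,
    edges: list[tuple[int, int]],
    components: list[int],
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Mediation models per edge: age->FNC->sRT and age->nWBV->FNC.

    ``edges`` are component labels; ``components`` maps labels to the rows
    of the FNC matrices. Age is coded old = 1, young = 0.
    """
    tab = behavior_table.set_index("subject_id")
    sids = list(fncs)
    x = (tab.loc[sids, "group"].str.lower() == "old").to_numpy(float)
    gender = tcglm._gender_indicator(tab.loc[sids, "gender"].to_numpy())
    srt = tab.loc[sids, "srt"].to_numpy(float)
    pos = {c: i for i, c in enumerate(components)}

    fnc_results, vol_results = {}, {}
    for edge in edges:
        i, j = pos[edge[0]], pos[edge[1]]
        z = np.array([fncs[sid].z[i, j] for sid in sids])
        spec = mediation.MediationSpec(
            x=x, m=z, y=srt, covariates=gender, n_boot=n_boot, seed=seed
        )
        fnc_results[edge] = mediation.mediation_test(spec)
        if "nwbv" in tab.columns:
            nw = tab.loc[sids, "nwbv"].to_numpy(float)
            spec_v = mediation.MediationSpec(
                x=x, m=nw, y=z, covariates=gender, n_boot=n_boot, seed=seed + 1
            )
            vol_results[edge] = mediation.mediation_test(spec_v)
    return fnc_results, vol_results


def run_pipeline(
    data: StudyData,
    n_ic: int,
    run_pcs: int = 30,
    n_reps: int = 5,
    seed: int = 0,
    backrecon: str = "gica",
    alpha: float = 0.05,
    n_boot: int = 10_000,
    screen_artifacts: bool = False,
    performance_edges: list[tuple[int, int]] | None = None,
) -> PipelineResult:
    """Run every stage in order on one study.

    ``performance_edges`` limits the mediation models; by default the
    edges significant in the group comparison are carried forward.
    """
    model, comps = fit_ica_stage(
        data, n_ic=n_ic, run_pcs=run_pcs, n_reps=n_reps, seed=seed,
        backrecon=backrecon,
    )
    keep = list(range(model.n_ic))
    if screen_artifacts:
        mean_tc = np.mean([c.timecourses for c in comps.values()], axis=0)
        flagged = gica.flag_artifact_components(
            model, data.mask, data.mask_index, timecourses=mean_tc,
            TR_s=data.TR_s,
        )
        keep = [c for c in keep if c not in flagged]

    values, task_table, task_related = glm_stage(data, comps, keep=keep)
    # FNC needs at least one pair; fall back to all screened components
    components = task_related if len(task_related) >= 2 else keep
    fncs, edge_table, retained = fnc_stage(data, comps, components)
    behavior_table = behavior_stage(data)

    if performance_edges is None:
        performance_edges = [
            p for p, s in zip(edge_table.pairs, edge_table.significant) if s
        ]
    result = PipelineResult(
        model=model, components=comps, contrast_values=values,
        task_table=task_table, task_related=task_related,
        fnc_matrices=fncs, edge_table=edge_table,
        retained_components=retained, behavior=behavior_table,
    )
    tab = behavior_table.set_index("subject_id")
    sids = list(fncs)
    gender = tcglm._gender_indicator(tab.loc[sids, "gender"].to_numpy())
    srt = tab.loc[sids, "srt"].to_numpy(float)
    pos = {c: i for i, c in enumerate(components)}
    family = max(len(performance_edges), 1)
    for edge in performance_edges:
        z = np.array([fncs[sid].z[pos[edge[0]], pos[edge[1]]] for sid in sids])
        result.performance[edge] = fnc_mod.edge_performance_regression(
            z, srt, gender, family=family, alpha=alpha
        )
    med_edges = [e for e, r in result.performance.items() if r["significant"]]
    if not med_edges:
        med_edges = performance_edges
    fnc_med, vol_med = mediation_stage(
        data, fncs, behavior_table, med_edges, components,
        n_boot=n_boot, seed=seed,
    )
    result.mediation_fnc = fnc_med
    result.mediation_volume = vol_med
    return result


def match_sources(
    estimated: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment of estimated to true sources by |correlation|.

    Returns (assignment, |r| per true source): ``assignment[k]`` is the
    estimated row matched to true row k.
    """
    from scipy.optimize import linear_sum_assignment

    est = estimated - estimated.mean(axis=1, keepdims=True)
    tru = truth - truth.mean(axis=1, keepdims=True)
    est /= np.linalg.norm(est, axis=1, keepdims=True)
    tru /= np.linalg.norm(tru, axis=1, keepdims=True)
    corr = np.abs(tru @ est.T)  # true x estimated
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]
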