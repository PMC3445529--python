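# fncpipe

Group spatial ICA, functional network connectivity (FNC) and bootstrap
mediation analysis for task fMRI aging studies — with a fully synthetic
study generator so that every stage of the pipeline can be validated by
parameter recovery.

## The scientific problem

Advancing age changes brain structure, the coordination of activity
between brain networks, and cognitive performance. A natural causal
question is whether these changes form a chain: does age slow working
memory performance *because* it weakens the functional coupling between
networks, and is that weakened coupling in turn a consequence of global
brain atrophy?

`fncpipe` implements the full analysis path for a verbal delayed item
recognition (DIR) experiment: subjects encode 1, 3 or 6 letters
(stimulus, 3 s), hold them (retention, 7 s) and answer a recognition
probe (up to 3 s). Memory load crossed with task phase defines nine
regressors of interest, each a boxcar convolved with the canonical
double-gamma hemodynamic response function h(t) = g₆(t) − g₁₆(t)/6
(gamma densities, unit scale). The pipeline then proceeds:

1. **Group spatial ICA** — temporal PCA within each run (30 PCs), a
   second PCA across all stacked subject-runs, and infomax ICA on the
   group-whitened data, repeated with distinct seeds and clustered
   (ICASSO) to keep only stable components; subject-specific time
   courses and maps come from GICA back-reconstruction through the
   stored reduction operators.
2. **Task-relatedness** — each component time course is fit with the
   convolved design (OLS); six contrasts (load-dependent and
   load-independent per phase) are tested within each age group
   controlling for gender, Bonferroni-corrected; a component is
   task-related if significant in either group.
3. **FNC** — per subject, the Pearson correlation between component
   time courses, Fisher z = atanh(r); between-group two-sample tests per
   edge (gender-adjusted, Bonferroni over all pairs); components with no
   significant edge are pruned; surviving edges are regressed against
   the speeded performance measure sRT (the OLS slope of per-load median
   RT against set size 1, 3, 6).
4. **Mediation** — single-mediator models with age group as the binary
   exposure: indirect effect a·b, where c = c′ + a·b exactly for OLS
   with shared covariates, interval-estimated with a stratified
   bootstrap (group sizes preserved exactly) and bias-corrected
   percentile confidence intervals. Both directions are tested:
   age → FNC → sRT, and age → nWBV → FNC, where
   nWBV = (GM + WM)/(GM + WM + CSF) is normalized whole brain volume.

Because no raw scanner data ship with the package, a synthetic study
generator (`fncpipe.synth`) creates 4D NIfTI runs, trial event tables,
demographics and tissue volumes from a model in which every downstream
estimate — source maps, per-subject FNC, sRT slopes, mediation paths —
is known exactly.

## Worked example

A reduced synthetic study (12 young + 12 old subjects, 10³ voxel grid,
6 sources, 3 runs × 69 scans at TR = 3 s) through the whole pipeline:

```python
import numpy as np
import fncpipe as f
from fncpipe.mediation import MediationSpec, mediation_test
from fncpipe.pipeline import behavior_stage, fit_ica_stage, study_from_memory

cfg = f.SynthConfig.reduced(n_young=12, n_old=12, seed=7)
study = f.simulate_study(cfg)
data = study_from_memory(study)

model, comps = fit_ica_stage(data, n_ic=6, run_pcs=20, n_reps=5, seed=3)
assign, rs = f.match_sources(model.sources, study.truth.source_maps)
print(f"spatial recovery |r| per planted source: {np.round(rs, 3)}")

sids = [s.subject_id for s in study.subjects]
young = np.array([s.group == "young" for s in study.subjects])
zs = {sid: f.compute_fnc(comps[sid].timecourses, comps[sid].run_lengths).z
      for sid in sids}
ze = np.array([zs[sid][assign[0], assign[1]] for sid in sids])
print(f"planted edge Fisher z: young mean {ze[young].mean():.3f}, "
      f"old mean {ze[~young].mean():.3f}")

beh = behavior_stage(data).set_index("subject_id")
srt = beh.loc[sids, "srt"].to_numpy(float)
gender = (beh.loc[sids, "gender"] == "M").to_numpy(float)
res = mediation_test(MediationSpec(x=(~young).astype(float), m=ze, y=srt,
                                   covariates=gender, n_boot=2000, seed=0))
print(f"indirect a*b = {res.indirect:.4f}, "
      f"95% BC CI ({res.ci_low:.4f}, {res.ci_high:.4f})")
```

prints

```
spatial recovery |r| per planted source: [1. 1. 1. 1. 1. 1.]
planted edge Fisher z: young mean 0.515, old mean 0.148
indirect a*b = 0.0407, 95% BC CI (0.0118, 0.0787)
```

Reading the numbers: all six planted spatial sources are recovered
essentially perfectly by the group ICA; the planted connectivity edge is
much stronger in the young group (the generator plants z ≈ 0.57 vs
0.06); and the mediation model attributes a significant part of the old
group's steeper RT-versus-load slope to that weakened edge — the 95%
bias-corrected bootstrap interval for the indirect effect excludes zero,
as planted.

The same chain is available from the shell, stage by stage, with a YAML
config:

```bash
fncpipe -c config.yaml all      # synth → design → ica → glm → fnc → behavior → mediate
```

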