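"""Group spatial ICA: two-stage PCA, infomax, ICASSO stability, back-reconstruction.

The pipeline follows the standard group spatial ICA scheme for multi-subject
fMRI: a temporal PCA within each run of each subject (whitening, 30
components retained by default), a second temporal PCA across the stacked
reduced data of all subject-runs, infomax ICA on the group-whitened data,
stability selection by repeating ICA and clustering the estimates (ICASSO),
and back-reconstruction of subject-specific time courses and spatial maps
through the stored reduction operators.

Conventions: data matrices are scans x voxels with the per-voxel mean
removed; PCA is temporal (the scans dimension is reduced, the spatial
dimension is preserved); source rows have unit variance and the voxel with
the largest absolute weight is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_N_IC = 36
DEFAULT_RUN_PCS = 30
DEFAULT_ICASSO_REPS = 20

#: infomax defaults (natural-gradient, logistic nonlinearity)
MAX_STEPS = 512
W_TOL = 1e-6
ANNEAL = 0.9
#: scheduled geometric anneal: after a full-rate burn-in the learning rate
#: decays each sweep, forcing the (row-normalized) weight change under W_TOL
ANNEAL_START = 64
ANNEAL_STEP = 0.97
BLOWUP = 1e9
MAX_WEIGHT = 1e8


class NotWhitenedError(ValueError):
    """Input to ICA does not have identity covariance."""


class MissingReductionError(KeyError):
    """No stored PCA reduction for the requested subject-run."""


@dataclass
class RunData:
    """One run of masked, voxel-demeaned fMRI data (scans x voxels)."""

    matrix: np.ndarray
    subject_id: str
    run_id: int
    mask_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def key(self) -> tuple[str, int]:
        return (self.subject_id, self.run_id)

    @classmethod
    def from_raw(
        cls, raw: np.ndarray, subject_id: str, run_id: int,
        mask_index: np.ndarray | None = None,
    ) -> "RunData":
        """Demean each voxel's time series; drop nothing (mask applied upstream)."""
        raw = np.asarray(raw, dtype=float)
        return cls(raw - raw.mean(axis=0, keepdims=True), subject_id, run_id,
                   mask_index)


@dataclass
class PCAReduction:
    """Whitening (basis) and dewhitening (debasis) operators of a temporal PCA.

    ``basis`` is retained x scans, ``debasis`` is scans x retained;
    ``basis @ debasis`` is the identity on the retained subspace.
    """

    basis: np.ndarray
    debasis: np.ndarray
    eigenvalues: np.ndarray

    @property
    def retained(self) -> int:
        return self.basis.shape[0]


@dataclass
class GroupICAModel:
    """Aggregate sources with the operators needed for back-reconstruction."""

    sources: np.ndarray  # n_ic x voxels, unit variance rows
    group_mixing: np.ndarray  # group-PC-space mixing, retained_2 x n_ic
    run_reductions: dict[tuple[str, int], PCAReduction]
    group_reduction: PCAReduction
    stack_order: list[tuple[str, int]]
    stability_iq: np.ndarray | None = None
    converged: bool = True
    artifact_components: list[int] = field(default_factory=list)

    @property
    def n_ic(self) -> int:
        return self.sources.shape[0]

    def group_slice(self, key: tuple[str, int]) -> slice:
        """Rows of the stacked reduced data belonging to one subject-run."""
        idx = self.stack_order.index(key)
        r1 = next(iter(self.run_reductions.values())).retained
        return slice(idx * r1, (idx + 1) * r1)


@dataclass
class SubjectComponents:
    """Back-reconstructed per-subject time courses and spatial maps."""

    subject_id: str
    timecourses: np.ndarray  # total scans (runs concatenated) x n_ic
    spatial_maps: np.ndarray  # n_ic x voxels
    run_lengths: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PCA reduction


def _temporal_pca(matrix: np.ndarray, retained: int) -> tuple[PCAReduction, np.ndarray]:
    """Eigendecomposition of the scans x scans covariance; whitened output."""
    n_rows, n_vox = matrix.shape
    if retained > n_rows:
        raise ValueError(f"retained={retained} exceeds rows={n_rows}")
    cov = matrix @ matrix.T / n_vox
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:retained]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError(
            f"rank-deficient input: retained={retained} exceeds effective rank"
        )
    scale = np.sqrt(evals)
    basis = (evecs / scale).T  # retained x scans
    debasis = evecs * scale  # scans x retained
    reduction = PCAReduction(basis=basis, debasis=debasis, eigenvalues=evals)
    return reduction, basis @ matrix


def reduce_run(run: RunData, retained: int) -> tuple[PCAReduction, np.ndarray]:
    """Temporal PCA of one run, keeping ``retained`` whitened components.

    The reduced data (retained x voxels) have identity covariance across
    the retained dimensions (population normalisation, 1/voxels).
    """
    return _temporal_pca(run.matrix, retained)


def reduce_group(
    stacked: np.ndarray, retained_2: int
) -> tuple[PCAReduction, np.ndarray]:
    """Second-stage temporal PCA across stacked subject-run reduced data.

    ``stacked`` is (n_subject_runs * retained_1) x voxels in subject-major,
    run-minor order; the caller records that order in the model.
    """
    return _temporal_pca(stacked, retained_2)


# ---------------------------------------------------------------------------
# infomax ICA


def normalize_signs(sources: np.ndarray, mixing: np.ndarray | None = None):
    """Flip each source so its largest-|weight| voxel is positive.

    Idempotent; the compensating flip is applied to the mixing columns.
    """
    flips = np.ones(sources.shape[0])
    for i, row in enumerate(sources):
        peak = np.argmax(np.abs(row))
        if row[peak] < 0:
            flips[i] = -1.0
    out = sources * flips[:, None]
    if mixing is None:
        return out
    return out, mixing * flips[None, :]


def _rownorm(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return W / norms


def _check_white(white: np.ndarray, tol: float = 1e-3) -> None:
    n = white.shape[0]
    cov = white @ white.T / white.shape[1]
    if np.max(np.abs(cov - np.eye(n))) > tol:
        raise NotWhitenedError(
            "input covariance deviates from identity by more than "
            f"{tol}; whiten with reduce_run/reduce_group first"
        )


def infomax_ica(
    white: np.ndarray,
    seed: int,
    lrate: float | None = None,
    block: int | None = None,
    max_steps: int = MAX_STEPS,
    w_tol: float = W_TOL,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Natural-gradient infomax ICA with a logistic nonlinearity.

    Starts from a seeded random rotation so repeated runs explore
    distinct basins (the basis of ICASSO stability). Random-permutation
    mini-batches; the learning rate anneals (x 0.9, with a restart to the
    initial rotation) whenever an update blows up, and decays
    geometrically after a full-rate burn-in; convergence when the
    between-sweep change of the row-normalized unmixing falls below
    ``w_tol``, or after ``max_steps`` sweeps.

    Returns ``(unmixing, sources, converged)``; sources are unit-variance,
    sign-normalized rows of ``unmixing @ white``.
    """
    _check_white(white)
    n, n_vox = white.shape
    rng = np.random.default_rng(seed)
    if block is None:
        block = max(int(np.floor(np.sqrt(n_vox / 3.0))), 8)
    if lrate is None:
        # scaled for unit-variance whitened input: large enough that the
        # separating rotation completes within the full-rate burn-in
        lrate = 0.01 / np.log(max(n, 2))

    # seeded random-rotation start: repetitions explore distinct basins,
    # which is what makes ICASSO stability informative (a Gaussian-only
    # subspace then keeps its arbitrary rotation and clusters poorly)
    W0 = np.linalg.qr(rng.standard_normal((n, n)))[0]
    W = W0.copy()
    eye_b = None
    converged = False
    step = 0
    prev_change: np.ndarray | None = None
    while step < max_steps:
        step += 1
        perm = rng.permutation(n_vox)
        W_old = W.copy()
        blowup = False
        for start in range(0, n_vox - block + 1, block):
            x = white[:, perm[start : start + block]]
            u = W @ x
            y = 1.0 / (1.0 + np.exp(-u))
            if eye_b is None or eye_b.shape[0] != n:
                eye_b = np.eye(n)
            # natural gradient: dW = lr * (block*I + (1-2y) u^T) W
            W = W + lrate * ((block * eye_b + (1.0 - 2.0 * y) @ u.T) @ W) / block
            if not np.isfinite(W).all() or np.max(np.abs(W)) > MAX_WEIGHT:
                blowup = True
                break
        if blowup:
            lrate *= ANNEAL
            W = W0.copy()
            prev_change = None
            continue
        # convergence is judged on the row-normalized unmixing matrix:
        # the logistic fixed point lets the weight scale creep while the
        # separating directions are already stationary, and the sources
        # are rescaled to unit variance afterwards anyway
        change = _rownorm(W) - _rownorm(W_old)
        delta = np.linalg.norm(change)
        if delta > BLOWUP:
            lrate *= ANNEAL
            W = W0.copy()
            prev_change = None
            continue
        if delta < w_tol:
            converged = True
            break
        # anneal when the update direction swings by more than 60 degrees,
        # plus the scheduled decay once past the burn-in
        if prev_change is not None:
            denom = np.linalg.norm(prev_change) * delta
            if denom > 0 and np.vdot(prev_change, change) / denom < 0.5:
                lrate *= ANNEAL
        if step > ANNEAL_START:
            lrate *= ANNEAL_STEP
        prev_change = change
    if not converged:
        warnings.warn(
            f"infomax did not converge in {max_steps} sweeps "
            f"(last delta {delta:.2e})",
            RuntimeWarning,
        )
    sources = W @ white
    sd = sources.std(axis=1)
    sd[sd == 0] = 1.0
    W = W / sd[:, None]
    sources = sources / sd[:, None]
    sources, mixing = normalize_signs(sources, np.linalg.pinv(W))
    W = np.linalg.pinv(mixing)
    return W, sources, converged


# ---------------------------------------------------------------------------
# ICASSO stability selection


def cluster_estimates(
    pooled: np.ndarray, n_clusters: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering of pooled ICA estimates.

    Similarity is the absolute Pearson correlation between source maps.
    Returns (labels in 1..n_clusters, similarity matrix); the labels are a
    partition — every estimate belongs to exactly one cluster.
    """
    centered = pooled - pooled.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    sim = np.abs((centered / norms[:, None]) @ (centered / norms[:, None]).T)
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(
        linkage(squareform(dist, checks=False), method="average"),
        t=n_clusters, criterion="maxclust",
    )
    return labels, sim


def icasso(
    white: np.ndarray,
    n_ic: int | None = None,
    n_reps: int = DEFAULT_ICASSO_REPS,
    seed: int = 0,
    seeds: list[int] | None = None,
    **ica_kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Repeat infomax with distinct seeds and cluster the pooled estimates.

    Similarity between estimates is the absolute Pearson correlation of
    their spatial maps; average-linkage agglomerative clustering partitions
    the ``n_reps * n_ic`` estimates into ``n_ic`` clusters. Each cluster is
    summarised by its centrotype (the member with the largest total
    within-cluster similarity) and the stability index
    ``Iq = mean intra-cluster similarity - mean extra-cluster similarity``.

    Returns ``(sources, mixing, iq, converged)`` where ``sources`` holds the
    centrotypes (sign-normalized, unit variance), ``mixing`` is the
    least-squares mixing of the whitened data onto them, and ``iq`` is the
    per-component stability in [0, 1] (clipped below at 0 only by data).
    """
    if seeds is None:
        if n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        seed_rng = np.random.default_rng(seed)
        seeds = [int(s) for s in seed_rng.integers(0, 2**31 - 1, size=n_reps)]
    elif len(seeds) < 2:
        raise ValueError("need at least 2 repetitions")
    n = white.shape[0]
    if n_ic is None:
        n_ic = n

    estimates = []
    all_converged = True
    for s in seeds:
        _, sources, conv = infomax_ica(white, seed=int(s), **ica_kwargs)
        all_converged &= conv
        estimates.append(sources)
    pooled = np.vstack(estimates)  # (n_reps * n_ic) x voxels
    labels, sim = cluster_estimates(pooled, n_ic)

    centrotypes = np.empty((n_ic, pooled.shape[1]))
    iq = np.empty(n_ic)
    for c in range(1, n_ic + 1):
        members = np.flatnonzero(labels == c)
        outside = np.flatnonzero(labels != c)
        sub = sim[np.ix_(members, members)]
        centro = members[np.argmax(sub.sum(axis=1))]
        centrotypes[c - 1] = pooled[centro]
        if len(members) > 1:
            intra = (sub.sum() - len(members)) / (len(members) * (len(members) - 1))
        else:
            intra = 1.0
        extra = sim[np.ix_(members, outside)].mean() if len(outside) else 0.0
        iq[c - 1] = intra - extra

    order = np.argsort(iq)[::-1]
    centrotypes, iq = centrotypes[order], iq[order]
    sd = centrotypes.std(axis=1)
    sd[sd == 0] = 1.0
    centrotypes = normalize_signs(centrotypes / sd[:, None])
    # least-squares mixing of whitened data onto the centrotype sources
    mixing = white @ np.linalg.pinv(centrotypes)
    return centrotypes, mixing, iq, all_converged


# ---------------------------------------------------------------------------
# full decomposition and back-reconstruction


def fit_group_ica(
    runs: list[RunData],
    n_ic: int = DEFAULT_N_IC,
    run_pcs: int = DEFAULT_RUN_PCS,
    n_reps: int = DEFAULT_ICASSO_REPS,
    seed: int = 0,
) -> GroupICAModel:
    """Two-stage reduction + ICASSO infomax over a list of subject-runs."""
    run_reductions: dict[tuple[str, int], PCAReduction] = {}
    stack_order: list[tuple[str, int]] = []
    reduced_blocks = []
    for run in runs:
        red, reduced = reduce_run(run, run_pcs)
        run_reductions[run.key] = red
        stack_order.append(run.key)
        reduced_blocks.append(reduced)
    stacked = np.vstack(reduced_blocks)
    group_red, white = reduce_group(stacked, n_ic)
    sources, mixing, iq, converged = icasso(
        white, n_ic=n_ic, n_reps=n_reps, seed=seed
    )
    return GroupICAModel(
        sources=sources,
        group_mixing=mixing,
        run_reductions=run_reductions,
        group_reduction=group_red,
        stack_order=stack_order,
        stability_iq=iq,
        converged=converged,
    )


def back_reconstruct(
    model: GroupICAModel,
    runs: list[RunData],
    method: str = "gica",
) -> SubjectComponents:
    """Subject-specific time courses and spatial maps for one subject's runs.

    GICA back-reconstruction routes each run's reduced data through the
    subject-run partition of the group dewhitening and the ICA mixing:
    time courses are ``run_debasis @ group_debasis[partition] @ mixing`` and
    spatial maps solve the corresponding partitioned forward model by
    pseudo-inverse. ``method="dual_regression"`` instead regresses the
    aggregate maps onto the run data.
    """
    if method not in ("gica", "dual_regression"):
        raise ValueError(f"unknown back-reconstruction method {method!r}")
    subject_id = runs[0].subject_id
    tcs, maps, lengths = [], [], []
    pinv_sources = np.linalg.pinv(model.sources)
    for run in runs:
        if run.key not in model.run_reductions:
            raise MissingReductionError(
                f"no stored reduction for subject-run {run.key}"
            )
        red = model.run_reductions[run.key]
        if method == "dual_regression":
            tc = run.matrix @ pinv_sources  # scans x n_ic
            smap = np.linalg.pinv(tc) @ run.matrix
        else:
            sl = model.group_slice(run.key)
            g_de = model.group_reduction.debasis[sl, :]  # r1 x r2
            partition = g_de @ model.group_mixing  # r1 x n_ic
            tc = red.debasis @ partition  # scans x n_ic
            reduced = red.basis @ run.matrix  # r1 x voxels
            smap = np.linalg.pinv(partition) @ reduced  # n_ic x voxels
        tcs.append(tc)
        maps.append(smap)
        lengths.append(run.n_scans)
    return SubjectComponents(
        subject_id=subject_id,
        timecourses=np.vstack(tcs),
        spatial_maps=np.mean(maps, axis=0),
        run_lengths=lengths,
    )


def save_model(model: GroupICAModel, path) -> None:
    """Serialize a fitted model (arrays + stacking order) to one .npz."""
    keys = [f"{sid}::{rid}" for sid, rid in model.stack_order]
    arrays = {
        "sources": model.sources,
        "group_mixing": model.group_mixing,
        "group_basis": model.group_reduction.basis,
        "group_debasis": model.group_reduction.debasis,
        "group_eigenvalues": model.group_reduction.eigenvalues,
        "stability_iq": model.stability_iq
        if model.stability_iq is not None else np.array([]),
        "stack_order": np.array(keys),
        "converged": np.array([model.converged]),
        "artifacts": np.array(model.artifact_components, dtype=int),
    }
    for key, red in zip(keys, (model.run_reductions[k] for k in model.stack_order)):
        arrays[f"run_basis::{key}"] = red.basis
        arrays[f"run_debasis::{key}"] = red.debasis
        arrays[f"run_eigenvalues::{key}"] = red.eigenvalues
    np.savez_compressed(path, **arrays)


def load_model(path) -> GroupICAModel:
    with np.load(path, allow_pickle=False) as z:
        keys = [str(k) for k in z["stack_order"]]
        stack_order = []
        run_reductions = {}
        for key in keys:
            sid, rid = key.rsplit("::", 1)
            k = (sid, int(rid))
            stack_order.append(k)
            run_reductions[k] = PCAReduction(
                basis=z[f"run_basis::{key}"],
                debasis=z[f"run_debasis::{key}"],
                eigenvalues=z[f"run_eigenvalues::{key}"],
            )
        iq = z["stability_iq"]
        return GroupICAModel(
            sources=z["sources"],
            group_mixing=z["group_mixing"],
            run_reductions=run_reductions,
            group_reduction=PCAReduction(
                basis=z["group_basis"],
                debasis=z["group_debasis"],
                eigenvalues=z["group_eigenvalues"],
            ),
            stack_order=stack_order,
            stability_iq=iq if iq.size else None,
            converged=bool(z["converged"][0]),
            artifact_components=z["artifacts"].tolist(),
        )


def flag_artifact_components(
    model: GroupICAModel,
    mask: np.ndarray,
    mask_index: np.ndarray,
    timecourses: np.ndarray | None = None,
    TR_s: float = 3.0,
    erode_iter: int = 1,
    hf_cutoff_hz: float = 0.1,
    hf_frac: float = 0.5,
) -> list[int]:
    """Rule-based stand-in for visual artifact screening.

    A component is flagged when its peak |weight| voxel falls outside the
    eroded interior of the brain mask (rim/edge artifacts), or when more
    than ``hf_frac`` of its mean time-course power lies above
    ``hf_cutoff_hz`` (physiological/scanner noise). The flagged list can be
    overridden in the pipeline config.
    """
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(mask.astype(bool), iterations=erode_iter)
    interior_lin = np.flatnonzero(interior.ravel())
    inside = np.isin(mask_index, interior_lin)

    flagged = []
    for i, row in enumerate(model.sources):
        if not inside[np.argmax(np.abs(row))]:
            flagged.append(i)
    if timecourses is not None:
        freqs = np.fft.rfftfreq(timecourses.shape[0], d=TR_s)
        power = np.abs(np.fft.rfft(timecourses, axis=0)) ** 2
        power[0] = 0.0  # ignore DC
        total = power.sum(axis=0)
        total[total == 0] = 1.0
        hf = power[freqs > hf_cutoff_hz].sum(axis=0) / total
        for i in range(model.n_ic):
            if hf[i] > hf_frac and i not in flagged:
                flagged.append(i)
    model.artifact_components = sorted(flagged)
    return model.artifact_components
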