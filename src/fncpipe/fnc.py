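"""Functional network connectivity: per-subject correlation matrices and tests.

FNC between two independent components is the Pearson correlation of their
back-reconstructed time courses within one participant, Fisher
z-transformed. Edges are compared between age groups (two-sample t,
gender-adjusted, Bonferroni over all pairs), components with no significant
edge are pruned, and surviving edges are regressed against speeded task
performance (sRT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tcglm import between_group_test, _gender_indicator

#: correlations are clipped to +/- (1 - CLIP_EPS) before atanh
CLIP_EPS = 1e-12
ALPHA = 0.05


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z = atanh(r), with |r| clipped below 1 to keep z finite."""
    r = np.clip(r, -(1.0 - CLIP_EPS), 1.0 - CLIP_EPS)
    return np.arctanh(r)


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    return np.tanh(z)


@dataclass
class FNCMatrix:
    """Symmetric components x components Fisher-z matrix for one subject.

    The diagonal is NaN (self-connectivity is undefined); masked edges
    (constant time courses) are NaN as well.
    """

    z: np.ndarray
    subject_id: str
    masked_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.z.shape[0]


def compute_fnc(
    timecourses: np.ndarray,
    run_lengths: list[int] | None = None,
    subject_id: str = "",
) -> FNCMatrix:
    """FNC matrix from one subject's component time courses.

    Runs are demeaned individually then concatenated (removing inter-run
    offsets) before the Pearson correlation; z = atanh of the clipped r.

    Parameters
    ----------
    timecourses:
        total scans x components.
    run_lengths:
        scans per run, in order; one run assumed if omitted.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.shape[1] < 2:
        raise ValueError("need at least 2 components")
    if tc.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    if run_lengths is None:
        run_lengths = [tc.shape[0]]
    parts, start = [], 0
    for ln in run_lengths:
        block = tc[start : start + ln]
        parts.append(block - block.mean(axis=0, keepdims=True))
        start += ln
    cat = np.vstack(parts)

    sd = cat.std(axis=0)
    constant = sd == 0
    masked = []
    k = tc.shape[1]
    if constant.any():
        warnings.warn(
            f"constant time course(s) {np.flatnonzero(constant).tolist()}: "
            "incident edges masked",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(cat, rowvar=False)
    z = fisher_z(r)
    for i in np.flatnonzero(constant):
        z[i, :] = np.nan
        z[:, i] = np.nan
        masked.extend((min(i, j), max(i, j)) for j in range(k) if j != i)
    np.fill_diagonal(z, np.nan)
    return FNCMatrix(z=z, subject_id=subject_id, masked_edges=sorted(set(masked)))


@dataclass
class EdgeTestTable:
    """Between-group t-tests per unordered component pair (Table-4 layout)."""

    components: list[int]
    pairs: list[tuple[int, int]]
    t: np.ndarray
    p: np.ndarray
    young_mean: np.ndarray
    young_se: np.ndarray
    old_mean: np.ndarray
    old_se: np.ndarray
    family_size: int
    alpha: float = ALPHA
    n_excluded: np.ndarray | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha / self.family_size


def edge_group_tests(
    fncs: list[FNCMatrix],
    group: np.ndarray,
    gender: np.ndarray,
    components: list[int] | None = None,
    alpha: float = ALPHA,
) -> EdgeTestTable:
    """Between-group tests of edge strength, Bonferroni over all pairs.

    The Bonferroni family is the pair count k(k-1)/2. Subjects with a
    masked edge are excluded pairwise; the exclusion count is reported.
    """
    k = fncs[0].n_components
    if components is None:
        components = list(range(k))
    group = np.asarray(group)
    gender = np.asarray(gender)
    zs = np.stack([f.z for f in fncs])  # subjects x k x k

    from .tcglm import _young_indicator

    young = _young_indicator(group).astype(bool)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    family = len(pairs)
    t = np.empty(family)
    p = np.empty(family)
    ym = np.empty(family)
    yse = np.empty(family)
    om = np.empty(family)
    ose = np.empty(family)
    nex = np.zeros(family, dtype=int)
    for e, (i, j) in enumerate(pairs):
        vals = zs[:, i, j]
        ok = np.isfinite(vals)
        nex[e] = int((~ok).sum())
        t[e], p[e] = between_group_test(vals[ok], group[ok], gender[ok])
        yv = vals[ok & young]
        ov = vals[ok & ~young]
        ym[e], om[e] = yv.mean(), ov.mean()
        yse[e] = yv.std(ddof=1) / np.sqrt(len(yv))
        ose[e] = ov.std(ddof=1) / np.sqrt(len(ov))
    return EdgeTestTable(
        components=components,
        pairs=[(components[i], components[j]) for i, j in pairs],
        t=t, p=p,
        young_mean=ym, young_se=yse, old_mean=om, old_se=ose,
        family_size=family, alpha=alpha, n_excluded=nex,
    )


def prune_unconnected(table: EdgeTestTable) -> tuple[list[int], list[int]]:
    """Drop components incident to no significant edge.

    Returns (retained, removed) component lists, sorted.
    """
    sig = table.significant
    connected: set[int] = set()
    for s, (i, j) in zip(sig, table.pairs):
        if s:
            connected.update((i, j))
    retained = sorted(connected)
    removed = sorted(set(table.components) - connected)
    return retained, removed


def edge_performance_regression(
    z_edge: np.ndarray,
    srt: np.ndarray,
    gender: np.ndarray,
    family: int = 1,
    alpha: float = ALPHA,
) -> dict:
    """OLS of sRT on one edge's z, controlling for gender.

    Bonferroni over ``family`` (the number of edges tested). Returns the
    slope, its t and p, and the corrected significance flag.
    """
    z_edge = np.asarray(z_edge, dtype=float)
    srt = np.asarray(srt, dtype=float)
    g = _gender_indicator(gender)
    cols = [np.ones_like(srt), z_edge]
    if np.ptp(g) > 0:
        cols.append(g - g.mean())
    X = np.column_stack(cols)
    from .tcglm import _ols

    res = _ols(X, srt)
    return {
        "slope": float(res.betas[1]),
        "t": float(res.t[1]),
        "p": float(res.p[1]),
        "significant": bool(res.p[1] < alpha / family),
        "family_size": family,
    }
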