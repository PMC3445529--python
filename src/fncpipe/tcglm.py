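"""Component time-course GLM: contrast values, group tests, task-relatedness.

Each back-reconstructed component time course is fit with the convolved
task design (ordinary least squares over the concatenated runs). The six
contrasts of interest are evaluated per subject per component, then tested
within each age group (one-sample, controlling for gender) and between
groups (two-sample, controlling for gender). A component is task-related
if any of its within-group contrast tests survives Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignMatrix

ALPHA = 0.05


@dataclass
class OLSResult:
    betas: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    dropped: list[int]
    sigma2: float = float("nan")
    xtx_inv: np.ndarray | None = None
    kept: list[int] | None = None

    def contrast_test(self, weights: np.ndarray) -> tuple[float, float, float]:
        """t-test of a linear contrast of the coefficients.

        Returns (estimate, t, two-sided p); weights on dropped columns
        must be zero.
        """
        w = np.asarray(weights, dtype=float)
        if self.kept is not None and len(w) != len(self.kept):
            if any(w[j] != 0 for j in self.dropped):
                raise ValueError("contrast weights nonzero on dropped columns")
            w = w[self.kept]
        est = float(w @ np.nan_to_num(self.betas, nan=0.0)[self.kept]
                    if self.kept is not None else w @ self.betas)
        var = float(self.sigma2 * w @ self.xtx_inv @ w)
        t = est / np.sqrt(var) if var > 0 else np.inf * np.sign(est)
        p = float(2.0 * stats.t.sf(abs(t), self.df))
        return est, float(t), p


def _ols(X: np.ndarray, y: np.ndarray) -> OLSResult:
    """Plain OLS with classical standard errors; drops aliased columns."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    dropped: list[int] = []
    keep = list(range(k))
    if rank < k:
        # greedy drop of columns that do not increase rank
        keep = []
        cur = np.empty((n, 0))
        for j in range(k):
            cand = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(cand) > cur.shape[1]:
                keep.append(j)
                cur = cand
            else:
                dropped.append(j)
        warnings.warn(
            f"design is rank-deficient; dropped aliased columns {dropped}",
            RuntimeWarning,
        )
        X = X[:, keep]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df if df > 0 else np.nan
    se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df) if df > 0 else np.full_like(t, np.nan)

    betas_full = np.full(k, np.nan)
    se_full = np.full(k, np.nan)
    t_full = np.full(k, np.nan)
    p_full = np.full(k, np.nan)
    for out_i, j in enumerate(keep):
        betas_full[j] = beta[out_i]
        se_full[j] = se[out_i]
        t_full[j] = t[out_i]
        p_full[j] = p[out_i]
    return OLSResult(betas_full, se_full, t_full, p_full, df, dropped,
                     sigma2=sigma2, xtx_inv=XtX_inv, kept=keep)


def fit_component_glm(tc: np.ndarray, design: DesignMatrix) -> OLSResult:
    """OLS fit of one component time course against the run-blocked design."""
    tc = np.asarray(tc, dtype=float).ravel()
    if tc.shape[0] != design.matrix.shape[0]:
        raise ValueError(
            f"time course has {tc.shape[0]} scans, design has "
            f"{design.matrix.shape[0]}"
        )
    return _ols(design.matrix, tc)


def contrast_values(betas: np.ndarray, design: DesignMatrix) -> dict[str, float]:
    """Contrast-weighted beta values for the six contrasts of interest."""
    b = np.nan_to_num(betas, nan=0.0)
    return {name: float(w @ b) for name, w in design.contrasts.items()}


def within_group_test(
    values: np.ndarray, gender: np.ndarray
) -> tuple[float, float]:
    """One-sample t-test of the group mean, controlling for gender.

    Regression of the contrast values on an intercept plus a centered
    gender indicator; returns (t, p) for the intercept with df = n - 2.
    A single-gender group falls back to a plain one-sample t-test.
    """
    values = np.asarray(values, dtype=float)
    g = _gender_indicator(gender)
    if np.ptp(g) == 0:
        warnings.warn(
            "single-gender group: plain one-sample t-test", RuntimeWarning
        )
        t, p = stats.ttest_1samp(values, 0.0)
        return float(t), float(p)
    X = np.column_stack([np.ones_like(values), g - g.mean()])
    res = _ols(X, values)
    return float(res.t[0]), float(res.p[0])


def between_group_test(
    values: np.ndarray, group: np.ndarray, gender: np.ndarray
) -> tuple[float, float]:
    """Two-sample test young vs old, controlling for gender.

    Regression on intercept + group indicator + centered gender; the group
    indicator is oriented so a positive t means young > old. ``group`` may
    be string labels ("young"/"old") or any two-level coding whose *lower*
    sorted value is treated as young.
    """
    values = np.asarray(values, dtype=float)
    ind = _young_indicator(group)
    if len(np.unique(ind)) < 2:
        raise ValueError("both groups must be present")
    g = _gender_indicator(gender)
    cols = [np.ones_like(values), ind - ind.mean()]
    if np.ptp(g) > 0:
        cols.append(g - g.mean())
    else:
        warnings.warn("single-gender sample: gender covariate dropped",
                      RuntimeWarning)
    X = np.column_stack(cols)
    res = _ols(X, values)
    return float(res.t[1]), float(res.p[1])


def _young_indicator(group: np.ndarray) -> np.ndarray:
    """1 for young, 0 for old; accepts labels or binary codes."""
    arr = np.asarray(group)
    if arr.dtype.kind in "USO":
        low = np.char.lower(arr.astype(str))
        return (low == "young").astype(float)
    levels = np.unique(arr)
    if len(levels) > 2:
        raise ValueError("group must be two-level")
    # lower numeric code = young (old coded 1 downstream in mediation)
    return (arr == levels[0]).astype(float)


def _gender_indicator(gender: np.ndarray) -> np.ndarray:
    arr = np.asarray(gender)
    if arr.dtype.kind in "USO":
        arr = arr.astype(str)
        levels = np.unique(arr)
        return (arr == levels[-1]).astype(float)
    return arr.astype(float)


@dataclass
class TaskRelatednessTable:
    """Within/between group t and p values per component and contrast."""

    components: list[int]
    contrast_names: list[str]
    t_within: np.ndarray  # 2 x components x contrasts (young, old)
    p_within: np.ndarray
    t_between: np.ndarray  # components x contrasts
    p_between: np.ndarray
    family_size: int
    alpha: float = ALPHA

    @property
    def task_related(self) -> np.ndarray:
        thr = self.alpha / self.family_size
        return (self.p_within < thr).any(axis=(0, 2))


def component_group_tests(
    values: np.ndarray,
    group: np.ndarray,
    gender: np.ndarray,
    components: list[int] | None = None,
    contrast_names: list[str] | None = None,
    family_size: int | None = None,
    alpha: float = ALPHA,
) -> TaskRelatednessTable:
    """Within- and between-group tests for subjects x components x contrasts.

    ``family_size`` defaults to components x contrasts x 2 groups — the
    full set of within-group decisions made.
    """
    values = np.asarray(values, dtype=float)
    n_sub, n_comp, n_con = values.shape
    if components is None:
        components = list(range(n_comp))
    if contrast_names is None:
        contrast_names = [f"contrast{i}" for i in range(n_con)]
    young = _young_indicator(group).astype(bool)
    if family_size is None:
        family_size = n_comp * n_con * 2

    t_w = np.empty((2, n_comp, n_con))
    p_w = np.empty((2, n_comp, n_con))
    t_b = np.empty((n_comp, n_con))
    p_b = np.empty((n_comp, n_con))
    for c in range(n_comp):
        for k in range(n_con):
            for gi, sel in enumerate((young, ~young)):
                t_w[gi, c, k], p_w[gi, c, k] = within_group_test(
                    values[sel, c, k], np.asarray(gender)[sel]
                )
            t_b[c, k], p_b[c, k] = between_group_test(
                values[:, c, k], group, gender
            )
    return TaskRelatednessTable(
        components=components,
        contrast_names=contrast_names,
        t_within=t_w,
        p_within=p_w,
        t_between=t_b,
        p_between=p_b,
        family_size=family_size,
        alpha=alpha,
    )


def classify_task_related(table: TaskRelatednessTable) -> tuple[list[int], list[int]]:
    """Bonferroni task-relatedness: significant in at least one age group.

    Returns (retained components, excluded components), both sorted.
    """
    related = table.task_related
    retained = sorted(c for c, r in zip(table.components, related) if r)
    excluded = sorted(c for c, r in zip(table.components, related) if not r)
    return retained, excluded
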