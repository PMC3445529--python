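"""Single-mediator mediation with stratified bootstrap BC percentile CIs.

Two causal questions are posed of the aging data: does functional network
connectivity (an FNC edge's Fisher z) mediate the effect of age group on
speeded task performance (sRT), and does global brain volume (nWBV)
mediate the effect of age group on FNC. Age group is binary (old = 1,
young = 0), gender enters every regression as a centered covariate, and
the indirect effect a*b is interval-estimated by a stratified bootstrap
(resampling within each age group, preserving the group sizes) with
bias-corrected percentile confidence intervals.

Paths: c total effect (y ~ x), a exposure->mediator (m ~ x), b
mediator->outcome adjusted for exposure, c' direct effect (both from
y ~ x + m). With identical covariates in all three OLS fits the exact
decomposition c = c' + a*b holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_N_BOOT = 10_000
DEFAULT_CI_LEVEL = 0.95


@dataclass
class MediationSpec:
    """Inputs for one mediation model.

    x is the binary exposure (old = 1, young = 0); m the mediator; y the
    outcome; covariates (e.g. gender) are centered internally.
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    covariates: np.ndarray | None = None
    n_boot: int = DEFAULT_N_BOOT
    ci_level: float = DEFAULT_CI_LEVEL
    seed: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.m = np.asarray(self.m, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = len(self.x)
        if len(self.m) != n or len(self.y) != n:
            raise ValueError("x, m, y must have equal length")
        if self.covariates is not None:
            cov = np.asarray(self.covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            if cov.shape[0] != n:
                raise ValueError("covariates must match subject count")
            self.covariates = cov - cov.mean(axis=0, keepdims=True)
        levels = np.unique(self.x)
        if len(levels) != 2:
            raise ValueError("x must be binary (two groups present)")


@dataclass
class MediationResult:
    c: float
    a: float
    b: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float
    boot_mean: float
    boot_sd: float
    n_redrawn: int = 0

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


def _design(x_cols: list[np.ndarray], cov: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x_cols[0])] + x_cols
    X = np.column_stack(cols)
    if cov is not None:
        X = np.column_stack([X, cov])
    return X


def _solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
        warnings.warn("collinear covariates: using pseudo-inverse",
                      RuntimeWarning)
        return np.linalg.pinv(X) @ y
    return np.linalg.solve(XtX, X.T @ y)


def fit_paths(spec: MediationSpec) -> tuple[float, float, float, float]:
    """OLS path coefficients (a, b, c, c_prime), all gender-adjusted."""
    cov = spec.covariates
    c = _solve(_design([spec.x], cov), spec.y)[1]
    a = _solve(_design([spec.x], cov), spec.m)[1]
    bc = _solve(_design([spec.x, spec.m], cov), spec.y)
    c_prime, b = bc[1], bc[2]
    return float(a), float(b), float(c), float(c_prime)


def _indirect_batched(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, cov: np.ndarray | None,
    idx: np.ndarray,
) -> np.ndarray:
    """a*b for a batch of resampled datasets (idx: replicates x n)."""
    B, n = idx.shape
    xs = x[idx]
    ms = m[idx]
    ys = y[idx]
    ones = np.ones((B, n))
    cols_a = [ones, xs]
    cols_b = [ones, xs, ms]
    if cov is not None:
        cov_s = cov[idx]  # B x n x k
        cols_a += [cov_s[:, :, j] for j in range(cov.shape[1])]
        cols_b += [cov_s[:, :, j] for j in range(cov.shape[1])]
    Xa = np.stack(cols_a, axis=2)  # B x n x p
    Xb = np.stack(cols_b, axis=2)
    beta_a = np.linalg.solve(
        np.einsum("bnp,bnq->bpq", Xa, Xa),
        np.einsum("bnp,bn->bp", Xa, ms)[..., None],
    )[..., 0]
    beta_b = np.linalg.solve(
        np.einsum("bnp,bnq->bpq", Xb, Xb),
        np.einsum("bnp,bn->bp", Xb, ys)[..., None],
    )[..., 0]
    return beta_a[:, 1] * beta_b[:, 2]


def stratified_bootstrap(
    spec: MediationSpec, statistic=None
) -> tuple[np.ndarray, int]:
    """Bootstrap sample of the indirect effect under stratified resampling.

    Each replicate draws, with replacement, exactly n_young subjects from
    the young stratum and n_old from the old stratum (the age-group sample
    sizes are preserved exactly). ``statistic`` defaults to the indirect
    effect a*b recomputed on the replicate; a custom callable receives
    ``(x, m, y, covariates)`` arrays for one replicate. Replicates with a
    degenerate (zero-variance) mediator or outcome are redrawn; the redraw
    count is returned alongside the sample.
    """
    rng = np.random.default_rng(spec.seed)
    strata = [np.flatnonzero(spec.x == v) for v in np.unique(spec.x)]
    n = len(spec.x)
    B = spec.n_boot

    def draw(k: int) -> np.ndarray:
        idx = np.empty((k, n), dtype=np.intp)
        pos = 0
        for s in strata:
            idx[:, pos : pos + len(s)] = s[rng.integers(0, len(s), size=(k, len(s)))]
            pos += len(s)
        return idx

    idx = draw(B)
    n_redrawn = 0
    for _ in range(100):  # redraw degenerate replicates
        bad = (np.ptp(spec.m[idx], axis=1) == 0) | (np.ptp(spec.y[idx], axis=1) == 0)
        if spec.covariates is not None:
            # a covariate constant within every stratum aliases the
            # intercept/group columns (e.g. all-male young, all-female old)
            for j in range(spec.covariates.shape[1]):
                cov_j = spec.covariates[idx, j]
                const_all = np.ones(len(idx), dtype=bool)
                pos = 0
                for s in strata:
                    block = cov_j[:, pos : pos + len(s)]
                    const_all &= np.ptp(block, axis=1) == 0
                    pos += len(s)
                bad |= const_all
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        idx[bad] = draw(int(bad.sum()))

    if statistic is None:
        boot = _indirect_batched(spec.x, spec.m, spec.y, spec.covariates, idx)
    else:
        cov = spec.covariates
        boot = np.array([
            statistic(
                spec.x[row], spec.m[row], spec.y[row],
                cov[row] if cov is not None else None,
            )
            for row in idx
        ])
    return boot, n_redrawn


def bc_percentile_ci(
    boot: np.ndarray, point: float, level: float = DEFAULT_CI_LEVEL
) -> tuple[float, float]:
    """Bias-corrected (BC, no acceleration) percentile confidence interval.

    z0 = Phi^-1 of the fraction of bootstrap values below the point
    estimate (ties counted as half); the interval endpoints are the
    bootstrap percentiles at Phi(2 z0 + z_{alpha/2}) and
    Phi(2 z0 + z_{1-alpha/2}).
    """
    boot = np.asarray(boot, dtype=float)
    B = len(boot)
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap distribution", RuntimeWarning)
        return float(point), float(point)
    frac = (np.sum(boot < point) + 0.5 * np.sum(boot == point)) / B
    frac = np.clip(frac, 1.0 / B, 1.0 - 1.0 / B)  # clamp degenerate z0
    z0 = stats.norm.ppf(frac)
    alpha = 1.0 - level
    zlo, zhi = stats.norm.ppf(alpha / 2.0), stats.norm.ppf(1.0 - alpha / 2.0)
    plo = stats.norm.cdf(2.0 * z0 + zlo)
    phi = stats.norm.cdf(2.0 * z0 + zhi)
    lo, hi = np.quantile(boot, [plo, phi])
    return float(lo), float(hi)


def mediation_test(spec: MediationSpec) -> MediationResult:
    """Full mediation analysis: paths, stratified bootstrap, BC interval."""
    a, b, c, c_prime = fit_paths(spec)
    boot, n_redrawn = stratified_bootstrap(spec)
    lo, hi = bc_percentile_ci(boot, a * b, spec.ci_level)
    return MediationResult(
        c=c, a=a, b=b, c_prime=c_prime, indirect=a * b,
        ci_low=lo, ci_high=hi,
        n_boot=spec.n_boot, ci_level=spec.ci_level,
        boot_mean=float(boot.mean()), boot_sd=float(boot.std(ddof=1)),
        n_redrawn=n_redrawn,
    )
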