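"""Discrete gLV fitting by gradient-matching ridge regression.

Dividing the gLV equation by x_i gives d(ln x_i)/dt = b_i + sum_j a_ij x_j:
between consecutive samples the finite-difference log growth rate of each
taxon is a linear function of the community state at the interval start.
Each taxon is therefore fit by a ridge-regularized linear model with an
unpenalized intercept (the intrinsic growth rate).

Compositional caveat: abundances here are relative, so fitted
coefficients describe the dynamics of proportions, not absolute
densities; this matches the data the method is designed for.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.linear_model import Ridge

from .models import GLVModel, RegressionSystem, TimeSeriesProfile
from .synthetic import simulate_glv

__all__ = [
    "build_regression_system",
    "pool_regression_systems",
    "fit_glv",
    "predict_trajectory",
    "choose_lambda",
]

#: Intervals longer than this (days) are excluded by default: a single long
#: fasting gap would otherwise dominate the finite-difference responses.
DEFAULT_GAP_THRESHOLD = 5.0


def build_regression_system(
    profile: TimeSeriesProfile,
    pseudo: float | None = None,
    gap_threshold: float | None = DEFAULT_GAP_THRESHOLD,
    predictor: str = "start",
) -> RegressionSystem:
    """Lay out the per-interval gradient-matching regression.

    Zeros are replaced by ``pseudo`` (default: half the smallest nonzero
    relative abundance in the profile) before taking logs.  Responses are
    divided by each interval's own width, so uneven sampling (6 h vs 12 h)
    is handled directly; intervals wider than ``gap_threshold`` days are
    dropped (pass ``None`` to keep all).

    ``predictor`` selects where community abundances enter the design:
    ``"start"`` (explicit-Euler convention, the default) or
    ``"midpoint"`` (interval mean, second-order accurate — preferred for
    densely sampled data).
    """
    if predictor not in ("start", "midpoint"):
        raise ValueError("predictor must be 'start' or 'midpoint'")
    if profile.n_times < 3:
        raise ValueError("need at least 3 time points for gradient matching")
    x = profile.abundances.copy()
    if pseudo is None:
        nonzero = x[x > 0]
        pseudo = float(nonzero.min()) / 2.0
    x = np.where(x > 0, x, pseudo)

    dt_all = np.diff(profile.times)
    keep = np.ones(len(dt_all), dtype=bool)
    if gap_threshold is not None:
        keep = dt_all <= gap_threshold
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable intervals after gap exclusion")

    logx = np.log(x)
    starts = np.where(keep)[0]
    if predictor == "midpoint":
        pred = 0.5 * (x[:, starts] + x[:, starts + 1])
    else:
        pred = x[:, starts]
    design = np.column_stack([np.ones(len(starts)), pred.T])
    responses = (logx[:, starts + 1] - logx[:, starts]) / dt_all[starts]
    return RegressionSystem(
        taxa=list(profile.taxa),
        design=design,
        responses=responses,
        dt=dt_all[starts],
    )


def pool_regression_systems(systems: list[RegressionSystem]) -> RegressionSystem:
    """Stack the intervals of several profiles of the same community.

    Useful when replicate hosts (or repeated runs) observe one community:
    the pooled design is far better conditioned than any single
    trajectory's.  All systems must share the taxon list.
    """
    if not systems:
        raise ValueError("need at least one system")
    taxa = systems[0].taxa
    for s in systems[1:]:
        if s.taxa != taxa:
            raise ValueError("all systems must share one taxon list")
    return RegressionSystem(
        taxa=list(taxa),
        design=np.vstack([s.design for s in systems]),
        responses=np.hstack([s.responses for s in systems]),
        dt=np.concatenate([s.dt for s in systems]),
    )


def fit_glv(system: RegressionSystem, lam: float = 1e-3) -> GLVModel:
    """Solve the per-taxon ridge regressions and assemble a GLVModel.

    ``lam`` penalizes the interaction coefficients only; the intercept
    (growth rate) is unpenalized.  At ``lam=0`` a rank-deficient design
    is rejected rather than silently pseudo-inverted.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = system.design[:, 1:]
    n = len(system.taxa)
    if lam == 0 and np.linalg.matrix_rank(system.design) < n + 1:
        raise np.linalg.LinAlgError(
            "design is rank-deficient at lambda=0; use lambda > 0"
        )
    b = np.empty(n)
    a = np.empty((n, n))
    ridge = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
    for i in range(n):
        ridge.fit(X, system.responses[i])
        b[i] = ridge.intercept_
        a[i] = ridge.coef_
    # Self-limitation can be lost to shrinkage on degenerate data; nudge the
    # diagonal below zero so the result is always a valid gLV model.
    diag = np.diag(a).copy()
    bad = diag >= 0
    if bad.any():
        warnings.warn(
            f"{bad.sum()} non-negative self-interaction(s) clamped to a small "
            "negative value",
            stacklevel=2,
        )
        diag[bad] = -1e-12
        a[np.diag_indices(n)] = diag
    return GLVModel(taxa=list(system.taxa), growth_rates=b, interactions=a)


def choose_lambda(
    system: RegressionSystem,
    grid: np.ndarray | None = None,
) -> float:
    """Leave-one-interval-out cross-validation for the ridge penalty.

    The mean squared prediction error is pooled across taxa and the
    penalty with the smallest pooled error wins.
    """
    if grid is None:
        grid = np.logspace(-6, 1, 15)
    m = system.n_intervals
    errors = np.zeros(len(grid))
    X = system.design[:, 1:]
    for g, lam in enumerate(grid):
        ridge = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
        sse = 0.0
        for k in range(m):
            mask = np.arange(m) != k
            for i in range(len(system.taxa)):
                ridge.fit(X[mask], system.responses[i, mask])
                pred = ridge.predict(X[k : k + 1])[0]
                sse += (pred - system.responses[i, k]) ** 2
        errors[g] = sse
    return float(grid[int(np.argmin(errors))])


def predict_trajectory(
    model: GLVModel, x0: np.ndarray, times: np.ndarray
) -> TimeSeriesProfile:
    """Noise-free forward simulation of a fitted model (fit diagnostics)."""
    return simulate_glv(model, x0, times, noise_sd=0.0)
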