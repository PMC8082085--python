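"""Encoding model: Poisson GLM with task-event kernels.

Predicts a unit's binned spike counts during the late odor-sampling
analysis span — from 370 ms after odor onset (the median go-cue
excitation onset) to the odor port exit — from two groups of temporal
basis functions: one anchored at odor onset ("odor_onset", the
odor-triggered component) and one anchored at the odor port exit with a
negative window ("pre_port_exit", the pre-movement component).

Each variable's *relative contribution* is the drop in cross-validated
deviance-explained when that variable group is removed, clipped at zero
and normalized across groups.  A unit whose response is locked to odor
onset (with jittered exit latency) loads on the odor_onset group; a
pre-movement ramp loads on pre_port_exit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import PoissonRegressor
from sklearn.model_selection import GroupKFold

from .session_io import Session, TrialEvents, UnitSpikeTrain

__all__ = [
    "VariableSpec",
    "DesignSpec",
    "DesignMatrix",
    "GLMFit",
    "raised_cosine_basis",
    "build_design_matrix",
    "fit_glm",
    "relative_contribution",
    "psth_reconstruction_r",
]

ANALYSIS_START_AFTER_ODOR_ON = 0.370  # s


@dataclass(frozen=True)
class VariableSpec:
    name: str
    anchor_event: str  # e.g. "odor_on" or "port_exit"
    window: tuple[float, float]  # relative to anchor, s
    n_basis: int = 8
    basis: str = "raised_cosine"  # or "boxcar"

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError(f"{self.name}: empty window")
        if self.n_basis < 1:
            raise ValueError(f"{self.name}: need >= 1 basis function")


@dataclass(frozen=True)
class DesignSpec:
    variables: tuple[VariableSpec, ...] = (
        VariableSpec("odor_onset", "odor_on", (ANALYSIS_START_AFTER_ODOR_ON, 0.90)),
        VariableSpec("pre_port_exit", "port_exit", (-0.30, 0.0)),
    )
    bin_width: float = 0.020
    span_start: float = ANALYSIS_START_AFTER_ODOR_ON  # s after odor_on
    # analysis span end is the odor port exit

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]


def raised_cosine_basis(
    window: tuple[float, float], n_basis: int, t: np.ndarray
) -> np.ndarray:
    """cos² bumps tiling a window; interior sum is exactly 1.

    Centers are evenly spaced over the window with spacing d; each bump
    is cos²(π(t−c)/(2d)) on |t−c| ≤ d, so only neighbours overlap and
    cos² + sin² keeps the partition flat away from the edges.
    """
    w0, w1 = window
    if n_basis == 1:
        out = np.zeros((t.size, 1))
        out[(t >= w0) & (t < w1), 0] = 1.0
        return out
    centers = np.linspace(w0, w1, n_basis)
    d = centers[1] - centers[0]
    out = np.zeros((t.size, n_basis))
    for j, c in enumerate(centers):
        u = (t - c) / d
        m = np.abs(u) <= 1.0
        out[m, j] = np.cos(np.pi * u[m] / 2.0) ** 2
    return out


def boxcar_basis(
    window: tuple[float, float], n_basis: int, t: np.ndarray
) -> np.ndarray:
    """Contiguous indicator bins partitioning the window."""
    edges = np.linspace(window[0], window[1], n_basis + 1)
    out = np.zeros((t.size, n_basis))
    for j in range(n_basis):
        out[(t >= edges[j]) & (t < edges[j + 1]), j] = 1.0
    return out


def _evaluate_basis(var: VariableSpec, t_rel: np.ndarray) -> np.ndarray:
    if var.basis == "raised_cosine":
        return raised_cosine_basis(var.window, var.n_basis, t_rel)
    if var.basis == "boxcar":
        return boxcar_basis(var.window, var.n_basis, t_rel)
    raise ValueError(f"unknown basis {var.basis!r}")


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_bins_total, n_predictors)
    y: np.ndarray  # spike counts per bin
    groups: np.ndarray  # trial id per row (for blocked CV)
    rel_onset: np.ndarray  # bin center − odor_on per row
    rel_exit: np.ndarray  # bin center − port_exit per row
    column_variable: np.ndarray  # variable name per column
    spec: DesignSpec
    n_trials: int
    n_dropped_trials: int

    def columns_of(self, variable: str) -> np.ndarray:
        return np.where(self.column_variable == variable)[0]


def build_design_matrix(
    unit: UnitSpikeTrain,
    session: Session,
    spec: DesignSpec | None = None,
    trials: Sequence[TrialEvents] | None = None,
    min_trials: int = 20,
) -> DesignMatrix:
    """Concatenated analysis-span bins of correct go trials.

    Rows are 20 ms bins of ``[odor_on + 370 ms, port_exit)`` per trial;
    trials whose span is empty are dropped (counted).  Columns are the
    basis functions of each variable, evaluated at the bin centers
    relative to that variable's anchor event.
    """
    spec = spec or DesignSpec()
    if trials is None:
        trials = session.select_trials("go", "correct", "go-cue")
    rows_X, rows_y, rows_g, rows_on, rows_ex = [], [], [], [], []
    n_dropped = 0
    for trial in trials:
        t0 = trial.odor_on + spec.span_start
        t1 = trial.port_exit
        n_bins = int(np.floor((t1 - t0) / spec.bin_width))
        if n_bins < 1:
            n_dropped += 1
            continue
        centers = t0 + spec.bin_width * (np.arange(n_bins) + 0.5)
        edges = t0 + spec.bin_width * np.arange(n_bins + 1)
        counts = np.diff(np.searchsorted(unit.spike_times, edges))
        cols = []
        for var in spec.variables:
            anchor = trial.event_time(var.anchor_event)
            cols.append(_evaluate_basis(var, centers - anchor))
        rows_X.append(np.hstack(cols))
        rows_y.append(counts)
        rows_g.append(np.full(n_bins, trial.trial_id))
        rows_on.append(centers - trial.odor_on)
        rows_ex.append(centers - trial.port_exit)
    n_used = len(rows_y)
    if n_used < min_trials:
        raise ValueError(
            f"unit {unit.unit_id}: only {n_used} usable trials (< {min_trials})"
        )
    column_variable = np.concatenate(
        [[v.name] * v.n_basis for v in spec.variables]
    )
    return DesignMatrix(
        X=np.vstack(rows_X),
        y=np.concatenate(rows_y).astype(float),
        groups=np.concatenate(rows_g),
        rel_onset=np.concatenate(rows_on),
        rel_exit=np.concatenate(rows_ex),
        column_variable=np.asarray(column_variable),
        spec=spec,
        n_trials=n_used,
        n_dropped_trials=n_dropped,
    )


# ---------------------------------------------------------------------------
# fitting


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


@dataclass
class GLMFit:
    coefficients: np.ndarray  # full model, fitted on all rows
    intercept: float
    alpha: float  # ridge strength actually used
    r2_full: float  # cross-validated deviance explained
    r2_reduced: dict[str, float]
    relative_contribution: dict[str, float]
    cv_mu: np.ndarray  # held-out predictions, aligned with design rows
    design: DesignMatrix
    warning: str | None = None


def _cv_deviance_explained(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    alpha: float,
    n_folds: int,
) -> tuple[float, np.ndarray]:
    """Pooled held-out deviance explained and per-row held-out mu."""
    gkf = GroupKFold(n_splits=n_folds)
    mu = np.empty_like(y)
    dev_model = 0.0
    dev_null = 0.0
    for tr, te in gkf.split(X, y, groups):
        model = PoissonRegressor(alpha=alpha, max_iter=300)
        model.fit(X[tr], y[tr])
        mu_te = model.predict(X[te])
        mu[te] = mu_te
        dev_model += _poisson_deviance(y[te], mu_te)
        dev_null += _poisson_deviance(y[te], np.full(te.size, y[tr].mean()))
    if dev_null <= 0:
        return 0.0, mu
    return 1.0 - dev_model / dev_null, mu


def fit_glm(
    design: DesignMatrix,
    alphas: Sequence[float] = (1e-4, 1e-2, 1.0),
    cv_folds: int = 5,
    seed: int = 0,
) -> GLMFit:
    """Ridge-penalized Poisson GLM with blocked cross-validation.

    The ridge strength is selected on the full model by grouped 3-fold
    CV over ``alphas`` and reused for the reduced models, so the full /
    reduced comparison is not confounded by different regularization.
    Deviance explained is computed on held-out trial blocks relative to
    an intercept-only model.  Fold assignment is by trial, so bins of
    one trial never straddle the train/test split.
    """
    X, y, groups = design.X, design.y, design.groups
    if X.shape[0] <= 10 * X.shape[1]:
        raise ValueError(
            f"too few rows ({X.shape[0]}) for {X.shape[1]} predictors"
        )
    # inner alpha selection on the full model
    best_alpha, best_score = alphas[0], -np.inf
    for alpha in alphas:
        score, _ = _cv_deviance_explained(X, y, groups, alpha, 3)
        if score > best_score:
            best_alpha, best_score = alpha, score

    r2_full, cv_mu = _cv_deviance_explained(X, y, groups, best_alpha, cv_folds)
    r2_reduced: dict[str, float] = {}
    for name in design.spec.variable_names:
        keep = design.column_variable != name
        r2_red, _ = _cv_deviance_explained(
            X[:, keep], y, groups, best_alpha, cv_folds
        )
        r2_reduced[name] = r2_red

    contrib, warning = relative_contribution_table(r2_full, r2_reduced)

    final = PoissonRegressor(alpha=best_alpha, max_iter=300)
    final.fit(X, y)
    return GLMFit(
        coefficients=final.coef_.copy(),
        intercept=float(final.intercept_),
        alpha=float(best_alpha),
        r2_full=float(r2_full),
        r2_reduced=r2_reduced,
        relative_contribution=contrib,
        cv_mu=cv_mu,
        design=design,
        warning=warning,
    )


def relative_contribution_table(
    r2_full: float, r2_reduced: dict[str, float]
) -> tuple[dict[str, float], str | None]:
    """Normalized per-variable contributions from full/reduced R²."""
    raw = {k: max(0.0, r2_full - v) for k, v in r2_reduced.items()}
    total = sum(raw.values())
    warning = None
    if total <= 0:
        warning = "no variable reduced the explained deviance; uniform split"
        warnings.warn(warning, stacklevel=2)
        n = len(raw)
        return {k: 1.0 / n for k in raw}, warning
    return {k: v / total for k, v in raw.items()}, warning


def relative_contribution(fit: GLMFit, variable: str) -> float:
    """Fraction of the total explained-variance loss owned by one variable."""
    return fit.relative_contribution[variable]


def psth_reconstruction_r(
    fit: GLMFit,
    align_event: str = "odor_on",
    grid_width: float = 0.020,
    min_trials_per_bin: int = 5,
) -> float | None:
    """Pearson r between held-out predicted and observed aligned PSTHs.

    Held-out per-bin predictions (from the outer CV folds) and observed
    counts are re-aligned to the chosen event, averaged across trials on
    a common grid, and correlated.  Returns None when the prediction is
    constant (correlation undefined).
    """
    d = fit.design
    if align_event == "odor_on":
        rel = d.rel_onset
    elif align_event == "port_exit":
        rel = d.rel_exit
    else:
        raise ValueError(f"unsupported alignment {align_event!r}")
    idx = np.round(rel / grid_width).astype(int)
    pred, obs = [], []
    for k in np.unique(idx):
        m = idx == k
        if m.sum() < min_trials_per_bin:
            continue
        pred.append(fit.cv_mu[m].mean())
        obs.append(d.y[m].mean())
    pred = np.asarray(pred)
    obs = np.asarray(obs)
    if pred.size < 3 or np.std(pred) < 1e-12 or np.std(obs) < 1e-12:
        return None
    return float(stats.pearsonr(pred, obs)[0])


def glm_summary_row(unit_id: str, fit: GLMFit) -> dict:
    """One row of the glm_fits.csv export."""
    r_on = psth_reconstruction_r(fit, "odor_on")
    r_ex = psth_reconstruction_r(fit, "port_exit")
    row = {"unit_id": unit_id, "r2_full": fit.r2_full}
    for name in fit.design.spec.variable_names:
        row[f"contrib_{name}"] = fit.relative_contribution[name]
    row["r_onset_aligned"] = np.nan if r_on is None else r_on
    row["r_exit_aligned"] = np.nan if r_ex is None else r_ex
    return row
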