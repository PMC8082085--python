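"""Population trajectory geometry: PCA subspaces, distance, velocity.

A pseudopopulation matrix (units × time bins × conditions) of
trial-averaged, smoothed, per-unit z-scored firing rates is the
substrate.  PCA over time-by-condition samples gives the odor-sampling
subspace and per-condition trajectories; the separation between the
go and no-go population vectors and the rate of change (velocity) of
each trajectory are compared against a baseline band (mean ± 2 SD of
pre-odor bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .psth import align_and_bin, smooth
from .session_io import Session, TrialEvents

__all__ = [
    "PopulationMatrix",
    "PCSubspace",
    "GeometryTrace",
    "build_population_matrix",
    "pca_subspace",
    "trajectory_distance",
    "trajectory_velocity",
    "neural_weights",
    "sliding_weights",
    "compare_weights_by_type",
    "TypeWeightComparison",
]

DEFAULT_CONDITIONS = ("go", "no-go")


@dataclass
class PopulationMatrix:
    data: np.ndarray  # (n_units, n_bins, n_conditions), normalized
    raw: np.ndarray  # same shape, before normalization (Hz)
    unit_ids: list[str]
    bin_centers: np.ndarray  # relative to align event, s
    conditions: tuple[str, ...]
    normalization: str  # "zscore" or "raw"
    norm_mean: np.ndarray  # per-unit
    norm_sd: np.ndarray  # per-unit
    excluded_units: list[str]

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    def denormalize(self) -> np.ndarray:
        """Invert the per-unit normalization (round-trip check)."""
        if self.normalization == "raw":
            return self.data.copy()
        return (
            self.data * self.norm_sd[:, None, None]
            + self.norm_mean[:, None, None]
        )


def build_population_matrix(
    sessions: Sequence[Session] | Session,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    align_event: str = "odor_on",
    window: tuple[float, float] = (0.2, 0.6),
    bin_width: float = 0.020,
    kernel_sd: float = 0.060,
    normalization: str = "zscore",
    min_trials: int = 10,
) -> PopulationMatrix:
    """Pseudopopulation of trial-averaged smoothed rates.

    Units are pooled across sessions; each unit's per-condition PSTH is
    computed from correct trials of that condition, then the unit's time
    courses are z-scored over the concatenated conditions (zero-variance
    units map to zeros).  Units lacking ``min_trials`` correct trials in
    any condition are excluded and reported.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    if normalization not in ("zscore", "raw"):
        raise ValueError("normalization must be 'zscore' or 'raw'")
    unit_rows: list[np.ndarray] = []
    unit_ids: list[str] = []
    excluded: list[str] = []
    bin_centers = None
    # pad the binning window by the kernel support and crop after
    # smoothing, so edge renormalization cannot inflate variance at the
    # boundary bins (which would bias the baseline significance band)
    pad = 4 * kernel_sd
    padded = (window[0] + pad, window[1] + pad)
    n_pad = int(round(pad / bin_width))
    for session in sessions:
        cond_trials = {}
        for cond in conditions:
            kind = "go-cue" if cond == "go" else "no-go-cue"
            cond_trials[cond] = session.select_trials(cond, "correct", kind)
        for unit in session.units:
            if any(len(cond_trials[c]) < min_trials for c in conditions):
                excluded.append(unit.unit_id)
                continue
            per_cond = []
            for cond in conditions:
                counts = align_and_bin(
                    unit, cond_trials[cond], align_event, padded, bin_width
                )
                psth = smooth(counts, kernel_sd)
                per_cond.append(psth.rate[n_pad:-n_pad])
                if bin_centers is None:
                    bin_centers = psth.bin_centers[n_pad:-n_pad]
            unit_rows.append(np.column_stack(per_cond))
            unit_ids.append(f"{session.session_id}/{unit.unit_id}"
                            if len(sessions) > 1 else unit.unit_id)
    if not unit_rows:
        raise ValueError("no units satisfied the per-condition trial minimum")
    raw = np.stack(unit_rows)  # (units, bins, conds)
    if normalization == "zscore":
        flat = raw.reshape(raw.shape[0], -1)
        mean = flat.mean(axis=1)
        sd = flat.std(axis=1)
        safe_sd = np.where(sd > 0, sd, 1.0)
        data = (raw - mean[:, None, None]) / safe_sd[:, None, None]
        data[sd == 0] = 0.0
    else:
        mean = np.zeros(raw.shape[0])
        sd = np.ones(raw.shape[0])
        data = raw.copy()
    return PopulationMatrix(
        data=data,
        raw=raw,
        unit_ids=unit_ids,
        bin_centers=bin_centers,
        conditions=tuple(conditions),
        normalization=normalization,
        norm_mean=mean,
        norm_sd=np.where(sd > 0, sd, 0.0) if normalization == "zscore" else sd,
        excluded_units=excluded,
    )


@dataclass
class PCSubspace:
    loadings: np.ndarray  # (n_units, k), orthonormal columns
    explained_variance_ratio: np.ndarray
    trajectories: dict[str, np.ndarray]  # condition -> (k, n_bins)
    bin_centers: np.ndarray


def pca_subspace(matrix: PopulationMatrix, k: int = 3) -> PCSubspace:
    """PCA of the population over concatenated condition time courses.

    Samples are time bins of both conditions (joint fit, giving one
    shared subspace); features are units.  Trajectories are the
    per-condition projections onto the leading components.
    """
    n_units, n_bins, n_cond = matrix.data.shape
    if n_units < k:
        raise ValueError(f"k={k} exceeds the {n_units} available units")
    # samples = bins*conds, features = units
    samples = matrix.data.reshape(n_units, n_bins * n_cond).T
    rank = np.linalg.matrix_rank(samples - samples.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(samples)
    loadings = pca.components_.T  # (units, k)
    trajectories = {}
    for ci, cond in enumerate(matrix.conditions):
        cond_data = matrix.data[:, :, ci]  # (units, bins)
        centered = cond_data.T - pca.mean_
        trajectories[cond] = (centered @ loadings).T  # (k, bins)
    return PCSubspace(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        trajectories=trajectories,
        bin_centers=matrix.bin_centers,
    )


@dataclass
class GeometryTrace:
    kind: str  # "distance" or "velocity"
    bin_centers: np.ndarray
    values: np.ndarray
    baseline_mean: float
    baseline_sd: float
    significant: np.ndarray  # values > mean + 2 SD
    condition: str | None = None

    def first_significant_time(self) -> float | None:
        idx = np.flatnonzero(self.significant)
        return float(self.bin_centers[idx[0]]) if idx.size else None


def _baseline_band(
    centers: np.ndarray, values: np.ndarray, baseline_window: tuple[float, float]
) -> tuple[float, float, np.ndarray]:
    in_base = (centers >= baseline_window[0]) & (centers < baseline_window[1])
    if in_base.sum() < 3:
        raise ValueError("fewer than 3 baseline bins for the significance band")
    mean = float(values[in_base].mean())
    sd = float(values[in_base].std())
    flags = values > mean + 2 * sd
    return mean, sd, flags


def trajectory_distance(
    matrix: PopulationMatrix,
    subspace: PCSubspace | None = None,
    baseline_window: tuple[float, float] = (-0.2, 0.0),
) -> GeometryTrace:
    """Per-bin Euclidean separation between the two condition vectors.

    Computed in the full normalized space by default; pass a fitted
    subspace to measure within the leading components instead.  Bins
    exceeding the baseline mean + 2 SD are flagged.
    """
    if matrix.data.shape[2] != 2:
        raise ValueError("distance needs exactly two conditions")
    if subspace is None:
        a = matrix.data[:, :, 0]
        b = matrix.data[:, :, 1]
    else:
        a = subspace.trajectories[matrix.conditions[0]]
        b = subspace.trajectories[matrix.conditions[1]]
    values = np.linalg.norm(a - b, axis=0)
    mean, sd, flags = _baseline_band(matrix.bin_centers, values, baseline_window)
    return GeometryTrace(
        kind="distance",
        bin_centers=matrix.bin_centers.copy(),
        values=values,
        baseline_mean=mean,
        baseline_sd=sd,
        significant=flags,
    )


def trajectory_velocity(
    matrix: PopulationMatrix,
    condition: str,
    width: float = 0.100,
    step: float = 0.020,
    baseline_window: tuple[float, float] = (-0.2, 0.0),
) -> GeometryTrace:
    """Rate of change of one condition's population vector.

    ‖x(t + w) − x(t)‖ / w evaluated every ``step``; the trace is indexed
    by the midpoint t + w/2.
    """
    ci = matrix.conditions.index(condition)
    x = matrix.data[:, :, ci]  # (units, bins)
    centers = matrix.bin_centers
    dt = centers[1] - centers[0]
    lag = int(round(width / dt))
    if lag < 1 or lag >= centers.size:
        raise ValueError("velocity window must span >= 2 bins")
    stride = max(1, int(round(step / dt)))
    idx0 = np.arange(0, centers.size - lag, stride)
    vals = (
        np.linalg.norm(x[:, idx0 + lag] - x[:, idx0], axis=0) / width
    )
    mid = centers[idx0] + width / 2.0
    mean, sd, flags = _baseline_band(mid, vals, baseline_window)
    return GeometryTrace(
        kind="velocity",
        bin_centers=mid,
        values=vals,
        baseline_mean=mean,
        baseline_sd=sd,
        significant=flags,
        condition=condition,
    )


def neural_weights(subspace: PCSubspace, dimension: int = 1) -> np.ndarray:
    """Per-unit |loading| on one principal component (1-based index)."""
    return np.abs(subspace.loadings[:, dimension - 1])


def sliding_weights(
    matrix: PopulationMatrix,
    width: float = 0.100,
    step: float = 0.020,
) -> tuple[np.ndarray, np.ndarray]:
    """|PC1 loading| per unit in each sliding window.

    Returns (window_centers, weights) with weights shaped
    (n_units, n_windows); degenerate windows (zero variance) yield NaN.
    """
    n_units, n_bins, n_cond = matrix.data.shape
    centers = matrix.bin_centers
    dt = centers[1] - centers[0]
    span = max(2, int(round(width / dt)))
    stride = max(1, int(round(step / dt)))
    starts = np.arange(0, n_bins - span + 1, stride)
    out = np.full((n_units, starts.size), np.nan)
    mid = centers[starts] + (span - 1) * dt / 2.0
    for wi, s in enumerate(starts):
        seg = matrix.data[:, s : s + span, :].reshape(n_units, -1).T
        if np.allclose(seg.std(axis=0), 0):
            continue
        pca = PCA(n_components=1, svd_solver="full")
        pca.fit(seg)
        out[:, wi] = np.abs(pca.components_[0])
    return mid, out


@dataclass
class TypeWeightComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # pairwise table (group1, group2, meandiff, p-adj, reject)
    group_means: dict[str, float]


def compare_weights_by_type(
    weights: np.ndarray, type_labels: Sequence[str]
) -> TypeWeightComparison:
    """One-way ANOVA of per-unit weights across neuron types + Tukey HSD."""
    labels = np.asarray(type_labels)
    groups = [weights[labels == t] for t in np.unique(labels)]
    groups = [g for g in groups if g.size >= 3]
    if len(groups) < 2:
        raise ValueError("need >= 2 types with >= 3 units each")
    f, p = stats.f_oneway(*groups)
    keep = np.isin(labels, [t for t in np.unique(labels)
                            if (labels == t).sum() >= 3])
    tk = pairwise_tukeyhsd(weights[keep], labels[keep])
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    means = {
        str(t): float(weights[labels == t].mean()) for t in np.unique(labels)
    }
    return TypeWeightComparison(
        f_statistic=float(f), p_value=float(p), tukey=tukey_df,
        group_means=means,
    )
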