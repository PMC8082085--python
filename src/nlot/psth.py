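"""Event-aligned binning, Gaussian smoothing, and epoch firing rates.

All analyses bin spikes into half-open 20 ms bins aligned to a task
event and, where a rate estimate is needed, smooth with a 60 ms-SD
Gaussian kernel (truncated-kernel renormalization at the window edges,
so a constant rate stays constant up to the boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .session_io import TrialEvents, UnitSpikeTrain, epoch_bounds

__all__ = [
    "AlignedCounts",
    "SmoothedPSTH",
    "align_and_bin",
    "smooth",
    "epoch_rates",
    "event_aligned_histogram_series",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_KERNEL_SD",
]

DEFAULT_BIN_WIDTH = 0.020  # s
DEFAULT_KERNEL_SD = 0.060  # s


@dataclass(frozen=True)
class AlignedCounts:
    """Trial × bin spike-count matrix aligned to one event.

    Bin ``b`` covers ``[event − pre + b·w, event − pre + (b+1)·w)``;
    a spike exactly on an edge falls in the later bin.
    """

    unit_id: str
    align_event: str
    window: tuple[float, float]  # (pre, post), both >= 0, seconds
    bin_width: float
    matrix: np.ndarray  # (n_trials, n_bins) int
    trial_ids: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def bin_edges(self) -> np.ndarray:
        pre, post = self.window
        return -pre + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class SmoothedPSTH:
    """Trial-averaged smoothed firing rate (Hz) on the AlignedCounts grid."""

    unit_id: str
    align_event: str
    window: tuple[float, float]
    bin_width: float
    bin_centers: np.ndarray
    rate: np.ndarray  # (n_bins,) Hz
    kernel_sd: float
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_s": self.bin_centers, "rate_hz": self.rate}
        )


def align_and_bin(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialEvents],
    event_name: str = "odor_on",
    window: tuple[float, float] = (0.5, 1.0),
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> AlignedCounts:
    """Bin spikes around an event, one row per trial.

    ``window = (pre, post)`` extends from ``pre`` seconds before to
    ``post`` seconds after the event.
    """
    pre, post = window
    if pre + post <= 0:
        raise ValueError("window must have positive total length")
    n_bins = int(round((pre + post) / bin_width))
    mat = np.zeros((len(trials), n_bins), dtype=int)
    trial_ids = np.empty(len(trials), dtype=int)
    for i, trial in enumerate(trials):
        t_event = trial.event_time(event_name)
        if t_event is None:
            raise ValueError(
                f"trial {trial.trial_id}: event {event_name!r} absent"
            )
        rel = unit.spike_times - (t_event - pre)
        # tiny epsilon (in bin units) keeps spikes that land exactly on a
        # bin edge in the later bin despite float cancellation error
        idx = np.floor(rel / bin_width + 1e-9).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        mat[i] = np.bincount(idx, minlength=n_bins)
        trial_ids[i] = trial.trial_id
    return AlignedCounts(
        unit_id=unit.unit_id,
        align_event=event_name,
        window=window,
        bin_width=bin_width,
        matrix=mat,
        trial_ids=trial_ids,
    )


def smooth(
    counts: AlignedCounts, kernel_sd: float = DEFAULT_KERNEL_SD
) -> SmoothedPSTH:
    """Trial-averaged rate smoothed with a Gaussian kernel.

    The kernel is discretized on the bin grid (support ±4 SD) and
    normalized to unit mass; at the window edges the truncated kernel is
    renormalized, which conserves total spike mass to within the kernel
    tail leakage and avoids edge rate suppression.
    """
    if counts.bin_width >= kernel_sd:
        raise ValueError("bin_width must be smaller than kernel_sd")
    mean_counts = counts.matrix.mean(axis=0)
    rate = mean_counts / counts.bin_width  # Hz, unsmoothed

    half = int(np.ceil(4 * kernel_sd / counts.bin_width))
    x = np.arange(-half, half + 1) * counts.bin_width
    kernel = np.exp(-0.5 * (x / kernel_sd) ** 2)
    kernel /= kernel.sum()

    smoothed = np.convolve(rate, kernel, mode="same")
    support = np.convolve(np.ones_like(rate), kernel, mode="same")
    smoothed = smoothed / support

    return SmoothedPSTH(
        unit_id=counts.unit_id,
        align_event=counts.align_event,
        window=counts.window,
        bin_width=counts.bin_width,
        bin_centers=counts.bin_centers,
        rate=smoothed,
        kernel_sd=kernel_sd,
        n_trials=counts.matrix.shape[0],
    )


def epoch_rates(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialEvents],
    epoch_name: str,
) -> np.ndarray:
    """Per-trial firing rate (Hz) in a named epoch: count / duration."""
    rates = np.empty(len(trials))
    for i, trial in enumerate(trials):
        start, end = epoch_bounds(trial, epoch_name)
        if end <= start:
            raise ValueError(
                f"trial {trial.trial_id}: zero-duration epoch {epoch_name!r}"
            )
        rates[i] = unit.count_in(start, end) / (end - start)
    return rates


def event_aligned_histogram_series(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialEvents],
    event_sequence: Sequence[tuple[str, tuple[float, float]]],
    bin_width: float = DEFAULT_BIN_WIDTH,
    kernel_sd: float = DEFAULT_KERNEL_SD,
) -> list[SmoothedPSTH]:
    """Event-aligned histogram segments along a trial's event sequence.

    ``event_sequence`` is a list of ``(event_name, (pre, post))``.
    Trials missing an event are excluded from that segment (a warning
    reports the count); segments are returned separately — variable
    inter-event latencies mean they must not be interpolated across.
    """
    segments: list[SmoothedPSTH] = []
    for event_name, window in event_sequence:
        present = [t for t in trials if t.event_time(event_name) is not None]
        n_missing = len(trials) - len(present)
        if n_missing:
            warnings.warn(
                f"{event_name}: {n_missing} trial(s) lack the event; excluded",
                stacklevel=2,
            )
        if not present:
            continue
        counts = align_and_bin(unit, present, event_name, window, bin_width)
        segments.append(smooth(counts, kernel_sd))
    return segments


def psth_to_csv(psth: SmoothedPSTH, path) -> None:
    """Export a PSTH with a bin-center header row."""
    psth.to_frame().to_csv(path, index=False)
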