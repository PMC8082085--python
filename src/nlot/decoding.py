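"""Sliding-window population decoding of trial type (go vs no-go).

Pseudotrials are assembled by resampling each unit's class-conditioned
trials independently (pooling units across sessions and destroying
within-session noise correlations — the standard pseudopopulation
construction).  A linear-kernel support vector machine is trained and
tested at every sliding window, yielding accuracy time courses for
increasing population sizes (neuron-dropping curves), a 50% chance
reference, and the smallest population whose accuracy reaches the
animals' behavioral accuracy.

Cross-validation is performed at the *source-trial* level: each unit's
real trials are split into folds first and pseudotrials are resampled
within the training and test sides separately.  Resampling before
splitting would let per-unit class-mean sampling noise leak across the
split and bias accuracy above chance on non-selective data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .session_io import Session, TrialEvents, UnitSpikeTrain

__all__ = [
    "PseudoTrialMatrix",
    "DecodingCurve",
    "build_pseudopopulation",
    "decode_accuracy",
    "decoding_timecourse",
]

CHANCE_LEVEL = 0.5


@dataclass
class PseudoTrialMatrix:
    """Balanced pseudotrial spike counts for one sliding window.

    ``counts``/``labels`` hold one draw of the resampled matrix (go
    label 1, no-go 0, ``n_pseudotrials`` rows per class).  The per-unit
    source-trial counts are retained so cross-validation can re-split
    and re-resample at the source level.
    """

    counts: np.ndarray  # (2 * n_pseudotrials, n_units)
    labels: np.ndarray
    window: tuple[float, float]  # relative to align event, s
    unit_ids: list[str]
    seed: int
    source_go: list[np.ndarray]  # per unit, per real-trial counts
    source_nogo: list[np.ndarray]

    @property
    def n_pseudotrials(self) -> int:
        return int((self.labels == 1).sum())


def _window_counts(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialEvents],
    align_event: str,
    window: tuple[float, float],
) -> np.ndarray:
    out = np.empty(len(trials))
    for i, t in enumerate(trials):
        t0 = t.event_time(align_event)
        out[i] = unit.count_in(t0 + window[0], t0 + window[1])
    return out


def _pooled_units(
    sessions: Sequence[Session] | Session,
) -> list[tuple[Session, UnitSpikeTrain]]:
    if isinstance(sessions, Session):
        sessions = [sessions]
    return [(s, u) for s in sessions for u in s.units]


def _resample(
    sources: Sequence[np.ndarray], n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_units) matrix, each column resampled independently."""
    return np.column_stack(
        [src[rng.integers(src.size, size=n)] for src in sources]
    )


def build_pseudopopulation(
    sessions: Sequence[Session] | Session,
    window: tuple[float, float],
    n_units: int,
    n_pseudotrials: int = 100,
    align_event: str = "odor_on",
    seed: int = 0,
    min_trials: int = 10,
) -> PseudoTrialMatrix:
    """Sample units and build a balanced pseudotrial matrix.

    ``n_units`` units are sampled without replacement from the pooled
    sessions (units lacking ``min_trials`` correct trials per class are
    unusable); each unit's correct go and no-go trials are resampled
    with replacement, independently per unit, to ``n_pseudotrials``
    rows per class.
    """
    pool = _pooled_units(sessions)
    rng = np.random.default_rng(seed)
    usable = []
    for s, u in pool:
        n_go = len(s.select_trials("go", "correct", "go-cue"))
        n_ng = len(s.select_trials("no-go", "correct", "no-go-cue"))
        if n_go >= min_trials and n_ng >= min_trials:
            usable.append((s, u))
    if n_units > len(usable):
        raise ValueError(
            f"requested {n_units} units but only {len(usable)} usable"
        )
    chosen_idx = rng.choice(len(usable), size=n_units, replace=False)
    source_go, source_nogo, uids = [], [], []
    for idx in chosen_idx:
        s, u = usable[int(idx)]
        go_trials = s.select_trials("go", "correct", "go-cue")
        ng_trials = s.select_trials("no-go", "correct", "no-go-cue")
        source_go.append(_window_counts(u, go_trials, align_event, window))
        source_nogo.append(_window_counts(u, ng_trials, align_event, window))
        uids.append(u.unit_id)
    counts = np.vstack(
        [
            _resample(source_go, n_pseudotrials, rng),
            _resample(source_nogo, n_pseudotrials, rng),
        ]
    )
    labels = np.concatenate(
        [np.ones(n_pseudotrials, int), np.zeros(n_pseudotrials, int)]
    )
    return PseudoTrialMatrix(
        counts=counts,
        labels=labels,
        window=window,
        unit_ids=uids,
        seed=seed,
        source_go=source_go,
        source_nogo=source_nogo,
    )


def decode_accuracy(
    matrix: PseudoTrialMatrix,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """Source-level k-fold CV accuracy of a linear-kernel SVM.

    Each unit's real trials are partitioned into ``folds`` chunks (a
    seeded permutation per unit); fold ``f`` trains on pseudotrials
    resampled from the other chunks and tests on pseudotrials resampled
    from chunk ``f`` alone, so no real trial informs both sides.
    """
    if np.unique(matrix.labels).size < 2:
        raise ValueError("decoding requires both classes present")
    n_pseudo = matrix.n_pseudotrials
    if n_pseudo < 4:
        raise ValueError("need >= 4 pseudotrials per class")
    rng = np.random.default_rng(seed)
    n_units = len(matrix.source_go)
    # per-unit permutations of source-trial indices
    perms_go = [rng.permutation(s.size) for s in matrix.source_go]
    perms_ng = [rng.permutation(s.size) for s in matrix.source_nogo]
    n_test = max(4, n_pseudo // folds)
    accs = []
    for f in range(folds):
        train_go, test_go, train_ng, test_ng = [], [], [], []
        for u in range(n_units):
            for sources, perm, tr_list, te_list in (
                (matrix.source_go[u], perms_go[u], train_go, test_go),
                (matrix.source_nogo[u], perms_ng[u], train_ng, test_ng),
            ):
                chunks = np.array_split(perm, folds)
                te_idx = chunks[f]
                tr_idx = np.concatenate(
                    [c for i, c in enumerate(chunks) if i != f]
                )
                tr_list.append(sources[tr_idx])
                te_list.append(sources[te_idx])
        X_train = np.vstack(
            [_resample(train_go, n_pseudo, rng), _resample(train_ng, n_pseudo, rng)]
        )
        y_train = np.concatenate(
            [np.ones(n_pseudo, int), np.zeros(n_pseudo, int)]
        )
        X_test = np.vstack(
            [_resample(test_go, n_test, rng), _resample(test_ng, n_test, rng)]
        )
        y_test = np.concatenate([np.ones(n_test, int), np.zeros(n_test, int)])
        clf = SVC(kernel="linear", C=C)
        clf.fit(X_train, y_train)
        accs.append(clf.score(X_test, y_test))
    return float(np.mean(accs))


@dataclass
class DecodingCurve:
    table: pd.DataFrame  # bin_center_s, n_units, mean_accuracy, sd_accuracy
    chance: float
    behavioral_accuracy: float
    min_units_reaching_behavior: dict[float, int | None]  # per window center

    def accuracy(self, bin_center: float, n_units: int) -> float:
        t = self.table
        row = t[
            (np.isclose(t.bin_center_s, bin_center)) & (t.n_units == n_units)
        ]
        return float(row.mean_accuracy.iloc[0])


def decoding_timecourse(
    sessions: Sequence[Session] | Session,
    population_sizes: Sequence[int] = (1, 5, 10, 25, 50, 100),
    window_width: float = 0.100,
    step: float = 0.020,
    span: tuple[float, float] = (-0.2, 0.8),
    align_event: str = "odor_on",
    n_resamples: int = 20,
    n_pseudotrials: int = 100,
    folds: int = 5,
    seed: int = 0,
    behavioral_accuracy: float | None = None,
) -> DecodingCurve:
    """Accuracy time courses across sliding windows and population sizes.

    Every (window, size) cell is the mean ± SD over ``n_resamples``
    independent unit samples.  ``min_units_reaching_behavior`` records,
    per window, the smallest population size whose mean accuracy meets
    the behavioral accuracy (None where no size does).
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    if behavioral_accuracy is None:
        n_corr = sum(
            sum(1 for t in s.trials if t.outcome == "correct")
            for s in sessions
        )
        n_tot = sum(len(s.trials) for s in sessions)
        behavioral_accuracy = n_corr / n_tot
    n_avail = len(_pooled_units(sessions))
    sizes = sorted({min(sz, n_avail) for sz in population_sizes})

    starts = np.arange(span[0], span[1] - window_width + 1e-9, step)
    rows = []
    min_units: dict[float, int | None] = {}
    for wi, w0 in enumerate(starts):
        window = (float(w0), float(w0 + window_width))
        center = float(w0 + window_width / 2)
        reached: int | None = None
        for sz in sizes:
            accs = []
            for r in range(n_resamples):
                child = int(
                    np.random.SeedSequence(seed, spawn_key=(wi, sz, r))
                    .generate_state(1)[0] % (2**31)
                )
                mat = build_pseudopopulation(
                    sessions, window, sz, n_pseudotrials,
                    align_event=align_event, seed=child,
                )
                accs.append(decode_accuracy(mat, folds=folds, seed=child))
            mean_acc = float(np.mean(accs))
            rows.append(
                {
                    "bin_center_s": center,
                    "n_units": sz,
                    "mean_accuracy": mean_acc,
                    "sd_accuracy": float(np.std(accs)),
                }
            )
            if reached is None and mean_acc >= behavioral_accuracy:
                reached = sz
        min_units[center] = reached
    return DecodingCurve(
        table=pd.DataFrame(rows),
        chance=CHANCE_LEVEL,
        behavioral_accuracy=float(behavioral_accuracy),
        min_units_reaching_behavior=min_units,
    )
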