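"""Session containers and plain-text session I/O.

A *session* is one behavioral recording: a set of sorted single units
(spike timestamps on the session clock, in seconds) plus a per-trial
behavioral event table for an odor-guided go/no-go task.

Conventions used throughout the package:

* time unit is seconds (float64), zero at session start;
* events are instants, epochs are half-open intervals ``[start, end)``;
* odor valve opening and odor port entry are the same timestamp (the
  animal's nose poke triggers the valve), stored once as ``odor_on``.

On disk a session is a directory with ``units.csv`` (``unit_id,
spike_time_s``), ``trials.csv`` (one row per trial) and ``meta.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnitSpikeTrain",
    "TrialEvents",
    "Session",
    "SessionValidationError",
    "EpochUndefinedError",
    "epoch_bounds",
    "load_session",
    "write_session",
    "load_deposited",
    "EPOCH_NAMES",
]

#: seconds of pre-iti_end time in the long / short baseline epochs
BASELINE_LONG_S = 1.0
BASELINE_SHORT_S = 0.2
#: default epoch length after the anchoring event for drinking / no-go waiting
POST_EVENT_EPOCH_S = 1.0

EPOCH_NAMES = (
    "baseline_long",
    "baseline_short",
    "odor_sampling",
    "drinking",
    "no_go_waiting",
)

TRIAL_COLUMNS = [
    "trial_id",
    "trial_type",
    "outcome",
    "odor_kind",
    "iti_end_s",
    "odor_on_s",
    "odor_off_s",
    "port_exit_s",
    "water_entry_s",
    "water_on_s",
]


class SessionValidationError(ValueError):
    """An invariant of the session format is violated."""


class EpochUndefinedError(ValueError):
    """A named epoch does not exist for the given trial type/behavior."""


@dataclass(frozen=True)
class UnitSpikeTrain:
    """Spike timestamps of one sorted unit, seconds on the session clock."""

    unit_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.ndim != 1:
            raise SessionValidationError(
                f"unit {self.unit_id}: spike_times must be 1-D"
            )
        if times.size:
            if not np.all(np.isfinite(times)):
                raise SessionValidationError(
                    f"unit {self.unit_id}: non-finite spike time"
                )
            if times[0] < 0:
                raise SessionValidationError(
                    f"unit {self.unit_id}: negative spike time"
                )
            if np.any(np.diff(times) < 0):
                raise SessionValidationError(
                    f"unit {self.unit_id}: spike times not sorted"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def count_in(self, start: float, end: float) -> int:
        """Number of spikes in the half-open interval [start, end)."""
        lo, hi = np.searchsorted(self.spike_times, [start, end], side="left")
        return int(hi - lo)


@dataclass(frozen=True)
class TrialEvents:
    """Behavioral event timestamps for one trial.

    ``trial_type`` is the *cue* identity (go / no-go); ``outcome`` records
    whether the animal's behavior matched the cue.  ``water_entry`` is
    present whenever go behavior was executed (correct go or false-alarm
    no-go); ``water_on`` only when reward was delivered (correct go).
    """

    trial_id: int
    trial_type: str  # {"go", "no-go"}
    outcome: str  # {"correct", "error"}
    odor_kind: str  # {"go-cue", "no-go-cue", "odorless"}
    iti_end: float
    odor_on: float
    odor_off: float
    port_exit: float
    water_entry: float | None = None
    water_on: float | None = None

    def __post_init__(self) -> None:
        if self.trial_type not in ("go", "no-go"):
            raise SessionValidationError(
                f"trial {self.trial_id}: bad trial_type {self.trial_type!r}"
            )
        if self.outcome not in ("correct", "error"):
            raise SessionValidationError(
                f"trial {self.trial_id}: bad outcome {self.outcome!r}"
            )
        if self.odor_kind not in ("go-cue", "no-go-cue", "odorless"):
            raise SessionValidationError(
                f"trial {self.trial_id}: bad odor_kind {self.odor_kind!r}"
            )
        if not (self.iti_end <= self.odor_on < self.odor_off <= self.port_exit):
            raise SessionValidationError(
                f"trial {self.trial_id}: event order violated "
                f"(iti_end={self.iti_end}, odor_on={self.odor_on}, "
                f"odor_off={self.odor_off}, port_exit={self.port_exit})"
            )
        if self.water_on is not None and self.water_entry is None:
            raise SessionValidationError(
                f"trial {self.trial_id}: water_on without water_entry"
            )
        if self.water_entry is not None and self.water_entry < self.port_exit:
            raise SessionValidationError(
                f"trial {self.trial_id}: water_entry precedes port_exit"
            )

    @property
    def go_executed(self) -> bool:
        """True when the animal moved to the water port on this trial."""
        return self.water_entry is not None

    @property
    def sampling_duration(self) -> float:
        return self.port_exit - self.odor_on

    def event_time(self, name: str) -> float | None:
        return {
            "iti_end": self.iti_end,
            "odor_on": self.odor_on,
            "odor_off": self.odor_off,
            "port_exit": self.port_exit,
            "water_entry": self.water_entry,
            "water_on": self.water_on,
        }[name]


@dataclass
class Session:
    session_id: str
    units: list[UnitSpikeTrain]
    trials: list[TrialEvents]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.units:
            raise SessionValidationError("session has no units")
        if not self.trials:
            raise SessionValidationError("session has no trials")
        starts = [t.odor_on for t in self.trials]
        ends = [t.port_exit for t in self.trials]
        for i in range(1, len(self.trials)):
            if starts[i] <= ends[i - 1]:
                raise SessionValidationError(
                    f"trials {self.trials[i-1].trial_id} and "
                    f"{self.trials[i].trial_id} are not ordered in time"
                )

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit(self, unit_id: str) -> UnitSpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def select_trials(
        self,
        trial_type: str | None = None,
        outcome: str | None = None,
        odor_kind: str | None = None,
    ) -> list[TrialEvents]:
        out = []
        for t in self.trials:
            if trial_type is not None and t.trial_type != trial_type:
                continue
            if outcome is not None and t.outcome != outcome:
                continue
            if odor_kind is not None and t.odor_kind != odor_kind:
                continue
            out.append(t)
        return out

    def behavioral_accuracy(self) -> float:
        n_ok = sum(1 for t in self.trials if t.outcome == "correct")
        return n_ok / len(self.trials)


def epoch_bounds(trial: TrialEvents, epoch_name: str) -> tuple[float, float]:
    """Half-open bounds ``[start, end)`` of a named task epoch.

    * ``baseline_long`` — 1,000–0 ms before the end of the inter-trial
      interval (the classification baseline);
    * ``baseline_short`` — 200–0 ms before ITI end (the sliding-trace
      baseline);
    * ``odor_sampling`` — odor valve opening to odor port exit;
    * ``drinking`` — 1 s from water onset (go behavior only);
    * ``no_go_waiting`` — 1 s from odor port exit on no-go behavior.
    """
    if epoch_name == "baseline_long":
        return trial.iti_end - BASELINE_LONG_S, trial.iti_end
    if epoch_name == "baseline_short":
        return trial.iti_end - BASELINE_SHORT_S, trial.iti_end
    if epoch_name == "odor_sampling":
        return trial.odor_on, trial.port_exit
    if epoch_name == "drinking":
        if trial.water_on is None:
            raise EpochUndefinedError(
                f"trial {trial.trial_id}: drinking epoch undefined "
                "(no water onset on this trial)"
            )
        return trial.water_on, trial.water_on + POST_EVENT_EPOCH_S
    if epoch_name == "no_go_waiting":
        if trial.go_executed:
            raise EpochUndefinedError(
                f"trial {trial.trial_id}: no_go_waiting epoch undefined "
                "(go behavior was executed)"
            )
        return trial.port_exit, trial.port_exit + POST_EVENT_EPOCH_S
    raise ValueError(f"unknown epoch {epoch_name!r}; one of {EPOCH_NAMES}")


# ---------------------------------------------------------------------------
# plain-text format


def _opt(x) -> float | None:
    if x is None:
        return None
    if isinstance(x, float) and math.isnan(x):
        return None
    if isinstance(x, str) and x.strip() == "":
        return None
    return float(x)


def load_session(path: str | Path, *, sort_spikes: bool = False) -> Session:
    """Read a session directory (units.csv, trials.csv, meta.json).

    With ``sort_spikes=True`` unsorted spike times are sorted on load
    instead of raising a validation error.
    """
    path = Path(path)
    for fname in ("units.csv", "trials.csv", "meta.json"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing session file: {path / fname}")

    meta = json.loads((path / "meta.json").read_text())

    units_df = pd.read_csv(path / "units.csv", dtype={"unit_id": str})
    units: list[UnitSpikeTrain] = []
    order = meta.get("unit_order")
    groups = {uid: g["spike_time_s"].to_numpy(float)
              for uid, g in units_df.groupby("unit_id", sort=False)}
    for uid in order if order is not None else list(groups):
        times = groups.get(uid, np.empty(0))
        if sort_spikes:
            times = np.sort(times)
        units.append(UnitSpikeTrain(uid, times))

    trials_df = pd.read_csv(path / "trials.csv")
    trials = [
        TrialEvents(
            trial_id=int(r.trial_id),
            trial_type=str(r.trial_type),
            outcome=str(r.outcome),
            odor_kind=str(r.odor_kind),
            iti_end=float(r.iti_end_s),
            odor_on=float(r.odor_on_s),
            odor_off=float(r.odor_off_s),
            port_exit=float(r.port_exit_s),
            water_entry=_opt(r.water_entry_s),
            water_on=_opt(r.water_on_s),
        )
        for r in trials_df.itertuples(index=False)
    ]
    session_id = meta.get("session_id", path.name)
    return Session(session_id=session_id, units=units, trials=trials, meta=meta)


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory; timestamps keep 6-decimal precision."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = [
        (u.unit_id, f"{t:.6f}") for u in session.units for t in u.spike_times
    ]
    units_df = pd.DataFrame(rows, columns=["unit_id", "spike_time_s"])
    units_df.to_csv(path / "units.csv", index=False)

    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.6f}"

    trows = []
    for t in session.trials:
        trows.append(
            {
                "trial_id": t.trial_id,
                "trial_type": t.trial_type,
                "outcome": t.outcome,
                "odor_kind": t.odor_kind,
                "iti_end_s": fmt(t.iti_end),
                "odor_on_s": fmt(t.odor_on),
                "odor_off_s": fmt(t.odor_off),
                "port_exit_s": fmt(t.port_exit),
                "water_entry_s": fmt(t.water_entry),
                "water_on_s": fmt(t.water_on),
            }
        )
    pd.DataFrame(trows, columns=TRIAL_COLUMNS).to_csv(
        path / "trials.csv", index=False
    )

    meta = dict(session.meta)
    meta["session_id"] = session.session_id
    # empty units would otherwise vanish from the long-format CSV
    meta["unit_order"] = [u.unit_id for u in session.units]
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_deposited(path: str | Path) -> Session:
    """Best-effort adapter for externally deposited raw-data layouts.

    The public archive for this task's recordings does not document a
    machine-readable layout; this hook exists so a user who has arranged
    the deposited files into the plain-text session format (or a close
    variant) can load them through one entry point.  Currently it accepts
    exactly the ``units.csv``/``trials.csv``/``meta.json`` layout and
    raises a descriptive error otherwise.
    """
    path = Path(path)
    if (path / "units.csv").exists() and (path / "trials.csv").exists():
        if not (path / "meta.json").exists():
            (path / "meta.json").write_text("{}")
        return load_session(path)
    raise FileNotFoundError(
        f"{path}: expected units.csv + trials.csv; convert the deposited "
        "files to the documented session directory format first"
    )
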