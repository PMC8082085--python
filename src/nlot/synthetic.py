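"""Seeded synthetic go/no-go sessions with ground-truth neuron archetypes.

The generator emulates the statistical structure of single-unit
recordings from olfactory cortex during an odor-guided go/no-go task:

* log-normal baseline firing rates (population median 0.90 Hz,
  interquartile range 0.23–3.07 Hz);
* five response archetypes in the empirically reported proportions —
  type I (go-cue preferring: sharp go-cue excitation, persistent no-go
  suppression, drinking excitation), type II (the mirror image), type
  III (excited by both cues), type IV (suppressed by both cues, no-go
  waiting excitation), type V (non-responsive);
* per-trial odor-sampling durations drawn from log-normal distributions
  matching the reported medians/IQRs (788 ms go, 642 ms no-go), left-
  truncated at the 500 ms odor presentation the task enforces;
* behavioral accuracy ~90% (task criterion is >80%); error and odorless
  trials fire at baseline, reflecting the observation that distinct cue
  responses appear only on correct go trials.

Spikes are drawn from an inhomogeneous Poisson process by thinning.
Ground-truth labels and parameters are returned alongside the session
so downstream classification can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .session_io import Session, TrialEvents, UnitSpikeTrain

__all__ = [
    "ArchetypeParams",
    "GeneratorConfig",
    "GroundTruth",
    "DEFAULT_ARCHETYPES",
    "TYPE_LABELS",
    "sample_baseline_rates",
    "sample_sampling_durations",
    "make_trial_table",
    "intensity_function",
    "generate_spikes",
    "generate_session",
    "baseline_lognormal_params",
    "truncated_lognormal_params",
]

TYPE_LABELS = ("I", "II", "III", "IV", "V")

#: printed proportions of the five response types (fraction of all neurons)
DEFAULT_TYPE_PROPORTIONS = (0.389, 0.058, 0.115, 0.170, 0.268)

_Z75 = stats.norm.ppf(0.75)  # 0.6744897...


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class ArchetypeParams:
    """Rate-model parameters for one unit.

    ``excitation_gain`` scales the mean rate over the Gaussian bump's
    ±3 SD support relative to baseline; ``suppression_gain`` multiplies
    the baseline inside the suppression window.  Which cue receives the
    bump versus the suppression is determined by ``type_label``.
    """

    type_label: str
    baseline_rate: float  # Hz
    excitation_gain: float = 8.0  # mean-rate multiplier over the bump support
    suppression_gain: float = 0.1  # in [0, 1]
    peak_latency: float = 0.5  # s after odor_on
    peak_width: float = 0.06  # Gaussian SD, s
    suppression_onset: float = 0.35  # s after odor_on
    suppression_persistence: float = 0.8  # s past port_exit
    drinking_gain: float = 1.0
    waiting_gain: float = 1.0
    latency_jitter_sd: float = 0.02  # trial-to-trial SD of the bump peak, s

    def __post_init__(self) -> None:
        if self.type_label not in TYPE_LABELS:
            raise ValueError(f"bad type_label {self.type_label!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if not (0.0 <= self.suppression_gain <= 1.0):
            raise ValueError("suppression_gain must lie in [0, 1]")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be > 0")

    @property
    def bump_amplitude(self) -> float:
        """Peak height (Hz) above baseline of the excitation bump.

        Chosen so the mean rate over the bump's ±3 SD support equals
        ``excitation_gain × baseline_rate``.
        """
        mass = stats.norm.cdf(3) - stats.norm.cdf(-3)  # 0.9973
        return (
            (self.excitation_gain - 1.0)
            * self.baseline_rate
            * 6.0
            / (np.sqrt(2 * np.pi) * mass)
        )


#: archetype templates (baseline_rate filled in per unit)
DEFAULT_ARCHETYPES: dict[str, ArchetypeParams] = {
    "I": ArchetypeParams("I", 1.0, drinking_gain=3.0, waiting_gain=0.3),
    "II": ArchetypeParams("II", 1.0, drinking_gain=0.3, waiting_gain=3.0),
    "III": ArchetypeParams("III", 1.0),
    "IV": ArchetypeParams("IV", 1.0, waiting_gain=2.5),
    "V": ArchetypeParams("V", 1.0, excitation_gain=1.0, suppression_gain=1.0),
}


def baseline_lognormal_params(
    median: float = 0.90, q25: float = 0.23, q75: float = 3.07
) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and quartiles.

    mu = ln(median); sigma = ln(q75/q25) / (2 z_0.75).  With asymmetric
    printed quartiles the geometric spread is matched.
    """
    mu = np.log(median)
    sigma = np.log(q75 / q25) / (2 * _Z75)
    return float(mu), float(sigma)


def truncated_lognormal_params(
    median: float, q75: float, lower: float
) -> tuple[float, float]:
    """(mu, sigma) such that the log-normal *left-truncated at lower*
    has the requested median and upper quartile.

    Solved numerically; used so sampling durations respect the enforced
    minimum nose-poke duration while still matching printed quantiles.
    """

    def quantile(mu: float, sigma: float, p: float) -> float:
        f0 = stats.norm.cdf((np.log(lower) - mu) / sigma)
        return float(np.exp(mu + sigma * stats.norm.ppf(f0 + p * (1 - f0))))

    def eqs(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        return [
            quantile(mu, sigma, 0.5) - median,
            quantile(mu, sigma, 0.75) - q75,
        ]

    mu0 = np.log(median)
    sigma0 = np.log(q75 / median) / _Z75
    sol = optimize.root(eqs, [mu0, np.log(sigma0)], method="hybr")
    if not sol.success:  # pragma: no cover - well-conditioned in practice
        raise RuntimeError(f"truncated log-normal fit failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


@dataclass(frozen=True)
class GeneratorConfig:
    n_units: int = 100
    n_trials: int = 200
    type_proportions: tuple[float, ...] = DEFAULT_TYPE_PROPORTIONS
    behavioral_accuracy: float = 0.9
    odorless_fraction: float = 0.0
    # baseline-rate distribution (log-normal, Hz)
    baseline_median: float = 0.90
    baseline_q25: float = 0.23
    baseline_q75: float = 3.07
    #: responsive archetypes (I–IV) are redrawn until their baseline exceeds
    #: this floor: a near-silent unit cannot express measurable suppression,
    #: so assigning it a responsive ground-truth label would be meaningless.
    min_responsive_baseline: float = 0.5
    # odor-sampling-duration distributions (s); medians/quartiles of the
    # ≥ odor_presentation_s truncated log-normal
    go_duration_median: float = 0.788
    go_duration_q75: float = 0.962
    nogo_duration_median: float = 0.642
    nogo_duration_q75: float = 0.798
    odor_presentation_s: float = 0.5
    # session timing
    first_odor_on: float = 5.0
    post_trial_span: float = 2.0  # reserved for drinking / waiting epochs
    iti_gap: float = 2.0  # quiet time before the next baseline epoch
    archetypes: dict[str, ArchetypeParams] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.type_proportions, float)
        if p.size != 5 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("type_proportions must be 5 non-negative "
                             "values summing to 1")
        if not (0.0 < self.behavioral_accuracy <= 1.0):
            raise ValueError("behavioral_accuracy must lie in (0, 1]")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")


def _rng(seed, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# samplers


def sample_baseline_rates(
    n: int, config: GeneratorConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Draw i.i.d. log-normal baseline firing rates (Hz)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or GeneratorConfig()
    mu, sigma = baseline_lognormal_params(
        cfg.baseline_median, cfg.baseline_q25, cfg.baseline_q75
    )
    return _rng(seed, 0).lognormal(mu, sigma, size=n)


def sample_sampling_durations(
    n: int, trial_type: str, config: GeneratorConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Draw odor-sampling durations (s) for one trial type."""
    cfg = config or GeneratorConfig()
    if trial_type == "go":
        median, q75 = cfg.go_duration_median, cfg.go_duration_q75
    elif trial_type == "no-go":
        median, q75 = cfg.nogo_duration_median, cfg.nogo_duration_q75
    else:
        raise ValueError(f"bad trial_type {trial_type!r}")
    lower = cfg.odor_presentation_s
    mu, sigma = truncated_lognormal_params(median, q75, lower)
    rng = _rng(seed, 1 if trial_type == "go" else 2)
    # inverse-CDF sampling of the truncated log-normal
    f0 = stats.norm.cdf((np.log(lower) - mu) / sigma)
    u = rng.uniform(f0, 1.0, size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def make_trial_table(
    config: GeneratorConfig | None = None, seed: int = 0
) -> list[TrialEvents]:
    """Generate a randomized, non-overlapping trial event table."""
    cfg = config or GeneratorConfig()
    n = cfg.n_trials
    rng = _rng(seed, 10)

    trial_type = np.where(rng.random(n) < 0.5, "go", "no-go")
    outcome = np.where(
        rng.random(n) < cfg.behavioral_accuracy, "correct", "error"
    )
    odorless = rng.random(n) < cfg.odorless_fraction

    dur_go = sample_sampling_durations(n, "go", cfg, seed)
    dur_nogo = sample_sampling_durations(n, "no-go", cfg, seed)

    trials: list[TrialEvents] = []
    t = cfg.first_odor_on
    for i in range(n):
        tt = str(trial_type[i])
        oc = str(outcome[i])
        if odorless[i]:
            # odorless probe: no cue, the animal waits; count as correct no-go
            tt, oc, kind = "no-go", "correct", "odorless"
        else:
            kind = "go-cue" if tt == "go" else "no-go-cue"
        # duration follows the cue's distribution
        dur = float(dur_go[i] if tt == "go" else dur_nogo[i])
        odor_on = t
        odor_off = odor_on + cfg.odor_presentation_s
        port_exit = odor_on + dur
        go_executed = (tt == "go") == (oc == "correct") and kind != "odorless"
        water_entry = water_on = None
        if go_executed:
            water_entry = port_exit + 0.2 + 0.2 * float(rng.random())
            if tt == "go" and oc == "correct":
                water_on = water_entry + 0.05
        trials.append(
            TrialEvents(
                trial_id=i,
                trial_type=tt,
                outcome=oc,
                odor_kind=kind,
                iti_end=odor_on,
                odor_on=odor_on,
                odor_off=odor_off,
                port_exit=port_exit,
                water_entry=water_entry,
                water_on=water_on,
            )
        )
        t = port_exit + cfg.post_trial_span + cfg.iti_gap + 1.0
    return trials


# ---------------------------------------------------------------------------
# intensity model


def _gauss(t: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def intensity_function(
    params: ArchetypeParams,
    trial: TrialEvents,
    peak_jitter: float = 0.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Time-varying firing rate λ(t) (Hz) of one unit over one trial.

    Total function: returns the baseline rate outside the trial's
    modulation windows, so it can be evaluated anywhere.  Error and
    odorless trials fire at baseline (cue responses appear only on
    correctly executed cue trials).  The returned callable carries a
    ``lambda_max`` attribute for thinning.
    """
    b = params.baseline_rate
    label = params.type_label

    flat = label == "V" or trial.outcome == "error" or trial.odor_kind == "odorless"

    # which response does this archetype mount to the presented cue?
    go_trial = trial.trial_type == "go"
    bump = False
    suppress = False
    if not flat:
        if label == "I":
            bump, suppress = go_trial, not go_trial
        elif label == "II":
            bump, suppress = not go_trial, go_trial
        elif label == "III":
            bump = True
        elif label == "IV":
            suppress = True

    peak_t = trial.odor_on + params.peak_latency + peak_jitter
    amp = params.bump_amplitude if bump else 0.0
    sup_start = trial.odor_on + params.suppression_onset
    sup_end = trial.port_exit + params.suppression_persistence

    drink = (
        not flat
        and params.drinking_gain != 1.0
        and trial.water_on is not None
    )
    wait = (
        not flat
        and params.waiting_gain != 1.0
        and not trial.go_executed
    )
    drink_win = (trial.water_on, trial.water_on + 1.0) if drink else None
    wait_win = (trial.port_exit, trial.port_exit + 1.0) if wait else None

    def lam(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        mult = np.ones_like(t)
        if suppress:
            in_sup = (t >= sup_start) & (t < sup_end)
            mult = np.where(in_sup, params.suppression_gain, mult)
        if wait_win is not None:
            in_wait = (t >= wait_win[0]) & (t < wait_win[1])
            if suppress:  # suppression window takes precedence
                in_wait &= ~((t >= sup_start) & (t < sup_end))
            mult = np.where(in_wait, params.waiting_gain, mult)
        if drink_win is not None:
            in_drink = (t >= drink_win[0]) & (t < drink_win[1])
            mult = np.where(in_drink, params.drinking_gain, mult)
        out = b * mult
        if amp > 0:
            out = out + amp * _gauss(t, peak_t, params.peak_width)
        return np.maximum(out, 0.0)

    gains = [1.0]
    if drink:
        gains.append(params.drinking_gain)
    if wait:
        gains.append(params.waiting_gain)
    lam.lambda_max = b * max(gains) + (amp if amp > 0 else 0.0)
    return lam


def generate_spikes(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    t0: float,
    t1: float,
    lambda_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on [t0, t1) by thinning."""
    if t1 <= t0 or lambda_max <= 0:
        return np.empty(0)
    n = rng.poisson(lambda_max * (t1 - t0))
    if n == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, size=n))
    keep = rng.uniform(0, lambda_max, size=n) < rate_fn(cand)
    return cand[keep]


# ---------------------------------------------------------------------------
# session assembly


@dataclass(frozen=True)
class GroundTruth:
    """True archetype assignment of every generated unit."""

    labels: dict[str, str]  # unit_id -> type label
    params: dict[str, ArchetypeParams]
    seed: int

    def label_array(self, unit_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[u] for u in unit_ids])


def generate_session(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[Session, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Deterministic given (config, seed): unit labels, baseline rates,
    trial table and spike trains all derive from independent child
    streams of the seed.
    """
    cfg = config or GeneratorConfig()
    if seed is None:
        seed = cfg.seed

    rng_units = _rng(seed, 20)
    n = cfg.n_units
    labels = rng_units.choice(
        TYPE_LABELS, size=n, p=np.asarray(cfg.type_proportions)
    )
    rates = sample_baseline_rates(n, cfg, seed)
    # responsive archetypes need a measurable baseline to express
    # suppression; redraw low draws for types I-IV (type V keeps the tail)
    floor = cfg.min_responsive_baseline
    for i in range(n):
        while labels[i] != "V" and rates[i] < floor:
            rates[i] = sample_baseline_rates(1, cfg, int(rng_units.integers(2**31)))[0]

    trials = make_trial_table(cfg, seed)
    session_end = trials[-1].port_exit + cfg.post_trial_span + cfg.iti_gap

    units: list[UnitSpikeTrain] = []
    gt_labels: dict[str, str] = {}
    gt_params: dict[str, ArchetypeParams] = {}
    for i in range(n):
        uid = f"u{i:03d}"
        label = str(labels[i])
        params = replace(
            cfg.archetypes[label], type_label=label, baseline_rate=float(rates[i])
        )
        rng_u = _rng(seed, 30, i)
        spikes = []
        cursor = 0.0
        for trial in trials:
            # homogeneous baseline over the inter-trial gap
            spikes.append(
                generate_spikes(
                    lambda t: np.full(np.shape(t), params.baseline_rate),
                    cursor,
                    trial.odor_on,
                    params.baseline_rate,
                    rng_u,
                )
            )
            jitter = float(rng_u.normal(0.0, params.latency_jitter_sd))
            lam = intensity_function(params, trial, peak_jitter=jitter)
            trial_end = trial.port_exit + cfg.post_trial_span
            spikes.append(
                generate_spikes(lam, trial.odor_on, trial_end, lam.lambda_max, rng_u)
            )
            cursor = trial_end
        spikes.append(
            generate_spikes(
                lambda t: np.full(np.shape(t), params.baseline_rate),
                cursor,
                session_end,
                params.baseline_rate,
                rng_u,
            )
        )
        train = UnitSpikeTrain(uid, np.concatenate(spikes))
        units.append(train)
        gt_labels[uid] = label
        gt_params[uid] = params

    session = Session(
        session_id=f"synthetic-{seed}",
        units=units,
        trials=trials,
        meta={
            "generator": "nlot.synthetic",
            "seed": int(seed),
            "n_units": n,
            "n_trials": cfg.n_trials,
            "behavioral_accuracy_target": cfg.behavioral_accuracy,
        },
    )
    return session, GroundTruth(labels=gt_labels, params=gt_params, seed=int(seed))
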