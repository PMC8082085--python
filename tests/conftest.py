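"""Shared fixtures: synthetic sessions and hand-built units/trials."""

from __future__ import annotations

import numpy as np
import pytest

from nlot.session_io import Session, TrialEvents, UnitSpikeTrain
from nlot.synthetic import (
    ArchetypeParams,
    GeneratorConfig,
    generate_session,
    generate_spikes,
    intensity_function,
)


def make_fixed_trials(
    n: int,
    duration: float = 1.2,
    gap: float = 5.0,
    trial_type: str = "go",
    outcome: str = "correct",
    start: float = 5.0,
    with_water: bool = False,
) -> list[TrialEvents]:
    """Regularly spaced trials with a fixed odor-sampling duration."""
    kind = "go-cue" if trial_type == "go" else "no-go-cue"
    out = []
    t = start
    for i in range(n):
        water_entry = water_on = None
        if with_water and trial_type == "go" and outcome == "correct":
            water_entry = t + duration + 0.3
            water_on = water_entry + 0.05
        out.append(
            TrialEvents(
                trial_id=i,
                trial_type=trial_type,
                outcome=outcome,
                odor_kind=kind,
                iti_end=t,
                odor_on=t,
                odor_off=t + 0.5,
                port_exit=t + duration,
                water_entry=water_entry,
                water_on=water_on,
            )
        )
        t += duration + gap
    return out


def unit_from_params(
    params: ArchetypeParams,
    trials: list[TrialEvents],
    seed: int = 0,
    unit_id: str = "u0",
    post_span: float = 2.0,
) -> UnitSpikeTrain:
    """Spike train realized from the archetype intensity over given trials."""
    rng = np.random.default_rng(seed)
    b = params.baseline_rate
    spikes = []
    cursor = 0.0
    for tr in trials:
        spikes.append(
            generate_spikes(
                lambda t: np.full(np.shape(t), b), cursor, tr.odor_on, b, rng
            )
        )
        jitter = float(rng.normal(0.0, params.latency_jitter_sd))
        lam = intensity_function(params, tr, peak_jitter=jitter)
        end = tr.port_exit + post_span
        spikes.append(generate_spikes(lam, tr.odor_on, end, lam.lambda_max, rng))
        cursor = end
    return UnitSpikeTrain(unit_id, np.concatenate(spikes))


@pytest.fixture(scope="session")
def small_session():
    """30 units / 100 trials — shared by geometry, decoding, psth tests."""
    cfg = GeneratorConfig(n_units=30, n_trials=100)
    return generate_session(cfg, 3)


@pytest.fixture(scope="session")
def recovery_session():
    """Default-scale session for ground-truth recovery checks.

    100 units with the reported type proportions; 160 trials at 90%
    accuracy give well over 60 correct trials per condition.
    """
    cfg = GeneratorConfig(n_units=100, n_trials=160)
    return generate_session(cfg, 11)
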