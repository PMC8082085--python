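"""auROC, permutation tests, classification, traces and contrasts."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nlot.cue_response import (
    ClassifierConfig,
    auroc,
    auroc_test,
    classify_neuron,
    compare_durations,
    condition_contrast,
    peak_and_halfwidth,
    permutation_pvalue,
    sliding_auroc,
    sliding_auroc_pair,
    alignment_comparison,
    significant_proportion_timecourse,
    classify_session,
    trial_stability,
)
from nlot.psth import align_and_bin, smooth
from nlot.session_io import Session, TrialEvents, UnitSpikeTrain
from nlot.synthetic import ArchetypeParams, GeneratorConfig, generate_session

from conftest import make_fixed_trials, unit_from_params


# --- independent oracles ---------------------------------------------------


def auroc_bruteforce(a, b):
    """All-pairs counting: wins + half-ties over n_a*n_b."""
    wins = sum(1.0 for x in a for y in b if x > y)
    ties = sum(0.5 for x in a for y in b if x == y)
    return (wins + ties) / (len(a) * len(b))


def permutation_exhaustive(a, b):
    """Two-sided p by enumerating every split of the pooled sample."""
    pooled = list(a) + list(b)
    n, n_a = len(pooled), len(a)
    obs = abs(auroc_bruteforce(a, b) - 0.5)
    hits = total = 0
    for ix in combinations(range(n), n_a):
        sa = [pooled[i] for i in ix]
        sb = [pooled[i] for i in range(n) if i not in set(ix)]
        if abs(auroc_bruteforce(sa, sb) - 0.5) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


# --- auROC ------------------------------------------------------------------


class TestAuroc:
    def test_identical_samples_give_half(self):
        assert auroc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_complete_separation_gives_one(self):
        assert auroc([2, 3], [0, 1]) == 1.0

    def test_partial_overlap_with_ties(self):
        # 1 win + 2 half-ties over 9 pairs
        assert auroc([0, 1, 2], [1, 2, 3]) == pytest.approx(2 / 9)

    def test_rejects_empty_sample(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 5), min_size=1, max_size=10),
        b=st.lists(st.integers(0, 5), min_size=1, max_size=10),
    )
    def test_antisymmetry_including_ties(self, a, b):
        assert auroc(a, b) + auroc(b, a) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
        b=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
    )
    def test_equals_pair_counting_oracle(self, a, b):
        assert auroc(a, b) == pytest.approx(auroc_bruteforce(a, b), abs=1e-12)


class TestPermutation:
    def test_identical_samples_not_significant(self):
        p = permutation_pvalue([1.0] * 6, [1.0] * 6, n_perm=200, seed=0)
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_small_n(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.poisson(2.0, 4).astype(float)
            b = rng.poisson(4.0, 4).astype(float)
            p = permutation_pvalue(a, b, n_perm=1000, seed=1)  # auto-exact
            assert p == pytest.approx(permutation_exhaustive(a, b), abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        p_exact = permutation_exhaustive(a, b)
        p_mc = permutation_pvalue(a, b, n_perm=4000, seed=5, exact=False)
        # binomial error on the Monte-Carlo estimate
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc - p_exact) < 4 * se + 1 / 4000

    def test_strong_separation_is_significant(self):
        res = auroc_test(np.arange(10.0) + 20, np.arange(10.0), seed=0)
        assert res.direction == "excitation"
        assert res.p_value < 0.01

    def test_requires_minimum_permutations(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1.0], [2.0], n_perm=10)


# --- classification ---------------------------------------------------------


def _two_condition_session(params, n_per=40, seed=0):
    go = make_fixed_trials(n_per, duration=0.8, trial_type="go", start=5.0)
    nogo = make_fixed_trials(
        n_per, duration=0.7, trial_type="no-go",
        start=go[-1].port_exit + 6.0,
    )
    trials = sorted(go + nogo, key=lambda t: t.odor_on)
    for i, t in enumerate(trials):
        object.__setattr__(t, "trial_id", i)
    unit = unit_from_params(params, trials, seed=seed)
    return Session("s", [unit], trials), unit


class TestClassification:
    def test_go_preferring_archetype_labeled_type_i(self):
        p = ArchetypeParams("I", 2.0, excitation_gain=5.0,
                            suppression_gain=0.2)
        session, unit = _two_condition_session(p, n_per=60, seed=1)
        c = classify_neuron(unit, session, ClassifierConfig(seed=2))
        assert c.type_label == "I"
        assert c.go.direction == "excitation"
        assert c.preference.auroc > 0.5

    def test_constant_rate_unit_labeled_type_v(self):
        p = ArchetypeParams("V", 2.0, excitation_gain=1.0,
                            suppression_gain=1.0)
        session, unit = _two_condition_session(p, n_per=30, seed=4)
        c = classify_neuron(unit, session, ClassifierConfig(seed=2))
        assert c.type_label == "V"

    def test_both_suppressed_labeled_type_iv(self):
        p = ArchetypeParams("IV", 3.0, excitation_gain=1.0,
                            suppression_gain=0.1, waiting_gain=1.0)
        session, unit = _two_condition_session(p, n_per=60, seed=5)
        c = classify_neuron(unit, session, ClassifierConfig(seed=2))
        assert c.type_label == "IV"

    def test_insufficient_trials_flagged_unclassifiable(self):
        p = ArchetypeParams("I", 2.0)
        session, unit = _two_condition_session(p, n_per=5, seed=1)
        c = classify_neuron(unit, session, ClassifierConfig(seed=2))
        assert c.type_label is None
        assert not c.classifiable


# --- sliding traces ----------------------------------------------------------


class TestSlidingAuroc:
    def test_symmetric_bump_center_of_mass(self):
        p = ArchetypeParams("I", 2.0, excitation_gain=6.0, peak_width=0.08,
                            latency_jitter_sd=0.0)
        trials = make_fixed_trials(60, duration=1.2)
        unit = unit_from_params(p, trials, seed=2)
        trace = sliding_auroc(unit, trials, n_perm=500, seed=2)
        assert trace.center_of_mass == pytest.approx(0.5, abs=0.03)
        assert trace.onset_time is not None
        assert trace.onset_time <= trace.center_of_mass
        assert trace.duration > 0

    def test_stationary_unit_rarely_significant(self):
        p = ArchetypeParams("V", 3.0, excitation_gain=1.0,
                            suppression_gain=1.0)
        trials = make_fixed_trials(50, duration=1.2)
        rates = []
        for s in range(6):
            unit = unit_from_params(p, trials, seed=100 + s)
            trace = sliding_auroc(unit, trials, n_perm=500, seed=s)
            rates.append(trace.significant.mean())
        assert np.mean(rates) < 0.04  # per-bin alpha is 0.01

    def test_no_significant_bins_means_zero_duration(self):
        p = ArchetypeParams("V", 2.0, excitation_gain=1.0,
                            suppression_gain=1.0)
        trials = make_fixed_trials(30, duration=1.0)
        unit = unit_from_params(p, trials, seed=9)
        trace = sliding_auroc(unit, trials, n_perm=300, seed=1,
                              min_consecutive=3)
        if trace.duration == 0:
            assert trace.onset_time is None and trace.center_of_mass is None
        assert (trace.duration == 0) == (~trace.significant).all()

    def test_short_trials_dropped_from_late_bins(self):
        p = ArchetypeParams("V", 2.0, excitation_gain=1.0,
                            suppression_gain=1.0)
        trials = make_fixed_trials(20, duration=0.6) + make_fixed_trials(
            20, duration=1.1, start=200.0
        )
        unit = unit_from_params(p, trials, seed=3)
        trace = sliding_auroc(unit, trials, n_perm=300, seed=1)
        early = trace.n_trials[trace.bin_centers <= 0.5]
        late = trace.n_trials[trace.bin_centers > 0.7]
        assert early.max() == 40
        assert late.max() <= 20

    def test_preference_trace_flags_go_nogo_difference(self):
        p = ArchetypeParams("I", 2.0, excitation_gain=6.0,
                            suppression_gain=0.2)
        go = make_fixed_trials(40, duration=1.0)
        nogo = make_fixed_trials(40, duration=1.0, trial_type="no-go",
                                 start=400.0)
        unit = unit_from_params(p, go + nogo, seed=6)
        trace = sliding_auroc_pair(unit, go, nogo, n_perm=400, seed=3)
        sig_late = trace.significant[
            (trace.bin_centers > 0.4) & (trace.bin_centers < 0.6)
        ]
        assert sig_late.any()


# --- duration comparison and peak shape -------------------------------------


class TestDurations:
    def test_identical_lists_not_different(self):
        r = compare_durations([0.2, 0.3, 0.4] * 4, [0.2, 0.3, 0.4] * 4)
        assert r.p_value == pytest.approx(1.0)

    def test_planted_short_vs_long(self):
        rng = np.random.default_rng(0)
        exc = rng.normal(0.2, 0.05, 30).clip(0.02)
        sup = rng.normal(0.6, 0.15, 30).clip(0.02)
        r = compare_durations(exc, sup)
        assert r.p_value < 0.05
        assert r.median_a < r.median_b

    def test_matches_exact_enumeration_small_n(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 6)
            r = compare_durations(a, b)
            # independent exact computation: enumerate all splits of the
            # pooled sample and count U statistics at least as extreme
            u_obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
            n_a, pooled = len(a), np.concatenate([a, b])
            mu = len(a) * len(b) / 2.0
            hits = 0
            for ix in combinations(range(len(pooled)), n_a):
                sa = pooled[list(ix)]
                sb = np.delete(pooled, list(ix))
                u = stats.mannwhitneyu(sa, sb,
                                       alternative="two-sided").statistic
                if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                    hits += 1
            p_exact = hits / comb(len(pooled), n_a)
            assert r.p_value == pytest.approx(p_exact, abs=0.02)


class TestPeakHalfwidth:
    def _gauss_psth(self, sigma=0.1, baseline=0.0):
        trials = make_fixed_trials(1, start=10.0)
        counts = align_and_bin(
            UnitSpikeTrain("u", np.empty(0)), trials, "odor_on", (0.5, 1.0)
        )
        psth = smooth(counts)
        centers = psth.bin_centers
        rate = baseline + 10.0 * np.exp(-0.5 * ((centers - 0.3) / sigma) ** 2)
        object.__setattr__(psth, "rate", rate)
        return psth

    def test_halfwidth_of_gaussian_is_fwhm(self):
        psth = self._gauss_psth(sigma=0.1)
        peak, hw = peak_and_halfwidth(psth, baseline_rate=0.0)
        assert peak == pytest.approx(10.0, rel=0.02)
        assert hw == pytest.approx(2.355 * 0.1, abs=0.03)

    def test_flat_psth_has_no_halfwidth(self):
        psth = self._gauss_psth(sigma=0.1)
        object.__setattr__(psth, "rate", np.full_like(psth.rate, 4.0))
        peak, hw = peak_and_halfwidth(psth, baseline_rate=4.0)
        assert peak == pytest.approx(4.0)
        assert hw is None


class TestAlignmentComparison:
    def test_fixed_latency_shows_no_difference(self):
        # zero exit-latency jitter: the two alignments are shifted copies
        p = ArchetypeParams("I", 3.0, excitation_gain=5.0,
                            latency_jitter_sd=0.0)
        trials = make_fixed_trials(50, duration=0.8, with_water=True)
        units = [unit_from_params(p, trials, seed=s, unit_id=f"u{s}")
                 for s in range(6)]
        session = Session("s", units, trials)
        cmp_ = alignment_comparison(units, session)
        assert cmp_.p_peak > 0.05
        assert cmp_.warning is not None  # < 10 units

    def test_onset_locked_responses_peak_higher_when_onset_aligned(self):
        # jittered exit latency smears the exit-aligned average
        rng = np.random.default_rng(7)
        p = ArchetypeParams("I", 3.0, excitation_gain=6.0, peak_width=0.05,
                            latency_jitter_sd=0.0)
        units, all_trials = [], []
        t = 5.0
        trials = []
        for i in range(50):
            dur = float(rng.uniform(0.65, 1.2))
            tr = make_fixed_trials(1, duration=dur, start=t)[0]
            object.__setattr__(tr, "trial_id", i)
            trials.append(tr)
            t += dur + 5.0
        units = [unit_from_params(p, trials, seed=40 + s, unit_id=f"u{s}")
                 for s in range(12)]
        session = Session("s", units, trials)
        cmp_ = alignment_comparison(units, session)
        higher = np.mean(cmp_.peaks_onset > cmp_.peaks_exit)
        assert higher >= 0.8
        assert cmp_.p_peak < 0.05


# --- contrasts, stability, population time course ---------------------------


@pytest.fixture(scope="module")
def contrast_session():
    cfg = GeneratorConfig(
        n_units=12, n_trials=160, behavioral_accuracy=0.8,
        odorless_fraction=0.15,
    )
    return generate_session(cfg, 21)


class TestConditionContrast:
    def test_type_i_significant_only_in_correct_go(self, contrast_session):
        session, gt = contrast_session
        t1 = [u for u in session.units if gt.labels[u.unit_id] == "I"]
        assert t1, "fixture must contain a type I unit"
        hits = misses = 0
        for unit in t1:
            res = condition_contrast(unit, session,
                                     config=ClassifierConfig(seed=3))
            assert res["correct_go"].direction == "excitation"
            for cat in ("error", "odorless"):
                if cat in res and res[cat].direction != "none":
                    misses += 1
            hits += 1
        assert misses <= max(1, hits // 5)  # ~alpha-level false positives

    def test_all_categories_present_given_enough_trials(self, contrast_session):
        session, _ = contrast_session
        res = condition_contrast(session.units[0], session,
                                 config=ClassifierConfig(seed=3))
        assert {"correct_go", "correct_no_go", "error", "odorless"} <= set(res)


class TestStability:
    def test_stationary_unit_is_stable(self):
        p = ArchetypeParams("V", 3.0, excitation_gain=1.0,
                            suppression_gain=1.0)
        trials = make_fixed_trials(40, duration=0.8)
        flags = [
            trial_stability(
                unit_from_params(p, trials, seed=s), trials
            ).stable
            for s in range(10)
        ]
        assert np.mean(flags) >= 0.8

    def test_planted_drift_detected(self):
        # rate doubles over the session
        rng = np.random.default_rng(0)
        trials = make_fixed_trials(40, duration=0.8)
        spikes = []
        for i, tr in enumerate(trials):
            lam = 4.0 * (1 + i / len(trials))
            n = rng.poisson(lam * 0.8)
            spikes.append(rng.uniform(tr.odor_on, tr.port_exit, n))
        unit = UnitSpikeTrain("u", np.sort(np.concatenate(spikes)))
        assert not trial_stability(unit, trials).stable

    def test_reversing_trial_order_flips_correlation(self):
        rng = np.random.default_rng(1)
        trials = make_fixed_trials(30, duration=0.8)
        spikes = []
        for i, tr in enumerate(trials):
            n = rng.poisson(2.0 + 0.3 * i)
            spikes.append(rng.uniform(tr.odor_on, tr.port_exit, n))
        unit = UnitSpikeTrain("u", np.sort(np.concatenate(spikes)))
        fwd = trial_stability(unit, trials)
        rev = trial_stability(unit, trials[::-1])
        assert np.sign(fwd.rho) == -np.sign(rev.rho) != 0


class TestSignificantProportions:
    def test_drinking_excitation_elevated_for_type_i(self, small_session):
        session, gt = small_session
        cls = classify_session(session, ClassifierConfig(seed=2, n_perm=300))
        df = significant_proportion_timecourse(
            cls, session, align_events=("water_on",), window=(0.3, 1.0),
            n_perm=300, seed=4,
        )
        assert ((df.fraction >= 0) & (df.fraction <= 1)).all()
        t1 = df[(df.type_label == "I") & (df.direction == "excitation")]
        post = t1[t1.bin_center_s > 0.1].fraction
        assert post.max() > 0.5  # drinking_gain drives excitation

    def test_direction_fractions_sum_to_at_most_one(self, small_session):
        session, gt = small_session
        cls = classify_session(session, ClassifierConfig(seed=2, n_perm=300))
        df = significant_proportion_timecourse(
            cls, session, align_events=("port_exit",), window=(0.2, 0.6),
            n_perm=200, seed=4,
        )
        wide = df.pivot_table(
            index=["type_label", "bin_center_s"], columns="direction",
            values="fraction",
        )
        assert (wide.sum(axis=1) <= 1.0 + 1e-12).all()
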