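"""Cue-response quantification and five-type neuron classification.

The central statistic is the area under the ROC curve (auROC) between
two sets of single-trial firing rates: 0.5 means no discrimination,
values above 0.5 mean the first sample tends to be larger.  The auROC
equals the Mann–Whitney U statistic divided by n_a·n_b, with tied pairs
counted 0.5.  Significance is assessed by a label-permutation test
(two-sided on |auROC − 0.5|, p < 0.01 by default).

Classification (odor-sampling epoch versus the 1 s pre-trial baseline,
correct trials only):

* type I — significant response to ≥1 cue and significant go-cue
  preference (go-vs-no-go auROC > 0.5);
* type II — significant response and significant no-go-cue preference;
* type III — responsive, no preference, excited by both cues;
* type IV — responsive, no preference, suppressed by both cues;
* type V — no significant response to either cue.

Responsive units with no preference and opposite-direction cue
responses (a case the four named patterns do not cover) are assigned by
the direction of the larger |auROC − 0.5|; an exact tie falls to V.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psth import AlignedCounts, SmoothedPSTH, align_and_bin, epoch_rates, smooth
from .session_io import Session, TrialEvents, UnitSpikeTrain, epoch_bounds

__all__ = [
    "AUROCResult",
    "AUROCTrace",
    "NeuronClassification",
    "ClassifierConfig",
    "auroc",
    "permutation_pvalue",
    "auroc_test",
    "classify_neuron",
    "classify_session",
    "type_proportions",
    "sliding_auroc",
    "sliding_auroc_pair",
    "compare_durations",
    "peak_and_halfwidth",
    "alignment_comparison",
    "condition_contrast",
    "trial_stability",
    "significant_proportion_timecourse",
]

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000


# ---------------------------------------------------------------------------
# auROC and permutation test


def auroc(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """auROC of sample_a vs sample_b; ties counted 0.5.

    Equals P(a > b) + 0.5·P(a = b) over all cross pairs, i.e. the
    Mann–Whitney U statistic normalized by n_a·n_b.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("auroc requires non-empty samples")
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    u = r_a - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _rank_auroc_perms(
    ranks: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """auROC values under random relabelings, given pooled ranks."""
    n = ranks.size
    n_b = n - n_a
    # random subsets of size n_a via argsort of uniforms
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
    r_a = ranks[idx].sum(axis=1)
    return (r_a - n_a * (n_a + 1) / 2.0) / (n_a * n_b)


def _exact_auroc_extremes(values: np.ndarray, n_a: int) -> np.ndarray:
    """|auROC − 0.5| for every split of the pooled values."""
    n = values.size
    ranks = stats.rankdata(values)
    n_b = n - n_a
    out = np.empty(comb(n, n_a))
    for i, ix in enumerate(combinations(range(n), n_a)):
        r_a = ranks[list(ix)].sum()
        out[i] = abs((r_a - n_a * (n_a + 1) / 2.0) / (n_a * n_b) - 0.5)
    return out


def permutation_pvalue(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    exact: bool | None = None,
) -> float:
    """Two-sided permutation p for the auROC departing from 0.5.

    Monte-Carlo estimate with add-one smoothing,
    ``p = (1 + #extreme) / (1 + n_perm)``, so p ∈ (0, 1].  When the
    number of distinct splits is small (``exact=None`` switches over at
    ≤ ``n_perm`` splits) the full enumeration is used instead.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("permutation test requires non-empty samples")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs = abs(auroc(a, b) - 0.5)
    pooled = np.concatenate([a, b])
    n_splits = comb(pooled.size, a.size)
    if exact is None:
        exact = n_splits <= n_perm
    if exact:
        extremes = _exact_auroc_extremes(pooled, a.size)
        return float(np.mean(extremes >= obs - 1e-12))
    ranks = stats.rankdata(pooled)
    perms = _rank_auroc_perms(
        ranks, a.size, n_perm, np.random.default_rng(seed)
    )
    n_extreme = int(np.sum(np.abs(perms - 0.5) >= obs - 1e-12))
    return (1 + n_extreme) / (1 + n_perm)


@dataclass(frozen=True)
class AUROCResult:
    auroc: float
    p_value: float
    n_a: int
    n_b: int
    direction: str  # {"excitation", "suppression", "none"}

    @property
    def significant(self) -> bool:
        return self.direction != "none"


def auroc_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> AUROCResult:
    """auROC of a vs b with permutation significance and direction."""
    value = auroc(sample_a, sample_b)
    p = permutation_pvalue(sample_a, sample_b, n_perm=n_perm, seed=seed)
    if p < alpha and value > 0.5:
        direction = "excitation"
    elif p < alpha and value < 0.5:
        direction = "suppression"
    else:
        direction = "none"
    return AUROCResult(
        auroc=value,
        p_value=p,
        n_a=len(sample_a),
        n_b=len(sample_b),
        direction=direction,
    )


def _unit_seed(seed: int, unit_id: str, salt: int = 0) -> int:
    """Stable per-unit child seed (< 2**31)."""
    h = zlib.crc32(f"{unit_id}:{salt}".encode())
    return int((seed * 2654435761 + h) % (2**31))


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ClassifierConfig:
    min_trials: int = 10  # correct trials required per condition
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    baseline_epoch: str = "baseline_long"
    response_epoch: str = "odor_sampling"


@dataclass(frozen=True)
class NeuronClassification:
    unit_id: str
    type_label: str | None  # None when unclassifiable
    go: AUROCResult | None
    nogo: AUROCResult | None
    preference: AUROCResult | None

    @property
    def classifiable(self) -> bool:
        return self.type_label is not None

    @property
    def responsive(self) -> bool:
        return self.type_label is not None and self.type_label != "V"


def classify_neuron(
    unit: UnitSpikeTrain,
    session: Session,
    config: ClassifierConfig | None = None,
) -> NeuronClassification:
    """Assign one of the five response types to a unit.

    Uses correct go-cue and no-go-cue trials only; odor-sampling-epoch
    rates are compared against the 1 s pre-trial baseline of the same
    trials, and go against no-go rates for the preference.
    """
    cfg = config or ClassifierConfig()
    go_trials = session.select_trials("go", "correct", "go-cue")
    nogo_trials = session.select_trials("no-go", "correct", "no-go-cue")
    if len(go_trials) < cfg.min_trials or len(nogo_trials) < cfg.min_trials:
        return NeuronClassification(unit.unit_id, None, None, None, None)

    go_rates = epoch_rates(unit, go_trials, cfg.response_epoch)
    go_base = epoch_rates(unit, go_trials, cfg.baseline_epoch)
    nogo_rates = epoch_rates(unit, nogo_trials, cfg.response_epoch)
    nogo_base = epoch_rates(unit, nogo_trials, cfg.baseline_epoch)

    s = cfg.seed
    go = auroc_test(go_rates, go_base, cfg.n_perm,
                    _unit_seed(s, unit.unit_id, 1), cfg.alpha)
    nogo = auroc_test(nogo_rates, nogo_base, cfg.n_perm,
                      _unit_seed(s, unit.unit_id, 2), cfg.alpha)

    if not (go.significant or nogo.significant):
        return NeuronClassification(unit.unit_id, "V", go, nogo, None)

    pref = auroc_test(go_rates, nogo_rates, cfg.n_perm,
                      _unit_seed(s, unit.unit_id, 3), cfg.alpha)
    if pref.direction == "excitation":
        label = "I"
    elif pref.direction == "suppression":
        label = "II"
    else:
        go_exc, nogo_exc = go.auroc > 0.5, nogo.auroc > 0.5
        if go_exc and nogo_exc:
            label = "III"
        elif not go_exc and not nogo_exc:
            label = "IV"
        else:
            # mixed directions without preference: follow the larger effect
            dgo, dnogo = abs(go.auroc - 0.5), abs(nogo.auroc - 0.5)
            if dgo == dnogo:
                label = "V"
            else:
                label = "III" if (dgo > dnogo) == go_exc else "IV"
    return NeuronClassification(unit.unit_id, label, go, nogo, pref)


def classify_session(
    session: Session, config: ClassifierConfig | None = None
) -> list[NeuronClassification]:
    return [classify_neuron(u, session, config) for u in session.units]


def type_proportions(
    classifications: Sequence[NeuronClassification],
) -> dict[str, float]:
    """Fraction of classifiable units per type label."""
    usable = [c for c in classifications if c.classifiable]
    n = len(usable)
    return {
        t: (sum(1 for c in usable if c.type_label == t) / n if n else np.nan)
        for t in ("I", "II", "III", "IV", "V")
    }


# ---------------------------------------------------------------------------
# sliding auROC traces


@dataclass(frozen=True)
class AUROCTrace:
    unit_id: str
    condition: str
    align_event: str
    bin_centers: np.ndarray
    auroc: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray  # bool per bin
    n_trials: np.ndarray  # valid trials per bin
    width: float
    step: float
    onset_time: float | None
    center_of_mass: float | None
    duration: float

    def direction(self) -> np.ndarray:
        """Per-bin direction string given significance flags."""
        out = np.full(self.auroc.shape, "none", dtype=object)
        out[self.significant & (self.auroc > 0.5)] = "excitation"
        out[self.significant & (self.auroc < 0.5)] = "suppression"
        return out


def _trace_measures(
    centers: np.ndarray,
    values: np.ndarray,
    sig: np.ndarray,
    step: float,
    min_consecutive: int,
) -> tuple[float | None, float | None, float]:
    """Onset (first run of >= min_consecutive significant bins),
    |auROC−0.5|-weighted center of mass over significant bins, and
    total significant duration."""
    duration = float(sig.sum() * step)
    onset = None
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= min_consecutive:
            onset = float(centers[i - min_consecutive + 1])
            break
    com = None
    if sig.any():
        w = np.abs(values[sig] - 0.5)
        if w.sum() > 0:
            com = float(np.sum(centers[sig] * w) / w.sum())
        else:
            com = float(np.mean(centers[sig]))
    return onset, com, duration


def _sliding_bins(
    window: tuple[float, float], width: float, step: float
) -> np.ndarray:
    """Centers of sliding bins fully contained in [-pre, post]."""
    pre, post = window
    first = -pre + width / 2
    last = post - width / 2
    n = int(np.floor((last - first) / step + 1e-9)) + 1
    return first + step * np.arange(max(n, 0))


def _bin_rates(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialEvents],
    align_event: str,
    centers: np.ndarray,
    width: float,
) -> np.ndarray:
    """(n_trials, n_bins) firing rates in sliding bins around the event."""
    rates = np.empty((len(trials), centers.size))
    for i, trial in enumerate(trials):
        t0 = trial.event_time(align_event)
        for j, c in enumerate(centers):
            rates[i, j] = unit.count_in(t0 + c - width / 2, t0 + c + width / 2) / width
    return rates


def _per_bin_tests(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    valid: np.ndarray,
    n_perm: int,
    alpha: float,
    min_trials: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-bin auROC + permutation test.

    rates_a: (n_a, n_bins) sample-a rates; rates_b: either matching
    per-trial scalars broadcast per bin (n_a,) — paired baseline — or a
    (n_b, n_bins) matrix.  ``valid`` masks sample-a trials per bin.
    """
    n_bins = rates_a.shape[1]
    av = np.full(n_bins, np.nan)
    pv = np.full(n_bins, np.nan)
    sig = np.zeros(n_bins, bool)
    n_valid = np.zeros(n_bins, int)
    paired = rates_b.ndim == 1
    for j in range(n_bins):
        mask = valid[:, j]
        n_valid[j] = int(mask.sum())
        if n_valid[j] < min_trials:
            continue
        a = rates_a[mask, j]
        b = rates_b[mask] if paired else rates_b[:, j]
        if b.size < min_trials:
            continue
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        r_a = ranks[: a.size].sum()
        obs = (r_a - a.size * (a.size + 1) / 2.0) / (a.size * b.size)
        av[j] = obs
        perms = _rank_auroc_perms(ranks, a.size, n_perm, rng)
        n_ext = int(np.sum(np.abs(perms - 0.5) >= abs(obs - 0.5) - 1e-12))
        pv[j] = (1 + n_ext) / (1 + n_perm)
        sig[j] = pv[j] < alpha
    return av, pv, sig, n_valid


def sliding_auroc(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialEvents],
    condition: str = "",
    align_event: str = "odor_on",
    baseline_epoch: str = "baseline_short",
    window: tuple[float, float] = (0.2, 1.0),
    width: float = 0.100,
    step: float = 0.020,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    min_consecutive: int = 3,
    min_trials: int = 5,
    limit_event: str | None = "port_exit",
) -> AUROCTrace:
    """Sliding-bin auROC of event-aligned rates versus per-trial baseline.

    100 ms bins stepped by 20 ms; each bin's rates across trials are
    tested against a *bin-width-matched* baseline: the spike rate in the
    last ``width`` seconds of the (200 ms) short pre-trial baseline
    epoch.  Matching the window width makes the two count distributions
    identical under stationarity — comparing rates from unequal windows
    is not exchangeable (the coarser discreteness of the narrow window
    biases the auROC away from 0.5 even for a constant-rate unit) and
    would invalidate the permutation null.  When ``limit_event`` is set (default the odor port exit for
    odor-onset alignment), trials whose limit event falls before the end
    of a bin are dropped from that bin, so bins never mix post-epoch
    data in.  Onset requires ``min_consecutive`` consecutive significant
    bins; duration totals the significant bins; the center of mass
    weights significant bin centers by |auROC − 0.5|.
    """
    if align_event != "odor_on" and limit_event == "port_exit":
        limit_event = None  # the default limit only makes sense pre-exit
    centers = _sliding_bins(window, width, step)
    rates = _bin_rates(unit, trials, align_event, centers, width)
    base = np.empty(len(trials))
    for i, t in enumerate(trials):
        _, b_end = epoch_bounds(t, baseline_epoch)
        base[i] = unit.count_in(b_end - width, b_end) / width
    valid = np.ones(rates.shape, bool)
    if limit_event is not None:
        for i, t in enumerate(trials):
            lim = t.event_time(limit_event)
            if lim is not None:
                rel_lim = lim - t.event_time(align_event)
                valid[i] = centers + width / 2 <= rel_lim + 1e-12
    rng = np.random.default_rng(_unit_seed(seed, unit.unit_id, 7))
    av, pv, sig, n_valid = _per_bin_tests(
        rates, base, valid, n_perm, alpha, min_trials, rng
    )
    onset, com, duration = _trace_measures(centers, av, sig, step, min_consecutive)
    return AUROCTrace(
        unit_id=unit.unit_id,
        condition=condition,
        align_event=align_event,
        bin_centers=centers,
        auroc=av,
        p_values=pv,
        significant=sig,
        n_trials=n_valid,
        width=width,
        step=step,
        onset_time=onset,
        center_of_mass=com,
        duration=duration,
    )


def sliding_auroc_pair(
    unit: UnitSpikeTrain,
    trials_a: Sequence[TrialEvents],
    trials_b: Sequence[TrialEvents],
    condition: str = "go_vs_nogo",
    align_event: str = "odor_on",
    window: tuple[float, float] = (0.2, 1.0),
    width: float = 0.100,
    step: float = 0.020,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    min_consecutive: int = 3,
    min_trials: int = 5,
) -> AUROCTrace:
    """Sliding-bin auROC between two trial sets (e.g. go-vs-no-go
    preference), bin against matching bin."""
    centers = _sliding_bins(window, width, step)
    ra = _bin_rates(unit, trials_a, align_event, centers, width)
    rb = _bin_rates(unit, trials_b, align_event, centers, width)
    valid = np.ones(ra.shape, bool)
    rng = np.random.default_rng(_unit_seed(seed, unit.unit_id, 8))
    av, pv, sig, n_valid = _per_bin_tests(
        ra, rb, valid, n_perm, alpha, min_trials, rng
    )
    onset, com, duration = _trace_measures(centers, av, sig, step, min_consecutive)
    return AUROCTrace(
        unit_id=unit.unit_id,
        condition=condition,
        align_event=align_event,
        bin_centers=centers,
        auroc=av,
        p_values=pv,
        significant=sig,
        n_trials=n_valid,
        width=width,
        step=step,
        onset_time=onset,
        center_of_mass=com,
        duration=duration,
    )


# ---------------------------------------------------------------------------
# duration comparison, peak shape, alignment contrast


@dataclass(frozen=True)
class RankSumReport:
    p_value: float
    statistic: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    exact: bool


def compare_durations(
    excitation_durations: Sequence[float],
    suppression_durations: Sequence[float],
) -> RankSumReport:
    """Two-sided Wilcoxon rank-sum comparison of response durations."""
    a = np.asarray(excitation_durations, float)
    b = np.asarray(suppression_durations, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both duration lists must be non-empty")
    exact = a.size < 3 or b.size < 3
    if exact:
        import warnings

        warnings.warn("fewer than 3 durations on one side; exact test used",
                      stacklevel=2)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "auto"
    )
    return RankSumReport(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=a.size,
        n_b=b.size,
        exact=exact,
    )


def peak_and_halfwidth(
    psth: SmoothedPSTH,
    baseline_rate: float | None = None,
    search_window: tuple[float, float] | None = None,
) -> tuple[float, float | None]:
    """Peak rate and temporal half-width of a smoothed PSTH.

    The half-width is the contiguous span around the peak where the rate
    stays at or above baseline + (peak − baseline)/2.  ``baseline_rate``
    defaults to the mean rate over pre-event bins (centers < 0), or 0
    when the window starts at the event.  Returns (peak, None) for a
    flat PSTH.
    """
    centers = psth.bin_centers
    rate = psth.rate
    mask = np.ones(centers.size, bool)
    if search_window is not None:
        mask = (centers >= search_window[0]) & (centers <= search_window[1])
        if not mask.any():
            raise ValueError("empty search window")
    if baseline_rate is None:
        pre = centers < 0
        baseline_rate = float(rate[pre].mean()) if pre.any() else 0.0
    sub_rate = rate[mask]
    sub_centers = centers[mask]
    i_peak = int(np.argmax(sub_rate))
    peak = float(sub_rate[i_peak])
    if peak - baseline_rate <= 1e-12:
        return peak, None
    level = baseline_rate + (peak - baseline_rate) / 2.0
    above = sub_rate >= level
    lo = i_peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    half_width = float(sub_centers[hi] - sub_centers[lo] + psth.bin_width)
    return peak, half_width


@dataclass(frozen=True)
class AlignmentComparison:
    unit_ids: list[str]
    peaks_onset: np.ndarray
    peaks_exit: np.ndarray
    halfwidths_onset: np.ndarray
    halfwidths_exit: np.ndarray
    p_peak: float
    p_halfwidth: float
    warning: str | None


def alignment_comparison(
    units: Sequence[UnitSpikeTrain],
    session: Session,
    window_onset: tuple[float, float] = (0.2, 1.0),
    window_exit: tuple[float, float] = (1.0, 0.4),
    search: tuple[float, float] = (0.0, 1.0),
) -> AlignmentComparison:
    """Paired peak/half-width contrast: odor-onset vs port-exit alignment.

    For each unit the correct-go PSTH is computed aligned to the odor
    valve opening and to the odor port exit; peaks and half-widths are
    compared across units with the Wilcoxon signed-rank test.  A
    response locked to odor onset shows a higher, tighter peak in the
    onset alignment because exit latency jitter smears the exit-aligned
    average.
    """
    trials = session.select_trials("go", "correct", "go-cue")
    uids, pk_on, pk_ex, hw_on, hw_ex = [], [], [], [], []
    for unit in units:
        psth_on = smooth(align_and_bin(unit, trials, "odor_on", window_onset))
        psth_ex = smooth(align_and_bin(unit, trials, "port_exit", window_exit))
        p_on, h_on = peak_and_halfwidth(psth_on, search_window=search)
        p_ex, h_ex = peak_and_halfwidth(
            psth_ex, search_window=(-search[1], search[1])
        )
        uids.append(unit.unit_id)
        pk_on.append(p_on)
        pk_ex.append(p_ex)
        hw_on.append(np.nan if h_on is None else h_on)
        hw_ex.append(np.nan if h_ex is None else h_ex)
    pk_on, pk_ex = np.asarray(pk_on), np.asarray(pk_ex)
    hw_on, hw_ex = np.asarray(hw_on), np.asarray(hw_ex)
    warning = None
    if len(uids) < 10:
        warning = f"only {len(uids)} units; paired statistics are unstable"

    def signed_rank(x: np.ndarray, y: np.ndarray) -> float:
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 2 or np.allclose(x[ok], y[ok]):
            return 1.0
        return float(stats.wilcoxon(x[ok], y[ok]).pvalue)

    return AlignmentComparison(
        unit_ids=uids,
        peaks_onset=pk_on,
        peaks_exit=pk_ex,
        halfwidths_onset=hw_on,
        halfwidths_exit=hw_ex,
        p_peak=signed_rank(pk_on, pk_ex),
        p_halfwidth=signed_rank(hw_on, hw_ex),
        warning=warning,
    )


# ---------------------------------------------------------------------------
# condition contrasts, stability, population time courses

CONTRAST_CATEGORIES = ("correct_go", "correct_no_go", "error", "odorless")


def _category_trials(session: Session, category: str) -> list[TrialEvents]:
    if category == "correct_go":
        return session.select_trials("go", "correct", "go-cue")
    if category == "correct_no_go":
        return session.select_trials("no-go", "correct", "no-go-cue")
    if category == "error":
        return [t for t in session.trials
                if t.outcome == "error" and t.odor_kind != "odorless"]
    if category == "odorless":
        return session.select_trials(odor_kind="odorless")
    raise ValueError(f"unknown category {category!r}")


def condition_contrast(
    unit: UnitSpikeTrain,
    session: Session,
    categories: Sequence[str] = CONTRAST_CATEGORIES,
    config: ClassifierConfig | None = None,
) -> dict[str, AUROCResult]:
    """Odor-sampling-vs-baseline auROC per trial category.

    Categories with fewer than ``config.min_trials`` trials are omitted
    from the result (callers can detect the missing keys).
    """
    cfg = config or ClassifierConfig()
    out: dict[str, AUROCResult] = {}
    for k, category in enumerate(categories):
        trials = _category_trials(session, category)
        if len(trials) < cfg.min_trials:
            continue
        rates = epoch_rates(unit, trials, cfg.response_epoch)
        base = epoch_rates(unit, trials, cfg.baseline_epoch)
        out[category] = auroc_test(
            rates, base, cfg.n_perm,
            _unit_seed(cfg.seed, unit.unit_id, 100 + k), cfg.alpha
        )
    return out


@dataclass(frozen=True)
class StabilityResult:
    rho: float
    p_value: float
    slope: float  # Hz per trial, least-squares
    stable: bool  # no significant monotone drift at alpha 0.05
    n_trials: int


def trial_stability(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialEvents],
    epoch_name: str = "odor_sampling",
    alpha: float = 0.05,
) -> StabilityResult:
    """Across-trial stability of the epoch response (Spearman vs index)."""
    if len(trials) < 20:
        raise ValueError("stability requires >= 20 trials")
    rates = epoch_rates(unit, trials, epoch_name)
    idx = np.arange(rates.size, dtype=float)
    if np.allclose(rates, rates[0]):
        return StabilityResult(0.0, 1.0, 0.0, True, rates.size)
    rho, p = stats.spearmanr(idx, rates)
    slope = float(np.polyfit(idx, rates, 1)[0])
    return StabilityResult(
        rho=float(rho), p_value=float(p), slope=slope,
        stable=bool(p >= alpha), n_trials=rates.size,
    )


def significant_proportion_timecourse(
    classifications: Sequence[NeuronClassification],
    session: Session,
    trial_category: str = "correct_go",
    align_events: Sequence[str] = ("port_exit",),
    window: tuple[float, float] = (0.5, 1.5),
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    width: float = 0.100,
    step: float = 0.020,
) -> pd.DataFrame:
    """Per-type fraction of units significantly excited/suppressed per bin.

    For every classified unit a sliding auROC trace versus the short
    baseline is computed per alignment event; the output is a long-format
    table (align_event, type_label, bin_center_s, direction, fraction).
    Types with no classified units are absent.
    """
    trials_all = _category_trials(session, trial_category)
    by_type: dict[str, list[str]] = {}
    for c in classifications:
        if c.classifiable:
            by_type.setdefault(c.type_label, []).append(c.unit_id)

    rows = []
    for align_event in align_events:
        trials = [t for t in trials_all if t.event_time(align_event) is not None]
        if not trials:
            continue
        for label, uids in sorted(by_type.items()):
            exc = None
            sup = None
            centers = None
            for uid in uids:
                trace = sliding_auroc(
                    session.unit(uid), trials, condition=trial_category,
                    align_event=align_event, window=window, width=width,
                    step=step, n_perm=n_perm, seed=seed, alpha=alpha,
                    limit_event=None,
                )
                d = trace.direction()
                if exc is None:
                    centers = trace.bin_centers
                    exc = np.zeros(centers.size)
                    sup = np.zeros(centers.size)
                exc += d == "excitation"
                sup += d == "suppression"
            for direction, acc in (("excitation", exc), ("suppression", sup)):
                frac = acc / len(uids)
                for c, f in zip(centers, frac):
                    rows.append(
                        {
                            "align_event": align_event,
                            "type_label": label,
                            "bin_center_s": float(c),
                            "direction": direction,
                            "fraction": float(f),
                        }
                    )
    return pd.DataFrame(rows)
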