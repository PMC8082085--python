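# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions taken
where the design was genuinely open.

## Time and event conventions

Time is in seconds (float64) on the session clock. Events are instants;
epochs are half-open intervals `[start, end)`. Odor valve opening and
odor port entry are the same instant (`odor_on`): the nose poke
triggers the valve. Named epochs:

| epoch            | bounds                              | used for |
|------------------|-------------------------------------|----------|
| `baseline_long`  | `[iti_end − 1.0, iti_end)`          | classification baseline |
| `baseline_short` | `[iti_end − 0.2, iti_end)`          | sliding-trace baseline |
| `odor_sampling`  | `[odor_on, port_exit)`              | cue response |
| `drinking`       | `[water_on, water_on + 1.0)`        | reward responses |
| `no_go_waiting`  | `[port_exit, port_exit + 1.0)`      | waiting responses |

Binning is half-open with a spike exactly on an edge assigned to the
later bin; a tolerance of 10⁻⁹ bin widths absorbs float cancellation so
the assignment is invariant to shifting the whole session clock.

## auROC and the permutation test

For two sets of single-trial firing rates the auROC is
`P(a > b) + ½·P(a = b)` over all cross pairs — computed through average
ranks, which is exactly the Mann–Whitney U statistic divided by
n₁·n₂ and is antisymmetric under swapping the samples, ties included.

Significance is two-sided on `|auROC − 0.5|` under random relabeling of
the pooled trials. With Monte-Carlo sampling (default 1,000
permutations, seeded per unit) the p-value uses add-one smoothing,
`p = (1 + #extreme)/(1 + n_perm)`, so p ∈ (0, 1] and the test is valid
(never anti-conservative) at any permutation count. When the number of
distinct splits is at most `n_perm` the full enumeration is used
instead, making small-sample p-values exact. Degenerate all-equal data
give p = 1. Calibration: on 2,000 simulated null unit-condition pairs
(Poisson counts, 20 trials a side) the rejection rate at α = 0.01 falls
in [0.005, 0.02] (the discreteness of tied counts makes the test
slightly conservative, as expected).

**Exchangeability of the per-bin baseline.** Sliding-trace bins (100 ms)
are *not* compared against the 200 ms baseline-epoch rate: rates from
windows of unequal length have different discreteness, and for a
constant-rate unit near 3 Hz the expected auROC of a 100 ms-window rate
against a 200 ms-window rate is ≈ 0.45, not 0.5 — the permutation null
assumes exchangeability and would flag such bins. Each sliding bin is
instead compared against a *width-matched* baseline bin (the last
`width` seconds of the short baseline epoch). With this choice a
stationary unit shows ≈ 1% significant bins at α = 0.01. Neuron-level
classification keeps the conventional epoch-versus-1 s-baseline
contrast; at epoch scale (hundreds of ms, tens of trials) the residual
discreteness bias is well inside the permutation noise, and recovery on
ground-truth sessions exceeds 90%.

## Five-type classification

Using correct trials only, with at least 10 trials per condition
(otherwise the unit is flagged unclassifiable and excluded from
proportions):

1. go-cue and no-go-cue odor-sampling rates are each tested against the
   same trials' 1 s baselines (p < 0.01, permutation). No significant
   response to either cue → **type V**.
2. Among responsive units, the go-versus-no-go preference auROC is
   tested: significant > 0.5 → **type I**, significant < 0.5 →
   **type II**.
3. No preference: both point auROCs > 0.5 → **type III**; both < 0.5 →
   **type IV**; mixed directions (a case the four patterns do not
   cover) follow the direction of the larger |auROC − 0.5|, with an
   exact tie falling to type V. This residual rule is deterministic and
   affects only units at the significance boundary.

## Sliding auROC traces and derived measures

100 ms bins stepped by 20 ms, indexed by bin center, aligned to a task
event (odor onset by default). For odor-onset alignment, trials whose
port exit falls before the end of a bin are dropped from that bin, so
bins never mix post-sampling data in; bins with fewer than 5 valid
trials are undefined. Derived measures:

* **onset** — center of the first bin of the first run of ≥ 3
  consecutive significant bins (the run requirement suppresses isolated
  false positives at the per-bin α of 0.01);
* **duration** — number of significant bins × step;
* **center of mass** — Σ t·|auROC(t) − 0.5| / Σ |auROC(t) − 0.5| over
  significant bins. On a planted symmetric response centered 500 ms
  after odor onset this recovers 500 ± 20 ms.

No multiple-comparison correction is applied across bins; the per-bin
α = 0.01 is reported as-is, which is why onset uses the run criterion.

## PSTHs, peak and half-width

Spike counts in 20 ms bins, trial-averaged, converted to Hz, and
convolved with a Gaussian kernel of SD 60 ms ("60 ms wide" is read as
the SD; FWHM and full-support readings are selectable via
`kernel_sd`). The kernel is discretized to ± 4 SD and renormalized at
window edges (truncated-kernel renormalization), so a constant rate
stays constant up to the boundary and total spike mass is conserved to
≤ 1% for windows ≥ 6 kernel SDs. Peak rate is the maximum of the
smoothed trial average; the half-width is the contiguous span around
the peak where the rate stays above baseline + (peak − baseline)/2
(absent for a flat PSTH). Comparing odor-onset against port-exit
alignment across units uses the Wilcoxon signed-rank test on the
paired peaks and half-widths.

## Encoding GLM

Response: spike counts in 20 ms bins over the analysis span
`[odor_on + 0.370, port_exit)` of correct go trials (370 ms is the
median go-cue excitation onset; trials with an empty span are dropped
and counted). Predictors: two variable groups of 8 raised-cosine basis
functions each — cos² bumps whose centers tile the window with spacing
equal to their half-support, giving an exact partition of unity away
from the edges — anchored at odor onset (window 0.37–0.90 s) and at
port exit (window −0.30–0 s). A boxcar basis is available for tests.

Fitting: Poisson GLM with log link and an L2 (ridge) penalty
(scikit-learn `PoissonRegressor`), the penalty chosen from the grid
{10⁻⁴, 10⁻², 1} by grouped 3-fold CV on the full model and *reused for
the reduced models*, so full/reduced comparisons are not confounded by
different regularization. "Explained variance" is cross-validated
deviance-explained relative to an intercept-only model, with 5 outer
folds grouped by trial so bins of one trial never straddle the split.
The relative contribution of variable v is
`max(0, R²_full − R²_without_v)`, normalized across variables (uniform
with a warning if all are zero). PSTH-reconstruction r correlates
held-out per-bin predictions with observed counts after re-aligning
both to odor onset or port exit and averaging across trials.

On 50 simulated units with a planted 70/30 odor-onset/pre-exit
variance split the mean recovered contribution is within ±10 points;
single-source units recover ≈ 100/0. The two kernels overlap in
absolute time on short trials; identifiability comes from the
trial-to-trial variability of sampling durations.

## Population geometry

The pseudopopulation matrix holds per-unit, per-condition
trial-averaged smoothed rates on a common odor-onset-aligned grid
(units lacking 10 correct trials in a condition are excluded and
counted), z-scored per unit over the concatenated conditions
(zero-variance units map to zeros; z-scoring prevents high-rate units
dominating the PCA, and a raw option is retained for sensitivity
checks). The binning window is padded by 4 kernel SDs and cropped
after smoothing, so edge renormalization cannot inflate variance at
the boundary bins — important because the baseline significance band
is estimated from the earliest bins.

PCA is fitted jointly on both conditions (samples = time bins ×
conditions, features = units), giving one shared subspace; per-
condition trajectories are the projections. Separation is the per-bin
Euclidean distance between the two condition vectors, computed in the
full normalized space by default (any subspace projection can only
shrink it); velocity is `‖x(t + w) − x(t)‖ / w` with w = 100 ms stepped
by 20 ms. Both traces carry a baseline band (mean ± 2 SD over pre-odor
bins) and per-bin flags above mean + 2 SD.

Because smoothing correlates adjacent bins, isolated noise excursions
above the 2 SD band span up to a kernel width and their per-bin rate
does not shrink with more units or trials (the band is estimated from
the same fluctuations it thresholds). Divergence-onset statements in
the tests and the acceptance script therefore use the first *sustained*
run (≥ 120 ms) of flagged bins — the same logic as the trace onset
rule — and aggregate the median over sessions.

Per-unit weights are |loading| on a chosen component; sliding weights
re-fit PCA per 100 ms window. Across-type weight comparisons use
one-way ANOVA with Tukey's HSD (statsmodels).

## Decoding

Pseudotrials resample each sampled unit's class-conditioned correct
trials independently (with replacement), which destroys within-session
noise correlations — the standard pseudopopulation construction when
units come from different sessions. The classifier is a linear-kernel
SVM (C = 1; the margin parameter is not critical for spike counts at
these scales).

**Cross-validation is at the source-trial level.** Each unit's real
trials are partitioned into 5 folds first; training pseudotrials are
resampled from the training chunks and test pseudotrials from the
held-out chunk, so no real trial informs both sides. Resampling before
splitting would leak each unit's class-mean sampling noise across the
split and bias accuracy above chance on non-selective data (measured:
≈ 0.67 with 20 units where chance is 0.5); with source-level CV,
non-selective populations decode at 0.50 ± 0.05. Accuracy time courses
report mean ± SD over independent unit samples per population size,
with a 50% chance line, the sessions' behavioral accuracy as reference,
and per window the smallest population size whose mean accuracy reaches
it.

## Synthetic sessions

The generator emulates one recording session of the go/no-go task:

* **Baseline rates** — log-normal with median 0.90 Hz; σ is solved from
  the quartile ratio (0.23–3.07 Hz), matching the geometric spread. A
  two-parameter log-normal cannot match both asymmetric quartiles
  exactly; the fitted quartiles are within ~9%.
* **Trial table** — randomized go/no-go cues; odor presentation 0.5 s;
  odor-sampling durations log-normal left-truncated at 0.5 s (the task
  requires the nose to stay in during presentation), with (μ, σ) solved
  numerically so the *truncated* distribution has medians/upper
  quartiles 788/962 ms (go) and 642/798 ms (no-go); outcome is an error
  with probability 1 − accuracy (default 0.9; the task criterion is
  >80%); inter-trial gaps are long enough that no epochs of adjacent
  trials overlap.
* **Archetypes** — type I: Gaussian excitation bump on correct go
  trials (peak 500 ms after odor onset, SD 60 ms, amplitude set so the
  mean rate over the ±3 SD support is `excitation_gain` × baseline,
  default 8) plus sustained suppression on correct no-go trials
  (× 0.1 from 350 ms after onset until 0.8 s past port exit), drinking
  excitation (× 3) and waiting suppression (× 0.3); type II is the
  mirror image; type III bumps to both cues; type IV suppresses to both
  (with waiting excitation × 2.5); type V is flat. Bump latency jitters
  trial-to-trial with SD 20 ms (not reported empirically; exposed as a
  parameter). Error and odorless trials fire at baseline, reflecting
  the finding that distinct cue responses occur only on correct go
  trials. Default type proportions are the reported ones
  (38.9/5.8/11.5/17.0/26.8%).
* **Responsive-type baseline floor** — units assigned archetypes I–IV
  redraw their baseline until it exceeds 0.5 Hz. A near-silent neuron
  cannot express measurable suppression in counts, so labeling it with
  a responsive archetype would plant ground truth that no analysis
  (including an ideal observer) could recover; in recorded data such
  units necessarily land in the non-responsive class. Type V keeps the
  full log-normal tail.
* **Spikes** — inhomogeneous Poisson by thinning against the per-trial
  rate ceiling, homogeneous baseline between trials. No refractory
  period or inter-neuron correlation is modeled: all analyses operate
  on rates, not spike-train fine structure.

What passing tests on this generator do **not** show about real data:
recovery rates assume independent Poisson variability (real spike
counts are often over-dispersed and correlated across simultaneously
recorded units, which weakens both classification power and the
pseudopopulation decoding construction), archetypes are discrete
(real response profiles grade into each other), and behavioral timing
is stationary within a session.

## Problem sizes and determinism

Default analysis scale is one session of 100 units × 160–200 trials —
enough for ≥ 60 correct trials per condition, the regime in which
classification recovery is ≥ 90%; tests and the acceptance script use
this scale, with smaller sessions for shape/contract checks. Every
stochastic step (generation, permutations, CV folds, unit resampling)
takes an explicit seed; the pipeline fans one global seed out to
per-stage child seeds via `numpy.random.SeedSequence` spawn keys and
records them in the run manifest, making two runs from the same
config byte-identical.

## Known limitations

* The deposited-data adapter (`load_deposited`) accepts only the
  package's plain-text layout; the external archive's internal format
  is undocumented, so loading it requires a one-time conversion.
* The GLM names only the two kernels (odor-triggered, pre-port-exit);
  licking-rate, respiration or spike-history terms are out of scope.
* Per-bin significance is uncorrected across bins by design; onset and
  divergence statements must use the sustained-run rules above.
* The half-width measure assumes a unimodal peak; multi-peaked PSTHs
  report the span around the global maximum only.
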