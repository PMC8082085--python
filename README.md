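# nlot

Spike-train analysis of single units recorded in the nucleus of the
lateral olfactory tract (NLOT) — or any olfactory-cortex region — while
an animal performs an odor-guided go/no-go task. The package is for
systems neuroscientists who have sorted spike trains plus a per-trial
behavioral event table and want the full single-unit and population
characterization of cue coding:

1. **Cue-response quantification** — the area under the ROC curve
   (auROC) between odor-sampling-epoch firing rates and pre-trial
   baseline rates, with permutation-test significance (p < 0.01).
   The auROC equals the Mann–Whitney U statistic normalized by
   n₁·n₂ (ties counted ½): 0.5 = no discrimination, >0.5 = excitation,
   <0.5 = suppression.
2. **Five-type classification** — type I (significant go-cue
   preference), type II (no-go-cue preference), type III / IV
   (responsive to both cues without preference, excited / suppressed),
   type V (non-responsive).
3. **Sliding-window response dynamics** — auROC traces in 100 ms bins
   stepped by 20 ms, with onset time, significance-weighted center of
   mass, and response duration; peak rate and temporal half-width under
   odor-onset versus port-exit alignment (Wilcoxon signed-rank).
4. **Encoding model** — a ridge-penalized Poisson GLM predicting binned
   spike counts from 370 ms after odor onset to the odor port exit,
   with raised-cosine kernels anchored at odor onset and at port exit;
   each kernel's *relative contribution* is the drop in cross-validated
   deviance-explained when it is removed.
5. **Population geometry** — PCA trajectories of the trial-averaged,
   z-scored pseudopopulation; go-vs-no-go separation distance and
   trajectory velocity with mean ± 2 SD baseline bands; per-unit
   subspace weights with ANOVA/Tukey comparison across types.
6. **Decoding** — sliding-window linear-kernel SVM classification of
   trial type from pseudopopulation spike counts, with neuron-dropping
   curves and the minimal population size reaching behavioral accuracy.

A seeded synthetic-session generator provides ground-truth neuron
archetypes with the statistical structure the analysis assumes
(log-normal baseline rates, realistic odor-sampling durations, >80%
behavioral accuracy, inhomogeneous-Poisson spikes), so every stage is
testable end-to-end without any recordings.

## Worked example

Run the full pipeline on a small synthetic session from the shell:

```bash
cat > example.yaml <<'YAML'
mode: synthetic
seed: 42
n_perm: 500
generator:
  n_units: 40
  n_trials: 120
decoding_sizes: [1, 5, 10, 25, 40]
decoding_resamples: 5
decoding_step: 0.1
YAML
nlot run --config example.yaml --out example_run
```

which prints (about 15 s on a laptop):

```
Run summary — example_run
  units: 40  trials: 120  behavioral accuracy: 91.7%
  type proportions: I: 37.5%  II: 2.5%  III: 15.0%  IV: 10.0%  V: 35.0%
  responsive (≥1 cue): 65.0%
  GLM mean contributions: odor_onset: 100.0%  pre_port_exit: 0.0%
  decoding reaches behavioral accuracy (91.7%) from 0.350 s with 10 units
  ground-truth recovery: 100.0%
  confusion matrix (rows true, cols predicted I/II/III/IV/V):
    I:   15    0    0    0    0
    II:    0    1    0    0    0
    III:    0    0    6    0    0
    IV:    0    0    0    4    0
    V:    0    0    0    0   14
```

Reading the output: 65% of units responded significantly to at least
one cue odor; the classifier recovered every generated archetype label
(the confusion matrix diagonal); the encoding model attributes the
go-cue excitation almost entirely to the odor-onset kernel — the
generator locks responses to odor onset, so that is the correct
attribution; and by 350 ms after odor onset, 10 pseudorandomly sampled
units already decode trial type as accurately as the animal behaves.
All stage outputs (classifications, auROC traces, GLM fits, PCA
trajectories, distance/velocity, weights, decoding curves) are written
as CSV/JSON into `example_run/`, with seeds and wall times recorded in
`manifest.json`; `nlot report example_run` re-prints the summary.

The same analyses are available as a library:

```python
from nlot import (GeneratorConfig, generate_session,
                  ClassifierConfig, classify_session, type_proportions)

session, truth = generate_session(GeneratorConfig(n_units=40), seed=42)
labels = classify_session(session, ClassifierConfig(seed=1))
print(type_proportions(labels))
```

Sessions are plain-text directories (`units.csv`, `trials.csv`,
`meta.json`) — see `nlot.session_io` for the exact column contract and
`nlot synth` to generate one.

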