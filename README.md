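# syllakin

Subsecond analysis of open-field mouse locomotion from keypoint
trajectories: segmentation of pose time series into behavioral **syllables**
with a sticky autoregressive hidden Markov model (AR-HMM, Gibbs sampling),
followed by quantification of syllable velocity, usage, duration, transition
structure, entropy and group statistics. A synthetic-data module generates
multi-animal cohorts (control, parkinsonian-like "lesion", and a
velocity-only "treatment" rescue) with known ground truth, so every stage of
the pipeline is testable without raw videos.

## Modules

| module | purpose |
|---|---|
| `syllakin.synthetic` | Markov-switching keypoint simulator: sticky syllable chain, per-syllable centroid speed, AR pose dynamics, calibrated tracking jitter, condition transforms |
| `syllakin.preprocess` | likelihood gating + interpolation, egocentric alignment (centroid at origin, tail_base→nose along +x), PCA to a low-dimensional latent series |
| `syllakin.segmentation` | sticky AR-HMM (finite weak-limit sticky-Dirichlet prior, MNIW emissions) fit by Gibbs sampling; kappa scan selecting the model whose median syllable duration hits a 400 ms target; Viterbi decoding |
| `syllakin.metrics` | per-frame/per-syllable velocity, session velocity, usage and the 0.5 % expression filter, run-level transition matrices, steady state, entropy (rate / local-sum, configurable base), transition frequency, Δ-metric tables |
| `syllakin.stats` | Kruskal–Wallis + Dunn post hoc, Benjamini–Hochberg FDR, Mann–Whitney U, OLS regression |
| `syllakin.io` / `syllakin.cli` / `syllakin.pipeline` | DeepLabCut-dialect CSV and HDF5 keypoints, label/model serialization, published per-syllable reference tables, YAML experiment configs, CLI |

## CLI

```bash
syllakin simulate --out sim/ --n-animals 6 --condition lesion --severity 0.8 --seed 1
syllakin preprocess sim/lesion_*.csv --out pre/ --n-pcs 5
syllakin scan-kappa pre/*_latent.csv --grid 1e3,1e4,1e5 --out fit/
syllakin apply pre/*_latent.csv --model fit/model.json --out labels.csv
syllakin metrics --labels labels.csv --centroids pre/lesion_0_centroid.csv ... --out metrics.csv
syllakin compare --group control=ctrl.csv --group lesion=les.csv --out cmp/
syllakin run --config experiment.yaml --out results/   # end to end
```

Exit code 2 flags validation errors; stage-tagged logs go to stderr (`-v`
for verbose).

A minimal `experiment.yaml`:

```yaml
cohorts:
  control: {condition: control, n_animals: 6}
  lesion: {condition: lesion, n_animals: 7, severity: 0.8}
n_syllables: 12
session_duration_s: 300
labels_source: arhmm        # or ground_truth to skip model fitting
kappa_grid: [1e3, 1e4, 1e5]
seed: 0
```

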