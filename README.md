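# serialdep

Serial-dependence analysis for continuous-report working memory.

Perceptual reports are biased by sensory history: attracted toward what was
relevant a moment ago, repelled from what was just encoded. `serialdep` is a
Python toolkit for quantifying such biases both behaviorally and neurally in
delayed orientation-report experiments, aimed at cognitive/systems
neuroscientists working with continuous-report tasks and epoched
multichannel recordings (MEG/EEG-style data). It provides:

* **Behavioral statistics** — signed circular report errors on the 180°
  orientation circle; performance-bias curves (mean signed error vs.
  inducer–target distance, 64 overlapping quantile bins folded into 32 bins
  over absolute distance) and the *summed bias* index (positive =
  attraction, negative = repulsion); EM fitting of the three-component
  von Mises mixture (target / swap / uniform guess) with single-trial
  posterior weights.
* **Spatiotemporal decoding** — sliding-window channel features (e.g., 306
  sensors × 30 samples = 9180 dimensions), per-time-point PCA keeping 90%
  of training variance, 10-class LDA under stratified cross-validation;
  class evidence from Euclidean distances to class means in the
  9-dimensional discriminant space; representational-similarity curves and
  cosine-convolved evidence time courses; cross-decoding of the previous
  trial's target; sensor searchlight maps.
* **Neural bias scores** — CW/CCW evidence asymmetries relative to an
  inducer orientation, summarized over a 250–600 ms window; attraction
  positive, repulsion negative.
* **Permutation inference** — trial-wise sign-flip shuffle nulls with
  z-scored statistics, one-sample cluster-based permutation tests for time
  courses and bias curves, and alignment-shuffle nulls for decoding scores.
* **A synthetic-experiment generator** — trial tables, mixture responses
  with difference-of-Gaussians (DoG) biases, and orientation-tuned
  multichannel epochs with injectable encoding shifts and lingering traces,
  so every analysis stage has a known ground truth.

The core bias statistic: report errors are binned by the signed circular
distance Δ between an inducer orientation and the target, the curve b(Δ) is
sign-flipped and folded over |Δ|, and the summed bias Σₖ b(cₖ) over the 32
folded bins measures attraction (+) or repulsion (−). Its neural analogue
aligns classifier evidence to the presented orientation, averages the
clockwise-offset bins (−72°…−18°) minus the counterclockwise bins
(18°…72°), and contrasts trials with CW vs. CCW inducers.

See `docs/methods.md` for the full model and estimator descriptions.

## Worked example

Run a complete simulated experiment — 360 trials with an attractive
between-trial response bias, a repulsive within-trial bias, and a
sign-reversed lingering neural trace of the previous target
(`linger_amp = −0.3`) — and analyze it end to end:

```python
from serialdep.pipeline import RunConfig, DecodingConfig, StatsConfig, run_pipeline
from serialdep.simulate import NeuralParams

config = RunConfig(
    seed=3, n_trials=360, block_size=60,
    neural=NeuralParams(n_channels=16, sfreq=100.0, t_start=-0.1, t_end=0.75,
                        snr=1.0, linger_amp=-0.3, seed=3),
    decoding=DecodingConfig(window_len=10, n_folds=5, tmin=0.2, tmax=0.65, decim=3),
    stats=StatsConfig(n_iter=300),
)
report = run_pipeline(config, "runs/demo")
```

or equivalently from the shell: `serialdep run-all --out runs/demo`.
The run directory receives the trial table, epochs, evidence tensors,
bias-curve CSVs and a `report.json`. Key numbers from this configuration:

```text
behavior.between.summed_bias_deg   21.55   # attractive pull toward previous target (+)
behavior.mixture                   kappa 8.25, p_target 0.90, p_guess 0.097
decoding.grating2.window_mean      0.242   # cosine evidence, 250-600 ms (chance 0)
neural.between.window_mean        -0.377   # repulsive neural bias (z = -9.67)
neural.cross_decoding.window_mean -0.082   # negative = sign-reversed lingering trace
```

The positive behavioral summed bias reflects the planted attractive serial
dependence; decoding evidence well above zero shows the presented
orientation is recoverable from the sensors; and the negative neural-bias
and cross-decoding scores show the lingering suppressed trace of the
previous target pushing the current representation away from it.

## Layout

```
src/serialdep/
  circstats.py    # 180-degree circular primitives, DoG, uniformity tests
  simulate.py     # trial tables, biased responses, tuned epochs
  containers.py   # EpochsData (npz + JSON sidecar, MNE import)
  behavior.py     # circular errors, bias curves, mixture EM
  decoding.py     # features, decode_cv, alignment, cosine evidence, searchlight
  neuralbias.py   # inducer selection, asymmetry/neural-bias scores, cross-decoding
  stats.py        # sign-flip shuffle nulls, cluster permutation test
  pipeline.py     # RunConfig + end-to-end run directories
  cli.py          # `serialdep` command-line interface
```
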