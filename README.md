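# tojreplay

Behavioral analysis of **time-compressed forward memory replay** from
temporal-order-judgement (TOJ) reaction times.

In a TOJ experiment a subject (a macaque watching a two-clip naturalistic
video, say) is shown two probe frames after a short retention delay and must
pick the one that occurred earlier.  If the subject answers by *replaying*
the encoded episode forward in memory, reaction time should grow with the
chosen frame's position in the video — and the slope of that growth measures
how much faster replay runs than perception (the *compression factor*).
`tojreplay` implements the full latency-analysis toolchain for this
paradigm, driven by a synthetic trial generator so every stage runs without
any external data:

* **Trial tables** — typed schema for TOJ trials, CSV I/O, reaction-time
  exclusion filters (0.7–10 s), condition labelling (within clip 1 / within
  clip 2 / across the event boundary) and the temporal-similarity index
  TS = delay₂/delay₁.
* **LATER modelling** — under the Linear Approach to Threshold with Ergodic
  Rate model, promptness (1/RT) is Gaussian with mean μ/θ and SD σ₁/θ.
  `LaterModel.fit()` fits four variants of a two-condition contrast — null,
  *shift* (rate-of-rise change), *swivel* (threshold change), two-fits — and
  adjudicates them by BIC = −2 logL + k ln n (ΔBIC > 2 positive, > 6 strong
  evidence).
* **Reaction-time RSA** — per-segment mean RTs become a rank-scaled
  representational dissimilarity matrix (RDM) which is compared, by
  bootstrap Spearman correlation with Wilcoxon contrasts and
  Benjamini–Hochberg FDR control, against a parametric family of replay
  models ranging from full Global compression (the replay of clip 2 starts
  as early as clip 1's) to Strict-forward replay and beyond.
* **Regression & trends** — per-subject reciprocal-latency slopes on chosen
  frame location with ten standardized covariates, correctness splits, and
  hierarchical orthogonal-polynomial (linear/quadratic/cubic) trend tests.
* **Behavioral metrics** — compression factor, clip-1 vs clip-2 paired
  contrast, trial-type ANOVA, sliding-window accuracy curves, inverse
  efficiency scores.
* **Perceptual similarity** — RGB-histogram SSD, HOG correlation and a
  pluggable keypoint-descriptor distance (ORB backend included), for the
  across-context regressor.

## Worked example

```python
from tojreplay import generate_dataset, filter_rt, LaterModel
from tojreplay.rsa import ReplayRSA
from tojreplay.metrics import rt_span_from_table, compression_factor

table = filter_rt(generate_dataset(seed=42))   # 50 sessions x 100 trials
span = rt_span_from_table(table)
scan, factor = compression_factor(span)
print(f"RT span {span:.3f} s -> {scan:.1f} ms per video-second, "
      f"compression factor {factor:.2f}")
print(LaterModel.from_table(table).fit().summary())
print(ReplayRSA(table).fit(n_iter=100, seed=0).summary())
```

prints

```
RT span 1.089 s -> 108.9 ms per video-second, compression factor 9.18

variant      k         logL          BIC       dBIC  evidence
null         2      935.482    -1853.931    331.268  strong
shift        3     1016.470    -2007.393    177.807  strong
swivel       3      965.530    -1905.512    279.687  strong
two_fits     4     1109.632    -2185.199      0.000  weak <- best

RSA over 8 segments (100 bootstrap iterations)
  strict_forward       offset=+0.00  r = 0.970 +/- 0.001
  global_compression   offset=-4.00  r = -0.065 +/- 0.002
  strict_forward vs global_compression: Wilcoxon p = 3.85e-18 (FDR 3.85e-18)
```

Reading the output: mean RT rises ~1.1 s from the first to the last frame of
a ~10 s video, so replay traverses the episode roughly nine times faster
than perception.  The RSA decisively identifies the strict-forward replay
pattern over global compression for this generator.  On full-pipeline data
the two-fits LATER variant wins because chosen-frame location induces
extra latency variance per condition; on condition-pure latency samples the
generating variant (shift, swivel or null) is recovered — see
`docs/methods.md`.

A command-line interface mirrors the library:

```bash
tojreplay simulate --seed 1 --out run/
tojreplay run-all --seed 1 --out run/ --segments 8 --segments 10
```

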