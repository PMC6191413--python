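# sharplight

Does acting on the world *sharpen* or *cancel* the sensory processing of
expected action outcomes? Two long-standing accounts of prediction during
action make opposite claims about the underlying population code:

* **Sharpening** — predictive signals suppress neurons tuned *away* from
  the expected stimulus. The population response to an expected stimulus
  becomes sparser and higher in signal-to-noise, so expected stimuli are
  *easier* to decode from activity patterns, even though mean activity can
  drop.
* **Cancellation** — predictive signals suppress neurons tuned *toward*
  the expected stimulus, dampening its representation, so expected stimuli
  are *harder* to decode.

`sharplight` implements, at desk scale, the complete fMRI analysis chain
that arbitrates between these accounts, together with a generative
simulator that can instantiate either population code (or a null code).
It targets researchers who want to stress-test this class of multivariate
analysis — its false-positive control, its sensitivity, and its ability to
recover a known ground truth — without access to scanner data.

## The analysis chain

1. **Trial design** — balanced event tables: 8 runs × 48 trials per
   subject, 16 congruent / 16 incongruent / 16 no-move trials per run,
   observed stimulus (index vs little finger movement) balanced within
   every cell, judgement task blocked within run and counterbalanced.
2. **Response simulation** — voxel responses `baseline + amp · g`, where
   `amp` is `amp_preferred` or `amp_nonpreferred` by the voxel's tuning
   and the gain `g ∈ (0, 1]` applies on congruent (expected) trials to
   tuned-away voxels (sharpening) or tuned-toward voxels (cancellation).
   Emitted either directly as run-wise betas or as HRF-convolved BOLD
   time series.
3. **First-level GLM** — one regressor per stimulus × condition × run,
   double-gamma HRF, OLS betas per voxel.
4. **Searchlight decoding** — linear SVM (C = 1), leave-one-run-out
   cross-validation (8 folds, 14 training / 2 test patterns; 16 patterns
   per condition), sphere radius 3 voxels, accuracy − 50% written to the
   centre voxel.
5. **Group cluster inference** — 4 mm FWHM smoothing, one-sample t map,
   height threshold p < 0.001, cluster-extent threshold at FWE p < 0.05
   calibrated by sign-flip permutation of the maximum cluster size. The
   surviving clusters, defined from **no-move** maps only, are the ROIs.
6. **Congruency effects** — cluster-mean accuracies per condition into a
   cluster × congruency (× task) repeated-measures ANOVA with partial η²,
   plus within-participant 95% CIs (CI/√2 display convention).
7. **Voxel tuning** — per-voxel index-vs-little t contrast (t > 0 →
   index-preferred, t < 0 → little-preferred), then univariate betas per
   congruency × preference cell. Suppression confined to non-preferred
   cells is the sharpening signature; to preferred cells, cancellation.

## Worked example

```python
from sharplight import PipelineConfig, run_pipeline

config = PipelineConfig.recovery_default("sharpening", seed=0)
result = run_pipeline(config)
print("clusters:", [(c.label, c.size) for c in result.rois])
print("congruent - incongruent decoding: %+.3f" % result.decoding_congruency_diff)
print(result.signature.summary())
```

prints

```
clusters: [('c1', 82)]
congruent - incongruent decoding: +0.091
Repeated-measures ANOVA (N = 8)
  congruency                     F(1,7) = 101.256, p = 0.0000, partial eta^2 = 0.935
  preference                     F(1,7) = 839.206, p = 0.0000, partial eta^2 = 0.992
  congruency x preference        F(1,7) = 29.389, p = 0.0010, partial eta^2 = 0.808
  congruent vs incongruent, preferred cells:     t(7) = -1.211, p = 0.2650
  congruent vs incongruent, non-preferred cells: t(7) = -9.549, p = 0.0000
  verdict: sharpening
```

Read: one ROI of 82 voxels was found from no-move decoding maps; decoding
was 9 accuracy points better for congruent (expected) than incongruent
outcomes; univariate activity dropped on congruent trials only in voxels
tuned away from the shown stimulus — the sharpening fingerprint. A
cancellation simulation reverses both signs; a null simulation produces
neither. `recovery_experiment` runs this as a full confusion-matrix
experiment over replicate simulations.

A command-line interface mirrors the stages
(`sharplight design|simulate|glm|decode|rois|effects|tuning|run|recover`).

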