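# Methods

## Generative model

Each voxel either belongs to an *informative region* with a preferred
stimulus (index or little finger movement), or responds at baseline to
everything. The noise-free response of an informative voxel to one trial
type is

```
r(pref, observed, condition) = baseline + amp · g
amp = amp_preferred   if observed = pref
      amp_nonpreferred otherwise
g   = gain  if condition = congruent and
            (sharpening  and observed ≠ pref) or
            (cancellation and observed = pref)
      1     otherwise
```

with `amp_preferred > amp_nonpreferred ≥ 0` and `gain ∈ (0, 1]`. The gain
multiplies the evoked amplitude, not the baseline: the hypotheses are
about modulation of stimulus-evoked population responses. Modulation is
applied as congruent-trial suppression; only the congruent-vs-incongruent
contrast is meaningful (a congruent suppression is indistinguishable from
an incongruent facilitation), so this choice is a convention, not a claim.
No-move trials carry tuning signal but no congruency modulation — they
must support ROI definition that is independent of the congruency effect.
A `null` hypothesis ignores the gain entirely.

Two consequences follow analytically and are asserted as invariants:

* the Euclidean distance between the index and little mean patterns over
  informative voxels is larger on congruent than incongruent trials under
  sharpening, smaller under cancellation, equal under null
  (`pattern_separation`);
* mean activity of tuned-away voxels drops on congruent trials under
  sharpening only; of tuned-toward voxels under cancellation only.

## From population code to data

**Direct betas** (`simulate_betas`): each run × condition × stimulus cell
yields a coefficient volume `r(...) + ε`, `ε ~ N(0, noise_sd/√m)` with `m`
the trials in that cell — the variance reduction a GLM obtains from
within-run averaging. This is the fast path used by the large simulation
suites.

**Time series** (`simulate_timeseries`): per run, the evoked amplitude
`r(...) − baseline` of each trial is multiplied by a canonical
double-gamma HRF (response gamma shape 6, undershoot shape 16, ratio 1/6,
unit rate) locked to the observed-stimulus onset and evaluated in
continuous time at scan times (TR default 3.36 s), on top of the constant
baseline, an optional linear drift, and white Gaussian noise of SD
`noise_sd` per scan. The design-matrix builder uses the identical
continuous-time evaluation, so on noiseless data OLS returns the
generating amplitudes to machine precision — the round-trip contract the
tests enforce at 1e-6 relative.

The generator emulates: balanced factorial designs, spatially compact
informative regions, mixed preference populations, run-wise estimation
noise. It does **not** emulate physiological noise spectra, motion,
spatial normalisation error, inter-subject anatomical variability, or
temporal autocorrelation. Passing tests therefore validate the analysis
logic and its calibration under clean exchangeable noise, not robustness
to real-scanner artefacts.

## Analysis conventions

* **GLM**: OLS without prewhitening (point estimates remain unbiased;
  downstream analyses consume recovery, not efficiency). Events are
  zero-duration impulses (500 ms stimulus ≪ TR). Nuisance: centred linear
  drift + constant; real-data mode accepts arbitrary extra columns.
  Rank-deficient designs are rejected with the collinear columns named
  (pivoted QR).
* **Searchlight**: offsets `‖d‖ ≤ radius` on the integer lattice (123 at
  radius 3); spheres truncated at the mask boundary. Linear SVM, C = 1,
  no feature scaling, solved by scikit-learn's libsvm binding called at
  low level for speed; decisions are identical to
  `SVC(kernel="linear", C=1)` (asserted in tests), with zero decisions
  tie-broken to the first stimulus label in sorted order ("index").
  Accuracy is pooled over the 16 test classifications and stored minus
  chance (50%), so map values are multiples of 1/16 in [−0.5, 0.5].
* **Smoothing**: Gaussian, σ = FWHM/(2√(2 ln 2)) in voxel units, zero
  padding at the boundary (interior of a constant map unchanged; mass of
  an interior impulse preserved; edges attenuated).
* **Group inference**: one-sample t (df = n−1), one-sided height
  threshold at the t quantile of `height_p` (default 0.001); voxels with
  (numerically) zero across-subject variance get t = 0. Connected
  components use 26-connectivity (6/18 configurable). The extent
  threshold comes from a sign-flip permutation of the maximum cluster
  size (`n_perm` ≥ 100); a cluster is kept if
  `(1 + #{null ≥ size})/(n_perm + 1) ≤ extent_fwe_p`. This replaces
  random-field-theory FWE deliberately: the sign-flip null is exact under
  symmetric subject-level noise and needs no smoothness estimation. With
  very sparse suprathreshold maps the integer size statistic is heavily
  tied and the procedure becomes conservative; calibration is therefore
  checked on fields with searchlight-like spatial correlation, where the
  attained rate sits near nominal.
* **ANOVA**: balanced within-subject SS decomposition (any number of
  crossed factors), each effect tested against its subject interaction;
  partial η² = SS_effect/(SS_effect + SS_error); no sphericity
  correction (the factors of interest are two-level, where sphericity is
  moot; the three-level cluster factor is accepted uncorrected). Error
  bars use the within-participant 95% CI of the two-condition difference
  divided by √2.
* **Tuning**: preference from the sign of a paired t over all
  run × condition cells of beta(index) − beta(little); t = 0 voxels are
  excluded (measure-zero under continuous noise). Whether no-move cells
  enter the contrast is configurable (default: included). Univariate
  extraction uses unsmoothed native-grid betas. The verdict rule:
  significant congruent-trial suppression (α = 0.05, two-sided paired t)
  in non-preferred cells only → sharpening; preferred only →
  cancellation; both → mixed; neither → none. Because the preference
  contrast weights congruent and incongruent cells identically, the
  selection is orthogonal to the congruency contrast; a calibration test
  confirms the congruency × preference interaction stays at nominal α
  when preference and extraction come from the same null data.

## Pipeline and seeds

`PipelineConfig` carries every parameter and a single master seed from
which per-stage, per-subject substreams are derived (SeedSequence
spawning), so any stage can be rerun in isolation and the whole result
bundle is a pure function of the config. ROIs are computed from no-move
maps before the condition-specific maps exist, making the claimed
independence structural; a mutation test corrupts the condition maps and
checks the ClusterSet is unchanged.

## Study conditions for the simulation suites

Problem sizes are the package's own desk-scale choices:

* **Model recovery** (`PipelineConfig.recovery_default`): 8 subjects,
  8 runs × 48 trials, 8×8×8 grid, two blobs of radius 2 with 50/50
  preference mix, baseline 100, amplitudes 2/1, gain 0.5, noise_sd 4,
  searchlight radius 2 (commensurate with blob size on a small grid),
  200 extent permutations, 20 replicates per hypothesis. Noise and gain
  were fixed so blob decoding sits near 70–80% — off both chance and
  ceiling, leaving headroom for the congruency modulation in either
  direction.
* **Chance calibration**: pure-noise betas (empty informative region),
  radius-3 searchlight, mean accuracy compared to 50% within ±2
  Monte-Carlo SE. Map-mean accuracies have an SD of several accuracy
  points because the 16 test patterns are shared by every searchlight in
  a map.
* **Extent-FWE calibration**: 250 null datasets of 16 subjects on a 12³
  grid; subject maps are Gaussian fields with intrinsic smoothness
  σ ≈ 1.2 voxels (the correlation overlapping searchlights induce) plus
  the pipeline's 4 mm smoothing. Sixteen subjects give a 2¹⁶-element
  sign-flip group, rich enough that the integer size statistic is not
  dominated by ties.
* **ANOVA type-I calibration**: 400 null cell tables, 8 subjects,
  2 clusters × 2 congruency levels.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `baseline` | 100 | constant signal level (arbitrary units) |
| `amp_preferred` / `amp_nonpreferred` | 2 / 1 | evoked amplitude to preferred / other stimulus |
| `gain` | 0.7 | congruent-trial multiplicative suppression |
| `noise_sd` | 1 | beta noise scale before 1/√m shrinkage (per-scan SD in time-series mode) |
| `tr_s` | 3.36 s | scan repetition time |
| `radius_voxels` | 3 (9 mm) | searchlight radius |
| `smooth_fwhm_mm` | 4 mm | map smoothing before group inference |
| `height_p` / `extent_fwe_p` | 0.001 / 0.05 | height and extent thresholds |
| ITI | U(2, 6) s + 0.5 s stimulus | onset spacing with jitter |

Only the orderings of the amplitude/gain parameters matter for the
qualitative claims; absolute values are simulation conveniences.

## Known limitations

* Cluster-extent FWE is conservative when suprathreshold voxels are very
  sparse (integer size statistic, small sign-flip groups).
* The binary tuning split suffers contamination bias: when one preference
  class is strongly suppressed (cancellation), the fraction of voxels
  whose preference is misclassified leaks that suppression into the other
  class's cells. With low subject-level noise the post-hoc paired t can
  detect this small systematic leak, so a minority of cancellation
  simulations read as "mixed" (suppression on both sides) rather than
  pure cancellation; in the recovery experiment this accounts for
  essentially all off-diagonal mass on the cancellation row. Sharpening
  is less affected because its suppression (of the weaker, non-preferred
  amplitude) is smaller in absolute terms.
* The no-move delay (438 ms apparent-motion onset lag) and the cue–action
  mapping reversal are not modelled; regressors lock to observed-stimulus
  onset, where neither has a consequence.
* Task-split analyses in beta-direct mode regenerate per-task betas with
  the halved trial count entering through the noise term, rather than
  re-estimating a GLM on half the events.
* One-sample group t-tests on accuracies are used for ROI definition
  only; condition *differences* carry the inferential weight, since
  below-chance accuracies are not meaningful population quantities.
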