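# Methods

## Behavioral model

Each subject's session is a sequence of completed trials with conditions
(speed instruction ∈ {fast, slow}, target direction ∈ {down, right, up,
left}, perturbation ∈ {unperturbed, towards, away}) and outputs (reaction
time in seconds; speed error, the instructed-speed midpoint 0.67/0.33 minus
the realized normalized speed, bounded in [−0.67, 0.67] with |SE| ≤ 0.13
counted correct). Reaction time is z-scored per subject over completed
trials before any modeling; speed error is left on its natural scale.

Two scalar latent states carry trial history. The error state accumulates
past speed errors, the perturbed state past perturbation occurrences, each
by a first-order recursion `x_t = α x_{t−1} + u_{t−1}` starting at 0 with
decay `α ∈ (0, 1)`; the closed form
`x_t = α^{t−1} x_1 + Σ_i α^{t−i−1} u_i` is implemented alongside and tested
against the recursion. States stay constant within a trial (planning and
execution see the same value) and are z-scored over the session before
entering the regressions so weights compare across subjects; a constant
trace z-scores to zeros rather than NaN.

The observation equations are linear: RT on {constant, both states, one-hot
speed, one-hot direction}; SE on {constant, both states, z-scored RT, one-hot
speed × perturbation}. Complete one-hot blocks plus a constant are rank
deficient by design; weights are the minimum-norm least-squares solution
(SVD pseudo-inverse), so every category weight exists but only contrasts are
identifiable. Confidence intervals come from a full-rank reference-coded
refit (statsmodels OLS; baselines fast / down / fast-unperturbed); the
continuous coefficients (states, RT) are identical under both codings, which
the tests verify.

Fitting: decay constants are searched on the full grid 0.01…0.99 at 0.01
(both axes); per grid point the states are evolved, z-scored, and both
weight vectors fitted by OLS (the Gaussian maximum-likelihood estimate). The
selected grid point maximizes the mean of the two outputs' Pearson
correlations between observed and estimated behavior, ties broken by lower
summed RMSE; a pure-RMSE criterion is available
(`fit(criterion="rmse")`). One shared (α_SE, α_P) pair serves both
equations by default; an independent-per-output mode exists for sensitivity
analysis. The grid search is exact but fast (~30 ms per session at n = 300):
the condition block is projected out once per output, the 99 error-state and
99 perturbed-state traces are residualized once, and every grid pair reduces
to a 2 × 2 solve assembled from precomputed Gram matrices.

Goodness of fit is reported as Pearson r, R² (share of output variance
explained; clamped to [0, 100] % only for display), Gaussian deviance
(residual sum of squares), and 10-fold cross-validation with the states held
fixed from the full fit — the states are history-dependent, so folds refit
only the weights. Incomplete trials are dropped from both the regression and
the state index by default (`incomplete="drop"`); the alternative of letting
states evolve across incomplete trials with zero error input is available
(`incomplete="carry"`) and logged. Sessions without perturbations yield an
identically-zero perturbed state; its column drops out of the minimum-norm
fit and is reported as non-identifiable rather than propagating NaN.

## Synthetic data generator

The generator runs the model forward under the task's stated conditions:
50/50 speed instruction, uniform directions, 20 % perturbation probability
with force U(2.5, 15) N at a uniform angle. A perturbation is *towards* when
the absolute circular difference between its angle and the target bearing is
strictly below π/2, *away* otherwise (boundary → away). Generation is
sequential because speed error feeds the error state; the generating weights
therefore act on raw state traces, and the ground truth records the
realized scale factors that convert them to the fitted (z-scored) scale, so
recovery tests compare like with like.

Defaults are the study conditions where stated and realism choices where
not: 300 trials (a ~30-minute session), true decay constants 0.5 / 0.75
(mid-grid), RT noise SD 0.35 z-units and SE noise SD 0.13, RT mapped to
seconds by an affine transform with mean 0.8 s. The SE equation's constant
is solved so the stationary mean of SE is zero ("auto-centering"): subjects
practice before the session, and without this the perturbed state's positive
mean (p/(1−α_P)) would push a systematic drift through the feedback loop.
These defaults give single-session performance near 52 % and model fits at
the upper end of a plausible subject range. SE values are *not* clipped to
[−0.67, 0.67] by default — a clipped Gaussian would bias the linear
recovery tests — with clipping available as an option; the noise levels keep
essentially all mass inside the bounds anyway.

Cohorts spread performance by varying the SE noise SD (0.06…0.25 across
subjects) and scale the *planning-phase* (RT-equation) state weights from
1.4× to 0.6× across the performance gradient. The execution-phase feedback
weights stay at base for every subject: scaling them moves the closed loop's
gain (α_SE + feedback terms) toward the unit root and blows up the variance
of the best subjects, which is neither realistic nor stable.

LFP synthesis is minimal-sufficient for testing the analysis chain: per
channel, 1/f-shaped Gaussian background plus a 60 Hz line-noise sinusoid,
and for channels in an encoding target's region, a band-limited noise burst
(FFT brick-wall band, Tukey envelope with flat core) in the target's
(epoch, time, frequency) window whose amplitude is
`gain · max(1 + depth · z_state, 0.05)` per trial. No biophysics — no
dipoles, no spikes, no cross-frequency structure; passing tests demonstrate
the statistics, not neural realism. Epoch durations are exposed as
configuration (the eight-epoch default layout sums to ~5 s per trial) since
the on-screen timings are not available; harness-scale runs use shorter
layouts purely as a problem-size choice.

## Spectral preprocessing

Zero-phase notch at 60 Hz and all harmonics below Nyquist, specified by the
−1 dB bandwidth of 3 Hz; scipy's `iirnotch` takes the −3 dB bandwidth, so
the conversion `bw₃ = bw₁·√((1−g²)/g²)` with `g² = 10^{−0.1}` is applied
(second-order notch response). Complex Morlet CWT with center radian
frequency ω₀ = 6 on a logarithmic axis covering 1–200 Hz at 12 bins/octave
(≈ 92 bins; the choice makes the one-octave cluster filter exactly 13 bin
centers). Instantaneous power is averaged in 100 ms windows every 50 ms,
each bin labeled with its window's *end* time; then each frequency bin's
natural-log power is z-scored over the entire recording (stats stored for
inversion). Power is averaged linearly within windows and logged afterwards.
Edge effects extend roughly one wavelet width (~ω₀/(π f)) into each end;
analysis windows in the harnesses keep away from recording edges.

## Cluster-permutation statistic

Per channel and pixel: Spearman ρ across trials between the state and
normalized power, converted to `t = ρ√((n−2)/(1−ρ²))` (|ρ| = 1 capped at a
finite sentinel). Channel maps average within subject, subject maps across
subjects — a hierarchical mean, so a subject with many channels still casts
one vote. Regions with fewer than two subjects are excluded.

The cluster-forming threshold and the cluster statistic are genuine design
choices: pixels are screened by a second-level one-sample
t across subject means (two-tailed α = 0.05, df = n_subjects − 1 — subjects
are the unit of inference), supra-threshold pixels join under 4-adjacency
split by sign, and each cluster's statistic is its *mass* (sum of the
hierarchical-mean t). Clusters with bounding boxes under 250 ms or one
octave (center-to-center on the log₂ axis), or with fewer pixels than the
minimum box (5 × 13 at the default resolution), are discarded. The
permutation null shuffles each subject's trial order once per permutation
(shared across that subject's channels, independent across subjects),
re-runs the identical chain, and records the maximum surviving |mass|;
observed clusters get signed add-one p-values, `p = (k+1)/(N+1)` — the only
estimator consistent with a floor of 9.99 × 10⁻⁴ at N = 1000.
Benjamini–Hochberg at q = 0.015 (statsmodels) corrects across regions and
epochs. Surviving clusters in the same region with overlapping frequency
bins merge across epochs (union-find); each group is labeled with the
canonical band (delta 1–4, theta 4–8, alpha 8–15, beta 15–30, low gamma
30–60, high gamma 60–100, hyper gamma 100–200 Hz) holding the majority of
its pixel area, and called *persistent* if its members cover all eight
epochs, else *phasic*.

One calibration subtlety is worth stating plainly: the max-statistic
permutation test is exactly calibrated (false-positive rate α) only for the
*unfiltered* cluster statistic, where a maximum exists almost surely. Null
clusters spanning 250 ms × 1 octave essentially never form at this problem
scale, so the size-filtered test is strictly conservative — its realized
false-positive rate is near zero, never above α. `permutation_test`
therefore tracks both null distributions in one pass and reports both
p-values; the calibration harness asserts the binomial band around α on the
unfiltered statistic and conservativeness plus the post-FDR
false-discovery-proportion bound on the filtered pipeline.

## Encoding strength, selection, connectivity

For each cluster group and channel, power is averaged over the group's
pixels within each member epoch and then across epochs, giving one value
per trial; encoding strength is the mean over channels of |Spearman ρ|
between that series and the state (∈ [0, 1]). Regions are related to
session performance across subjects by Pearson correlation; a group is
selected when |r| > 0.75 *or* p < 0.05 (the magnitude rule compensates for
n ≤ 10 subjects), provided at least one subject sits strictly above and one
strictly below the cohort-average performance and at least three subjects
contribute. Channel connectivity is |Spearman ρ| between two channels'
trial series; subject connectivity averages unique cross pairs (diagonal
autocorrelations excluded); performance connectivity is the Pearson r of
subject strengths against performance (stored signed; only r > 0.5 is
exported to the positive-edge graph); population connectivity Fisher-z
averages subject strengths (values ≥ 1 clamped at 1 − 10⁻⁷), which keeps
the result between the subject minimum and maximum. No multiple-comparison
correction is applied to the performance correlations, matching the
descriptive use; a BH option exists.

## Study harnesses and problem sizes

`motorstates.experiments` holds the standing studies the tests and the
acceptance script run:

- **Parameter recovery** — 20 sessions × 300 trials at generator defaults;
  median |α̂ − α| per axis and empirical 95 % CI coverage of the continuous
  weights against the effective generating values.
- **Model comparison** — the same conditions with and without generating
  state weights; in-sample R² of full vs conditions-only fits.
- **Null calibration** — 4-subject, 3-region, 2-epoch, 40-trial cohorts at
  400 Hz with zero encoding gain, 150–200 permutations, 30–50 seeds.
- **Localization power** — one planted window (0.2–0.8 s, 20–80 Hz — two
  octaves and 0.6 s, large relative to the wavelet blur so bounding-box
  localization is meaningful) at gain 1.5; success = a surviving
  positive-sign cluster in the right region whose bounding box reaches
  Jaccard ≥ 0.5 against the *resolution-convolved* truth (the planted
  window broadened by the wavelet's half-power support and the window
  smear — no detector can localize below the instrument resolution).
- **Selection recovery** — 5-subject cohorts where the planted region's
  modulation depth scales with realized performance rank; the full chain
  (cluster statistic → FDR → grouping → encoding → selection) must flag
  exactly the planted region, and nothing at zero gain.

The reduced scales (short epochs, one channel per region and subject, a few
dozen trials, a few hundred permutations) are problem-size choices that keep
each study in the minutes range on one CPU; the statistical machinery they
exercise is identical at full scale.

## Numerical choices and limitations

Z-scores use the population SD; constant traces map to zeros. The
grid-score assembly guards rank-deficient 2 × 2 systems (a dead
perturbed-state column falls back to the single-column solve). Permutation
p-values use the add-one estimator; FDR uses |p| with signs retained.
Log-power flooring uses the smallest positive normal float. The 10-fold CV
shuffles with an explicit seed; every stochastic operation takes one, and
derived seeds stay below 2³¹.

Known limitations: the generator's LFP has no biophysical content, so
passing tests say nothing about volume conduction, referencing, or artifact
structure in real recordings; artifact rejection is out of scope (the
original procedure was manual); the behavioral generator's auto-centering
assumes practice-calibrated subjects; parameter-recovery accuracy is
specific to the default noise levels and degrades for decay constants near
the grid edges; and the selection stage inherits the ~5 % null rate of its
p < 0.05 rule whenever a spurious cluster group reaches it — protection at
zero gain comes from the FDR-corrected cluster stage upstream.
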