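# Methods

This note documents the models, estimators and numerical choices behind
`rnptrack`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## Coordinate system and projection

A microtubule is modelled as a straight, oriented segment from its minus
end to its plus end (polarity known from the brightly labelled plus-end
segment of polarity-marked microtubules). Particle positions are
projected onto the unit axis vector; the on-axis coordinate s is 0 at the
minus end and grows toward the plus end, so minus-end-directed transport
has negative velocity. The perpendicular residual is reported per frame
for quality control but plays no role downstream. Points projecting
outside [0, L] are kept and flagged rather than clipped, because
particles genuinely dwell at and slightly beyond the annotated ends.
Curved microtubules are not modelled; users should annotate straight
segments.

Tracking accuracy is the SD of a maximum-likelihood Gaussian fit to the
pooled frame-to-frame on-axis displacements of immobile particles (the
bin-free equivalent of fitting a displacement histogram). With i.i.d.
per-coordinate localization noise of SD σ, the on-axis displacement SD is
σ√2; the reference calibration of 11.3 nm therefore corresponds to
σ ≈ 8 nm per coordinate per frame. The run cutoff is twice the accuracy;
`measure_tracking_accuracy` returns it unrounded (22.6 nm for an 11.3 nm
accuracy) and the conventional working value truncates to 22 nm.
At least 30 pooled displacements are required; fewer is an error.

## Run segmentation

Displacements d with |d| ≤ cutoff are pause frames; maximal blocks of
same-sign displacements each with |d| > cutoff are runs. Run length is
Σ|d| over the block, duration is the block's frame count × frame
interval, and velocity is exactly length/duration. A reversal is scored
between consecutive displacements when both exceed the cutoff and their
signs differ (|sign(dᵢ) − sign(dᵢ₊₁)| = 2); sub-cutoff sign flips are
pauses, so a reversal always requires two qualifying flanking
displacements. Run terminators are pause, reversal, detachment (track
ends before the acquisition does), end of acquisition, and — when the
axis length is supplied — arrival within a threshold (two pixels by
default) of a microtubule end. Runs curtailed by the end of acquisition
are retained in run-length statistics.

Classification: a track whose total positional range is within one
camera pixel (105 nm) is stationary; otherwise it is
unidirectional_minus (≥1 minus run, no plus runs), unidirectional_plus
(the mirror case, reported separately because it is not expected in a
dynein-driven assay), or bidirectional. A motile track with no
above-cutoff run at all — slow diffusion — is classified bidirectional.
No bridging of pauses between same-direction runs is performed.

Population fractions are computed per imaging chamber among motile
(non-stationary) tracks and summarized as mean ± SEM **over chambers**,
not over particles; chambers without motile tracks are excluded with a
warning. Per-particle correlation analyses (mean minus- vs plus-end run
length or velocity) include only bidirectional particles with ≥20 runs
and report an OLS slope, R², and 95% CI; a slope of 1 indicates no
directional bias.

Sampling-rate artifact: segmenting the same diffusive tracks at a lower
frame rate yields longer measured runs and lower measured velocities,
because each frame integrates more sub-frame wandering into a larger net
displacement. `downsample` exposes this directly and the test suite
asserts the direction of both effects; comparisons between conditions
must therefore use matched frame rates.

## MSD analysis

The MSD is internally averaged — MSD(kΔt) = meanᵢ (s₍ᵢ₊ₖ₎ − sᵢ)², over
all start frames i — so every pair contributes once, and lags are capped
at one quarter of the trajectory duration, k ≤ ⌊(N−1)/4⌋, beyond which
the internal average is too poorly determined to use. Tracks shorter
than 8 frames are rejected.

The motion class comes from the log–log slope of the MSD curve: ≈2 for
transport, ≈1 for diffusion, with 1.5 as the classification threshold.
Two corrections make the single-trajectory slope accurate at realistic
track lengths, and both are on by default:

- the localization-noise floor (2σ² ≈ the squared tracking accuracy,
  ~128 nm² at the reference calibration) is subtracted before taking
  logs — without it the floor flattens short lags and biases the
  exponent down;
- each lag k is weighted by its effective number of independent pairs,
  ≈(N−k)/k. Near the quarter cap the internal average pools only a
  handful of independent segments; its log is noisy and Jensen-biased
  downward, and equal weighting lets those points drag the slope down.
  At the reference conditions (300 frames, 15 fps, D = 5000 nm²/s, 8 nm
  noise) the uncorrected estimator averages ≈0.92 per track with SD
  ≈0.18; with both corrections it averages ≈0.97 with SD ≈0.12, while
  ballistic tracks stay at 2.00.

The diffusion coefficient is half the slope of a straight-line fit of
MSD vs lag over the same capped range with a free intercept (which
absorbs the noise floor), weighted by the inverse sampling variance of
each lag by default; a negative fitted D is reported as 0 with a flag.
Condition contrasts of slope ensembles (e.g. ATP vs ATP–vanadate) use a
two-sided Mann–Whitney test on per-track slopes.

## Stepwise photobleaching

Each GFP-tagged subunit bleaches in one discrete step, so the number of
downward steps in a background-subtracted intensity trace counts the
labelled subunits of a complex.

The Chung–Kennedy filter combines, at each sample, the mean of the
preceding and of the following `window` samples (default 8), weighted by
the inverse of each predictor's summed squared prediction error over a
comparison window of the same length, raised to `weight_exponent`
(default 2). Plateaus are smoothed; across an edge the predictor that
reaches over the edge mispredicts badly and is suppressed, so edges are
preserved (exactly so for noiseless steps). The filter is
scale-equivariant. It is provided for display and for emulating manual
step counting.

Automated counting fits the **raw** trace: steps are placed greedily at
the χ²-optimal change points, with refinement sweeps that re-place each
change point while its neighbours are held fixed (this rescues the
classic greedy failure where the first breakpoint lands between two
nearby true steps). The number of steps is selected by penalized
likelihood, minimizing n·log(SSE_k/n) + 2(2k+1)·log n over k — robust
for traces whose residual is dominated by a long post-bleach baseline.
The counter-fit quality ratio (steps forced between the fitted ones) is
also computed and reported, and can be selected as the model-size
criterion for step-dense traces. Filtered traces must not be fed to the
fitter: window filtering correlates the noise and makes any
residual-based model selection overfit, which is why filtering and
fitting are deliberately separate stages here.

QC flags, applied per trace before pooling: not reaching baseline
(final plateau above baseline by more than half a typical step),
a sudden large drop (a single step removing >60% of the initial level —
candidate detachment of the whole complex), and excessive fluctuation
(more upward steps than half the downward count). Only passing traces
enter copy-number statistics. Copy numbers follow
mean steps / labelled fraction (default 0.49) = subunit copies, divided
by subunits per motor (default 2) = motor copies; SEMs are propagated by
the same divisions, treating the labelled fraction as exact.

At the reference simulation conditions (binomially labelled complexes,
step amplitude/noise SNR 5, bleach times exponential with mean one fifth
of the acquisition) the detector matches the true labelled count on ≈93%
of traces and its ensemble mean is within a few percent of the binomial
mean; residual bias comes from fluorophores bleaching within a frame or
two of each other, which merge into one step.

## Obstacle and end encounters

Obstacle puncta occupy one pixel-quantized footprint (105 nm) each; only
puncta that are stationary over the acquisition are scored (diffusing
patches are excluded); overlapping puncta are merged with a warning.
Scoring is per approach run: an encounter opens when a run's path
reaches a punctum's interval (±1 pixel tolerance), and the run's fate
decides the outcome — `pass` if it carries the particle out the far
side, `reversal` if it terminates there with a reversal (or with a
≤1-frame pause followed by an opposite-direction run), `detach` if the
track ends there before the acquisition does, `pause` otherwise when it
stalls beyond the pause threshold. The precedence when several apply is
reversal > detach > pause > pass. Runs that begin inside a punctum are
fresh encounters (repeated attempts all count) unless they immediately
follow an opposite-direction run, which marks them as the departing half
of a reversal already scored. Encounters unresolved at the end of
acquisition are flagged censored and excluded from outcome fractions,
which therefore sum to one.

The chance-coincidence null superimposes obstacle layouts from an
independent source onto obstacle-free tracks and scores them through the
identical code path, estimating how often each outcome would coincide
with an obstacle position by chance. Per-outcome observed-vs-null
contrasts use Fisher's exact test. In simulation the observed reversal
share approaches the obstacle blocking probability, while the null share
reflects the track model's intrinsic reversal rate: memoryless Brownian
motion thresholded at 22 nm reverses much more often (null share ≈0.3 at
the reference conditions) than real bidirectional cargo appears to, so
the observed/null *gap* — not the absolute null rate — is the meaningful
readout, and the tests assert a >2× gap.

End encounters open when the on-axis position comes within two pixels
(210 nm) of either end. Residence longer than one frame is a pause (its
duration measured from entry to exit or track end; pauses cut off by the
end of acquisition are censored and excluded from uncensored means);
brief contact followed by departure is a reversal; brief contact at
which the track ends is a detachment. At the 4.2 fps frame rate used for
end-encounter imaging, a transported particle bouncing off an end
transits the zone in ≲1 frame, so reflective ends score as reversals.

## Synthetic data

The generator exists so every stage can be validated against ground
truth. It emulates: 1D Brownian motion along the axis (Gaussian
increments of variance 2DΔt; the simplest generative model consistent
with a linear MSD), constant-velocity transport (−1200 nm/s preset, the
scale of dynein-driven RNPs), stationary spots, a two-state switching
mode, i.i.d. Gaussian localization noise per coordinate per frame
(8 nm default, reproducing the 11.3 nm displacement-SD calibration),
mixed populations with a set processive fraction, uniformly placed
single-pixel obstacles that block each approach with probability
`block_prob` (reflecting positions and flipping transport direction
while blocked), reflecting or unconstrained ends, exponential end dwells
followed by detachment, and bleaching traces with
Binomial(copies, label fraction) labelled fluorophores, i.i.d.
exponential bleaching times (default mean: one fifth of the
acquisition — well-separated steps that still reach baseline), constant
step amplitude, and Gaussian intensity noise. Fractional mean copy
numbers (e.g. 4.36) are realized by mixing the two flanking integers.

Determinism: identical seed and configuration give bit-identical output,
and a master seed expands into per-track substreams so extending an
ensemble never perturbs earlier tracks. Frame-rate presets are 15 fps
(66 ms) and 4.2 fps (236 ms); pixel size 105 nm; microtubule length
15 µm.

What the generator does **not** emulate — hence what passing tests do
not establish about real data: directional persistence or run-length
structure within bidirectional motion beyond what thresholded Brownian
increments produce (real cargo reverses less often by chance, so real
null-encounter rates are lower than the simulated ones); camera physics
(PSF, EMCCD gain, motion blur within an exposure); GFP blinking and
incomplete maturation; curved microtubules; intersecting-track
switching; correlated or heavy-tailed localization errors.

## Statistics

Summaries report mean ± SEM (SD/√n, ddof = 1) with n; densities are per
µm of microtubule. Two-group comparisons are two-sided: Mann–Whitney U
for continuous metrics (exact null for tie-free samples of ≤25,
otherwise the normal approximation with mid-rank tie correction; the
variant used is recorded) and Fisher's exact test for outcome
proportions. Stars follow 0.05/0.01/0.001. No multiple-testing
correction is applied by default, matching per-comparison reporting;
Holm adjustment is available.

## Known limitations

- The straight-axis assumption biases on-axis displacements low on
  curved microtubules.
- Step-count estimates are lower bounds where fluorophores bleach nearly
  simultaneously, and copy numbers inherit the assumption that the
  labelled fraction is exact.
- End-pause durations include the ≲1-frame transit of the 210 nm
  proximity zone, a +0.1–0.2 s offset that is negligible against dwell
  means of tens of seconds but not for sub-second dwells.
- Encounter scoring at pixel resolution cannot distinguish a reversal at
  an obstacle's near edge from one a few tens of nm before it.
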