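# Methods

## Stimulus design and data model

The two-tone protocol crosses nine frequency offsets (dF = −1 … +1 octave
around a center tone, 0.25-octave steps) with nine onset-to-onset
intervals (dT = −100 … +100 ms, 25-ms steps; negative dT means the dF tone
leads), giving 81 pairs, plus the ten component tones presented alone
(center tone and the nine dF tones).  FM sweeps span 4 octaves at
2.5–80 oct/s (6 rates × 2 directions).  Stimuli are delivered in
randomized blocks — each block contains every condition exactly once — with
five blocks (trials per condition) and a 5-s inter-trial interval.  These
counts and ranges are the design the defaults encode; the dF–dT ranges
cover the ethological FM-rate band of mouse vocalizations (|dF|/|dT| =
2.5–40 oct/s).

Data are held as trial-aligned dF/F snippets (`RoiTraceSet`): a 1-s
(30-frame) pre-onset baseline followed by 2.5 s post-onset at 30 Hz.  Real
recordings can be analyzed by packing them into the same container (HDF5
layout in `spectint.io`); nothing downstream distinguishes them from
synthetic data.

## Trace processing

Neuropil correction follows the ring-background scheme:
`F(t) = F_measured(t) − 0.9 × F_background(t)`, with background pixels
excluded when they carry large transients (> 3 SD of the pixel trace for
≥ 2 consecutive frames) while being uncorrelated with the cell (Pearson
r < 0.2 over the session) — the signature of a neighbouring soma in the
ring rather than shared neuropil.  If every pixel is excluded the
unfiltered mean is used with a logged warning.  dF/F is
`(F − F0)/(F0 + 20)` with F0 the per-trial baseline mean; the 20 a.u.
offset guards dim cells against near-zero denominators.  Cells at least 3%
brighter than their background ring pass QC (inclusive boundary).

Response amplitude is the baseline-subtracted mean dF/F in a
condition-specific window: 1 s from onset for two-tone stimuli *and* their
20-ms component tones (keeping the window common to T and L, so the
transient-shape factor cancels in LI), 1.2 s for 1-s pure tones, and sound
onset to 0.3 s after offset for FM sweeps.  The AUC over the same window is
stored alongside (it equals mean × duration and serves as a cross-check);
all downstream indices use the mean.  Negative amplitudes are kept at this
stage; index computations clamp at zero.

A response is significantly excitatory when baseline-subtracted dF/F
exceeds 3.3 × the baseline SD (pooled per ROI across all trials' pre-onset
frames) for at least 0.5 s of consecutive frames (ceil(0.5 × rate) = 15 at
30 Hz), both in strictly more than half of the trials and in the
trial-averaged trace.  A qualifying run must *start* inside the response
window but may extend beyond it: the 40 and 80 oct/s sweep windows (0.40 s,
0.35 s) are shorter than the 0.5-s run requirement, and the slow indicator
carries genuine responses well past the window, so confining the run to the
window would make fast-sweep detection impossible by construction.  Zero
baseline SD (noise-free synthetic data) raises a configuration error unless
an absolute floor (`min_baseline_sd`) is set.

## Interaction maps

`LI = (T − L)/(T + L)` with T and L clamped at zero; L is the sum of the
clamped center- and dF-tone trial means.  A grid cell receives an LI only
if the pair itself, the center tone, or the dF tone evoked a significant
response; T = L = 0 after clamping leaves the cell invalid (stored NaN) and
excluded from smoothing, population averages and bias sums — the
alternative of imputing 0 would fabricate "linear" cells out of silence.

Smoothing uses a 2-D Gaussian of SD 0.4 grid units (0.1 oct / 10 ms at the
0.25-oct / 25-ms spacing), renormalized over the valid cells within
4 SD, so invalid cells and edges do not drag estimates toward zero.
Population maps average per-cell values (smoothed by default) over the
neurons valid at each cell and report the per-cell n.

Per-cell nonlinearity is tested by comparing the five two-tone trial
amplitudes against the 25 pairwise sums of component-tone trial amplitudes
with a two-sided Wilcoxon rank-sum test at α = 0.1, direction taken from
the sign of the mean difference.  Sidedness is a choice (the source
procedure states test and α but not sidedness); two-sided with sign-read
direction keeps the facilitative and suppressive calls symmetric.  Note a
caveat measured by the validation suite: because the 25 sums are built
from only 10 underlying trials, they are strongly dependent, and the
rank-sum p (which assumes independent samples) is anti-conservative —
the empirical type-I rate under a matched null is ≈ 0.2 at nominal 0.1.
The test is retained in its standard form; its per-cell flags should be
read as a lenient screen, consistent with the deliberately high α.

Timing preference averages clamped amplitudes over a configurable dF set
(default {−1, −0.5, 0, +0.5, +1} oct — the exact 5-dF subset used in the
source analysis is not stated, and any 5-element set preserves the
40-shifted-pair arithmetic) at dT = 0 (coincident) versus the 8 shifted
dTs.  A neuron is coincidence-preferring when the coincident amplitude
exceeds 1.5 × the shifted one, and vice versa; shift-preferring neurons
subdivide into negative/positive-dT-preferring by the same ratio on the
4-negative vs 4-positive dT means, else symmetric.  The asymmetry index
`|(P − N)/(P + N)|` sums clamped amplitudes over all 9 dFs at positive
(P) and negative (N) dTs.

## FM sweeps and linearity-index bias

DSI = (U − D)/(U + D) with clamped amplitudes; per-rate DSIs are computed
only at rates with a significant response in ≥ 1 direction, and the
single summary DSI averages U and D over the responsive subset of
{10, 20, 40} oct/s *before* forming the ratio (not a mean of per-rate
DSIs).  `Bias_fac` (`Bias_supp`) is the summed positive (negative) LI in
the Upward region (dF·dT > 0 quadrants) minus the Downward region
(dF·dT < 0), over valid cells of the raw map with the dF = 0 row and
dT = 0 column excluded.  Raw rather than smoothed LI is used because
smoothing bleeds across the quadrant borders that define the bias; no
significance gate is applied to the summed cells.  With this orientation a
positive Bias_supp (less suppression in the Upward region) predicts
positive DSI.  DSI–bias association is Pearson's R with the two-sided
t-test on n − 2 df; per-rate variants are Bonferroni-corrected over the six
rates.

## Ensemble analysis

Population response vectors concatenate clamped trial-mean amplitudes over
all ROIs (pooled across datasets under one shared condition grid), with
non-significant entries forced exactly to zero.  Single-tone vectors are
zero-forced first and then summed to form the linear-sum vector.  Pearson
correlations are taken per (dF, dT) pair between the two-tone vector and
the linear-sum (and single-tone) vectors; dF = 0 pairs are excluded from
ensemble averaging, since there the "pair" is physically a single louder
tone (8 dFs × 8 shifted dTs = 64 shifted and 8 coincident pairs).
Zero-variance vectors make a pair undefined; such pairs are skipped, not
imputed.  Group contrasts use a two-way (area × timing) ANOVA on pair-level
correlations followed by Tukey's HSD over the four area–timing groups.

## Synthetic data generator

Each ground-truth cell specifies: center-tone amplitude and a Gaussian
dF-tone tuning curve (random preferred dF, bandwidth 0.3–0.8 oct); a true
9 × 9 LI kernel; FM amplitudes per (rate, direction); transient kinetics;
and noise levels.  Two-tone amplitudes invert the LI definition,
`T = L (1 + LI)/(1 − LI)`; template LI is capped at 0.95 to keep the
inversion finite.  Trial traces are amplitude × a unit-peak
difference-of-exponentials transient (rise τ 0.2 s, decay τ 1.5 s —
GCaMP6s-like values chosen so the 0.5-s consecutive-frames criterion is
meaningful; the indicator's true kinetics are not part of the design and
both are configurable), multiplied by lognormal trial noise (default
CV 0.2) and summed with Gaussian baseline noise (default SD 0.05 dF/F).
Trial-to-trial variability magnitudes are free parameters chosen as
plausible for L2/3 GCaMP6s data, not estimates from any recording.  One
global seed expands to per-cell substreams keyed by (seed, cell index,
purpose), so growing a population never reshuffles existing cells.

Two kernel templates model the area phenotypes.  The coincidence-tuned
template puts positive LI along the dT = 0 column (Gaussian in dF, zero at
dF = 0 where overlapping identical tones are just a louder single tone)
over uniform off-coincidence suppression; 40% of such cells have their
single-tone amplitudes scaled by 0.1, producing combination-only
responders.  The asymmetric template carries unequal uniform suppression
between the Upward and Downward regions plus two supralinear clusters —
one in an Upward-region quadrant, one in a Downward-region quadrant, with
independent strengths.  Placing one cluster per region keeps the
facilitative asymmetry statistically independent of the suppressive one
(a single cluster would shift both bias scores together); with
`dsi_coupling > 0` the up/down sweep amplitudes are tied to the kernel's
Bias_supp through a tanh link, the mechanism by which asymmetric lateral
inhibition is thought to produce direction selectivity, so the
DSI ~ Bias_supp association (and its absence for Bias_fac) is a
recoverable ground truth.

What the generator does *not* emulate: correlated noise across neurons,
response adaptation across blocks, motion artifacts, spike-to-fluorescence
nonlinearity, or frame images (the pixel model covers only one cell plus
its background ring).  Passing recovery tests therefore demonstrates the
correctness of the analysis chain, not robustness to every pathology of
real recordings.

## Numerical choices and degenerate inputs

- LI, DSI and asymmetry are NaN when their clamped denominators vanish;
  NaN propagates as "excluded", never as zero.
- The brightness QC boundary and other ratio thresholds use a 1e-12
  relative epsilon so exact boundary cases land on the inclusive side.
- Window lengths use ceil(duration × rate) with a 1e-9 guard against
  float artifacts.
- The rank-sum test returns "none" when all amplitudes are tied;
  `mannwhitneyu` picks its exact method for small untied samples.
- Chi-square comparisons of fractions omit the continuity correction by
  default (toggle available); Bonferroni adjustment is min(1, p·m).

## Validation benchmarks and problem sizes

`spectint.validation` measures, at sizes chosen to run in about a minute
on one core: exact LI-kernel recovery on noise-free cells (< 1e-6,
observed ~1e-16); median |LI error| ≈ 0.036 over 200 cells at CV 0.2;
significance-detector false positives on 200 pure-noise cells (observed
0); the nonlinearity-test type-I rate (≈ 0.2, see the caveat above); and
the area contrasts at 300 cells per template (coincidence-preferring
fractions with chi-square, the ensemble correlation dip at dT = 0, and
the presence/absence of the DSI ~ Bias_supp / Bias_fac correlations).
`scripts/acceptance.py` reports the same quantities as JSON.
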