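# Methods

## Kinetic model

A bound TF molecule observed in slow-tracking mode disappears for one of
three reasons: dissociation, photobleaching of the fluorophore, or (rarely)
the movie ending. The model is a two-component mixture: a fraction `f` of
molecules are transient ("fast") binders with dissociation rate `k_fast`,
the remainder are specific ("slow") binders with rate `k_slow`; an
independent single-step bleaching clock runs at `k_bleach`. The observable
dwell is the minimum of the binding lifetime and the bleach time, so the
survival function of observed dwells is

    S(t) = f·exp(−(k_fast + k_bleach)·t) + (1−f)·exp(−(k_slow + k_bleach)·t).

The fitted slow rate therefore estimates `k_slow + k_bleach`; subtracting the
slow rate of an H2B-Halo control — a stably incorporated histone whose
disappearance is dominated by bleaching — gives the corrected `k_off`, and
its inverse is the residence time. The fast component is reported but treated
as non-specific background, following the single-particle-tracking convention
that the slow/specific component carries the biology. The time at which the
fitted model reaches 1% bound is computed from the fitted model (not the
empirical curve, which rarely reaches 1%): closed form for single-exponential
fits, bisection to relative tolerance 10⁻⁶ otherwise.

Dwell-time conventions, stated explicitly because they shift apparent
fractions (never rates, by memorylessness of the exponential):

- duration = (last frame − first frame) × frame interval; gap-bridged frames
  count as bound;
- minimum track length 3 frames (i.e. dwells of ≥ 2 frame intervals at 5 Hz);
- tracks alive at the final movie frame are right-censored and excluded from
  survival curves; with 1000-frame movies and dwells far below 200 s the
  induced bias is negligible;
- survival curves are pooled within a biological replicate, fitted per
  replicate, and statistics (mean, SEM, two-tailed t-test) run across
  replicates, never across cells.

Because discretization to frame multiples and the minimum-length cut
left-truncate the dwell distribution, the apparent fast fraction at the
shifted origin differs from the generating `f` (each component is reweighted
by `exp(−k·t₀)`); the rates are unaffected. The fast-fraction recovery
benchmark therefore uses continuous dwell samples, while all rate benchmarks
run on discretized, truncated data as a camera would record them.

## Fitting

The two-exponential fit minimizes unweighted least squares on the empirical
survival values, parametrized as `(f, k_slow, ratio = k_fast/k_slow ≥ 1)` so
the ordering constraint holds by construction, with multi-start
initialization (12 starts: three rate scales around a data-driven decay
estimate × two ratios × two fractions) and an analytic Jacobian. If the best
fit is effectively single-exponential (`k_fast/k_slow < 1.5` or `f` outside
[0.01, 0.99]) a single exponential is refitted and flagged `collapsed`. A
maximum-likelihood fit of the left-truncated mixture on raw dwells is
provided as an independent cross-check mode; the two agree on the slow rate
within sampling error on simulated data. Photobleach corrections that come
out non-positive raise an error rather than being clamped — a TF that
appears more stable than H2B indicates a calibration problem the user must
see.

## Spot detection and tracking

Detection follows the multiple-target-tracing recipe. Per frame, background
mean and sd are estimated robustly (median and MAD); the test statistic is
the zero-mean, unit-norm Gaussian-template correlation divided by the
background sd, which is standard normal under the background-only null, so
the threshold is `Φ⁻¹(1 − loc_error)` with `loc_error = 10^−6.25` per pixel
(≈ 0.04 expected false positives per 256×256 frame). The frame is
median-subtracted and zero-padded before filtering; reflect padding would
mirror border noise and inflate the statistic's variance at the edges.
Candidates (local maxima above threshold) are refined by least-squares
Gaussian fits with the PSF width fixed at 1.2 px (the diffraction limit is
not refitted per spot); non-converging or non-positive-amplitude fits are
discarded. Fitted spots are subtracted and the residual re-tested for up to
three deflation loops to recover overlapping spots; duplicates within one
PSF sigma are merged keeping the higher statistic. MAD-based noise
estimation makes detection equivariant under gain changes.

Linking is per-frame optimal bipartite assignment (Hungarian algorithm)
minimizing total squared displacement. A track head unseen for `g` frames is
a candidate source for a detection within radius
`r = 3·sqrt(4·D_max·Δt·(1+g))` — the 2-D diffusion MSD form with a 3×
safety factor, configurable, since only `D_max = 0.5 µm²/s` is a given.
Each detection keeps at most 5 nearest candidate sources (the competitor
cap, applied per target). The assignment matrix is padded so that leaving a
head or detection unmatched costs more than any allowed match, which makes
the matching maximum-cardinality first, minimum-cost second; heads persist
one frame (`max_gaps = 1`) before the track is terminated. A brute-force
exhaustive-assignment oracle checks this matching on small instances in the
tests. Note the strict "more gap tolerance never yields more tracks"
monotonicity holds for well-separated molecules with missed detections (the
regime gap closing exists for); in dense clutter a gap-tolerant head can
steal a detection and reshuffle assignments.

## Synthetic data

The generator produces what the study's instruments would record, with
ground truth attached:

- **Dwell times**: mixture-exponential lifetimes with bleaching, floored to
  frame intervals, minimum-length filtered. Defaults: 5 Hz, 1000 frames, 30%
  fast fraction at 1 s⁻¹, bleach 0.05 s⁻¹.
- **Movies**: bound molecules are immobile 2-D Gaussian spots (σ = 1.2 px,
  amplitude 80 over Gaussian background sd 10 → SNR 8) for the duration of
  their bound interval, which starts at a uniformly random frame and ends at
  unbinding, bleaching or movie end (then flagged censored). After the
  interval the molecule is not rendered — an unbound molecule blurs out
  within one 200 ms exposure. A separate free population diffuses at
  2 µm²/s and is rendered with probability 0.05 per frame, standing in for
  the rare sharp appearance of a diffusing molecule; no explicit motion-blur
  model is used. Localization error arises naturally at detection; no noise
  is added to rendered positions. Molecule density is a free parameter
  (default ~6 concurrent spots per 256×256 frame, the well-separated regime
  the tracker assumes); the generator warns when the expected
  nearest-neighbor distance falls below 2 PSF sigma.
- **Cell images**: cell and chromatin are nested ellipses; the TF channel is
  constructed so the chromatin mean is exactly `ratio ×` the whole-cell mean,
  hence the true score is log₂(ratio); the H2B channel is bright only over
  chromatin; Gaussian noise on both.
- **Spike-in counts**: Binomial(total reads, fly fraction) per sample, or
  exact expectations in deterministic mode.

What the generator does not emulate — and what passing tests therefore do
not demonstrate about real data: camera-specific noise (EMCCD gain,
Poisson shot noise), drift, fluorophore blinking, 3-D defocus, cell-to-cell
variability in background and expression, chromosome-shaped (non-elliptical)
chromatin, or genomic structure in read counts. The benchmarks establish
that the estimators are correct and unbiased under their own model at
realistic sampling sizes, not that the model captures every property of the
instruments.

## Enrichment scoring

The whole-cell mask is the largest connected component above the lowest
threshold of a three-class multi-Otsu on the smoothed channel sum (three
classes because a mitotic cell has background, cytoplasm and chromatin
populations; a plain two-class Otsu merges cytoplasm into background when
chromatin contrast is strong). The chromatin mask is an Otsu threshold on
the smoothed H2B channel inside the cell. Background subtraction is off by
default — the score is a ratio of means, so a zero-offset camera needs none,
and subtracting an estimate changes the score's meaning; `background='mode'`
(histogram mode, i.e. the most common, extracellular intensity) or an
explicit number are available for cameras with a large offset. A CSV ROI
import path lets hand-drawn masks be used verbatim.

## Statistics

Condition and construct comparisons average each biological replicate first
and run a standard two-tailed t-test on the replicate means (equal-variance
by default, Welch optional); SEMs are across replicates. The headline
mitosis/interphase ratio is the ratio of condition means, with per-replicate
ratios also reported when replicates pair up. With a single replicate, means
are reported and the test is marked unavailable rather than computed.

## Problem sizes and tolerances

Benchmarks use 5000 dwells per replicate-condition for rate recovery (the
scale of a few cells' pooled tracks), 10⁵ dwells for the two-exponential
reference benchmark, and one 256×256×1000-frame movie at SNR 8 for
detection/tracking fidelity; at these sizes recovered rates sit within a few
percent of truth and the sampling spread across seeds is well inside the
15% / 5% / 10% acceptance bands used in the tests. Bisection tolerances are
10⁻⁶ relative; fits discard starts that fail to converge and report an error
only if all starts fail.

## Known limitations

- The two-exponential model cannot represent residence-time heterogeneity
  beyond two states; the `collapsed` flag covers the one-state limit but
  three-state kinetics will bias `k_slow` upward.
- Bleach correction by subtraction assumes bleaching and dissociation are
  independent and additive in rate, and that the H2B slow component is pure
  bleaching.
- The tracker has no motion model (bound molecules are immobile by
  assumption); fast-tracking diffusion analysis is out of scope.
- Segmentation assumes one dominant cell per field and single-plane images.
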