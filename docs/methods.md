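# Methods

This note documents the models, conventions, numerical choices, and
limitations behind `icspread`. Everything stated here is computed by
the package itself (tests or `scripts/acceptance.py`); no external
results are quoted.

## Geometry and conventions

Recordings are trials × channels × samples voltage tensors from a
16-channel, 50 µm-pitch single-shank probe sampled at 25 kHz along the
IC tonotopic axis. Channel 0 is the ventral-most site; index increases
toward dorsal. Because the ventral IC processes high frequencies,
characteristic frequency (CF) *decreases* with channel index; the
default map is log-spaced 48 → 8 kHz over the 16 channels (adjacent
ratio (8/48)^(1/15) ≈ 0.888, i.e. ~0.17 octave per channel). The map
is a parameter everywhere.

Stimulus levels are kept in native units (dB SPL for tones, mA for
current, V for coil drive) and mapped to a common dB axis with the
amplitude convention 20·log10(x/1 unit) → dB SPL / dB mA / dB V.

Trials are stored level-major (trial *i* belongs to level
*i* // repeats). One epoch is 30 ms with stimulus onset at 5 ms and a
25 pulses/s repetition rate; neither is dictated by the data model and
both are configurable.

## aMUA extraction

Four steps, each a separate operation with its own contract:

1. **Spike band**: 4th-order Butterworth band-pass, 325–6000 Hz,
   applied causally (forward only). Causality preserves response
   latency and — more importantly — prevents stimulus-artifact energy
   from leaking *backward* past the artifact excision boundary, which
   zero-phase (filtfilt) filtering would do. The filter order is a
   declared default (the band edges are the defining parameters);
   tests check the realized transfer function against the analytic
   magnitude response.
2. **Artifact excision**: samples in [onset, onset + 2 ms) are removed
   from the stream (not zero-filled), so no rectified artifact energy
   can enter the integral. Downstream indexing accounts for the 2 ms
   shift.
3. **Envelope**: full-wave rectification, 4th-order Butterworth
   low-pass at 475 Hz, polyphase resampling 25 → 12 kHz (rational
   factor 12/25). The low-pass precedes the decimation and provides
   its anti-aliasing. Negative filter ripple is clipped to zero: the
   envelope of a rectified signal is non-negative by definition.
4. **Response magnitude**: trapezoidal area under the envelope over
   the 2–15 ms post-onset window (13 ms), in volt·seconds.

The chain is positively homogeneous (aMUA(c·x) = c·aMUA(x), c > 0),
which makes every downstream d′ quantity invariant to amplifier gain.

## Neurometrics

Pairwise d′ between successive levels uses the unequal-variance
convention d′ = |μ_a − μ_b| / σ_rms with σ_rms the root-mean-square of
the two *sample* standard deviations (denominator n − 1). A
pooled-by-n variant is available (`variance="pooled"`). Zero-variance
cells with unequal means yield +inf and set a per-channel degeneracy
flag instead of being clamped.

Cumulative d′ is the running sum of pairwise values; it starts at 0,
is non-decreasing, and is scale-invariant.

**Small-sample null bias.** Because d′ is an absolute value, its null
expectation is not zero but ≈ √(2/n)·E|Z| ≈ 0.18 per level pair at
n = 39 trials. The bias accumulates *linearly* with the number of
level pairs, so a silent channel's cumulative d′ after k pairs is
centred on 0.18·k. This is an intrinsic property of the statistic, not
an implementation artifact; the test suite quantifies it against a
brute-force simulation oracle. Its practical consequence: spread masks
should be evaluated at reference levels that sit low on the level
grid, which the study's level-grid design guarantees (below).

## Spatial tuning curves and spread

The STC is the cumulative-d′ matrix over (level, channel). For
display/export the surface is refined 10× by bilinear interpolation
and iso-d′ contours at {1, 2, 4} are extracted by marching squares.
The *measurements*, however, use discrete definitions that do not
depend on the interpolation scheme:

* per-channel threshold: first crossing of cumulative d′ = 1, linear
  interpolation in level;
* best site (BS): channel with the lowest threshold; exact ties go to
  the channel with the larger cumulative d′ one level grid-step above
  the crossing, then to the lower index;
* reference level L\*: first (interpolated) level where the BS reaches
  cumulative d′ = 2 (or 4); since trial data exist only at tested
  levels, the suprathreshold mask (d′ > 1) is evaluated at the nearest
  tested level at or above L\*;
* spread: (max − min) channel index of the mask, × 50 µm for distance,
  converted to octaves through the tonotopic map;
* tips: maximal runs of contiguous suprathreshold channels at the
  d′ = 2 reference level.

A mask touching either end of the array marks the spread as a censored
lower bound (excluded from means, retained in the table); a BS that
never reaches the reference d′ leaves the measure missing.

The tonotopic map is fitted by regressing log2(tone frequency) on the
acoustic best sites and inverting; channels outside the measured BS
range carry extrapolated CFs and are flagged.

## Rate-level functions and dynamic range

The trial-mean aMUA at the BS versus level (dB axis) is fitted with a
3-parameter logistic r(x) = rmax/(1 + exp(−(x − x0)/s)) by least
squares, multi-started over slope (2–50 % of the level span) and
midpoint (25/50/75th level percentiles). Fits are rejected (DR
missing) when no start converges, when the fitted slope exceeds 10×
the tested span, or when the fitted curve varies by less than 5 % of
rmax across the tested levels — the last condition catches flat data,
which a saturated logistic can otherwise fit perfectly.

DR = x(0.9·rmax) − x(0.1·rmax) = 2·s·ln 9. A raw variant (linear
interpolation of the 10 %/90 % crossings of the measured normalized
curve) is available for sensitivity analysis. Curves whose top-level
mean stays below 90 % of the fitted maximum are flagged unsaturated;
their DR is a lower bound. `normalize_levels` shifts the dB axis so
the fitted half-maximum sits at 0 dB, enabling overlays across
experiments; the shift is idempotent and leaves DR unchanged.

Note the 3-parameter model has no baseline term. The rectified-noise
floor of real (and synthetic) aMUA therefore inflates the fitted slope
— and hence DR — by roughly 15–20 % relative to the generator's
programmed slope on the default synthetic conditions. The modality
*ordering* of DR is unaffected.

## Statistics

Spread/tip/DR tables (one row per experiment × condition) are compared
with a two-way ANOVA using Type II sums of squares (appropriate for
unbalanced designs; identical to the textbook decomposition when
balanced, which is how it is tested) with the interaction included by
default. Tukey HSD comparisons are made between least-squares means
(cell means averaged over the other factor) with the Tukey–Kramer
standard error and the studentized-range distribution on the residual
df; reported columns are LS mean difference, 95 % CI, adjusted p, and
star codes (*p<0.05, **p<0.01, ***p<0.001). Single-factor contrasts
use a pooled-variance Student t-test (Welch optional). Summaries are
mean ± sample SD.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth for recovery tests:

* **Recruitment**: added firing rate λ(ch, L) = rmax ·
  logistic((L − θ(ch))/s) on the dB axis. For tones the per-channel
  threshold is V-shaped in log-frequency distance from each channel's
  CF (θ = θ_c + 80 dB/octave · |log2(f/CF)|, a sharp multi-unit tip);
  for electric/magnetic it grows linearly with channel distance from
  the insertion center, by 10 dB per (σ channels). A `rect` profile
  (flat-top window, infinite threshold outside) provides rectangular
  activation of exactly known width for spread-recovery oracles.
* **Spiking**: per trial and channel, a Poisson count with mean λ·13 ms
  placed uniformly in the 2–15 ms post-onset window, convolved with a
  biphasic unit-peak 1 ms spike waveform (one sine cycle), over white
  Gaussian noise (SD 0.1 of spike peak). At high rates overlapping
  biphasic waveforms partially cancel, so mean aMUA is sublinear in λ
  — as in real rectified MUA; the λ-oracle tests therefore run in the
  sparse regime.
* **Artifact**: a deterministic decaying 1.5 kHz transient occupying
  exactly [onset, onset + 2 ms), scaled with the stimulus amplitude
  ratio. Energy outside the window is identically zero.
* **Determinism**: one integer seed drives counts, spike times, and
  noise; identical seeds reproduce the tensor bit for bit.

### Study conditions

The default per-modality parameters encode the physics the package
exists to measure, chosen once from signal-detection arithmetic:

| modality | levels | θ_c | s (dB) | spread |
|---|---|---|---|---|
| acoustic | 20–90 dB SPL, 10 dB steps, 32 kHz | 30 dB SPL | 5.91 | 80 dB/oct V-shape |
| magnetic | 2–23 dB V, 3 dB steps | 5 dB V | 2.29 | σ = 2.0 ch |
| electric | −16 – −2 dB mA, 2 dB steps | −14 dB mA | 0.737 | σ = 12.0 ch |

39 repeats per level; rmax 2500 Hz. The slopes make the logistic DR
(2 s ln 9) ≈ 26 / 10 / 3.2 dB, the characteristic acoustic > magnetic >
electric ordering; the σ values make the threshold gradient across the
array steep for coils (focal) and shallow for monopolar current
(broad), producing the magnetic ≈ acoustic < electric spread ordering.
Each level grid starts one step below θ_c so the d′ = 2/4 reference
levels fall at low level indices, keeping accumulated null bias on
silent channels well below the d′ = 1 criterion — the same property
that makes off-BS channels dark in real spatial tuning curves.
Insertion-site centers (channel 5.5 basal, 10.0 apical) keep wide
activation away from the array ends so spreads are usually
uncensored.

### What the generator does **not** emulate

No biophysical cochlea or IC model; no local-field potentials;
noise is white and uncorrelated across channels; single-site
(unimodal) recruitment only, so simulated tip counts are ≈ 1 for all
modalities — multi-tip profiles characteristic of broad electric
recruitment across cochlear turns are out of scope (the tip counter is
instead verified exhaustively against a run-length oracle on all 2¹⁶
masks). Passing tests demonstrate that the *analysis* recovers known
ground truth under these assumptions, not that the generator
reproduces every feature of in-vivo recordings.

## Problem sizes

Recovery and ordering experiments in the tests and acceptance script
use 8-level × 39-repeat × 16-channel × 30 ms recordings (about 4 M
samples each), 6 replicate simulated animals per condition in the
study, 100 seeded replicates for the spread-ordering experiment, and
50 seeds for noisy slope recovery — sizes chosen so the full suite and
the acceptance run each complete in a few minutes on one CPU while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* DR estimates inherit the no-baseline logistic bias described above.
* The suprathreshold mask is evaluated on the discrete level grid
  (nearest tested level at or above L\*), so coarse level steps
  quantize the reported spread; the interpolated-surface variant
  exists for sensitivity checks but the discrete rule is the default
  and the documented definition.
* With only 8 levels, fitted slopes for very steep (electric-like)
  recruitment rest on ~2 informative points; multi-start keeps the
  fits stable but per-experiment DR scatter is larger for electric
  runs.
* Tukey comparisons assume homoscedastic cells (pooled MSE), as is
  standard for HSD on LS means.
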