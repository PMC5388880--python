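# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. Empirical claims below are the properties the
test suite and `scripts/acceptance.py` themselves compute.

## Bolus-transit model and TTP estimation

A dye bolus passing a microvessel is modeled as a gamma-variate,

    F(t) = b + A (t − t0)^α exp(−(t − t0)/β),   t > t0,

with baseline `b`, onset `t0` (seconds from the injection trigger at
t = 0), shape `α` and scale `β`; the analytic peak is `TTP = t0 + αβ`.
The fit is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) on a reparameterized model whose amplitude is
the *peak height above baseline* — `(t−t0)^α` overflows for α near the
upper bound of 20, while the peak-height form stays O(1) everywhere.

Initialization is data-driven: a 5-sample moving average (used for
initialization only, never for fitting) locates the peak; the baseline
starts at the median of the pre-rise samples (before the peak, at most the
first tenth of the trace); sample noise is estimated from first
differences (`std(diff)/√2`), which ignores the smooth bolus trend; onset
starts at the first smoothed crossing of baseline + 3·noise; `α` starts
at 2 and `β` at `(t_peak − t0)/α`. Bounds: `t0 ∈ [0, t_peak]`,
`α ∈ (0.1, 20]`, `β ∈ (0.01, T]`. A trace with no suprathreshold rise
(peak height ≤ 5·noise SD) is returned non-converged rather than raising,
since flat vessels are an expected failure mode of line-scan data.
Recirculation of the dye is not modeled; an optional window truncation at
the first post-peak local minimum is available.

On noiseless traces the fitted TTP matches the analytic peak to ~1e-12 s
over a 5×5×5 grid of (t0, α, β); with noise at 5% of peak height the mean
TTP error is ~0.2% of truth. TTP is invariant to affine rescaling of the
fluorescence since baseline and amplitude are free parameters.

## Flow change from TTP dispersion

Hypercapnia raises flow by a factor `k`; transit-time *deviations*
contract by `1/k` (transit-time homogenization). Orthogonal (Deming)
regression of hypercapnic on normocapnic TTP — errors live on both axes —
uses the closed form

    slope = [s_yy − λ s_xx + √((s_yy − λ s_xx)² + 4 λ s_xy²)] / (2 s_xy),

with λ = 1 (orthogonal) by default and exposed as a parameter. The
network flow change is `100·(1/slope − 1)`. Degenerate clouds
(`s_xy = 0` with `s_yy = λ s_xx`) raise rather than returning an
arbitrary axis.

**Centering.** Vessel types differ systematically in arrival time
(arterioles ~3 s, venules ~5 s by default), and the mean TTP shift under
hypercapnia is governed by reactivity — a different, smaller effect than
the dispersion contraction. A pooled regression on globally centered
TTPs would therefore mix the between-type axis (slope ≈ 1 − R/100) with
the within-type axis (slope = 1/k) and bias the flow estimate; measured
on the default generator this inflates a true slope of 0.575 to ~0.79.
Pooled estimates consequently mean-center x and y *within vessel type*
(`center_by="vessel_type"`), which reduces to ordinary centering on
single-type subsets. Centering never changes the Deming slope of the
centered cloud itself.

**Uncertainty.** A case-resampling bootstrap over animals (2000 draws,
seeded; vessels of a resampled animal stay together) yields percentile
CIs. With one animal it falls back to resampling vessels. This respects
between-animal clustering without a parametric mixed model. Recovery at
realistic scale (147-vessel cohorts, realistic noise): the mean estimate over
50 replicates sits within ±5 points of the true +74% / −5.3% values, and
the 95% CI covers truth in ≥90% of replicates.

The reactivity-vs-amyloid-load relation is ordinary least squares of
percent reactivity on percent load (statsmodels), returning slope, SE,
R² and the two-sided p for zero slope. A constant response returns
slope 0 and R² = 0 exactly.

## Synthetic bolus cohorts

For vessel i of type v:

    TTP_normo = μ_v + δ_i,              δ_i ~ N(0, σ_v)
    TTP_hyper = (1 − R_v/100)·μ_v + δ_i/k + ε_i,   k = 1 + F/100,

with measurement noise ε (SD 0.05 s). Defaults: 147 vessels
(60 arterioles, 45 capillaries, 42 venules) over 9 animals assigned
round-robin; type means 3/4/5 s with SDs 0.5/0.6/0.7 s; F = +74% and
reactivities 15/13/15% for the healthy-like cohort (8.0/8.4/7.3% and
F = −5.3% for the impaired-like scenario). Traces are the gamma-variate
with α = 3, onset at half the target TTP, peak height 50 a.u. over a
100 a.u. baseline, 20 ms line period, 12 s scans, additive white noise
(SD 2.5 a.u., i.e. 5% of peak — line-scan noise is otherwise
uncharacterized). Draws whose curve would not fit the scan window
(TTP + 3β > duration) are redrawn, and nominally infeasible configs are
rejected. One seed is split hierarchically (`numpy SeedSequence`) so
sub-generators are independently reproducible. There is no between-animal
random effect in the generator, so animal-level bootstrap coverage here
reflects clustered resampling of exchangeable vessels; real cohorts with
animal effects will have wider CIs.

## PAC signal model

    x(t) = A_θ cos φ(t) + A_γ (1 + m cos(φ(t) − φ_c)) cos(2π f_γ t)
           + pink + white,
    φ(t) = 2π ∫ (f_θ + ν(t)) dt.

`m ∈ [0,1]` is the coupling depth; the raw MI of the clean coupled
component is `A_γ·m/2`. `ν(t)` is an Ornstein–Uhlenbeck instantaneous-
frequency wander (RMS 0.15 Hz, correlation time 1 s) shared by carrier
and envelope. It exists because physiological theta holds phase only
over a few cycles, and because a strictly periodic carrier makes a
circular time-shift of the envelope equivalent to a constant phase
offset — every shift surrogate would then retain the full coupling and
the surrogate test would be blind. The band-limited wander decorrelates
shifts at lags beyond a few seconds while keeping the modulation
sidebands inside the analysis filters (the extracted Hilbert envelope
matches `A_γ(1+m cos φ)` to <1% on clean signals; a Wiener phase drift
was rejected because its Lorentzian tails leak ~2% of modulation energy
out of any flat passband and distort the envelope by ~20%).

Amplitudes default to a prominent theta (A_θ = 1) and a modest gamma bump
(A_γ = 0.2) over a strong background (white and 1/f noise, SD 1.0 each;
pink noise is white noise spectrally shaped by a 1/f amplitude profile
with the DC bin zeroed). In-band gamma SNR is then near 1, which is the
physiological regime — cortical gamma is a small spectral bump, not a
clean tone.

## PAC estimation

Raw LFPs are low-passed at 500 Hz (zero-phase FIR) and decimated to
1 kHz. All filters are Hamming windowed-sinc linear-phase FIRs applied in
a single pass with exact group-delay compensation (mathematically
zero-phase for a symmetric FIR; verified by impulse test). Filter length
is set by transition width ≈ 3.3·fs/Δf with Δf the smaller of the band
width and the low edge (0.2·cutoff for low-passes): a 1 Hz theta bin at
1 kHz takes ~3300 taps, a 4 Hz gamma bin ~825. One filter length at each
end of the record is excluded from MI computation. Orders tied to cycles
of the low edge were rejected: a 23-tap filter for the 130 Hz bin has a
~140 Hz transition and cannot separate 4 Hz bins at all.

Phase modulation of a carrier at `f_mod` lives at carrier ± f_mod, so an
amplitude filter narrower than the modulation cannot carry the envelope
it is meant to measure. Each (phase band, amplitude band) cell therefore
extracts its envelope with the amplitude band padded by the top frequency
of its own phase band (labels unchanged, transition kept at the nominal
width, pad exposed as `sideband_pad`).

**Surrogate null.** The null is the circular time-shift family of the
envelope against the unshifted phase (shift preserves the envelope's
spectrum and autocorrelation). The FFT cross-correlation identity gives
the MI at *every* lag at once, so the default null is the exhaustive set
of admissible lags in [0.1·n, 0.9·n] — deterministic and with negligible
estimation error; a sampled mode reproduces the conventional 50-shuffle
population (`surrogate_mi`). `z_mi` is `(MI − mean(null))/SD(null)`.

**Significance.** Under no coupling the composite mean is approximately
an isotropic complex Gaussian, so null MI² is approximately exponential.
Measured over 10 800 null cells, a single-scale exponential is perfectly
calibrated in the bulk but ~1.8× anti-conservative at the
Bonferroni-corrected tail (α/108 ≈ 4.6e-4): the null scale wanders slowly
across a recording, making the marginal null a scale mixture. The default
test therefore fits one exponential scale per block of contiguous lags
(8 blocks) and uses the mixture p-value `mean_b exp(−MI²/s_b)`, which is
calibrated at the corrected threshold (measured tail ratio 1.00;
family-wise error 5/100 null recordings at α = 0.05). With the sampled
null the statistic `MI²/mean(surr²)` is exact-F(2, 2·n_surr). A Gaussian
z threshold and an empirical percentile mode remain available; both are
materially miscalibrated here (the empirical tail is undersampled because
adjacent lags are correlated) and are kept for comparison only.
Significance is Bonferroni-corrected across the 108 grid cells.

**A caveat on max-z localization.** For any cell containing coupled
energy, the null SD itself scales with that cell's coupled envelope
amplitude (the modulation beat survives shifting with a coherence time
set by the envelope bandwidth), so the z-score saturates at a common
ceiling (~22 at 120 s) across the whole coupled cluster and the argmax of
z among neighboring cells is effectively exchangeable. The *raw MI* peak,
by contrast, localizes the coupled cell exactly (2× margin over
neighbors; 100% bin-exact hits in testing) — use `raw_mi` for
localization and `z_mi`/significance for detection. This ceiling is
intrinsic to per-cell normalization against multiplicative nulls, not a
property of this implementation.

Cohort summaries reduce each electrode's comodulogram to a scalar
(mean z over all cells by default; max-z, mean raw MI, and
mean-significant-z variants are provided, since the reduction used for
published bar plots is rarely stated) and report mean ± SEM over
electrodes.

## Morphometry

All measures are transparent pixel ratios with 8-connectivity throughout
(components via `skimage.measure.label`, contact via chebyshev-distance
dilation). Background thresholding finds the smallest intensity at which
the background region's suprathreshold density is at most the target
(default 10 per 150 µm², the rule's upper bound; the target is a
parameter, not an assumed midpoint) — computed exactly by order
statistics. Plaque components under the minimum area (default 100 µm²,
matching the smallest plaques preserved by staining thresholds) are
discarded before computing percent load. 3D surface areas enter as
scalars; the package does not re-segment volumetric images. Mask-scene
generators construct every target pixel-exactly (equal-size square mural
cells, so detachment granularity is 1/n_cells; exact-area plaque blobs),
which is what makes the round-trip tests exact.

## Problem sizes

Recovery studies run at realistic experimental scale: 147-vessel cohorts (50
replicates for the flow-change studies in the test suite, 10 in the
acceptance script), 33-arteriole regressions (100 replicates), 120 s
LFPs (40 detection runs and 100 null runs in the suite; 10 and 40 in the
acceptance script), and 1000 random 64×64 masks against a flood-fill
oracle. PAC null calibration generates directly at the 1 kHz analysis
rate; detection runs exercise the full 20 kHz acquisition-and-decimation
path.

## Known limitations

- The generators are idealizations: no motion artifacts, recirculation,
  photobleaching or vessel-diameter changes in bolus traces; no
  nonstationary band power, spikes or volume conduction in LFPs; no
  stain-specific intensity structure in masks. Passing recovery tests
  shows estimator correctness under the stated models, not robustness to
  every artifact of real data.
- Flow-change uncertainty is bootstrap-based; no p-values for group
  contrasts are produced (the original analyses used mixed models).
- The comodulogram analyzes one continuous 120 s window; windowed or
  averaged variants are out of scope.
- Dedifferentiation-style cell classifications are observer-defined and
  enter only as per-instance flags.
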