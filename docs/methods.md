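# Methods

`granuletrace` quantifies the exchange of RNA–protein complexes between
phase-separated granules and their surroundings from fluorescence time
traces. A granule carrying slncRNA molecules (synthetic long non-coding
RNAs with tandem phage coat-protein hairpins) bound by fluorescent coat
proteins appears as a bright punctum; when a nucleoprotein complex enters
or is shed, the punctum's intensity steps up or down by a quantized amount.
The pipeline extracts those steps from noisy, bleaching traces and turns
them into rates, amplitude distributions and content estimates.

## Signal model and normalization

The observed spot signal and its local background are modelled as

    y(t) = (S(t) + c0) · f(t) + ε,        c(t) = c0 · f(t) + ε′,

with S(t) the granule signal of interest, c0 a constant underlying
background, f(t) the (unknown, multiplicative) photobleaching decay and ε
additive symmetric noise. Because f(t) multiplies both channels it cancels
in their ratio:

    S(t) = c0 · (y(t)/c(t) − 1).

This identity is exact for noise-free inputs regardless of the bleaching
law — the test suite verifies recovery of injected signals to a relative
error below 1e-6 for bleach timescales from 10 minutes to infinity. In
practice y is smoothed with a centered 13-point moving average (2 minutes
at 6 frames/minute) before the ratio, and c is replaced by a cubic
least-squares trend, which keeps the slow background drift and removes
frame noise.

Numerical choices:

* The moving average truncates its window at trace ends instead of padding;
  no synthetic values are introduced.
* c0 is estimated as the mean of the fitted background. Any positive choice
  rescales S globally without changing increment signs, so burst
  classification does not depend on this convention.
* Frames where the fitted background is non-positive have no defined S;
  they are masked (NaN), reported, and excluded from all downstream
  statistics rather than interpolated.
* The background polynomial is fitted in a scaled domain for conditioning;
  coefficients are reported in the unscaled domain for audit.

## Burst detection

Under a null of symmetric memory-less noise, the per-trace probability that
an instantaneous increment ΔS(tᵢ) is positive is estimated as
p_inc = N(ΔS>0)/N_tot (zero increments count in N_tot only, so
p_inc + p_dec ≤ 1). A run of m consecutive positive increments has null
probability p_inc^m; requiring p_inc^m ≤ 2⁻¹⁰ ("1 in 1000") gives

    m = −10 / log2(p_inc),

rounded up to whole time points, and analogously for decrements. Because
the moving average correlates increments over its window, any threshold
below the 13-point span is raised to the span. p = 0 yields an infinite
threshold (that direction undetectable); p = 1 is degenerate and pinned at
the span with a warning. The raw (unrounded, unenforced) thresholds are
reported alongside the enforced ones. The significance level is exposed as
a parameter (`alpha`, default 2⁻¹⁰).

Isolated reversals: a single opposing or zero increment flanked by
same-direction increments does not break a run, but at most one such
interruption is tolerated per run, and the interruption does not count
toward m — m counts same-direction increments only. This choice is what
keeps the stated null level honest: with unlimited non-adjacent reversals
the per-position probability of a spurious length-13 "run" in smoothed
symmetric noise is of order 3e-2 (measured ≈8 spurious events per one-hour
trace), whereas with a single uncounted reversal it is
2⁻¹³ + 12·2⁻¹⁴ ≈ 8.5e-4 ≤ 1e-3 (measured ≈0.2 spurious events per
noise-only trace). The tolerance count is exposed (`max_interruptions`).

Events are measured on the normalized, smoothed S: amplitude ΔI is the
endpoint difference S(end) − S(start) and duration Δt the spanned frames
times the frame interval. Gaps strictly between consecutive significant
events are emitted as unclassified segments; spans before the first and
after the last significant event are discarded, since segments truncated by
the observation window cannot be classified.

## Amplitude model

Amplitudes (or granule fluorescence values) are fitted with a quantized
Poisson: intensity I corresponds to I/K₀ complexes, and

    p(I) = λ^(I/K₀) e^(−λ) / (I/K₀)! ,

with the factorial continued off integers as Γ(I/K₀ + 1). Fitting proceeds
by binning the values (Freedman–Diaconis by default, overridable), and for
each λ on a grid (0 to 5 in steps of 0.25 by default) finding the K₀ that
minimizes the mean squared error between the model and the empirical bin
probabilities; the global minimum is returned, ties broken toward smaller
λ. K₀ is located by a 200-point logarithmic scan of the search interval
followed by bounded local refinement — the MSE landscape in K₀ is
multi-modal (sub-multiples of the true quantum alias), so a bare scalar
minimizer is not trusted alone.

Two details matter for identifiability:

* The model is renormalized over the *occupied* bins only. Quantized data
  leave interstitial bins structurally empty; penalizing the continuous
  Gamma interpolation there destroys the fit, and for continuous data
  essentially all bins are occupied so nothing changes.
* Each occupied bin is represented by the mean of its member values rather
  than its geometric center. Histogram edges are anchored at the data
  minimum, so geometric centers sit systematically off the amplitude
  quanta and bias K₀ downward by tens of percent.

Zero values are dropped with a warning before fitting (the renormalization
over the remaining support makes the comparison a truncated-model vs
truncated-data one, which is consistent); an all-zero input is the
degenerate λ = 0 delta and returned as such with zero error. λ = 0 on
positive-valued data concentrates all mass in the lowest occupied bin —
the model's literal degenerate limit, which is surfaced rather than
reinterpreted as an exponential. QQ points (fitted K₀·Poisson(λ) quantiles
against empirical quantiles) are returned for visual validation.

Parameter recovery under the generator's own amplitude model (K₀ = 100,
λ = 2, N = 2000) gives median λ̂ = 2.0 and median K̂₀ ≈ 99 over 20 seeds;
the acceptance-style test asserts the ±0.5 / 15 % bands.

## Image stage

Bright spots are local maxima at least `min_separation` pixels apart whose
peak intensity lies in the top fraction (default 10 %) of candidate
maxima; candidates not exceeding the frame median are treated as background
plateaus and dropped, so a uniform frame yields no spots. Detections are
refined to intensity-weighted centroids of a 7×7 neighbourhood. Note that
with very few spots of unequal brightness the top-decile rule keeps only
the brightest; pass `top_fraction=1.0` to keep all candidates.

Tracks link detections frame-to-frame by greedy nearest neighbour within
`max_displacement` pixels (ties broken by lower (row, col)); unmatched
spots terminate or start tracks. This is a deliberately simple, documented
linker, not a re-implementation of a feature-point tracker.

Per tracked point, a 14×14 pixel sub-frame (top-left corner at the rounded
centroid minus (7, 7); an even width cannot be symmetric, and this
convention is fixed) is classified by two-threshold Otsu into three
classes: spot region (brightest), cell background, dark background. The
per-frame means of the spot-region and cell-background classes form the
paired trace. Uniform sub-frames are flagged degenerate (both channels get
the uniform value); sub-frames with only two grey levels fall back to a
single Otsu threshold with no dark-background class. Spot area is the
largest 8-connected component of the spot-region mask. Class labels are
invariant under affine intensity rescaling, and class means are ordered by
construction.

## Synthetic data

The generator defines the conditions every statistical guarantee is tested
under. Entry and shedding are independent Poisson processes with rates
given per minute; the in-vitro-like preset uses shedding every 10 minutes
on average (0.1/min) with rarer entries (1/30 min), matching the observed
shedding scale of degrading granules, while the in-vivo-like preset
balances the two rates. Each event moves max(1, n) complexes with
n ~ Poisson(λ), each worth K₀ intensity units — so every event moves at
least one complex and the amplitude distribution is the one the fitting
stage assumes. Defaults: K₀ = 100 A.U., occupancy λ = 2.5 (in-vitro
preset), background c0 = 400 A.U. (granule experiments show 350–450 A.U.),
frame interval 10 s × 360 frames (one hour at 6 frames/minute), additive
Gaussian noise of equal sd on both channels, single-exponential bleaching
f(t) = exp(−t/τ). A schedule carries an `initial_content` baseline so
shedding-dominated runs do not immediately clip at zero; rendering clips
negative latent signal at zero and flags the trace. All randomness flows
through one explicit seed per call; identical (config, seed) reproduce
bit-identical schedules and traces.

The detection operating-characteristics experiment uses 100 one-hour
traces, σ = 20 A.U. (so a single-complex event of 100 A.U. is a 5σ step),
events spaced at least three smoothing spans apart, and mild bleaching
(τ = 120 min). Under those conditions sensitivity is ≈0.95 with ≈7 %
median amplitude error and ≈0.24 spurious events per noise-only trace.
Strong bleaching is deliberately excluded from this experiment: the ratio
normalization amplifies late-trace noise by 1/f(t), so a step that is 5σ
at acquisition is no longer 5σ in S once f(t) has decayed substantially —
that interaction is a property of the physics, not of the detector, and
the bleach-robustness guarantee is tested separately (noise-free, any τ).

What the generator does not emulate: realistic PSF optics and camera gain,
granule diffusion between frames, cell segmentation, spatially varying
background within a sub-frame, and correlated (non-Gaussian) noise.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, not performance on arbitrary real movies.

## Other summary statistics

* Net loss rate: (shedding − entry event counts) / number of tracked
  granules; with one tracked hour per granule, events per granule-hour.
* Content ratio: mean granule fluorescence / mean burst amplitude,
  interpreted as molecules per granule if the average burst carries one
  molecule.
* Quenching: a least-squares line through anchor constructs (assumed
  quench-free, e.g. the shortest hairpin cassettes) on the
  (labelled-uracil count, measured fluorescence) plane extrapolates the
  unquenched fluorescence; the quench factor is extrapolated/measured,
  floored at 1. Anchors get factor ≈1 by construction.
* Two-channel coupling: Pearson correlation on the shared unmasked frames
  of two aligned S series.
* Group comparisons: two-sided Wilcoxon rank-sum or Welch t test.

## Known limitations

* Run-length significance is per-trace and ignores multiplicity across
  traces; it mirrors the original procedure rather than adding FDR control.
* The greedy linker cannot resolve crossing spots; identity at close
  encounters is ambiguous by design.
* The quantized-Poisson fit needs amplitude distributions with visible
  structure; heavily overlapping quanta (noise sd comparable to K₀) blur
  the landscape and widen the λ/K₀ confidence.
* estimate_c0 on a bleaching background underestimates the true c0 by the
  time average of f(t); this rescales S globally and is documented rather
  than corrected, since event classification is scale-invariant.
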