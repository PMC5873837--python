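# Methods

This note records the models, conventions and numerical choices behind
`camobreak`, in the order data flows through the package.

## Imaging conventions

Pixel data are float64 in [0, 1]; 8- and 16-bit files are linearly rescaled
on read. Images are treated as already linearized — field photographs in
this kind of study are white-balanced against a gray standard at capture
time — and no gamma handling is applied anywhere.

Coordinates are 0-based, x rightward, y downward, with the center of pixel
(col *i*, row *j*) at (x = *i*, y = *j*). Polygon rasterization uses the
even-odd (crossing-number) rule with half-open semantics on pixel centers,
so an axis-aligned box [0, 10) × [0, 10) covers exactly 100 pixels and
abutting polygons tile without overlap.

The simulated-dichromat transform replaces R and G by their average
Y = (R + G)/2 and leaves B untouched. It is idempotent, and it preserves
the luminance channel (R + G)/2 *exactly* (in IEEE arithmetic,
(Y + Y)/2 = Y), which is the design property that lets one set of
luminance-based covariates describe both viewing conditions. No cone-catch
model of a real dichromat species is attempted: the game this emulates runs
on uncalibrated displays, where receptor-accurate rendering would be
illusory anyway.

## Measurement regions

"Distance from the target edge" is the exact Euclidean distance from a
pixel center to the nearest target pixel (distance transform); Euclidean
was chosen because the region is described by a radius. The annulus keeps
distances in (15, 500] px (defaults), the whole background everything
beyond the 15 px spacer; both are clipped at the image frame without
compensation, as the annuli of near-edge targets in real photographs also
run off-frame. The 15 px spacer guards against out-of-focus pixels that
blend target and background. On desk-scale synthetic images (256–384 px)
the package uses a scaled-down outer radius (80–100 px) so the annulus
remains a proper subset of the background; the 500 px default matches
multi-thousand-pixel field photographs.

## Granularity analysis and camouflage metrics

Band scales are s_k = 2·(√2)^k px up to a cap (256 px for adult-sized
targets → 15 bands; 128 px for eggs → 13 bands); a 10⁻⁶ relative tolerance
at the cap keeps the nominal top size in the schedule despite floating-point
drift in the √2 powers. Each band is an ideal (hard-edged) annular filter in
the Fourier amplitude domain passing wavelengths [s/2^¼, s·2^¼) — boundaries
at the geometric midpoints between neighbouring scheduled scales — with DC
always removed. Hard-edged filters were chosen over smooth-edged ones for
exact testability (a pure grating lands in exactly one band); the filter
bank sits behind a single function so a smoother kernel can be substituted
for sensitivity analysis. Before the FFT, pixels outside the measured
region are filled with the region's mean luminance, which keeps the padded
image's DC at the region mean and suppresses mask-edge ringing.

Band "energy" is the population SD of the filtered image over region
pixels; population (not sample) SD is used throughout the package,
including patch contrast. Pattern difference is the unnormalized sum of
absolute band-energy differences — note this makes it luminance-scale
dependent (energies scale with SD = contrast × mean), which is also why
pattern difference correlates with background luminance across photographs.
Luminance distribution difference is the total-variation distance
(Σ|p_i − q_i|/2) between 100-bin histograms on the *fixed* range [0, 1],
normalized so 0 = identical and 1 = disjoint; the fixed range keeps values
comparable across photographs. Chromatic (color-channel) camouflage metrics
and edge-disruption metrics are deliberately out of scope: the analysis is
about what the luminance channel carries.

## Synthetic scenes

The generator emulates the *statistical* structure of textured natural
backgrounds, not their appearance. A background is isotropic Gaussian noise
with power spectrum ∝ 1/f^β (β = 2, the classic natural-image slope) shaped
by a log-Gaussian bump at a characteristic texture scale (default 16 px,
bandwidth 0.7 octaves) — a pure power law is scale-free, so without a
characteristic scale the target's pattern-scale mismatch dial would be
unmeasurable. On top of this sits a large-scale illumination mottle
(fractional amplitude 0.15, wavelength half the image): natural scenes are
lit non-uniformly, and this is what makes the near-surround covariates
genuinely different from whole-background ones (with stationary noise the
two background scopes are collinear, r > 0.99, and the near/whole model
comparison has nothing to discriminate).

The target is an ellipse (polygon with 64 vertices) of background-like
texture whose dominant scale is multiplied by `target_pattern_scale_shift`
and whose mean is shifted by `target_lum_offset`; it shares the local
illumination mottle (a real animal sits in the local light) and is
alpha-blended over a 2 px feather. Chromatic variation is added as a
red–green modulation field of amplitude 0.08 around the luminance plane, so
dichromat rendering visibly changes the image while leaving luminance
untouched. Scenes are bit-reproducible from their seed.

What the generator does *not* emulate: object-like structure (stones,
grass, shadows with edges), the consistent body outline of a real animal,
specular highlights, and viewpoint effects. Passing tests therefore show
that the *pipeline* recovers known generative structure, not that real
nightjars would yield the same coefficients.

## Session simulation

Latent log search time is the linear predictor of the analysis model
(intercept log 4 s; slopes for log pattern difference, luminance
distribution difference, target area, background luminance and contrast,
slide number, first-slide and played-before indicators, log edge distance,
age-bracket offsets; viewing-condition main effect and interactions) plus
session and photograph random intercepts (SD 0.3 and 0.2) and lognormal
residual noise (SD 0.5). Times above 30 s become timeout records without a
capture time — they are logged so the exclusion rule is exercised, and
excluded (not censored) downstream, mirroring the argument that an online
participant who times out may simply have been distracted. Incorrect clicks
are Poisson (mean 0.3/slide, so ~0.4% of slides exceed the 2-click rule)
and spatially uniform; only the >2 filter consumes them downstream.

Default interaction coefficients follow the sign pattern expected for
consistently shaped adult targets — dichromats slower overall (+0.15), more influenced by
pattern difference (+0.2 on log time per log-unit) and luminance mismatch
(+0.4), relatively worse with small targets (−6×10⁻⁵/px) and dark
backgrounds (−0.5) — with magnitudes chosen so each interaction moves
expected log time by ≈ 0.2–0.3 across its covariate's simulated range,
the order of the 20–40% relative-risk effects reported for such games.
These are *not* claimed to equal any fitted latent coefficients (none are
published); they are plausible study conditions.

Sessions draw viewing condition (default 50/50), one of five age brackets
(5/10/50/25/10%), and a played-before flag (30%); each of the 20 slides
samples a scene with replacement and places the target uniformly in the
central 60% of the image. Edge distance is measured from the target center
to the nearest image edge (the reference point is a package choice; only
its log enters the model). All randomness flows from integer seeds through
`numpy.random` seed sequences, with per-session substreams derived by
counter, so studies are reproducible and session-order independent.

## The mixed model and its solver

The analysis model is y = Xβ + Zu + ε with independent random intercepts
per grouping factor (session, photograph, optionally season) and i.i.d.
residuals. Because the random structure is intercepts-only, the entire
likelihood reduces to fixed-size cross-products: with V = σ²(I + ZΛZ′) and
Λ the diagonal of per-factor variance ratios, Woodbury turns every GLS
quantity into solves against M = I_q + Λ^{1/2}Z′ZΛ^{1/2} (q = total
random-effect levels). β and σ² are profiled out; the 1–3 remaining
variance ratios are optimized by Nelder–Mead on the log scale (xatol 10⁻⁵),
with the λ → 0 boundary admissible — a zero-variance fit simply means the
term does not help. A fit therefore costs O(q³) per likelihood evaluation,
*independent of n*, and candidate models in the stepwise search reuse one
set of cross-products, merely slicing design columns. The solver is
validated against `statsmodels` MixedLM (one trivial group + variance
components) in the test suite: ML and REML log-likelihoods and coefficients
agree to ≈10⁻⁴.

Treatment coding uses trichromat and the lowest age bracket present as
references. Covariates are not standardized (reported terms are on their
raw scales). Rank-deficient designs raise an error listing the aliased
columns — with k photo-level covariates, at least k + 1 photographs are
needed.

BIC = −2 logLik + k ln n with k = fixed parameters + variance components +
1 (residual), n = analysis rows. Simplification runs in three phases:
backward fixed-effect elimination under ML (repeatedly dropping the single
term whose removal most decreases BIC; interactions always before their
parents, and the quadratic slide term before the linear one, so
marginality is never violated), forward addition of random intercepts under
REML (the session intercept is mandatory — it is the repeated-measures
backbone — and phase 1 runs with it alone so that phase 2's forward search
over photo/season is meaningful), then a second backward fixed pass under
ML with the final random structure. Ties (|ΔBIC| < 10⁻⁶) resolve to the
smaller model; a non-converged candidate counts as "not an improvement".
The near-vs-whole background scope is chosen by fitting the maximal model
on both covariate sets and keeping the lower ML BIC (tie → near, the
surround the search task presents).

Wald *F* statistics per term use the deliberately conservative lower-bound
denominator df = n − (fixed parameters) − (total random-effect levels).
The exact df convention behind published tables of this kind is rarely
printed; this one is stated as the package's convention, not an equivalence
claim.

## Recovery harness and problem sizes

The recovery harness simulates replicate studies of 250 sessions × 20
slides (n = 5000) over a 24-scene library (256 px images, 13-band schedule,
80 px annulus — a scaled-down version of the field protocol chosen so a
replicate completes in seconds) and pushes each through filtering,
covariate derivation, and the full three-phase selection.

Two experiments are run. The *focused recovery* experiment uses a
generating model with one strong viewing × log-pattern-difference
interaction (0.4) and every other viewing interaction zero, including the
null viewing × background-contrast candidate: selection must retain the
true term, reject the null one, and cover the true coefficient within 3 SE.
The strength is a power-analysis choice: against the BIC hurdle
ln 5000 ≈ 8.5, reliable (≥90%) retention needs a Wald z ≈ 5, and with
the photo-level covariate correlations the scene library induces (pattern
difference correlates ±0.5 with area, luminance and contrast across
photographs, exactly as its formula predicts), the default-strength
interactions sit near the detection boundary by design. The *sign
reproduction* experiment keeps all four default interactions active and
checks that maximal-model fits reproduce the generating sign pattern.

## Known limitations

- The ideal band-pass filter bank is a stated substitute for the (not
  fully specified) toolbox filters used with real photographs; absolute
  pattern-difference values are therefore convention-dependent, though
  orderings are robust.
- Pattern difference is unnormalized; whether the originating convention
  normalizes by total energy is unclear, so the raw sum is implemented and
  flagged here.
- Zero pattern difference (log undefined) raises rather than imputing an
  offset; synthetic scenes never produce it, real clone-stamped targets
  could.
- Timeouts are excluded, not modeled; a censoring-aware variant is out of
  scope by design.
- The solver handles random intercepts only — random slopes would need a
  different profiling structure (and a general-purpose library).
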