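# Methods

## The problem

Relative water content, RWC = (FM − DM)/(TM − DM), is the ecophysiological
standard for a leaf's degree of water saturation (FM fresh mass, TM fully
turgid mass, DM oven-dry mass). Measuring it gravimetrically is destructive
and slow. Non-contact resonant ultrasound spectroscopy (NC-RUS) offers an
instantaneous alternative: a leaf held between a pair of air-coupled
transducers behaves as a thin resonant plate, and the magnitude and phase of
its through-transmission coefficient in the 0.15–1.6 MHz range — in
particular the first thickness resonance near f₁ = c/(2h) — shift
systematically as the leaf dries. This package implements the full analysis
chain that regresses RWC from such spectra, together with a physics-based
generator of synthetic drying experiments so that every stage is testable
without access to instrument data.

## Synthetic drying experiments (`ncrus.simulate`)

**Forward model.** A leaf is modelled as a single homogeneous lossy layer in
air at normal incidence:

    T(f) = 1 / [cos(kh) + (i/2)(z + 1/z) sin(kh)],
    z = ρc / Z_air,  k = 2πf/c − iα(f),  α(f) = α_ref · f / 1 MHz,

with thickness h, sound speed c, density ρ and attenuation α_ref (Np/m at
1 MHz); Z_air = 415 Pa·s/m. The sign of the imaginary wavenumber follows the
e^{+iωt} convention so that positive attenuation damps (|T| ≤ 1 for every
passive state; the matched lossless plate, z = 1 and α = 0, transmits 0 dB at
all frequencies). Attenuation rising linearly with frequency is the minimal
dispersion law that keeps the resonances finite-Q. A two-layer (palisade +
spongy mesophyll) refinement exists in the literature; the single layer
already reproduces the qualitative drying phenomenology (peak shifts up in
frequency, loses height and broadens as the leaf dries) and keeps the
generator transparent.

Note on the |T| maximum: attenuation skews the peak slightly below c/(2h),
by ≈ δ²·f₁ with δ = α_ref·c/(2π·1 MHz). For the default trait ranges this is
a few hundred Hz at full turgor — below the 2.5 kHz analysis grid step —
which is why peak-location checks against c/(2h) are run at RWC = 1.

**Hydration trajectory.** Per-leaf traits hold dry and turgid endpoints for
h, c, ρ and α_ref; intermediate states interpolate linearly in RWC.
Endpoint priors (uniform ranges) are chosen so that (i) thickness shrinks
proportionally more on drying than sound speed drops, making f₁(RWC)
strictly monotone (decreasing in RWC) for every sampled leaf — the property
that makes the spectra informative about hydration — and (ii) f₁ stays
inside the measured window for RWC ∈ [0.5, 1]. Attenuation roughly doubles
from turgid to dry, so resonances broaden as the leaf dries.

The *spread* of the priors is deliberately narrow (coefficients of variation
of a few percent per trait): the dataset emulates mature leaves of one
species grown at one site, and the leaf-to-leaf variation of the spectra
must not swamp the hydration-driven variation within a leaf — otherwise no
model trained on some leaves could predict an unseen one, which is exactly
the transferability regime this analysis targets. Wider priors are a
constructor argument (`TraitPriors`).

**Acquisition.** Three transducer bands (0.15–0.35, 0.35–0.95, 0.5–1.6 MHz)
with log-uniform native grids of 81/121/111 points — never stated by any
instrument convention here; chosen so the later 2.5 kHz resampling is a
genuine interpolation. Additive Gaussian noise, σ = 0.5 dB in magnitude and
0.05 rad in phase, doubled over the outer 10% of each band's points to mimic
sensitivity roll-off at the band edges.

**Dataset shape.** Defaults reproduce the study conditions: 31 leaves,
around nine drying states per leaf adjusted to 280 measurements total, RWC
drawn from a two-component uniform mixture with 63% of its mass in
[0.88, 1] (above the turgor-loss point) and 37% on [0.52, 0.88), sorted
descending per leaf (drying order). FM is back-computed from RWC and the
leaf's masses so the RWC annotation round-trips exactly. Everything is a
pure function of the seed.

What the generator does **not** emulate: transducer transfer functions,
diffraction and misalignment, within-leaf heterogeneity (veins, two-layer
structure), humidity drift during drying, or mass-measurement error. Tests
passing on this data therefore validate the pipeline's bookkeeping,
numerics and statistical machinery — not field performance on real leaves.

## Preprocessing (`ncrus.preprocess`)

Per measurement: unwrap phase within each band (interpolating wrapped phase
across ±π is meaningless), pool the three bands sorted by frequency
(averaging channels at exactly duplicated frequencies — the shared 0.35 MHz
band edge), then interpolate both channels onto the common 601-point grid,
100 kHz to 1.6 MHz at 2.5 kHz. Seven interpolation methods — linear, cubic
(shape-preserving piecewise-cubic Hermite), splines (not-a-knot cubic
spline), nearest, next, previous, Akima — each produce one [601 × 2] sample,
a ×7 augmentation in which the small inter-method perturbations stand in
for acquisition-time variability: 280 measurements → 1960 samples. Below
the lowest measured frequency (the grid starts at 100 kHz, the lowest
transducer at 150 kHz) all methods hold the nearest measured value; splines
would otherwise extrapolate wildly into a region with no data.

## Resonance parameters (`ncrus.features`)

Four parameters per sample: the global maximum of the dB magnitude, the
frequency and (unwrapped) phase at that maximum, and the normalized −6 dB
bandwidth — the separation of the first frequencies on either side of the
peak at which the magnitude drops 6 dB below it (crossings located by
linear interpolation between bracketing grid samples), divided by the peak
frequency. The −6 dB drop is measured on the dB channel relative to the
peak, not as half power of linear amplitude. Samples whose magnitude never
crosses the threshold on one side within the grid carry an undefined flag
and are excluded from feature-based regression. The fundamental dominates
the analysis window for sub-wavelength leaves, so "first resonance" is
operationalized as the global maximum; a first-local-maximum mode is
available (`peak_mode="first-local"`).

## Cross-validation and balancing (`ncrus.dataset`)

Evaluation is leaf-one-out: all measurements of one leaf, and all seven
interpolated versions of each, form the test set of one fold; the other 30
leaves train. This mimics deployment on a completely new leaf and prevents
any leakage through interpolated siblings.

Because ~63% of measurements sit in RWC ∈ [0.88, 1], each fold's training
pool is balanced by RWC histogram equalization: 10 equal-width bins over
the observed range (~0.05 RWC per bin), every non-empty bin randomly
downsampled without replacement to the smallest non-empty bin's count.
Discarded samples form a pseudo-validation pool (not independent of
training — same leaves, sibling interpolants). Balancing is re-drawn
independently per fold from the fold's derived seed.

## Models (`ncrus.models`)

**1D CNN** on the [601 × 2] spectrum, 18 layers: input → [conv 17×11 → BN →
ReLU] → [conv 55×7 → BN → ReLU → pool 2] → [conv 70×11 → BN → ReLU →
pool 2] → FC 25 → dropout 0.3 → FC 25 → dropout 0.3 → FC 1 → MSE regression
output. Convolutions are same-padded, stride 1, so the length bookkeeping is
601 → 300 → 150 and the flatten is 150·70 = 10500 (312,896 learnable
parameters). Training: SGDM (momentum 0.8247), minibatch 32, initial
learning rate 0.0875 with three drops of factor 10 at the quarter points of
the epoch budget (⌈E·k/4⌉, k = 1, 2, 3; 88/175/263 for the full 350-epoch
schedule), L2 penalty 1.25e−7. Inputs are standardized per channel with
training-fold statistics (batch norm alone does not normalize the input
layer). Weights use uniform fan-in initialization from the run seed.

The engine is a compact NumPy implementation (im2col convolutions evaluated
as BLAS matrix products, exact analytic gradients verified against finite
differences). Two numerical choices matter:

- *Gradient clipping.* At learning rate 0.0875 the curvature of the
  10500-dimensional flatten→FC1 block exceeds the stable step size and
  plain SGDM diverges within a few minibatches, for any initialization
  scale or loss normalization. Updates therefore use global gradient-norm
  clipping (threshold 1.0, configurable) — the standard stabilizer exposed
  by mainstream training toolkits — leaving the prescribed learning-rate
  schedule, momentum, batch size and L2 untouched.
- *Precision.* float32 by default; float64 available for gradient checks.

**Random forest** on the four resonance parameters: 400 regression trees on
bootstrap resamples, 2 of the 4 variables considered per split, minimum 3
observations per tree leaf (scikit-learn backend). Undefined-bandwidth rows
are excluded from both fitting and scoring, and logged.

## Evaluation (`ncrus.evaluate`)

Per-sample predictions (one per interpolated version) and per-measurement
predictions (mean of the seven versions) are summarized by global RMSE,
Pearson's R, and the least-squares line of predictions on true RWC. Model
families are compared by a two-sided paired t-test on per-leaf RMSE
(identical inputs → t = 0, p = 1; a zero-variance nonzero difference is
flagged degenerate rather than given an undefined statistic). The seven
interpolation methods are compared by one-way repeated-measures ANOVA over
the per-measurement error matrix with Bonferroni-corrected paired t-tests
and Tukey–Kramer follow-ups; on well-behaved runs no method should differ —
the augmentation is a perturbation, not a bias.

## Reproducibility and problem sizes

A single master seed drives everything; stage seeds derive by stage-name
hashing (`child_seed`), so the dataset, every fold's balancing draw, and
every model's initialization are reproducible from one integer. The
package's benchmark configuration runs the random forest over the full
31-fold leaf-one-out CV and the CNN with a 50-epoch schedule over the first
8 folds — the sizes at which the cross-validated behaviour (R well above
0.8 for both families on default synthetic data) is already stable and a
full run stays desk-scale. The full 350-epoch, 31-fold CNN schedule is a
config change (`RunConfig(cnn_epochs=350, max_folds=None)`).

## Known limitations

- The single-layer forward model cannot produce the double-resonance
  signatures of strongly stratified leaves.
- Linear RWC→trait interpolation is a convenience; real drying curves are
  nonlinear near the turgor-loss point.
- The CNN engine is CPU-only and single-threaded BLAS-bound; the full
  350-epoch × 31-fold schedule is hours, not minutes.
- The synthetic benchmark measures recovery of the generator's own
  structure; agreement with gravimetric RWC on real leaves can only be
  established with instrument data.
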