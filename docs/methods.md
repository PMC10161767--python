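# Methods

## The problem

Arthropod cuticle (the model system here is stomatopod telson cuticle) is a
twisted-plywood composite of chitin-protein nanofibers. A micro-focused X-ray
beam passing through a thin section produces a wide-angle diffraction pattern
whose chitin (110) ring carries the 3D orientation statistics of every fiber
in the illuminated volume. Radially integrating that ring gives a 1D
azimuthal profile I(χ), χ ∈ [−180°, 180°). Most cuticle regions contain two
fiber families — an in-plane Bouligand stack and an out-of-plane pore-canal
family — so I(χ) typically shows two pairs of diffraction arcs. The task is
the inverse problem: recover nine orientation parameters from one I(χ) curve,
fast enough for beamline-scale batches, and robustly against detector gaps
and counting noise.

## Forward model

Each fiber group is a planar fan of unit axes. The plane z = 0 is tilted by a
rotation about the lab x axis by α, then about the lab y axis by β (the beam
travels along +z, the detector is the x–y plane, χ is measured from +x
counter-clockwise). Within the plane, axes fan uniformly (Gaussian optional)
over [γ − Δγ/2, γ + Δγ/2] around the mean in-plane angle γ. The group weights
λ₁, λ₂ enter only through the ratio λ₁/λ₂.

For a fiber axis **f**, fiber symmetry distributes the (110) reciprocal
vectors uniformly over the pole circle {q : |q| = Q, q·**f** = Q cos σ} with
σ = 90° (equatorial reflection; Q = 2π/d, d = 4.6 Å for α-chitin). The
detector observes the intersection of the |q| = Q sphere with the Ewald
sphere at 10 keV: a ring at constant q_z = −Q²/2k. Each axis' pole circle
crosses that ring at zero, one or two azimuths, obtained in closed form from
A cos χ + B sin χ = C. Every crossing is deposited on the χ grid (360 bins of
1°) with a periodic Gaussian kernel of width 5° (the intrinsic arc width from
mosaic spread and crystallite size; it must match between training-set
generation and reconstruction) and a Lorentz-type weight 1/sin ψ, ψ the
crossing angle of the two curves on the sphere (clipped at sin ψ ≥ 0.05 to
keep tangency cusps finite). The two groups' quadrature curves (181 fan nodes
by default; 1° steps at the widest fan) combine as λ₁C₁ + C₂ and the sum is
normalized to unit maximum. A seeded Monte-Carlo sampler implementing the
same physics by random fan draws and stochastic kernel jitter serves as an
independent oracle in the tests; agreement is verified per bin against the
Monte-Carlo standard error (under unit-area normalization, since a noisy
per-replicate maximum biases peak bins).

All eight angles are periodic with period 180° (an axis equals its negation)
and are normalized into (−90, 90]; the degenerate geometry with no crossings
anywhere returns a flagged all-zero curve.

## Sampling ranges (the synthetic study conditions)

No authoritative range table is available to this package. The defaults are
fixed by a consistency argument against the full-scale per-label recovery
statistics the method is known to achieve, which jointly determine each
parameter's truth variance:

| parameter | default range | rationale |
|---|---|---|
| α | U(−4°, 4°) | R² 0.82 with MAE 0.73° ⟹ σ ≈ 2.2° |
| β | U(−10°, 10°) | R² 0.97 with MAE 0.77° ⟹ σ ≈ 5.6° |
| γ₁, γ₂ | U(0°, 90°), U(−90°, 0°) | "two well separated" fiber families; γ₁ R² 0.96 / MAE 4.9° ⟹ σ ≈ 26–31° |
| Δγ | U(5°, 90°) | arcs (not full rings) observed; R² 0.94 ⟹ residual ≈ 6° |
| λ₁/λ₂ | log-U(0.1, 10) | MAE 0.45 with R² 0.94 ⟹ σ ≈ 2.3; ratio and inverse symmetric |

Physically: sections are mounted near-normal to the beam, so fiber-plane
tilts are small; a twisted-plywood stack spans all in-plane angles; Δγ → 180°
would merge arcs into rings and make γ unidentifiable. Disjoint γ ranges make
the canonical ordering γ₁ ≥ γ₂ hold by construction; a shared range with
swap-based ordering remains available (`LabelRanges(gamma2=None)`).

## Corruption

Three seeded steps, in order, emulate experimental artifacts:

1. **Poisson noise** — each curve is scaled to an expected peak count drawn
   log-uniformly from [200, 20 000], Poisson-sampled per bin, and rescaled
   (additive-Gaussian and mixed variants of matching variance are available
   via ``CorruptionConfig(noise=...)``).
2. **Circular blockwise masking** — contiguous blocks (uniform length 5–60
   bins, wrap-around allowed) are invalidated until exactly
   round(0.3 · n_bins) = 108 bins are masked (the final block is truncated so
   the ratio is exact); masked bins carry intensity 0 and a False mask flag.
3. **Random scaling** — the maximum is set to a uniform draw from
   [0.95, 1.05] instead of exact normalization.

Regressors consume the concatenation [intensity; mask] (720 features), so
true zeros stay distinguishable from missing signal. During FCNN training the
corruption is **re-drawn every epoch** from the stored clean curves (a bank
of 4096 pre-generated masks plus fresh Poisson/scale draws): freezing a
single corruption realization measurably overfits mask placements at desk
scale, while per-epoch re-masking mirrors masked-image-modeling practice.
Validation and test curves keep a fixed, stored corruption.

## Label codec

Angles are doubled and mapped to (cos 2θ, sin 2θ) on the unit circle, so
θ = ±90° encode identically and predictions are continuous across the wrap.
Decoding halves the two-argument arctangent; tilt and mean angles use the
(−90°, 90°] branch, the spreads Δγ use [0°, 180°) (Δγ is encoded with the
same doubling for architectural uniformity, accepting the 0 ≡ 180
identification). The quantity ratio is regressed as ln(λ₁/λ₂) and
exponentiated at decode. Group order is canonicalized to γ₁ ≥ γ₂ (ties broken
by larger Δγ, then larger β), and decoding re-canonicalizes, which near the
±90° wrap may exchange the group slots of an equivalent configuration.

## Regressors

`FCNNRegressor` is a ReLU multilayer perceptron (default hidden sizes
512-256-128, float32) trained with Adam (lr 3 × 10⁻³ in the study-scale runs,
batch 128) on the mean absolute error of the 17 encoded targets, with early
stopping on validation MAE and learning-rate halving on plateau. Targets are
z-scored internally and un-scaled at prediction: the tilt coordinates span
tiny intervals (cos 2β ∈ [0.94, 1] for β ∈ ±10°) and would otherwise receive
a vanishing share of the MAE gradient. The implementation is a compact numpy
network with exact backpropagation, which also provides the exact input
gradients that saliency analysis needs. `BaselineRegressor` wraps
scikit-learn KNN / random-forest / SVR multi-output regressors on the same
flattened features; hyperparameters come from a documented validation-set
grid (KNN k ∈ {1, 3, 5, 10, 20}, etc.).

## Evaluation

The headline metric is reconstruction RMSE: predicted parameters are pushed
back through the forward model and compared with the observed curve on
mutually valid bins, both unit-max normalized — applicable identically when
no ground truth exists (phase II). Peak agreement is the pooled Pearson
correlation of matched peak locations and intensities (peaks: circular local
maxima with prominence ≥ 0.05, at most four, masked-adjacent peaks dropped;
matching: greedy nearest within 15°, wrap-aware unwrapping of matched pairs).
Label metrics are per-parameter R² and MAE with circular (period-180)
residuals for angles. The five-repetition protocol re-splits the data and
re-initializes the network each time and reports mean (SD). A synthetic
phase-II stand-in re-masks held-out clean curves with block lengths from a
disjoint range (70–120 bins), emulating unseen gap layouts.

Desk scale here means 20 000 labels (the full-scale protocol uses 100 000), up to
60 training epochs, and five repetitions, sized so the whole protocol runs in
about a quarter hour on one CPU core. At that scale the package reproduces the full-scale
peak-location Pearson (≈ 0.998) and γ recovery (R² ≈ 0.93–0.95, MAE ≈ 3°),
while reconstruction RMSE converges to ≈ 0.07 (full-scale reference 0.0265)
and λ MAE to ≈ 0.6.

## What the generator does not emulate

Simulated curves share the real data's peak multiplicity, counting noise and
gap structure, but not: non-Gaussian intrinsic peak shapes, background from
amorphous scattering and ring overlap, detector geometry distortions, or
deviations of real fiber populations from the two-planar-fan model. Passing
phase-I tests therefore demonstrates correct inversion of the stated forward
model under realistic corruption, not performance on beamline data.

## Known limitations

* **Tilt recovery is information-limited in this geometry.** The Ewald ring
  sits only q_z/Q = 0.135 below the reciprocal equator at 10 keV, so α and β
  perturb the curve at ≈ 0.0026 RMS per degree — an order of magnitude weaker
  than γ. An oracle grid fit of β with every other parameter known leaves a
  residual SD of ≈ 4° on corrupted curves; no regressor can beat that bound.
  The full-scale study reports far better tilt recovery, implying a stronger
  tilt coupling in its (unavailable) model variant; under this
  implementation's geometry the α/β R² values stay near zero and are reported
  as such.
* **Saliency highlights flanks and valleys, not crests.** Because curves are
  unit-max normalized, peak tops are pinned near 1 and carry little
  information; trained networks place gradient mass on arc flanks and
  inter-arc valleys (saliency–curve correlation ≈ −0.7). The
  `peak_concentration` statistic is reported with arc-adaptive windows but
  the package does not assert crest concentration.
* Quadrature at the default 181 fan nodes leaves percent-level discretization
  error near fold points of the fan-to-azimuth map; raise `n_quad` where
  bin-exact curves matter (the Monte-Carlo oracle tests use 721).
* The model covers exactly two fiber groups; the multi-group extension
  (fitting several models and selecting by reconstruction error) is out of
  scope.
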