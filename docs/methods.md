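# Methods

This note records the models behind `wlrs`, the defaults and why they were
chosen, the numerical choices that matter, and what the synthetic-data
generator does and does not emulate.

## Optical model

The transducer is modelled as a stratified medium at normal incidence:
ambient (medium 0), a short ordered list of homogeneous transparent films,
and a semi-infinite silicon substrate. Each interface contributes the
normal-incidence Fresnel amplitude rᵢⱼ = (nᵢ − nⱼ)/(nᵢ + nⱼ); each film of
index n and thickness d contributes a one-pass phase δ = 2π n d/λ. The
effective reflection coefficient is built by backward recursion from the
deepest interface, folding each layer in through its round-trip factor
e^{−2iδ}; the measured quantity is the squared magnitude.

Assumptions and their consequences:

* **Normal incidence only.** The reflection probe delivers and collects
  light vertically; the small angular spread of a fiber probe is ignored.
  Oblique incidence and polarization are out of scope.
* **Real, dispersionless indices by default** (SiO₂/protein 1.46,
  photoresist 1.40, Si 4.00). Real silicon is dispersive and absorbing in
  the visible; treating it as a real constant overstates fringe contrast
  slightly but leaves fringe *positions* — the measured signal — intact.
  Any layer may instead carry a wavelength → index callable (e.g. a Cauchy
  law) when realism matters.
* **Semi-infinite substrate.** Opaque Si has no backside reflection.
* With all-real indices the model satisfies 0 ≤ R ≤ 1 exactly, is invariant
  under inserting zero-thickness or index-matched layers, and obeys the
  scaling R(λ; d) = R(cλ; cd); these are enforced as property tests.

For the two-film stack the package also evaluates the fully expanded
closed form E = A/B, where A and B are the expanded squared magnitudes of
the numerator and denominator of the two-layer amplitude ratio (they share
all cosine cross terms and differ only in constants). Closed form, Abeles
recursion and an independent characteristic-matrix implementation (kept in
the test suite, deliberately a different formulation) agree to below
10⁻¹⁰ over randomized stacks; this three-way agreement is the package's
primary correctness argument for the optics.

## Spectrum processing

Absolute reflectance is R(λ) = (S − D)/(REF − D) pointwise on a shared
grid; a non-positive denominator anywhere raises an error naming the
wavelength, since it means the reference or dark is unusable there.

Extrema are found by a prominence-filtered local peak search, then refined
to sub-grid resolution with a parabola through the extremum and its two
neighbours. The prominence default is 2% of the local amplitude range —
enough to reject noise wiggles at the noise levels studied here while
keeping genuine shallow fringes. A *fringe* is operationalised as one
reflectance **minimum** in the range, because the minimum is the feature
the real-time readout tracks. Note that the number of minima of a single
film in a fixed window is *not* monotone in thickness: a minimum can leave
the red edge before the next enters at the blue edge; the tests therefore
check the count against the analytic condition 2nd = (m + ½)λ rather than
asserting monotonicity.

λ_max tracking restricts the search to a short window (±40 nm by default)
re-centred on the previous frame's extremum, mirroring how drift in the
source spectrum is handled in practice; a frame with zero or multiple
candidate extrema aborts with the timestamp rather than guessing. The
linearised conversion Δd₁ = k·(Δλ/λ)·d₂ uses k = 2.06 for the standard
protein/SiO₂-photoresist/Si stack. The constant is treated as a supplied
calibration value (stored, overridable), not re-derived: its derivation
depends on the phase condition at the tracked extremum and is not uniquely
determined by the three indices alone.

## Spectral fitting

The inversion minimises Σ[R_model(λᵢ; θ) − R_obs(λᵢ)]² over a spectral
window, with θ a named subset of layer thicknesses (optionally one
refractive index). Residuals are defined on plain reflectance — not log or
derivative — to match the normalization output directly.

* **Optimizer**: `scipy.optimize.least_squares` with the `trf` trust-region
  method — the same damped Gauss–Newton family as Levenberg–Marquardt, but
  supporting the box bounds the problem needs (adlayers cannot be
  negative). Cost tolerance 10⁻¹⁰, at most 200 iterations.
* **Bounds**: ±20% of nominal for transducer layers (≥ 50 nm), [0, 50] nm
  for adlayers; estimates pinned at a bound are flagged.
* **Initialization**: the nominal fabrication thickness, or a caller
  override. The interference cost surface is fringed, so a start far from
  truth can land in a side minimum; when a converged fit still leaves a
  residual RMS above 5×10⁻³ (far above the noise levels studied), a coarse
  deterministic scan of the bounded parameter box (25 points per axis, ≤ 2
  free parameters) is evaluated and the best point is refit. This keeps
  self-inversion exact from any start within ±10% of truth while costing
  nothing on warm-started sensorgram frames.
* **Windowing**: both full-range and λ_max-window fits are supported; the
  window mode is what a sensorgram pipeline uses (smaller, faster,
  insensitive to broad-band drifts), while resolution studies default to
  the full 450–800 nm range.
* **Uncertainty**: per-parameter standard errors from the Gauss–Newton
  covariance (JᵀJ)⁻¹ scaled by the residual variance at the optimum.

Detection resolution is defined operationally as 3 × SD of the fitted
thickness over seeded Monte-Carlo replicates at fixed truth. The noise
model everywhere is per-wavelength independent multiplicative Gaussian
noise, standard deviation expressed as a fraction of the signal; any
resolution claim carries its noise level, grid size and replicate count.
At the reference conditions (0.2% noise, 512-point 450–800 nm grid, 5 nm
adlayer on 1000 nm SiO₂/Si, 200 replicates) the study lands near 0.2 Å,
i.e. comfortably sub-Ångström; resolution grows roughly linearly with the
noise fraction and improves with grid density.

## Synthetic experiments

The generator defines the study conditions for every end-to-end test:

* **Binding**: 1:1 Langmuir kinetics with adlayer thickness proportional to
  fractional occupancy — d(t) = d_max·[k_on C/(k_on C + k_off)]·
  (1 − e^{−(k_on C + k_off)t}), optional dissociation phase with C = 0.
  This is the minimal standard model for antibody–antigen and
  biotin–streptavidin sensorgrams; it ignores mass-transport limitation,
  surface heterogeneity and steric crowding, so real sensorgrams will
  deviate at high capture density and fast k_on. Default study conditions
  use k_on = 10⁵ M⁻¹s⁻¹, k_off = 10⁻³ s⁻¹ (K_D = 10 nM) and d_max = 5 nm —
  typical IgG-scale values.
* **Swelling**: vapour sorption into a polymer film as a first-order
  relaxation to baseline·(1 + equilibrium_swelling) with symmetric
  desorption. Real sorption can be non-Fickian and history-dependent; the
  single-τ form is a deliberate stand-in sufficient to exercise the
  readout chain.
* **Two-site / enhancement steps** are modelled as multiplicative gains on
  d_max per added reagent layer (default 4.0 for a secondary-antibody
  step).
* **Scanning**: spotted reagent bands are top-hats at the configured
  width/pitch, the probe spot is a Gaussian of configurable FWHM (default
  0.4 mm), and the profile is their analytic convolution (difference of
  error functions) sampled at the stage step, with multiplicative noise.
  Band extraction averages the central half of each band; resolution is
  judged by the plateau-to-gap modulation contrast, with an overlap flag
  below 10% contrast. The reference layout (seven 0.5 mm bands at 1.0 mm
  pitch, 0.25 mm step, 1% noise) yields between-band CVs under 5%.
* **Calibration**: responses (endpoint thickness or initial rate) vs
  concentration are fitted with a four-parameter logistic
  y = d + (a − d)/(1 + (x/c)^b); the direction (increasing for
  direct/two-site, decreasing for competitive) is checked and flagged
  rather than forced. The limit of detection is the concentration whose
  predicted response departs from the blank mean by 3 blank SDs (the SD
  multiplier is configurable, since 2 SD conventions exist); a zero blank
  SD gives a flagged degenerate LOD, and an LOD beyond the top calibrator
  is clipped and flagged as a bound. For a Langmuir endpoint assay run to
  equilibrium the 4PL midpoint c coincides with K_D, which the round-trip
  test (generator → noisy spectra → fits → calibration) exploits: it
  requires c within 10% of the generator's K_D.

What passing these tests shows — and does not. They demonstrate that the
analysis chain is self-consistent and numerically correct under the stated
noise model; they do not certify performance on real instruments, where
wavelength-correlated source drift, temperature, non-specific binding and
matrix effects dominate the error budget.

## Numerical and interface choices

* Quadratic (3-point) extremum refinement rather than wider stencils:
  error is already below 0.01 nm on the grids used.
* Forward model vectorised over wavelength; fits on a 512-point grid take
  milliseconds, so a 200-replicate resolution study runs in about a
  second.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); file outputs carry the seed and a config
  hash in header comments. Headers deliberately contain no timestamp so
  identical config + seed gives byte-identical files.
* On-disk formats are plain delimited text with `repr`-precision floats and
  round-trip parsing, so write → read is lossless.
* Problem sizes in the test suite (grids of 64–512 points, ≤ 200 Monte-
  Carlo replicates, short sensorgrams) were chosen as the smallest sizes at
  which the statistical claims are stable across seeds.

## Known limitations

* No absorbing (complex-index) films, roughness/EMA layers, oblique
  incidence or polarization; no backside reflection.
* No mass-transport or heterogeneity corrections in the kinetics; K_D
  recovery from transport-limited data would be biased.
* The 2.06 shift-conversion constant is specific to the stated stack and
  tracked extremum; applying it to other stacks requires recalibration.
* The fitter's coarse-scan rescue covers at most two free parameters;
  higher-dimensional fits rely on a good initialization.
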