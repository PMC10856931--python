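# Methods

## Dose model

The package implements the TG43-U1 factorisation for sealed cylindrical
sources. Conventions and numerical choices:

* Polar angle θ is measured from the source long axis; bench coordinates
  (sensor at lateral distance y, source moved along z) convert via
  r = √(y² + Δz²), θ = atan2(y, −Δz), so a source displaced to larger z than
  the sensor maps to θ > π/2. Only the symmetry about the transverse plane
  matters physically; the signed mapping is fixed and documented so that
  simulated and analysed data agree.
* The subtended angle β is computed from the explicit endpoint vectors of the
  active segment with `atan2(cross, dot)`, which is stable at all angles; on
  the transverse plane it reduces to 2·atan(L/2r). The on-axis branch
  G = (r² − L²/4)⁻¹ is taken when sin θ < 10⁻⁹ to avoid dividing by a
  vanishing sine. L = 0 selects 1/r² exactly.
* The radial dose function is implemented as a single exponential multiplying
  the polynomial, g(r) = (Σₙ aₙ rⁿ)·e^(−aₑ r), n = −2…3. A per-term
  exponential parameterisation would only coincide for a shared decay
  constant; the single-factor form is the standard heuristic for fitted
  radial dose data and is the one implemented.
* Anisotropy tables are bilinearly interpolated on (r, θ in degrees).
  Queries outside the tabulated hull are clamped to the nearest edge with a
  warning — published tables rarely extend below r ≈ 0.25 cm, while phantom
  scans can. By convention F(·, 90°) = 1 and g(r₀) = 1; violations warn but
  are used as given, never silently renormalised.
* Units: distances cm, rates Hz internally and kHz at I/O boundaries, times
  s, angles radians (table columns in degrees).

## Counting model and simulator

The synthetic-data generator defines the study conditions for every test:

* Photon and dark pulses are independent Poisson processes. Gross windows
  see signal + dark; each point carries an independently sampled paired dark
  run, and the analysis subtracts per point: PCR = (N_gross − N_dark)/Δt,
  σ = √(N_gross + N_dark)/Δt. Negative PCR values (downward dark
  fluctuations) are retained and flagged, not clipped — clipping would bias
  the zero-signal intercept the linearity check relies on.
* Discriminator threshold: at 0.5 p.e. every primary avalanche counts; at
  1.5 p.e. an avalanche counts only if it fires at least one cross-talk
  neighbour, which by the datasheet definition of the optical cross-talk
  probability is Bernoulli thinning by p_OCT. Higher-multiplicity cross-talk
  chains are deliberately out of scope: they change the multiplicity
  distribution, not the 1.5 p.e. counting mean.
* Dead time acts on the mean registered rate: paralyzable R·e^(−Rτ) by
  default, non-paralyzable R/(1+Rτ) for comparison, with τ = 35 ns (the
  shaped discriminator pulse width). Paralyzable is the default because the
  loss mechanism is the overlap of analog pulses of comparable duration —
  an arrival during an ongoing pulse extends the occupancy — rather than a
  fixed per-event insensitive window. The event-by-event arrival-time
  simulation used as the test oracle confirms both closed forms. The
  pile-up probability 1 − e^(−Rτ) is 13% at 4 MHz, which is why linearity
  ranges top out in the few-MHz region regardless of the detector.
* One seeded generator drives each simulation run; the seed is recorded in
  every output container and file, and fixed seeds reproduce bit-identical
  counts.

Study-condition defaults, chosen once from the physics of the emulated
campaigns:

| parameter | default | rationale |
|---|---|---|
| lab scan window | 1 ms/point | scope-gated rate metering; the per-point Poisson error (~1–3% of rate) matches the scatter visible in measured response curves. With 0.1 s windows the relative errors would be ~10⁻³ and a 35 ns dead time would make even the lowest currents of the grid measurably nonlinear, leaving no linear range at all. |
| current grid | 0.05→0.3 mA step 0.05, then step 0.1 to 1.0 (13 points) | the laboratory protocol |
| HDR campaign | 1.5 p.e., 0.1 s windows, y ∈ {0.5,1,2,3,5} cm, z steps 2.5 mm (5 mm for \|z\|>2 cm at y≥1 cm) | the phantom protocol; 1.5 p.e. keeps near-source rates inside the linear range |
| LDR campaign | 0.5 p.e., 0.5 s windows, r = 5–20 mm step 1 mm | seed rates are far below pile-up; the longer window lowers the MDR |
| HDR conversion | 2.8 MHz per dose unit (0.5 p.e., at 2 cm) | puts near-source rates above 10 MHz and the 10 cm extrapolation at ~26 kHz after cross-talk thinning — the operating regime of an afterloader campaign |
| LDR conversion | 3 kHz per dose unit | places the MDR crossing and the 5%-precision distance in the few-cm range characteristic of a single seed |
| synthetic sources | Ir-192-like line source (L = 0.36 cm, aₑ = 0.012 /cm, g(10 cm) ≈ 0.91); I-125-like point source (aₑ = 0.25 /cm, g falls to ~0.47 of its 2 cm value by 5 cm) | match the slopes of published radial dose data for the two isotope classes; both normalised to g(2 cm) = 1 |
| synthetic anisotropy | F = 1 − 0.3·e^(−r/10)·cos²θ | unity on the transverse plane, ~30% axial shadowing near the capsule, relaxing with distance — the qualitative shape of published look-up tables. The real tables are source-model specific and are configuration, not constants. |

What the generator does **not** emulate: pulse waveforms and shaping
electronics, the Cherenkov spectrum of the stem effect (only an optional
z-asymmetric rate contamination term, off by default, for exercising the
exclusion filter), scintillator afterglow dynamics (only as the per-point
dark-run pairing that the subtraction logic needs), temperature dependence
of the dark rate, and real source tables. Passing tests therefore validate
the statistical machinery and the geometry/units chain, not the detector
physics of a specific instrument.

## Laboratory figures of merit

* MDR = 3√(DCR/Δt), evaluated for the 0.1 s (HDR) and 0.5 s (LDR) windows
  from the mean dark rate measured in the scan's own dark runs; the
  datasheet-DCR prediction is reported alongside when available. The 1/√Δt
  scaling ties the two windows together.
* Linearity: weighted least squares of PCR on current with 1/σ² weights,
  intercept retained (its compatibility with zero validates the per-point
  subtraction). Points enter in order of increasing current; the retained
  fit is the **largest** prefix with reduced χ² ≤ 2.7 at n − 2 degrees of
  freedom. Scanning all prefixes rather than stopping at the first failure
  keeps a single noisy 1-d.o.f. short prefix (which fails ~10% of the time
  for perfectly linear data — exactly the 90% CL of the gate) from
  truncating an otherwise linear range. No interior-point outlier removal.
* Sensitivity is the fitted slope; the smallest resolvable current step is
  3σ/m in the linear regime.

## Pre-clinical analysis

* Calibration selects the measurement nearest (r₀, θ₀) within ±0.05 cm and
  ±2°, using an arc-length metric (Δr, r₀Δθ) so radial and angular misses
  are commensurate; exact ties are ambiguous and raise.
* Symmetrisation maps each point to the transverse plane:
  PCR_sym(r) = PCR(r, θ)·[G(r, θ₀)/G(r, θ)]/F(r, θ). The geometry-factor
  ratio moves the line-source solid angle to θ₀ and the anisotropy factor
  divides out capsule shadowing; the construction is the identity at θ₀ with
  F ≡ 1. Stem-affected bench rows are excluded by a lateral-distance cut
  (default y ≥ 2 cm) rather than corrected.
* The radial profile is fitted by weighted nonlinear least squares
  (trust-region reflective) with d bounded ≥ 0 so the profile decays.
  Initialisation: a from the innermost points assuming 1/r² (duplicate radii
  from symmetrised ±z pairs are averaged), b = c = 0, d from the log-slope
  of the outermost distinct pair after removing the 1/r² part. The four
  parameters are strongly correlated; individual errors can be large while
  predictions stay tight, which is why all derived figures propagate the
  full covariance (first-order delta method with numerical gradients) rather
  than per-parameter errors.
* SP and ΔR convert the fitted rate to counts in the mode's window
  (N = h·Δt, dark N = DCR·Δt); σ_PCR in ΔR is the single-window Poisson rate
  uncertainty including dark counts, the same count model as SP. The MDR
  crossing is found by bracketing + Brent on h(r) = MDR; since the crossing
  typically lies beyond the measured range, the compliance search extends
  the domain to twice the target distance and reports "beyond domain" when
  the profile stays above the MDR throughout. When simulated points average
  repeated windows, the quoted error is the spread (sample standard
  deviation) of the repeats, the convention used for measured error bars.

## Known limitations

* ΔR = 3σ_PCR/|h′| is a first-order formula. Its leading error for an
  inverse-square profile is (3/2)·ΔR/r, and for steep exponential profiles
  the controlling scale is the attenuation length 1/d instead; the
  displacement-oracle test validates it in the inverse-square-dominated
  regime (ΔR/r < 0.03, d ≤ 0.15 /cm), which is where it is used.
* Profile extrapolation beyond the measured range (10 cm HDR target from
  ≤ 7 cm data) inherits the model form; the quoted uncertainty covers the
  parameter covariance, not model misspecification.
* The analysis assumes the dead-time distortion is negligible over the
  fitted range; under the full study conditions this holds for the
  stem-free HDR subset (≲ 3% at 2 cm, absorbed by the fit) and everywhere
  for LDR. Energy-correction curves produced with the default dead time show
  the corresponding near-source suppression by construction.
* Problem sizes in the test suite (4000 windows for moment checks, 200
  seeded scans for slope coverage, 10 seeds × two campaign grids for profile
  recovery, 0.02 s event-by-event dead-time runs) were chosen to keep
  statistical false-failure probabilities per test far below 10⁻³ while the
  whole suite runs in seconds.
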