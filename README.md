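# fibredose

Analysis pipeline for **scintillating-fibre brachytherapy dosimeters read out
by silicon photomultipliers (SiPMs) in photon-counting mode**. It is aimed at
medical-physics groups prototyping in-vivo dose monitors for high-dose-rate
(HDR, e.g. ¹⁹²Ir afterloader) and low-dose-rate (LDR, e.g. ¹²⁵I seed)
brachytherapy, who need to (i) select and characterise a counting detector in
the laboratory and (ii) assess a probe against clinical design specifications
using phantom scans around a real source.

## What it computes

**Dose model.** The expected dose rate around a sealed cylindrical source
follows the AAPM TG43-U1 factorisation

```
D(r, θ) = s_k Λ · F(r, θ) · G(r, θ)/G(r₀, θ₀) · g(r)
```

with air-kerma strength `s_k`, dose-rate constant `Λ`, line-source geometry
factor `G(r, θ) = β/(L r sinθ)` (β the angle subtended by the source at the
measurement point; `1/r²` in the point-source limit), radial dose function
`g(r) = (Σₙ aₙ rⁿ)·e^(−aₑ r)` for n = −2…3, and a tabulated 2-D anisotropy
factor `F(r, θ)`. The reference point is (r₀, θ₀) = (2 cm, π/2).

**Laboratory figures of merit**, from X-ray-tube current scans with paired
dark runs:

* minimum detectable rate `MDR = 3·√(DCR/Δt)` — three Poisson standard
  deviations of the dark counts in the counting window Δt;
* linearity range — the largest low-current prefix of the scan whose weighted
  straight-line fit PCR = m·I keeps reduced χ² ≤ 2.7 (≈ 90% CL at one
  residual degree of freedom); pile-up of the ~35 ns discriminator pulses
  bends the response at a few MHz and trips the gate;
* sensitivity — the slope m of the linear regime. Counting at a 1.5 p.e.
  threshold thins the rate by the optical cross-talk probability p_OCT,
  trading sensitivity for an extended linear range at high dose rates.

**Pre-clinical performance**, from phantom scans: calibration at the
reference geometry, energy-correction curves (data/model ratio vs distance),
angular symmetrisation onto the transverse plane, a weighted fit of the
radial profile

```
h(r) = (a/r² + b/r + c) · e^(−d·r)
```

and from it the statistical precision `SP = √(N_PCR + N_DCR)/N_PCR`, the
spatial resolution `ΔR = 3σ_PCR/|h′(r)|`, the distance at which the signal
falls to the MDR, and a pass/fail report against the per-mode design targets
(HDR: sensing to 10 cm, 1 mm resolution at 5 cm, 5% precision in 0.1 s at
10 cm; LDR: 3 cm / 3 mm at 3 cm / 5% in 0.5 s at 3 cm).

A counting-statistics simulator (Poisson photon and dark counts, Bernoulli
cross-talk thinning, paralyzable or non-paralyzable dead time, TG43-driven
spatial profiles) generates every input format, so the whole chain runs and
is tested without instrument data.

## Worked example

Simulate an HDR phantom campaign (source stepped along z at lateral sensor
distances y = 0.5–5 cm, 1.5 p.e. threshold, 0.1 s windows) and analyse it:

```bash
fibredose simulate --mode hdr --detector PM1125 --threshold 1.5 \
    --seed 3 --out hdr.csv --source-out hdr_source.yaml
fibredose analyze-hdr --scan hdr.csv --source hdr_source.yaml --out report.json
```

The report contains (seed 3):

```
k = 714.1                      # kHz per model dose unit at the 2 cm reference
EC slope = 0.084 /cm           # energy-correction trend; non-zero here because
                               # pile-up suppresses counts near the source
h-fit: a=2819, b=199, c=0.00, d=0.062, reduced chi2 = 0.98
PCR(10 cm) = 25.99 ± 1.24 kHz  # extrapolated signal at the HDR target distance
SP(10 cm; 0.1 s) = 2.94 ± 0.08 %   (target < 5%  -> pass)
ΔR(5 cm; 0.1 s) = 0.786 ± 0.016 mm (target < 1 mm -> pass)
all_pass = true
```

i.e. the simulated probe resolves the source at 10 cm with ~3% single-window
precision and sub-millimetre positional sensitivity at 5 cm, comfortably
inside the HDR design targets. The same flow with `--mode ldr` /
`analyze-ldr` runs the point-source analysis, where the dark-count floor
limits the usable range to a few cm.

The library mirrors the CLI: `LinearityModel(...).fit()` and
`RadialProfileModel(...).fit()` return results objects carrying estimates,
covariances and `summary()` tables, with the derived figures as methods.

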