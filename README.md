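# oecp — sensing-volume analysis for open-ended coaxial dielectric probes

Open-ended coaxial probes (OECPs) measure the dielectric properties of
biological tissue from the complex reflection coefficient at the probe
aperture.  The method assumes the sample is homogeneous within the probe's
*sensing volume* — the small region, described by a sensing **depth** (axial)
and a sensing **radius** (lateral), that actually contributes to the
measurement.  When the sensing volume straddles a tissue boundary (fat vs.
tumor, fat vs. muscle), the reading is a biased mixture, which is a major
error source in breast-tissue dielectric spectroscopy.  Quantifying the
sensing volume of small-aperture probes (2.20 mm and 3.58 mm diameter) is
therefore a prerequisite for choosing the right probe for heterogeneous
samples.

This package implements that analysis as a reproducible pipeline, with a
synthetic bilayer generator standing in for the physical sliding-rail /
micrometer displacement apparatus:

- **Dielectric models** — single-pole Debye materials,
  `ε(ω) = ε∞ + (εs − ε∞)/(1 + jωτ)`, plus static conductivity; complex
  permittivity convention `ε* = ε′ − jσ/(ωε₀)`.  A versioned library covers
  Teflon, ethanol, methanol, deionized water and two tissue-mimicking
  phantom solutions (DMSO, sugar–salt).
- **Three-standard calibration** — the bilinear probe model
  `ε* = (A₁ρ − A₂)/(A₃ − ρ)`, with per-frequency coefficients solved in
  closed form from short (`ρ₁ = A₃`), open (`ρ₂ = (A₂+A₃)/(A₁+1)`) and
  reference-liquid standards, and its exact Möbius inversion.
- **Bilayer synthesis** — displacement sweeps across a Teflon/liquid
  interface with a monotone exponential permittivity transition
  `ε_eff(d) = ε₂′ + (ε₁′ − ε₂′)e^{−d/λ}`, calibrated so the 90% crossing
  sits exactly at a configurable ground-truth distance; 0.05 mm steps,
  VNA-style complex Gaussian noise on ρ, 5 replicates, aperture scaling
  between probe geometries.
- **Threshold extraction** — the sensing distance is the displacement at
  which the measured ε′ reaches 90% of the liquid's value, with an 87–93%
  tolerance band and bracket averaging when the band is jumped.
- **Statistics** — one-way ANOVA of extracted distances across the seven
  measurement frequencies (300–1500 MHz in 200 MHz steps) and ordinary
  least squares of sensing radius on sensing depth.

## Worked example

`examples/sensing_distance.py` builds a noise-free Teflon/deionized-water
vertical sweep whose true 90% crossing is 0.62 mm (the measured sensing
depth of the 2.20 mm probe for water) and applies the threshold rule:

```
displacement (mm) -> eps' (% of tissue 2)
   0.00     2.10  (  2.6%)
   0.05    15.19  ( 18.9%)
   ...
   0.60    71.55  ( 89.2%)
   0.65    73.00  ( 91.0%)

ground truth 90% crossing : 0.620 mm
extracted sensing depth   : 0.600 mm (in_band)
```

The probe starts on Teflon (ε′ = 2.1) and the effective permittivity rises
toward water (ε′ ≈ 80.2); the first part of the sweep changes rapidly and
the tail slowly, as on the bench.  The recorded micrometer position nearest
the 90% target is 0.60 mm — within half a 0.05 mm step of the true
crossing, which is the best any grid-recording rule can do without
interpolation.

Other examples: `material_spectra.py` (library spectra over the band),
`calibrate_and_invert.py` (noisy calibration, inversion error of a methanol
load), `full_pipeline.py` (the complete study with replicate summaries,
ANOVA table and radius-vs-depth fits).  A thin CLI wraps the same
functions: `oecp simulate | calibrate | extract | stats | run | ingest`.

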