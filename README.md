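# lamdiff

Analysis pipeline and forward simulator for lamellar neutron diffraction
from oriented lipid multilayers (archaeal diether/tetraether membranes and
their mixtures).

The analysis chain turns reduced diffraction data into membrane structural
parameters:

1. **reduction** — rocking-scan (Ω × 2θ) maps are integrated into 1D
   diffractograms; Bragg peaks are detected and fitted as Gaussians on a
   shared linear background, giving integrated intensities with
   counting-statistics uncertainties.
2. **lamellar** — peak positions become scattering vectors
   q_z = 4π·sin θ/λ; the repeat distance follows from a weighted linear fit
   of q vs diffraction order (d = 2π/slope, with σ_d propagated from the
   slope), or d = 2π/q₁ when only one order is available.
3. **nsld** — integrated intensities are corrected for absorption
   (C_abs = α/(1−e^−α), α = 2µt/sin θ), the Lorentz factor
   (C_Lor = sin 2θ) and the beam-footprint flux factor
   (C_flux = 1/erf(L·sin θ/(√8·δ))), giving |F_h| = √(I_h·C_abs·C_Lor·C_flux).
   The centrosymmetric sign ambiguity is resolved by enumerating all 2ⁿ
   hypotheses and keeping those with a density minimum at the midplane and
   maxima in the polar-head region; ρ(z) = (2/d)·Σ V_h|F_h|cos(2πhz/d).
   Reconstruction is refused below 3 orders.
4. **profile_metrics** — Gibbs–Luzzati bilayer thickness d_b
   (head-peak-to-head-peak, parabolic sub-grid refinement), water layer
   d_w = d − d_b, midplane trough depth, hydrocarbon hump, and a
   constrained mirrored-Gaussian decomposition into headgroup/CH2/CH3/water
   contributions (water via 100%/8% D₂O contrast difference).
5. **forward_sim** — parametric ground-truth profiles for four sample
   archetypes (diether `D`, tetraether `T`, mixtures `DT11`/`DT21`) with a
   packaged table of per-condition periods and thicknesses; renders noisy
   1D diffractograms and 2D Ω-maps by exactly inverting the analysis-side
   corrections, so the whole chain is verifiable by parameter recovery.
6. **cli_io** — TSV + JSON-sidecar formats, YAML run configuration, and the
   `lamdiff` command-line tool.

## CLI

```sh
lamdiff --seed 0 simulate --preset DT11 --rh 95 --temp 70 --out dt11.tsv --map
lamdiff reduce --in dt11_map.tsv --out reduced.tsv
lamdiff dspacing --in dt11.tsv
lamdiff nsld --in dt11.tsv --out profile.tsv
lamdiff metrics --in profile.tsv
lamdiff report --inputs dt11.tsv --inputs other.tsv --out metrics.json
```

Angles are degrees on disk (radians internally), lengths in Å, q in Å⁻¹.
Every data file carries a `<name>.meta.json` sidecar with provenance
(instrument, condition, seed). Identical config + seed produce
byte-identical outputs.

## Conventions and caveats

- NSLD amplitudes are arbitrary units; no absolute scale (10⁻⁶ Å⁻²) is
  assigned. All reported metrics are invariant under amplitude rescaling.
- The flux-correction denominator is configurable
  (`flux_denominator: sqrt8 | eight`, default `sqrt8`).
- Preset profile shapes are qualitative emulations constrained by the
  published per-condition periods, thicknesses and profile features;
  intermediate conditions are interpolated linearly (a fixture convention).
- Raw instrument files (NeXus) and detector-efficiency calibration are out
  of scope; inputs are assumed reduced and calibrated.
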