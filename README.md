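# colpoqc

Quality-assurance battery for digital colposcopes: image-quality,
illumination and photobiological-safety metrics, exercised end-to-end on
synthetically generated test-target images and spectra.

Metrics implemented:

- **Geometry** — USAF-1951 group/element ↔ resolving power conversion,
  checkerboard corner detection with sub-pixel refinement, SMIA TV radial
  distortion (barrel/pincushion %), diagonal field of view, magnification.
- **Color** — sRGB ↔ CIELAB (D50 Bradford-adapted or D65), ΔE\*ab / ΔC\*ab
  reproduction error against a calibrated patch chart, and a Lab
  mean/variance statistics-transfer color match.
- **Illumination** — spectral peak ± FWHM from emission spectra; FWHM beam
  diameter (equivalent-area diameter of the ≥50 %-luminance region) with
  grid-based physical-scale calibration.
- **Safety** — ANSI/IESNA RP-27-style blue-light (L_B) and retinal-thermal
  (L_R) weighted radiances with bundled B(λ)/R(λ) tables, angular-subtense
  clamping to [0.011, 0.11] rad, and exempt-group verdicts.
- **Specular** — hot-pixel fraction (Rec.601 luma > 250) and the maximum
  illumination power satisfying a specular threshold, with simulated power
  sweeps.
- **Synthetic targets** — seeded, deterministic generators for distorted
  checkerboards (with ground-truth corners), USAF bar patterns, color
  charts, beam/diffuser images, LED/halogen/filtered spectra and
  cervix-like scenes with exact injected specular fractions.

## CLI

Every metric is exposed under a single `colpoqc` entry point:

```sh
colpoqc gen checkerboard --k1 -0.05 board.png     # + JSON ground-truth sidecar
colpoqc distortion board.png --rows 27 --cols 34 --square-mm 2
colpoqc fov board.png --rows 27 --cols 34
colpoqc gen spectrum --kind led --center-nm 530 --fwhm-nm 30 green.csv
colpoqc spectrum green.csv
colpoqc beam beam.png --grid grid.png --pitch-mm 10
colpoqc hazard spectrum.csv --beam-mm 40 --distance-mm 40 --scale 1e-6
colpoqc specular scene.png --threshold 0.5
colpoqc sweep --seed 3 sweep.csv
colpoqc characterize --config devices.toml --out report/
```

`characterize` runs the full battery for every `[device.<name>]` section of
a TOML config and writes `report.json` plus a Markdown comparison table
with one row per device.

## Notes

- All processing is 8-bit RGB; deeper sources are down-converted at read
  time. Pixel coordinates are 0-based, row-major, origin top-left.
- The bundled color-chart Lab reference (`colpoqc.synthetic.DEFAULT_CHART_LAB`)
  is a plausible, **non-certified** default; supply the vendor's certified
  CSV (`patch_id,L,a,b`) for real chart work.
- Hazard weightings are bundled at 5-nm resolution
  (`src/colpoqc/data/*.csv`) following the published ACGIH/ICNIRP lamp
  photobiological hazard functions; linear interpolation between nodes,
  zero outside support.
- Absolute radiometric calibration is never guessed: hazard computations
  require an explicit scale factor to W·cm⁻²·nm⁻¹·sr⁻¹
  (`EmissionSpectrum.scaled(factor, absolute=True)`).
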