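# picowash

Quantification toolkit for on-chip droplet washing in droplet
microfluidics. A "washer" is a unit operation that simultaneously
injects wash fluid into and removes fluid from water-in-oil droplets
moving past it as confined plugs; `picowash` provides the image-analysis
and design tooling needed to characterise such a device:

- **`scenesim`** — seeded synthetic droplet-channel imagery (short-exposure
  frames at random plug-train phases, analytic long-exposure streaks,
  calibration series of stationary droplets at known dye fractions) with
  imposed ground truth, so every downstream stage is testable without a
  microscope.
- **`gating`** — retrospective gating: localize a reference droplet in each
  randomly-phased frame (intensity-threshold centroid, or exhaustive
  sum-square-difference template matching) and reorder the frames by
  position to reconstruct the sub-millisecond washing event.
- **`calibmap`** — per-pixel linear calibration from gray value to
  z-averaged dye fraction (linearised Beer–Lambert), dilution maps, and
  heatmap-integrated dilution factors.
- **`washquant`** — long-exposure streak quantification: normalized
  intensity profiles, plug geometry statistics, single and serial
  dilution factors, bead retention.
- **`fluidics`** — exact rectangular-duct hydraulic resistance, electrolyte
  channel resistance, and the resistor-network design rule for operating
  several washers in series.

Intended users: microfluidics labs quantifying washing efficiency from
transmitted-light or fluorescence imagery, and device designers checking
serial-washer layouts.

## The model in brief

Long-exposure imaging averages moving dye-laden plugs into a streak with
per-column intensity `I ∝ p_droplet · C_dye`, where the duty fraction is
`p_droplet = L_drop / (L_drop + L_space)`. From three aligned exposures
(device operating, device idle, dropletless background) the normalized
profile is

```
I(x) = (I_wash(x) − I_back(x)) / (I_cntl(x) − I_back(x))
```

and the dilution factor `DF = C_pre / C_post` follows from segment
averages of `I(x)` flanking the washer, corrected for plug-geometry
changes:

```
DF = [⟨I_pre⟩ · L_drop,post/(L_drop,post + L_space,post)]
   / [⟨I_post⟩ · L_drop,pre/(L_drop,pre + L_space,pre)]
```

Retrospective gating localizes a reference droplet in frame after frame
by minimising `E(x) = Σ_k (g_k(x) − G_ref,k)²` between a reference patch
`G_ref` and the subimage whose leftmost column is `x`, then sorts frames
by `x`. Pixel-wise calibration fits `fraction = a·gray + b` per pixel
from frame-averaged reference images at known dye dilutions; integrating
a calibrated map gives `DF = 1 / mean(fraction)`. For `N` washers in
series, uniform simultaneous operation requires
`N (R_H + R_L) / R_wash < 0.01` for both the hydraulic and electrical
resistances of the connecting (R_H, wash; R_L, waste) and internal
(R_wash) channels.

## Worked example

```python
import picowash as pw

scene = pw.build_scene(
    {"washers": [{"position_um": 300.0, "stage_dilution": 4.0}]}, seed=1
)
tt = pw.transit_time(scene)
print(f"washing timescale: {tt.duration_ms:.3f} ms ({tt.duration_display}), "
      f"min AC frequency: {tt.min_field_frequency_khz:.2f} kHz ({tt.frequency_display})")

roi = pw.Roi(0, 50, 0, 600)
profile = pw.normalize_profile(
    pw.column_profile(pw.render_long_exposure(scene, "wash"), roi),
    pw.column_profile(pw.render_long_exposure(scene, "control"), roi),
    pw.column_profile(pw.render_long_exposure(scene, "background"), roi),
)
geom = pw.PlugGeometry(L_drop=85.0, L_space=85.0)
result = pw.serial_dilution(profile, [(285.0, 315.0)], geom)
print(f"segment means <I_pre>, <I_post>: "
      f"{result.segment_means[0]:.3f}, {result.segment_means[1]:.3f}")
print(f"recovered dilution factor: {result.overall_df:.3f}  (ground truth 4)")
```

prints

```
washing timescale: 0.459 ms (~0.5 ms), min AC frequency: 2.18 kHz (2 kHz)
segment means <I_pre>, <I_post>: 1.000, 0.250
recovered dilution factor: 4.000  (ground truth 4)
```

The 85 μm plug advancing at `v = Q/A` (2 mL/h through a 50 × 60 μm
cross-section) takes ~0.5 ms to travel its own length — the washing
timescale, whose reciprocal sets the ~2 kHz minimum frequency for the
coalescence-triggering AC field. The normalized streak drops from 1.0
upstream to 0.25 downstream of a fold-4 washer, and the estimator
returns the imposed dilution factor exactly in the noiseless limit.

The same stages are available from the shell:

```bash
picowash simulate --mode long --seed 1 --out sim/
picowash quantify --wash sim/long_wash.tif --control sim/long_control.tif \
    --background sim/long_background.tif --roi 0:50,0:600 \
    --washers 285:315 --out quant/
picowash designcheck --device device.yaml --out report.json
```

Every stage writes a `provenance.json` (configuration, seed, software
version, input checksums) beside its outputs.

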