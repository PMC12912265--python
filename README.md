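# yolkflow

Quantification of yolk-cell cortical dynamics during zebrafish epiboly.

During epiboly the blastoderm spreads over the yolk cell, pulled by a
contractile actomyosin band in the external yolk syncytial layer (e-YSL).
Characterizing that machinery from live microscopy requires several
independent measurements, and `yolkflow` implements the complete
quantification pipeline as a tested, reusable library:

- **Cortical actin flow** by particle image velocimetry (PIV): windowed
  mean-subtracted normalized cross-correlation between consecutive frames,
  sub-pixel Gaussian peak refinement, spurious-vector filtering by
  peak-to-second-peak signal-to-noise ratio and a physical speed cap,
  and directional statistics (quadrant fractions, rose histograms,
  one-tailed χ² against reference proportions).
- **FRAP kinetics**: bleach-depth normalization
  N(t) = (F(t) − F_bleach)/(F_pre − F_bleach) and a single-exponential fit
  N(t) = m·(1 − e^(−t/τ)), reporting the half-time τ·ln 2 and mobile
  fraction m.
- **Laser-ablation recoil**: gap width w(t) from intensity profiles with
  sub-pixel threshold crossings; the initial recoil velocity (a cortical
  tension proxy) as the early-window least-squares slope dw/dt.
- **Fluorescence accumulation**: ROI intensity series with first-frame or
  reference-region normalization and per-minute OLS slopes.
- **Macropinosome counting**: threshold + 8-connected components with a
  closed 0.2–2 µm² area band.
- **EB-comet speeds**: local-maximum detection with sub-pixel refinement,
  greedy nearest-neighbour linking, path-length/duration speeds.
- **Embryo morphometry**: circularity 4πA/P² from a sub-pixel silhouette
  contour, and epiboly progression as the margin's fractional position on
  the animal–vegetal axis, with per-trial wild-type normalization.
- **Group statistics**: Welch's t, exact/approximate Mann–Whitney U, χ²
  goodness of fit.

Because suitable public reference movies do not exist, the package ships a
first-class synthetic-data generator (`yolkflow.synth`) producing
calibrated TIFF stacks and traces for every modality — advected punctate
actin texture with a programmed velocity field, FRAP traces with
incomplete bleaching, opening ablation gaps, sized endocytic disks, moving
comets, elliptical silhouettes — each with Poisson/Gaussian camera noise
and an exported ground-truth sidecar. Every analysis stage is validated
end-to-end against these known truths.

## Worked example

`examples/` contains one short script per capability. For instance,
measuring margin-directed actin flow
(`python examples/01_actin_flow_piv.py`):

```text
valid vectors: 686
mean speed:    0.549 µm/min (true 0.500)
quadrant fractions: {'up': 0.867, 'down': 0.004, 'left': 0.063, 'right': 0.066}
```

A synthetic movie with 0.5 µm/min upward flow under shot noise is analyzed
with a 14.8 µm interrogation window; the pooled valid vectors point
overwhelmingly into the "up" (animal/margin) quadrant and the mean speed
recovers the programmed magnitude. Or FRAP
(`python examples/02_frap_half_time.py`):

```text
tau:             10.48 s   (true 10.00)
half-time:       7.26 s  (tau * ln 2)
mobile fraction: 0.861
```

## Command line

Each stage is also exposed as a thin CLI over the library:

```bash
yolkflow simulate --scenario flow --seed 3 --out sim/
yolkflow piv --input sim/flow.tif --pixel-size 0.25 --frame-interval 0.5 --out piv/
yolkflow frap --trace trace.csv --bleach-frame 10 --frame-interval 0.5 --out frap/
```

Subcommands: `simulate`, `piv`, `frap`, `ablation`, `accumulation`,
`intensity`, `puncta`, `comets`, `morphometry`, `stats`. Every run writes
CSV results plus a JSON run summary with the resolved parameters and
package version.

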