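# vdcyto

Image-analysis toolkit for **viscoelastic deformability cytometry (vDC)**:
high-throughput, label-free mechanical phenotyping of single cells imaged in
parallel microchannels.

Cells driven through a constricted channel by a viscoelastic carrier fluid
(e.g. dilute PEO in PBS) deform into characteristic bullet shapes. A
high-speed camera records bright-field frames of a 1024 × 80 px region of
interest spanning up to 10 channels at 1,000–10,000 frames/s, and each cell's
contour is reduced to its projected area *A*, perimeter *l*, and
**deformability**

$$D = 1 - \frac{2\sqrt{\pi A}}{l}$$

the isoperimetric deficit: 0 for a circle, growing toward 1 as the contour
departs from circularity. Populations are compared in the
(area, deformability) plane via density scatterplots, 50%-of-maximum density
contours, polygonal gates for rare-cell quantification, and nonparametric
statistics.

The package is aimed at instrument builders and analysts who need a
**testable** version of this pipeline: a synthetic frame generator renders
bullet-shaped cells with *exact* per-cell polygon ground truth (area,
perimeter, deformability, position, velocity), so the detection chain can be
validated end-to-end against geometry instead of against another image
processor.

## What is inside

| module | role |
| --- | --- |
| `vdcyto.shapes` | bullet contour family with exact quadrature and monotone deformability inversion |
| `vdcyto.synth` | population sampling, bright-field frame rendering (PSF, motion blur, shot/read noise), Poisson arrival streams, truth manifests |
| `vdcyto.io_formats` | multi-page TIFF / PNG-directory / raw-stream frame I/O, schema-stamped results CSV, JSON configs |
| `vdcyto.detection` | background estimation, thresholding, sub-pixel contour tracing, per-cell features (D, brightness, aspect ratio, convex-hull area ratio), presence filtering, velocity estimation |
| `vdcyto.gating` | histogram/KDE density maps, 50%-density contours, gate derivation/application, Clopper–Pearson rare-cell ratios |
| `vdcyto.stats` | population summaries, Mann-Whitney U, one-way ANOVA + Tukey, significance stars |
| `vdcyto.streaming` | bounded-buffer acquisition/analysis/accumulation emulation with live density |
| `vdcyto.flow` | Carreau shear-thinning viscosity fits, Re/Wi/El numbers |
| `vdcyto.presets` | population specs calibrated to published blood, cell-line, and leukemia statistics |

## Worked example

Simulate two blood-cell populations at their published deformability and
size distributions, run the full pipeline, and compare them:

```python
from vdcyto import presets
from vdcyto.pipeline import measure_population, recovery_report
from vdcyto.stats import mann_whitney_u

rbc_table, rbc_truth = measure_population(presets.RBC, 1000, seed=42)
pbmc_table, pbmc_truth = measure_population(presets.PBMC, 1000, seed=43)

for name, table, truth in [("RBC", rbc_table, rbc_truth),
                           ("PBMC", pbmc_table, pbmc_truth)]:
    r = recovery_report(table, truth)
    print(f"{name}: {r['n_accepted']} cells accepted | "
          f"measured D = {r['measured_mean_deformability']:.3f} "
          f"(generator truth {r['true_mean_deformability']:.3f}) | "
          f"measured area = {r['measured_mean_area_um2']:.1f} um^2")

rbc_d = rbc_table[rbc_table.accepted]["deformability"]
pbmc_d = pbmc_table[pbmc_table.accepted]["deformability"]
res = mann_whitney_u(rbc_d, pbmc_d, ("RBC", "PBMC"))
print(f"Mann-Whitney U = {res.statistic:.0f}, P = {res.p_value:.3g} ({res.stars})")
```

prints

```
RBC: 1000 cells accepted | measured D = 0.154 (generator truth 0.160) | measured area = 35.7 um^2
PBMC: 1000 cells accepted | measured D = 0.053 (generator truth 0.050) | measured area = 28.5 um^2
Mann-Whitney U = 999902, P = 0 (****)
```

Every generated cell was detected; the measured red-cell deformability sits
≈ 0.006 below truth (the documented PSF rounding limit at ~7 px equivalent
radius, well inside the recovery tolerance), areas are within ~1%, and the
two populations — similar in size but different in stiffness — separate with
overwhelming significance, matching the phenotyping logic this measurement
was designed for.

The same stages are scriptable from the shell:

```sh
vdcyto simulate --population rbc --rate 500 --duration 0.5 \
    --out frames.tif --manifest truth.json --seed 1
vdcyto process --frames frames.tif --out cells.csv --log run.log
vdcyto gate derive --cells reference.csv --out gate.json --plot gate.png
vdcyto gate apply --cells mixture.csv --gate gate.json
vdcyto stats --cells a.csv --cells b.csv --test mwu --out report.json
vdcyto flow fit-carreau --data rheology.csv
```

## Limitations

The synthetic frames model contrast, blur, and noise — not cell optics or
deformation physics; see `docs/methods.md` for the full model description,
estimator design choices, and known measurement biases.
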