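# orgamapper

Quantifies **where organelles sit inside cells** from 2D multi-channel
fluorescence images.  Given a nucleus stain, a cytoplasm (or inverted
membrane) stain and an organelle marker, the pipeline segments nuclei and
single cells, detects blob-shaped organelles (lysosomes, endosomes, Golgi
fragments, ...) and measures, for every detection, its Euclidean distance from
the nucleus edge — the read-out that distinguishes, say, perinuclear
clustering of lysosomes after a knockdown from a dispersed distribution.
It is written for cell biologists who need a scriptable, reproducible
alternative to interactive point-and-click analysis.

## The measurements

For each segmented cell with mask $C$ and nucleus mask $N$, an exact
Euclidean distance map $D(p) = \min_{q \in N} \lVert p - q \rVert$ is
computed over the cytoplasm $C \setminus N$ and calibrated to µm.  Each
organelle detection at $p$ gets

- a **raw distance** $d = D(p)$,
- a **normalized distance** $d / F$, where $F$ is the cell's Feret (maximum
  caliper) diameter — this removes pure cell-size effects,
- peak intensities in the organelle and optional measurement channels,
- an angle about the nucleus center of mass (for circular variance,
  $1 - |\frac{1}{n}\sum_k e^{i\theta_k}|$).

Detection uses a scale-normalized Laplacian-of-Gaussian filter
($-\sigma^2 \nabla^2 G_\sigma$, optimal for blobs of radius
$\approx \sqrt{2}\sigma$) followed by prominence-filtered maxima: a maximum
survives if it stands at least the prominence above the highest saddle
connecting it to a higher maximum.  Intensity-based read-outs (the
perinuclear index: intensity within a fixed perimeter of the nucleus vs.
beyond it; binned intensity-vs-distance profiles) are provided for organelles
that spot detection cannot resolve.  Conditions are compared per cell with
the unpaired two-sample Wilcoxon rank-sum test, and any point detector can be
benchmarked against manual labels via greedy distance matching and
$F_1 = \mathrm{TP} / (\mathrm{TP} + 0.5(\mathrm{FN} + \mathrm{FP}))$.

A synthetic-cell generator renders 8-bit 3-channel fields with exact ground
truth and drives a robustness study that quantifies, via an *error factor*
$|R/R_0 - 1|$ against the unperturbed cell, how sensitive each positioning
method is to cell size, background level and organelle size.

## Worked example

```python
import dataclasses
from orgamapper import (SimulationParams, analyze_field, compare_groups,
                        generate_cell, study_settings)
from orgamapper.simulate import simulate_condition

# one simulated cell: 20 organelles on an annulus 40 +- 5 px from the nucleus
field, truth = generate_cell(SimulationParams())
result = analyze_field(field, study_settings())
record = result.cell_records[0]
print(len(result.detections), round(record.feret_um, 1))
# -> 20 279.4        (all organelles found; Feret of the 140x90 px oval cell)

# two conditions, 20 cells each: organelles near (10 px) vs far (25 px)
near = simulate_condition(dataclasses.replace(
    SimulationParams(), organelle_placement_radius=10.0), 20, seed=100)
far = simulate_condition(dataclasses.replace(
    SimulationParams(), organelle_placement_radius=25.0), 20, seed=200)
res = compare_groups(near["mean_distance_um"], far["mean_distance_um"])
print(round(near["mean_distance_um"].mean(), 1),
      round(far["mean_distance_um"].mean(), 1), res.pvalue)
# -> 10.4 25.3 1.4508889103849684e-11
```

The per-cell mean distances recover the simulated placement radii and the
rank-sum test separates the conditions decisively.

The same stages are available from the shell:

```bash
orgamapper simulate --out sim/ --sweep cell_scale   # fields + error_factors.csv
orgamapper run --input images/ --settings settings.xml --output results/
orgamapper analyze --condition ctrl=results_ctrl --condition kd=results_kd \
    --output analysis/
orgamapper validate --manual manual.csv --auto auto.csv
```

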