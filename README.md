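# spheromet

Quantitative image analysis for 3D tumor-spheroid outgrowth assays, plus
the cytometry arithmetic that goes with them. The package implements, as a
tested and reusable pipeline, the readouts used to decide whether a
treatment pushes cancer cells toward a metastatic phenotype:

* **Spheroid segmentation** — brightfield inversion, weighted channel
  merging, intensity cut-off, largest-component selection, border
  extraction.
* **Morphometry** — rotational **symmetry** from angular moments
  Z_nm = Σ ρⁿ e^(−imφ) I(ρ,φ) on the unit disk (score
  1 − Σ_{m>0}|Z_nm| / Σ|Z_nm|); **threshold compactness**
  c = s_body²/s_border, where s_body is the area of the ≥60%-of-maximum
  intensity core and s_border the whole spheroid area (the normalised
  ratio s_body/s_border is reported alongside); **profile**, the mean
  shortest border→core distance (smaller = steeper edge).
* **Matrix-cell outgrowth** — segmentation of DiL-labeled cells outside
  the spheroid, exclusion of autofluorescent conglomerates (summed DiL
  > 2×10⁵ a.u.), live/dead classification by mean sytox-green intensity
  (dead > 3×10³ a.u.), and each cell's shortest distance to the spheroid
  border.
* **Time-lapse tracking** — per-frame detection, greedy
  mutual-nearest-neighbour linking, accumulated distance, cell counts,
  cluster area.
* **Cytometry** — singlet/scatter/DAPI⁻ gating, mean fluorescence
  intensity (MFI), **treatment-matched autofluorescence correction**
  (stained − unstained of the *same* treatment, because treatment itself
  raises autofluorescence), fold change to untreated control, and
  DAPI-based floater enumeration.

Because such studies rarely deposit raw images, the package ships a
first-class synthetic-data module (`spheromet.synth`) that renders
multi-channel spheroid scenes, drifting-cell time-lapse stacks, and
cytometry event grids with exact ground truth, so every stage is testable
end to end.

## Worked example

```python
from spheromet import (SpheroidScene, generate_spheroid_image,
                       analyze_outgrowth, morphometry)
from spheromet.segmentation import segment_image

scene = SpheroidScene(seed=0)             # 120 µm spheroid, 30 cells, 3 conglomerates
image, truth = generate_spheroid_image(scene)
mask = segment_image(image)               # invert brightfield, merge, threshold
records, summary = analyze_outgrowth(image, mask)
print(summary.n_detected, summary.n_conglomerates_excluded,
      summary.n_live, summary.n_dead, round(summary.pct_viable, 1))
res = morphometry(image["dil"], mask)
print(round(res.symmetry, 4), round(res.compactness_norm, 4))
```

prints

```
33 3 20 10 66.7
0.9993 0.3592
```

i.e. all 33 generated objects are found, the 3 conglomerates are excluded
by the DiL-sum rule, the 10 constructed dead cells are classified by the
sytox rule (viability 66.7%), the spheroid is almost perfectly
rotationally symmetric, and ~36% of its area is high-intensity core.

The numbered scripts under `analysis/` run the same pipeline as small
narrative studies (shape sweeps, noise ladders, correction recovery) and
write their tables to `results/`. A `spheromet` CLI exposes each stage
(`spheromet simulate spheroid --seed 0 --out scene/`, `spheromet segment`,
`spheromet morpho`, `spheromet outgrowth`, `spheromet track`,
`spheromet cytometry correct|floaters`); identical seeds and configs give
byte-identical CSV outputs.

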