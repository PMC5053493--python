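# mfoct — multi-functional OCT processing for longitudinal retinal studies

`mfoct` re-implements a multi-contrast optical coherence tomography (OCT)
processing pipeline for longitudinal imaging of the mouse retina, of the kind
used to follow spontaneous retinal–choroidal neovascularization in VLDLR
knockout mice.  From dual-polarization complex tomograms it computes three
kinds of contrast and everything needed to quantify them over months:

* **Reflectivity** `I = |S_V|² + |S_H|²`, with respiratory-motion
  compensation, retina flattening and repeat averaging;
* **Polarization contrast**: per-voxel Stokes vectors `(I, Q, U, V)` and the
  degree of polarization uniformity
  `DOPU = √(⟨q⟩² + ⟨u⟩² + ⟨v⟩²)` over a 3 × 9 × 5 (z × x × t)
  spatio-temporal window, evaluated only where more than 80% of the window
  exceeds the vitreous background threshold `s̄_b + 3σ(s_b)` — melanin
  (RPE, choroid, migrated intraretinal deposits) depresses DOPU toward 0;
* **OCT angiography**: the averaged magnitude of complex differences between
  consecutive repeats, `1/(m−1) Σ |C_{i+1} − C_i|`, after bulk-phase
  compensation and removal of severely moved frames.

On top of the contrast stages it provides graph-based segmentation of six
retinal boundaries (ILM, IPL/INL, INL/OPL, OPL/ONL, anterior RPE, posterior
choroid) by minimum-cost paths through axial-gradient cost images, four
en-face screening projections (outer-retina variance, thickness, minimum
DOPU, depth-coded angiography), circumpapillary annulus quantification with
a 75% coverage rule, and the longitudinal statistics (monthly clustering,
elimination/imputation of missing data, repeated-measures ANOVA with
Bonferroni post hoc tests, Mann-Whitney U, Pearson correlation).

No public datasets exist for this acquisition, so the package ships a
first-class synthetic phantom (`mfoct.phantom`) that generates seeded
dual-channel volumes with full ground truth — speckle, depolarizing RPE and
melanin deposits, decorrelating flow in vessels, ~1 Hz axial respiratory
motion, hyperreflective lesions and programmed outer-retina thinning — and
the entire pipeline is validated against that ground truth.

## Worked example

```python
import numpy as np
from mfoct import default_scene, make_phantom, run_full_pipeline, PipelineConfig
from mfoct.evaluation import SeedAnnotations

spec = default_scene((256, 128, 64, 5))        # z × x × y × repeats
volume, truth = make_phantom(spec, seed=1)
annotations = SeedAnnotations(onh=(64.0, 32.0),
                              lesions=list(truth.lesion_coords),
                              deposits=list(truth.deposit_coords))
config = PipelineConfig(annulus_inner_px=13, annulus_outer_px=26)
result = run_full_pipeline(volume, annotations, config,
                           mouse="m1", eye="left", postnatal_day=72)
print(result.record.quality)
for key, value in sorted(result.record.metrics.items()):
    print(key, round(value, 2) if isinstance(value, float) else value)
```

prints

```
accepted
deposit_count 2
lesion_count 1
thickness_ir_um 119.92
thickness_or_um 90.05
thickness_tr_um 209.97
```

i.e. the acquisition passed the segmentation sanity check, both melanin
deposits and the lesion were recorded, and the mean total / inner / outer
retinal thickness over the circumpapillary annulus matches the phantom's
programmed geometry (210 / 120 / 90 µm) to a fraction of a pixel.

The numbered drivers under `analysis/` run the study end to end:
`01_simulate.py` (write phantom volumes + annotations), `02_process.py`
(full pipeline → en-face TIFF/PNG maps and `records.csv`),
`03_longitudinal.py` (monthly clustering of the printed lesion/deposit
counts and recovery of a programmed 4 µm/month outer-retina thinning),
`04_statistics.py` (repeated-measures ANOVA, Mann-Whitney U, Pearson ρ on a
cohort simulated from the printed monthly summaries).

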