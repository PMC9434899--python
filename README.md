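# csfspace

Automated three-dimensional volumetry of cerebrospinal-fluid (CSF) spaces on
T1-like brain MRI, aimed at separating idiopathic normal-pressure
hydrocephalus (INPH) from Alzheimer's disease (AD). INPH shows the DESH
pattern — enlarged lateral ventricles and Sylvian fissures with a *tight*
high-convexity subarachnoid space — while AD enlarges ventricles ex vacuo
without high-convexity tightness. The package measures three CSF
compartments per subject, normalizes them by intracranial volume (ICV), and
computes the **VOSS index** (ventricle over subarachnoid space),

    VOSS = V_LV / V_HC ,

the ratio of lateral-ventricle volume to high-convexity subarachnoid-space
volume, which discriminates the two conditions sharply.

## What it does

- **Phantom simulation** (`csfspace.phantom`): head phantoms with exact
  voxel ground truth (GM/WM/CSF ellipsoid head, parametric ventricles,
  high-convexity CSF rind, Sylvian clefts, multiplicative bias field,
  Gaussian noise), plus cohort-level sampling of normalized volumes and VOSS
  ratios from log-normal families calibrated to published group statistics,
  with a Gaussian copula imposing the published within-group correlations.
- **Preprocessing** (`csfspace.preprocess`): polynomial log-domain bias
  correction, Otsu-based brain extraction, deterministic k-means tissue
  classification, linear-mixing partial-volume fractions, ICV, and a
  multi-resolution affine registration.
- **Ventricle segmentation** (`csfspace.ventricle_seg`): graph-cuts energy
  minimization (globally optimal via max-flow/min-cut) with atlas-prior data
  terms, contrast-sensitive smoothness, hard seeds, and morphological
  post-processing.
- **Talairach grid** (`csfspace.talairach`): the 11 × 12 × 8 = 1056-cell
  proportional grid from the AC/PC landmarks and the brain bounding box, and
  the two study ROIs (high convexity: 40 cells; Sylvian region: 120 cells).
- **Volumetry** (`csfspace.volumetry`): regional CSF volumes (partial-volume
  fraction sums or hard-label counts), largest-component filtering for the
  Sylvian region, ICV normalization, VOSS index.
- **Statistics** (`csfspace.stats`): Kruskal–Wallis / ANOVA with Dunn or
  Tukey-on-ranks post-hoc, Pearson correlations, and ROC analysis of the
  VOSS index with the Youden-optimal cutoff.

## Worked example

```python
import numpy as np
from csfspace import PhantomSpec, RunConfig, make_phantom, subject_pipeline
from csfspace.cli import _training_atlas

atlas = _training_atlas(96, seed=42)          # blurred mean of 5 training masks
intensity, truth = make_phantom(PhantomSpec(
    ventricle_scale=5.5, hc_sas_thickness=2.5, sylvian_width=10.0,  # INPH-like
    noise_sd=4.0, bias_amplitude=0.1, seed=7))
rec = subject_pipeline(intensity, atlas, RunConfig(), truth.ac, truth.pc,
                       subject_id="inph_demo", group="INPH")
print(f"LV   {rec.lv_volume:9.0f} mm^3  (truth {truth.true_volumes['lateral_ventricle']:.0f})")
print(f"HC   {rec.hc_volume:9.0f} mm^3  (truth {truth.true_volumes['high_convexity_sas']:.0f})")
print(f"Syl  {rec.sylvian_volume:9.0f} mm^3  (truth {truth.true_volumes['sylvian']:.0f})")
print(f"VOSS {rec.voss:9.2f}")
```

prints

```
LV       65780 mm^3  (truth 65864)
HC        1851 mm^3  (truth 1840)
Syl      26432 mm^3  (truth 26496)
VOSS     35.53
```

i.e. each regional volume is recovered within a fraction of a percent of the
phantom's exact ground truth at the cohort noise level (noise SD = 5% of the
GM mean), and the resulting VOSS index lands squarely in the INPH range —
far above the AD-typical values around 5.

The same pipeline is scriptable from the shell:

```bash
csfspace run --n-per-group 3 --shape 64 --seed 5 --out results/demo
csfspace stats --cohort results/demo/cohort.csv --out results/demo/report.json
```

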