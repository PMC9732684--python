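# mucoquant

Compartmental quantification of CD3 and γδ T cells in colon mucosa from
H-DAB immunohistochemistry images, with mixed-model fold-change statistics.

Intraepithelial lymphocyte (IEL) counts — and in particular the balance of
γδ T cells between the epithelium, the 5 μm subepithelial zone beneath the
basement membrane, and the lamina propria — differ between ulcerative
colitis (UC), Crohn's disease (CD) and healthy mucosa, and shift with
histological activity (Nancy index). `mucoquant` implements the complete
computational pathology pipeline needed to measure this on calibrated
stained-tissue images, plus the statistics to compare groups, for
researchers building or validating automated IEL quantification.

## What it does

1. **Stain separation** — colour deconvolution of H-DAB images in
   optical-density space, `OD = −log10(I/255)`, unmixed with the standard
   hematoxylin/DAB unit vectors (configurable).
2. **Segmentation** — tissue mask by total absorbance; epithelium mask from
   a trainable per-pixel random-forest classifier (or QuPath-style GeoJSON
   annotations).
3. **Compartments** — epithelium, the subepithelial band (Euclidean
   dilation of the epithelium by 5 μm, minus the epithelium, clipped to
   tissue) and lamina propria; an exact partition of the tissue raster.
4. **Cells** — nucleus detection on the hematoxylin OD channel
   (smoothed-peak markers + watershed), nucleus-area filter at the
   0.225 μm/px reference scale (inclusive 125–3,000 px²), 1.5 μm cell
   expansion with nearest-nucleus splitting, and a three-class random
   forest (positive / negative / artefact).
5. **Quantification** — per-biopsy counts per compartment obeying the exact
   subtraction identities; IELs and subepithelial cells per 100 epithelial
   cells, lamina propria cells per mm², and γδ/CD3 ratios.
6. **Statistics** — random-intercept linear mixed model on natural-log
   measures (`log y = Xβ + b_subject + ε`), REML via the profiled variance
   ratio, LSD pairwise contrasts reported back-transformed as fold changes
   `FC = exp(Δ)` with t-based 95% CIs, ICC, covariate-adjusted refits,
   Spearman blood–mucosa correlation and Kruskal–Wallis location tests.

A synthetic-data module generates ground-truthed H-DAB tiles (Beer–Lambert
forward rendering with planted nuclei, classes and compartments) and
cohort count tables with planted fold changes and variance components, so
every stage is testable without slide scans or patients.

## Worked example

```python
import numpy as np
from mucoquant import (SyntheticTissueSpec, generate_tissue_image,
                       separate_stains, detect_nuclei, filter_by_area)

image, truth = generate_tissue_image(SyntheticTissueSpec(seed=0))
stains = separate_stains(image)
cells = filter_by_area(detect_nuclei(stains))
print(len(truth.cells), len(cells))
```

prints `198 192`: the tile plants 198 objects (including 5 artefacts that
the area filter and classifier are there to reject) and detection recovers
192 candidate nuclei; matched at 2 px this is an F1 of about 0.99.

Cohort-level inference:

```python
from mucoquant import generate_cohort_counts, run_study_analysis
from mucoquant.synthetic import default_cohort_design

cohort = generate_cohort_counts(default_cohort_design(seed=0))
results = run_study_analysis(cohort)
print(results.report())
```

The report lists, for every stain × compartment, all pairwise group fold
changes in the Table-style layout `FC (95% CI) p`, e.g.

```
CD3       lamina_propria     CD_active vs CD_inactive     FC 2.20 (95% CI 1.60-3.02) p=0.0000 *
TCRdelta  epithelium         CD_inactive vs UC_inactive   FC 0.63 (95% CI 0.47-0.83) p=0.0011 *
```

meaning active CD mucosa carries about twice the lamina-propria CD3
density of inactive CD, and inactive CD markedly fewer γδ IELs than
inactive UC, in this synthetic cohort (which plants exactly that
qualitative pattern).

The same pipeline is scriptable from the shell:

```bash
mucoquant simulate --out sim --n-images 4 --seed 1
mucoquant train-seg --images sim/tile_000.png --masks sim/tile_000_epithelium.png \
                    --images sim/tile_001.png --masks sim/tile_001_epithelium.png \
                    --out seg.joblib
mucoquant train-cells --tiles sim --out clf.joblib
mucoquant quantify --images sim/tile_002.png --segmenter seg.joblib \
                   --classifier clf.joblib --out quant
mucoquant stats sim/cohort.csv --out results
```

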