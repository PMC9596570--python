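# mitoflux

Quantitative image analysis of **basal and damage-induced mitophagic flux**
from tandem-fluorescent LC3 (tfLC3, mRFP+GFP) confocal microscopy.

The tfLC3 reporter exploits pH: GFP fluorescence is quenched and degraded in
acidic autophagolysosomes while mRFP persists, so puncta positive in *both*
channels mark neutral-pH autophagosomes. Their accumulation under
bafilomycin A1 (which blocks lysosomal acidification) measures autophagic
flux, and their association with the mitochondrial network measures
mitophagy. `mitoflux` turns multi-channel TIFF images of single cells into
per-cell counts, association fractions and membrane-potential ratios, with a
built-in synthetic-microscopy generator so the entire pipeline is testable
against ground truth without any raw data.

Intended users: cell biologists and image analysts quantifying
autophagosome/mitophagy dynamics from spinning-disk or laser-scanning
confocal data (2-D frames, Z-stacks, or time-lapse series).

## Method

**Spot detection.** Each channel is filtered with a scale-normalised
Laplacian of Gaussian at a fixed spot scale (σ = 3 px for 56.6 nm pixels,
matching the ~250 nm diffraction limit). The binary mask is the set of
pixels whose response *R* exceeds the adaptive threshold

&nbsp;&nbsp;&nbsp;&nbsp;*R* > μ(*R*) + *z* · σ(*R*),

with μ, σ taken over the analysis support (the cell mask). The preference
parameter *z* (default 1.75) trades recall against precision and is
intensity scale-free: detection is invariant under affine rescaling
*aI* + *b* of the image. Objects of area ≤ 25 px (fixed-cell mode) or
≤ 4 px (live mode) are below the precision limit and removed.

**Dual puncta and association.** A GFP object and an mRFP object sharing at
least one pixel are merged (pixel union over the connected overlap graph)
into one dual punctum — the unit counted as an autophagosome. Each dual
punctum is related to the mitochondrial mask by the minimum Euclidean
distance between closest object edges; distances ≤ 5 px (≈ 250 nm, the
resolution limit) count as mitochondria-associated.

**Potential ratio.** For each dual punctum overlapping the mitochondrial
mask, the mean mitochondrial-dye intensity under the punctum is divided by
the mean of the adjacent segment and by the mean over all segments in the
cell; per-cell boxplot statistics summarise the distribution (median < 1:
autophagosomes sit on mitochondria of below-average membrane potential).

**Live-cell mode.** Time-lapse series are segmented automatically
(90th-percentile suppression, median cascade 3/5/9, largest connected
component, widened by 4 dilations of radius 2 px and closed), checked for
cross-channel consistency (Jaccard ≥ 0.8) and border contact. Detection
runs at high recall (*z* = 1.75 / 3.75) followed by three object-level
false-positive filters: Cohen's *d* ≥ 0 against the cell intensity
distribution, peak intensity above the Tukey fence Q3 + 1.5·IQR, and
area > 4 px.

**Sensitivity study.** Per-cell counts are recomputed over a *z* grid; for
every (cell line, condition pair, *z*) triple a Kruskal–Wallis test is run
at the Bonferroni-corrected level α/m with *m* the full grid size — for the
canonical design of 4 conditions, 2 cell lines and 21 *z*-values,
m = C(4,2) · 2 · 21 = 252.

## Worked example

```python
import mitoflux as mf
from mitoflux.pipeline import PipelineConfig, analyze_scene

spec = mf.SceneSpec(seed=10, n_dual=4, n_gfp_only=3, n_rfp_only=3, frac_near_mito=0.5)
truth, scene = mf.simulate_scene(spec)
res = analyze_scene(scene, PipelineConfig(mode="fixed_cell"), roi=truth.cell_mask)
s = res.summary
print(s.n_gfp, s.n_rfp, s.n_dual, s.n_dual_near_mito, s.fraction_near_mito)
```

prints

```
7 7 4 2 0.5
```

— 7 puncta per channel (4 dual + 3 single), 4 dual GFP+mRFP puncta of which
2 lie within the 5-px resolution limit of a mitochondrial segment: the dual
count is the flux readout, and the associated fraction (0.50) is the
mitophagy readout. Running `examples/02_detect_puncta.py` scores the
detector against ground truth (30 true puncta at peak SNR 5 → 30 detected,
recall 1.00, precision 1.00), and `examples/04_potential_ratio.py` shows
the ratio statistic recovering deliberately depolarised mitochondria
(per-cell median ratio 0.70 when all puncta are placed on half-potential
segments). The `examples/` directory has one short script per capability.

A thin CLI wraps the same functions:

```sh
mitoflux simulate out/ --seed 1          # synthetic scene + ground truth
mitoflux detect out/scene.tif --channel gfp
mitoflux run out/scene.tif --mode timelapse
mitoflux sweep counts.csv --alpha 0.05
```

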