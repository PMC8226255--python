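# isletpath

Whole-slide image analysis of multiplexed-immunofluorescence **pancreas
sections**: tissue/islet/cell detection, endocrine and immune cell
classification, and spatial statistics of immune infiltration — the digital
pathology workflow used to characterize the endocrine pancreas and screen for
insulitis in type 1 diabetes research, implemented as a tested, scriptable
Python pipeline.

It is aimed at researchers who quantify pancreas sections (e.g. biobank
material stained for insulin, proinsulin, glucagon, chromogranin A, the
prohormone convertases PC1/3 and PC2, CPE, and the immune markers CD45, CD3,
CD8) and want a reproducible, headless alternative to interactive analysis.

## What it computes

Given a multichannel fluorescence slide (TIFF, Hoechst + marker channels,
with microns-per-pixel calibration):

1. **Tissue detection** — threshold the Gaussian-smoothed mean of all
   channels; artifact removal and hole filling; areas in mm².
2. **Cell detection** — median + Gaussian filtering of the nuclear channel,
   intensity threshold, distance-transform watershed to split touching
   nuclei, area filtering, and 5 µm cell expansion with mutual (Voronoi-style)
   clipping. Per-cell mean intensities are measured per compartment (nucleus,
   cytoplasm, whole cell) on the raw channels, then *smoothed features* are
   added: Gaussian-weighted neighborhood means over a 25 µm radius
   (w = exp(−d²/2σ²), σ = 12.5 µm).
3. **Islet segmentation** — a random-forest pixel classifier over multiscale
   intensity features (raw + Gaussian scales 1/2/4/8 µm per channel), trained
   on a small labeled ROI and applied section-wide; predicted components are
   hole-filled, polygonized, and kept only if they own **≥ 10 detected
   cells** — the field's operational definition of an islet, which excludes
   scattered single endocrine cells.
4. **Cell classification** — single-measurement threshold classifiers
   (feature > t) and point-trained random-forest object classifiers over the
   full feature vector. Composites use set intersection: **beta = INS⁺ ∧
   PI⁺**, alpha = GCG⁺, enzyme positivity per lineage. T cells are gated in
   two stages (CD8 evaluated only on CD3⁺ cells), so **CD4 = CD3⁺ \ CD8⁺**
   exactly in every stratum.
5. **Spatial analysis** — Euclidean distance from each immune cell centroid
   to the nearest islet polygon (0 inside), binned into the five canonical
   bands [0, 1), [1, 50], (50, 200], (200, 500], > 500 µm (bin 0 =
   intra-islet, bin 1 = peri-islet), plus distance heatmaps clipped at
   250 µm.
6. **Quantification** — per-islet composition and density, PI/INS count
   ratios, immune counts/densities per compartment, infiltrated-islet
   proportions, cohort mean ± **population** SD (ddof = 0) with NA exclusion,
   and consensus **insulitis scoring**: ≥ 15 CD45⁺ or ≥ 6 CD3⁺ cells within
   or immediately adjacent to ≥ 3 islets of ≥ 150 µm equivalent diameter,
   with at least one pseudoatrophic (insulin-deficient) islet present.

A first-class **synthetic slide generator** (`isletpath.synthetic`) renders
pancreas-like slides — an elongated tissue region, islets as quasi-circular
cell clusters with configurable beta/alpha fractions, acinar and scattered
endocrine cells, and immune cells placed by sampling the five distance bands —
with exhaustive ground truth, so every stage has a recoverable target.

## Worked example

```bash
isletpath simulate --seed 0 --out sim/      # synthetic slide + ground truth
isletpath run --slide-dir sim/ --out run/   # full pipeline
isletpath compare --run-dir run/ --truth-dir sim/
```

or, as a library (this is what `analysis/02_simulate_and_run.py` runs):

```python
from isletpath.synthetic import SlideSpec, generate_slide
from isletpath.pipeline import RunConfig, run_pipeline

spec = SlideSpec(width_px=1600, height_px=1600, n_islets=14,
                 islet_cells_min=12, islet_cells_max=150,
                 immune_distance_weights=(0.01, 0.12, 0.40, 0.47, 0.0),
                 seed=7)
slide, truth = generate_slide(spec)
result = run_pipeline(slide, RunConfig(seed=8), truth=truth)
```

which prints:

```
simulated: 14 islets, 4630 cells, 1.35 mm² tissue
pipeline:  14 islets, 4649 cells, 1.35 mm² tissue, beta 66.2% of islet cells
  CD45: 276 cells, 203.9/mm², bins (7, 43, 96, 130, 0), 64.3% islets infiltrated
  CD3: 150 cells, 110.8/mm², bins (3, 21, 53, 73, 0), 42.9% islets infiltrated
  CD8: 68 cells, 50.2/mm², bins (0, 11, 28, 29, 0), 14.3% islets infiltrated
insulitis verdict: False
```

All 14 islets are recovered (none under 10 cells), the recovered beta share
(66.2%) sits within sampling error of the generator's 65%, immune densities
are within ~1% of truth, and — as expected for a healthy-pancreas condition —
the consensus insulitis definition is not met.

The numbered drivers under `analysis/` tell the full story: published-table
aggregation (`01`), simulate + run (`02`), and truth recovery plus the
thresholding-vs-machine-learning comparison (`03`); their tables land in
`results/`.

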