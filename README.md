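# retinatopo

Topological quantification of 3-D retinal vascular networks.

In the neonatal mouse retina, a superficial (primary) capillary plexus and a
deep (secondary) plexus are bridged by radially oriented *vertical sprouts*.
Hyperoxia (the oxygen-induced-retinopathy model, OIR) preferentially
obliterates the secondary plexus and the sprouts while largely sparing the
primary sheet — a 3-D phenotype that flat-mount 2-D imaging cannot resolve.
`retinatopo` implements the quantification side of that analysis for traced
vascular networks and binary image stacks, plus a synthetic two-plexus
generator so the whole pipeline runs and is tested without any image data.

It is aimed at researchers quantifying microvascular architecture from
light-sheet or confocal stacks after filament tracing, and at method
developers who need a ground-truthed vascular phantom.

## What it computes

* **Euler characteristic and connectivity.** For a binary volume,
  χ = n₀ − n₁ + n₂ − n₃ over the vertices, edges, faces and cubes of the
  cubical complex of the foreground; for a traced skeleton graph
  G = (V, E), χ = |V| − |E|. Global loop-richness is reported as
  *connectivity* = 1 − χ: pendant branches leave it unchanged, every new
  link between existing nodes raises it by one, disconnected fragments
  lower it.
* **Clustering coefficients.** Per node, C_i = 2·|links among
  neighbours| / (k_i(k_i − 1)) — the local, dimensionless counterpart to the
  global connectivity — with degree/clustering histograms, the mean C, and
  the fraction of exactly-zero nodes.
* **Morphometrics.** Total vessel length (Σ polyline arc lengths), total
  volume (Σ πr²ℓ per edge), branch points (degree ≥ 3) and terminal points.
* **Sprout segmentation.** A sliding-window PCA classifier: the top
  principal component of the foreground voxels in each 40 µm window gives
  the local vessel orientation; windows whose orientation lies within 35° of
  the local radial direction vote *sprout*, the rest *plexus*, and voxels
  take the majority vote. Reports the sprout volume fraction.
* **Validation.** Dice and generalized Dice coefficients (inverse-square
  volume weights) against ground-truth labels, and a window-size ×
  cutoff-angle sweep.
* **Study runner.** A paired normoxia-vs-OIR simulation study (n = 5 per
  group) with central/middle/peripheral regional statistics, VOI sampling,
  Student's t-tests and ANOVA + Tukey, producing a tidy CSV/JSON report.

## Worked example

```python
import retinatopo as rt

retina = rt.generate_retina(rt.RetinaParams(seed=7))   # hemisphere, normoxia
summary = rt.clustering_summary(retina.graph)
print(f"chi = {summary.chi}   connectivity = {summary.connectivity}")
print(f"modal degree = {summary.modal_degree}")
print(f"mean clustering = {summary.mean_clustering:.4f}")
print(f"zero-clustering fraction = {summary.zero_fraction:.3f}")

volume, truth = rt.voxelize(retina.graph, 4.0)          # 4 µm voxels
labels, votes = rt.segment_sprouts(volume, rt.SegmentationParams())
report = rt.generalized_dice(truth, labels)
print(f"sprout volume fraction = {rt.sprout_volume_fraction(labels):.3f}")
print(f"GDC vs ground truth = {report.gdc:.3f}")
```

prints

```
chi = -1728   connectivity = 1729
modal degree = 3
mean clustering = 0.0213
zero-clustering fraction = 0.903
sprout volume fraction = 0.109
GDC vs ground truth = 0.817
```

Read: the healthy synthetic network is one connected mesh with ~1.7 × 10³
independent loops (χ is large and negative); its nodes typically join three
neighbours, and 90 % of them have no links among their neighbours — a
honeycomb-like reticulation with low local clustering. About 11 % of the
vascular volume is vertical sprouts, and the PCA auto-segmentation agrees
with the ground-truth labels at GDC 0.82, above the 0.7 bar conventionally
read as excellent agreement. Applying `rt.apply_oir` and re-running the same
metrics shows the OIR signature: connectivity and sprout fraction collapse
while mean clustering barely moves.

A command-line interface mirrors the library
(`retinatopo generate | oir | metrics | segment | validate | sweep |
compare | run-study`); see `retinatopo --help`.

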