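# Methods

`retinatopo` quantifies the topology of 3-D retinal vascular networks — the
kind produced by light-sheet imaging of cleared neonatal mouse retinas
followed by filament tracing — and ships a synthetic generator of the
two-plexus architecture so that every stage of the pipeline is testable
without image data. This note records the models, the defaults and why they
were chosen, and the places where a design decision was genuinely open.

## The synthetic retina

The neonatal retinal vasculature is modelled as two reticulated capillary
sheets — the superficial (primary) plexus and the deep (secondary) plexus —
bridged by radially oriented vertical sprouts. Each sheet is a honeycomb
lattice (interior node degree 3, matching the modal branch order of traced
capillary networks) laid out either on a hemispherical shell or on two
parallel planes (flat mode, used for closed-form unit tests where "radial"
is simply +z).

Geometry defaults describe a plausible P12 mouse eye and are all parameters:
shell radius 1000 µm, inter-plexus separation 120 µm (the vasculature spans
roughly 0–240 µm of retinal depth), mesh edge 60 µm, capillary radius 3 µm.
The inter-plexus distance and capillary calibre are stated assumptions, not
measured values.

Three generator choices matter for downstream statistics:

* **Equal-area projection.** The planar honeycomb is mapped to the shell
  with a Lambert azimuthal equal-area projection (pole on the optic-disk
  axis), so mesh density is uniform per unit shell area and regional
  morphometrics are homogeneous by construction. The residual length
  anisotropy of the projection (radial stretch / azimuthal compression,
  ≤ ~6 % at the rim) is the only systematic regional signal left.
* **Shared angular lattice.** Both plexuses are two radii of the same
  angular lattice, so a vertical sprout — drawn from a primary node to its
  nearest secondary node for a fraction `sprout_density = 0.3` of primary
  nodes — is nominally exactly radial. Positional jitter (σ = 5 µm) is
  applied tangentially in the projection plane, which keeps each layer on
  its shell and keeps sprouts within a few degrees of radial.
* **Triangle chords.** Capillary networks show a small minority of locally
  clustered nodes. With probability `chord_rate` per node, one pair of its
  neighbours is joined by a chord, creating a triangle that gives three
  nodes a positive clustering coefficient; `chord_rate = 0.033` therefore
  calibrates ≈ 3 × 0.033 ≈ 10 % of nodes to positive clustering (measured:
  9.3 ± 0.4 % across seeds), with the remaining ~90 % exactly zero.

The OIR (oxygen-induced retinopathy) perturbation deletes edges
independently per compartment: secondary-plexus and sprout edges everywhere
with probability 0.95 each, primary edges only inside the central third of
the radius with probability 0.8. Nodes left isolated are removed. This is a
purely stochastic obliteration model — no VEGF signalling, flow, or regrowth.

### What the generator does not emulate

No imaging physics (PSF, shadowing, noise), no vessel calibre hierarchy
(arterioles/venules), no tortuosity (edges are straight chords), and no
spatial correlation in the OIR dropout beyond the central/peripheral split.
Passing tests therefore demonstrate that the *quantification machinery* is
correct and that the *direction* of the OIR effects is recovered under a
faithful structural model; they do not validate absolute values on real
light-sheet stacks.

## Voxelisation

Graphs are rasterised as unions of capsules (radius per edge) on a cubic
grid (arrays `[z][y][x]`, voxel centres at `(index + 0.5)·voxel_size`). A
foreground voxel's ground-truth label is the compartment of the nearest
contributing edge; distance ties go to *sprout*, because sprouts are thin
and would otherwise be under-counted at their junctions with the plexus.

One discretisation artifact is worth knowing: where two capsules meet at a
sharp angle (the 60° corners of triangle chords), the discrete tubes can
come into diagonal voxel contact slightly before they merge, adding one
small spurious handle (Δχ = −1) per such corner at 2–4 µm voxels. Chord- and
jitter-free networks voxelise topology-exactly, which is what the
voxel-versus-graph Euler consistency tests use.

## Topology

**Euler characteristic.** For a binary volume, χ = n₀ − n₁ + n₂ − n₃ over
the distinct vertices, edges, faces and cubes of the closed cubical complex
of the foreground (shared cells counted once — not a local 2×2×2 kernel; an
exhaustive cell-enumeration oracle backs this in the tests). For a traced
skeleton graph χ = |V| − |E|, with parallel edges counted individually and
degree-2 points absorbed into polylines (homotopy-equivalent, and the
granularity at which filament tracers report nodes). The network's global
loop-richness is reported as connectivity = 1 − χ. Rewrite behaviour:
appending a pendant edge leaves χ unchanged; adding an edge between existing
nodes lowers χ by 1; adding a disjoint component raises it by 1.

**Clustering.** The local clustering coefficient is the standard
Watts–Strogatz quantity, C_i = 2·|links among N_i| / (k_i(k_i − 1)) on the
simple undirected view; nodes of degree < 2 carry C_i = 0 rather than being
excluded, since terminal nodes are part of the traced network. Summaries
report the arithmetic mean over all nodes, the degree histogram, and a
clustering histogram with an exact-zero bin plus 0.05-wide bins over (0, 1]
(right-closed, so C = 0.05 falls in the first positive bin).

## Sprout segmentation

A cubic window (default 40 µm) slides at stride 20 µm over the binary
stack. Windows with ≥ 10 foreground voxels yield the top principal component
of their foreground coordinates — the local vessel orientation, sign-free.
The angle θ between that orientation and the radial ray from the origin to
the window centre classifies the window: θ ≤ 35° votes *sprout*, otherwise
*plexus*. The origin is the foreground centre of mass by default (flat
fixtures use the +z axis instead). Open choices resolved here:

* **Vote fusion.** With stride = window/2 a voxel is covered by up to 8
  windows; each foreground voxel takes the majority of sprout/plexus votes,
  ties and ambiguous-only coverage defaulting to plexus (conservative toward
  the dominant class).
* **Ambiguity.** Windows whose anisotropy ratio λ₁/λ₂ falls below 2.0 —
  typically bifurcations or crossings of differently oriented vessels, where
  a single principal axis is meaningless — vote *ambiguous* and never force
  a sprout call.
* **Sign.** Vessel orientation has no sense, so |cos θ| is used and
  θ ∈ [0°, 90°].

On the hemisphere, the centre-of-mass origin sits on the axis about half a
radius above the sphere centre, which misestimates the radial direction by
up to ~26° at the rim; the margins to the 35° cutoff (sprouts) and to
90° − 35° (plexus) absorb this, which is why the method works with the
paper-style data-driven origin.

The sprout volume fraction is sprout voxels over all foreground voxels; it
is undefined (an error, not 0) on an all-background volume.

## Validation

Per-class agreement uses the Dice coefficient DSC = 2|X∩Y|/(|X|+|Y|)
(both-empty = 1). Multi-class agreement uses the generalized Dice
coefficient with inverse-square-volume weights ω_i = 1/|X_i|² taken from the
ground-truth labels, over the foreground classes only — including background
would saturate the score on sparse vasculature. Classes empty in both
volumes are skipped; a class empty in the truth but present in the
prediction is weighted by its predicted size so spurious classes are
penalised instead of dividing by zero. A window-size × cutoff-angle sweep
(`sweep_gdc`, stride = window/2 unless overridden) reports GDC and per-class
DSC per parameter pair and the argmax row.

## Study design and statistics

`run_study` reproduces the comparison design: n = 5 retinas per group,
central / middle / peripheral regions split at equal radial thirds of the
distance from the optic-disk axis (half-open boundaries; the exact ring
radii are configurable since they are not anatomically fixed), and 5 VOIs
per region. VOIs are boxes with a 250 µm footprint and 200 µm thickness
along the local depth axis (the local radial direction on the hemisphere,
+z in flat mode); thickness-along-depth is the natural reading for a curved
retina and reduces to axis-aligned boxes in flat mode. Placement is uniform
per shell area within the region, without an overlap constraint.

The design is **paired**: OIR sample *i* is the perturbed twin of normoxia
sample *i* (same generator seed), so a zero-probability perturbation yields
literally identical cohorts, and the perturbation effect is not confounded
with lattice realisation noise. Between-animal variability — which dominates
the spread of dimensionless local metrics in real littermates — is emulated
by per-sample lognormal factors on `chord_rate` (CV 0.4) and
`sprout_density` (CV 0.15); without it, seed noise alone (~5–10 % CV) would
be unrealistically tight.

Two groups are compared with the unpaired two-tailed Student's t-test
(pooled variance; Welch available by flag), three or more with one-way ANOVA
plus Tukey HSD, significance at p < 0.05, no further multiplicity
correction. The regional homogeneity ANOVA uses one VOI per region per
normoxia animal (n = 5 per region), matching the design it emulates.
Identical constant groups (t = 0/0) are reported as p = 1. A full run with a
fixed master seed is bit-reproducible (`StudyReport.report_hash()`).

Problem sizes: the default study voxelises each retina at 4 µm (≈ 500² × 250
voxels, ≈ 1.6 × 10⁵ foreground) and runs the full segmentation per sample;
a complete 5-vs-5 study takes about a minute on one core.

## Known limitations

* χ from the voxel route counts cavities (none arise from capsule unions)
  but does not separate loops from components; no Betti decomposition.
* The skeleton-to-graph extractor is a minimal stand-in for interactive
  filament tracing: it assumes tubular foreground whose thinning yields
  clean 1-voxel chains. Even-diameter, exactly grid-symmetric tubes can be
  erased entirely by the underlying 3-D thinning; realistic (odd or
  off-grid) calibres are handled correctly, and radius estimates from the
  distance transform are upper-biased by about half a voxel.
* Segmentation quality degrades when windows mix differently oriented
  vessels; smaller windows reduce mixing but destabilise the orientation
  estimate. The 40/20/35° defaults are the validated operating point.
* The generator's OIR deletion probabilities are calibrated to the
  qualitative obliteration pattern (secondary/sprout loss everywhere,
  partial central primary loss), not fitted to measured dropout rates.
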