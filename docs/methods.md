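# Methods

This note documents the models, numerical choices and limitations behind
`scmst`, a reimplementation of a single-cell multiplex spatial
transcriptomics (scMST) analysis pipeline: serial single-molecule FISH
rounds on embryo cross sections, five genes per six-channel round, decoded
into per-cell transcript counts and clustered into ectodermal
subpopulations.

## The phantom: what it emulates, and what it does not

No imaging data ships with the package. Every end-to-end guarantee is
established on a synthetic acquisition (`scmst.phantom`) that mimics the
structure of the real experiment with complete ground truth:

- **Geometry.** 2 embryos x 3 fields of view (FOVs) of (12, 192, 192)
  voxels at (0.5, 0.25, 0.25) µm — a desk-scale miniature of the real
  sections (z-planes every 0.5 µm; lateral sampling coarsened and the FOV
  shrunk so the full suite runs in minutes on one CPU). ~50 cells per FOV.
- **Tissue.** A smoothly curving band (an idealized ectoderm section)
  tessellated into connected, Voronoi-like cells: blue-noise seed points
  grown by watershed on the anisotropy-scaled distance to the nearest seed.
  The band keeps a lateral margin larger than the maximum stage shift so
  every planted transcript stays inside all rounds' fields of view.
- **Expression.** Four subpopulations — three committed ectodermal domains
  (CNS, neural plate border, non-neural ectoderm) and a stem group
  co-expressing the pluripotency genes (*Nanog*, *PouV*, *Klf4*) — with a
  30-gene panel. Counts are Poisson per cell x gene with subpopulation
  means (default 8 for expressed genes, 0.2 baseline); a negative-binomial
  option exists for robustness experiments. Expressed-vs-baseline effect
  sizes are deliberately strong: the phantom validates the pipeline's
  plumbing, not its power at marginal effect sizes.
- **Optics.** Each transcript renders as a Gaussian PSF blob
  (sigma = (1.0, 1.3, 1.3) voxels). Dot amplitudes follow three classes:
  true signal (mean 1000, sd 80), non-specific binding (300 ± 60, scattered
  at 1e-4/voxel) and artifacts (3500 ± 400 at 8e-6/voxel) — separations far
  above 4 sd, so intensity triage is well-posed by construction. A smooth
  multiplicative illumination field (±25%), a camera baseline of 100 with
  +60 tissue autofluorescence, and read noise (sd 5) complete the image
  model. Dots of one channel are placed with a minimum separation slightly
  above the detector's suppression footprint, i.e. the phantom contains
  only *individually resolvable* transcripts. Real data has unresolvable
  doublets; passing tests therefore bound detector performance on
  resolvable dots only.
- **Acquisition artifacts.** Integer per-round stage shifts (|z| ≤ 1,
  |y|,|x| ≤ 8 voxels), a final immunostaining round carrying the membrane
  composite, and an optional repeated first-round hybridization with 80%
  transcript survival for the signal-recovery QC. The nuclear reference
  stain occupies channel 0 of every round so rounds can be registered.

Determinism: every FOV draws its RNG stream from
`(rng_seed, embryo, fov)`, so acquisitions are byte-reproducible and FOVs
are independent.

What the phantom does **not** model: camera-calibrated noise, subvoxel dot
positions, optical aberrations or depth-dependent PSFs, stripping
inefficiency between rounds, segmentation-hostile tissue (touching nuclei,
weak membranes), or cells spanning FOV borders beyond what edge-dropping
removes.

## Pre-processing

Order is fixed: flat-field correction, then a 3x3x3 3D median filter.

The flat-field estimator replaces low-rank/sparse decomposition with a
robust surrogate: the per-pixel median across z (and across FOVs when
several are supplied) is Gaussian-smoothed and normalized to mean 1. The
smoothing scale defaults to **half the image footprint**: at that scale the
estimate retains only the lowest-frequency multiplicative trend and
suppresses specimen structure (the tissue band otherwise bleeds into the
baseline and spatially biases corrected dot intensities, widening the
intensity classes that triage must separate). Since diffraction-limited
dots are sparse, the median projection is insensitive to them. The field is
clipped to be strictly positive; correction is voxelwise division.

The median filter uses edge replication at borders (the choice is
documented, not prescribed by the original description).

## Inter-round registration

The original workflow aligned rounds manually by visual inspection; here it
is automated as exhaustive normalized cross-correlation of the nuclear
reference channel over integer shifts within ±(2, 8, 8) voxels, computed
via FFT. Ties break toward the smaller absolute shift, lexicographically in
(z, y, x). Subvoxel registration is out of scope, matching the
whole-coordinate choice of the manual procedure. On the phantom (dot SNR
well above 3) recovery is exact for every planted shift.

## Dot detection and K-means triage

Detection is deliberately permissive — quality control is triage's job, not
the detector's. Candidates are local maxima of a difference-of-Gaussians
response (sigma = PSF, 2x PSF), separated by at least 1.5 sigma per axis
(anisotropy-aware footprint), above the 0.95 quantile of the response. The
floor quantile was chosen so that even dim non-specific dots are detected
on gene-dense channels: a higher floor adapts to the channel's dot density
and silently removes the dim class that K-means needs to see in order to
reject it.

Each dot is summarized by two features over its one-sigma ellipsoidal
support (7 voxels at the default PSF): **mean intensity** and **intensity
variability** (population sd; max−min available via config). Features are
computed on corrected but unfiltered volumes; detection runs on the
median-filtered ones.

Triage runs per gene (dots pooled across the section's FOVs): K-means with
10 restarts on standardized features, fit on a canonically sorted copy so
results are independent of dot ordering. The default k is 3 (the three
intensity classes); a silhouette-based selector with an elbow diagnostic is
available and any config override wins — mirroring the original pipeline's
admission that automated criteria needed manual oversight. The retain rule
("middle band") rejects the cluster with the dimmest mean-intensity
centroid (non-specific binding), any cluster whose centroid exceeds the
0.995 intensity quantile, and the cluster with the largest variability
centroid when it exceeds twice the median centroid variability (artifacts);
everything else is kept. If the rules reject every cluster, the largest
non-dim cluster is kept and a warning recorded.

Known limitation: on channels whose gene is essentially unexpressed
(a few dozen true dots among hundreds of noise-floor maxima), three
clusters cannot represent the four real populations and the kept set for
that gene can be wrong. The aggregate recall/precision guarantee (≥ 0.95)
holds because such channels carry few true dots by definition; per-gene
diagnostics expose them for manual k override, which is exactly the manual
escape hatch the original procedure kept.

The signal-recovery QC triages the repeated first round together with the
original first round and reports per-gene and overall kept-dot ratios;
the run fails QC below 0.70.

## Segmentation and counting

A classical seeded 3D watershed replaces the original's learned segmenter
in the same role: seeds are local maxima of the smoothed nuclei channel
(minimum spacing ≈ 0.8 cell radii, anisotropy-aware), the elevation map is
the smoothed membrane composite, and flooding is restricted to a tissue
mask (Otsu on the combined smoothed signal, morphologically closed at the
cell-radius scale, holes filled — the tissue's autofluorescence makes this
threshold well-defined). Components below 40 voxels are pruned and labels
made contiguous. Cells touching a lateral border are dropped by default
(partial cells bias counts); FOVs are never merged — consistent with the
source workflow, which analyzes FOVs independently and stitches only for
display.

Dot-to-cell assignment maps each kept dot through its round's registered
shift into the reference frame and reads the label at its centroid voxel
(centroid membership rather than majority-of-support: dots are
single-voxel scale). The count matrix is an AnnData (cells x genes,
integer) whose total equals the number of assigned kept dots exactly;
zero-count cells are retained and flagged.

## Normalization, clustering, selection

Counts are z-scored gene-wise in two passes on raw integers (no log
transform by default; `log1p` is a config option): first within each
embryo across its FOVs' cells, then again across the pooled embryos of a
stage. Cross-stage comparison pools the cells of all stages and applies a
single gene-wise z-score — a within-embryo first pass would remove exactly
the between-stage level differences that mode exists to expose. Sample
standard deviation (n−1) throughout; a zero-sd gene/group maps to z = 0
(keeping cells rather than dropping genes).

Cell clustering is agglomerative with cosine distance
d(u, v) = 1 − u·v/(|u||v|) and average linkage (configurable); genes are
clustered the same way for two-dimensional heatmap ordering. Distance with
an all-zero vector is defined as 1. The cluster count k is a per-stage
config input — the original chose cluster counts by heatmap inspection, so
no automatic k is imposed.

Co-expression selection takes the cells with z **strictly** greater than 0
for every gene of a set (intersection of per-gene filters); selections are
therefore monotone decreasing in the gene set. Overlap statistics between
selections and per-stage compositions (counts, percent of stage, percent of
selection at one decimal) are exact tabulations.

## Visualization

Back-mapping paints each cell's voxels with its group color (gray for
unanalyzed cells, black background) and projects along z by per-pixel label
majority (ties to the smaller label); it is a pure view and cannot alter
analysis outputs. Stitching pastes FOVs at supplied offsets (the original
used microscope stage positions; offsets are config inputs, not estimated)
with last-wins or error-on-overlap policies.

## Pipeline and reproducibility

`scmst run` validates its YAML config against a strict schema (unknown keys
rejected) before any stage executes, runs the stages in fixed order, and
writes per-stage artifacts plus a manifest with SHA-256 hashes. All
randomness flows from config seeds; re-running a config reproduces count
matrices, cluster labels and selections byte-identically. Problem sizes in
the test suite (one embryo section for imaging-level checks; two embryos
for expression-level checks; slightly reduced volumes for the double-run
determinism check) were chosen so the whole suite completes in a few
minutes on a single CPU.

## Probe design

Probes are 60 nt: the reverse complement of a binding site, a 4-nt linker
(sequence "AAAA"; only the length is prescribed by the source), and an HCR
initiator (B1–B5). The binding length is derived (60 − 4 − initiator
length); with the default 36-nt initiators the binding segment is 20 nt.
The exact binding/initiator split of the 60-mer is an assumption — it is
configurable, and the bundled initiator sequences are deterministic
synthetic stand-ins (the real amplifier sequences are kit-proprietary);
supply validated sequences for actual probe orders. Tiling is greedy left
to right: non-overlapping sites at least 2 nt apart passing GC bounds
[0.35, 0.70], capped at 24 probes per gene, warning (or failing, in strict
mode) below 13. Initiators are assigned per round so genes sharing a round
never share an initiator. Split-initiator (v3.0-style) probe pairs and
off-target screening are out of scope.
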