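# Methods

This note documents the models, parameter choices and numerical
conventions behind `raftscreen`, and what the synthetic data does and
does not establish about real screens.

## The screening model

A screen is a set of plates, each holding wells of cells on a microraft
grid. Wells are *labeled* (pure WT or pure mutant populations used for
training and testing) or *unlabeled* (admixtures whose per-cell genotypes
are unknown but whose expected WT:mutant proportion is known — the
"meta-feature"). Each imaged cell contributes a feature vector; a binary
classifier ensemble is trained on labeled wells, one model is selected,
and the rafts carrying the most confidently scored unlabeled cells are
picked and genotyped by amplicon sequencing. The genotypes are the
validation: model quality is measured *after the fact* as the agreement
between prediction and sequence.

The classifier operates per cell, so the method presumes the phenotype is
cell-autonomous and expressed at imaging time. Models are binary (WT vs
pooled mutants); per-mutant multiclass training is deliberately out of
scope, matching the screening design where mutant identity is only known
after sequencing.

## Synthetic-data generator

The generator (`synthdata`) emulates the screening inputs with known
ground truth. Defaults define the standard study conditions and were
chosen once:

* **Layout** — 2 plates × 4 wells: 3 labeled-WT and 3 labeled-mutant
  wells interleaved across plates (so a well-wise split can always train
  on two plates), plus unlabeled admixtures at 50:50 and 90:10
  WT:pathogenic. This mirrors the canonical mixing design for an
  *MFN2*-type experiment with four pathogenic variants (L76P, R94Q,
  P251A, R280H) against WT.
* **Cells** — 300 cells/well by default: a desk-scale stand-in for the
  tens of thousands of imaged cells in a real screen, large enough for
  stable AUCs per well and small enough that the full grid trains in
  seconds.
* **Features** — 170 features (the approximate size of a commercial
  high-content feature catalog), of which 12 are informative: pathogenic
  cells receive a standardized mean shift of `effect_size` (default 1.0,
  which places the selected model's held-out AUC near 0.9 — discriminable
  but overlapping, the regime the platform targets). Noise is multivariate
  normal with pairwise correlation 0.3 inside blocks of 5 features;
  block correlation reproduces the redundancy of real morphology features
  while keeping closed-form expectations for tests.
* **Batch effects** — each plate adds a per-feature offset ~ N(0, 0.5²).
  Because labeled training and testing wells are distinct wells, this
  creates the train/test distribution skew that makes the train−test AUC
  gap informative about overfitting.
* **Leaky features** — 2 features are near-exact copies of the well
  column index (noise SD 0.01). They model "global" position-proxy
  features and give the leak detector a guaranteed positive control.
* **Debris** — 5% of records get small, dim, irregular nuclei, outside
  every morphology gate.
* **Raft occupancy** — truncated Poisson(1.8) on 1..10 cells per raft,
  which exercises the crowded-raft (>6) gate and multi-cell conflict
  vetoes. 2% of rafts carry fiduciary marks.
* **Amplicon reads** — for each captured raft and panel locus, each
  member cell emits 30 read pairs. A mutant cell's reads at its own locus
  carry the mutant 20-mer with a per-cell probability drawn from
  Beta(8, 2) (mean 0.8): cDNA-overexpression lines retain endogenous WT
  signal, so the >50% call rule is non-trivially exercised. The true
  allele composition of such lines is not established; Beta(8, 2) is a
  stand-in, not a measured value. 20% of rafts are lost before
  sequencing (`capture_rate` 0.8), matching the ~80% genotype capture
  typical of single-cell isolation plus amplification. Per-base
  substitution errors default to 0.001.
* **Images** — nuclei as smooth blobs, mitochondrial puncta placed at
  radii ~ N(`aggregation_um`, sd) around each nucleus; the pathogenic
  setting uses a small radius (perinuclear aggregation), WT a large one.
  Raft walls and fiduciary squares are drawn in both channels.

One master seed drives everything through `numpy.random.SeedSequence`
child streams at fixed spawn indices, so identical configurations produce
byte-identical tables, images and FASTQ (gzip written with `mtime=0`).

**What passing tests do not show.** The generator's features are
Gaussian with a shared shift; real morphology features are skewed,
heteroscedastic and nonlinearly entangled with cell cycle and density.
Its batch effects are additive; real ones also alter scale and
correlation structure. Its reads have uniform quality and substitution
errors only (no indels, chimeras or index hopping). Success here
establishes the *correctness of the machinery* — splits, leak exclusion,
calibration, counting, calling — not the attainable accuracy on any real
cell line.

## Imaging front-end

The feature extractor is a deliberately parameter-light stand-in for
commercial tracing software, and equivalence with any commercial catalog
is not claimed. Nuclei: per-field Otsu threshold (no training data
needed), hole filling, connected components; objects report area,
perimeter, form factor 4πA/P², and intensities. Puncta: difference of
Gaussians at scales σ and 3σ (σ ≈ punctum radius), peak detection above
median + 5·MAD of the filtered image; each punctum is assigned to the
nearest nucleus if within 20 µm of its boundary (approximated as
centroid distance minus the equivalent-disc radius), else discarded.
About 30 features are produced rather than the full 170-feature
commercial catalog.

Raft calibration fits an affine map from stage coordinates to grid
indices by least squares on fiduciary marks (≥3 non-collinear points
required). Raft IDs are four-character codes; each axis encodes index
*i* as letter `'A' + i//10` plus a digit cycling 1..9,0, so (0,0) →
"A1A1". The instrument's own encoding is not public; any fixed
invertible scheme serves, and this one is documented and bit-stable.
Detections in the 12% field-overlap margins are de-duplicated by
nearest-centroid matching.

## QC and normalization

The fixed order is gates → leak exclusion → per-plate normalization.
Gate variables are nuclear area, form factor, nuclear and cell intensity,
distance to raft edge (default margin 5 µm), raft occupancy (> 6 cells
rejected) and fiduciary status. The literature gives gate *variables*
but not numeric thresholds, so defaults are placed at the [1%, 99%]
quantiles of a reference table of live nuclei and are fully
config-exposed. Rejected records are logged with the first failing gate
in alphabetical reason order (deterministic logs).

Normalization is per plate and feature: subtract the median, divide by
the σ-consistent MAD. MAD was chosen over mean/SD for robustness to
residual debris; it also replaces multi-dataset integration methods
(screen-scale batch harmonization is out of scope) — a documented
departure. Zero-MAD features are flagged constant and excluded from
modeling rather than raising. The transform is idempotent to
floating-point error.

Leak screening flags features whose rank-based association with well
identity is strong: Kruskal–Wallis η² = (H − k + 1)/(n − k) across wells
above 0.5, or features constant within every well but varying across
wells, plus any user-listed names. The 0.5 cutoff is far above the null
(η² ≈ 0 for hundreds of cells per well) and below a true position copy
(η² ≈ 1).

## Modeling

* **Split** — well-wise by default: per class, 2 labeled wells to
  training (on distinct plates when possible), the rest to testing;
  wells are never split, so batch effects cannot leak across the split.
  A randomized 80–20 cell split is available for screen mode.
* **Balancing** — SMOTE-style synthetic minority oversampling: new
  points p + u(q − p), u ~ U(0,1), q among the k = 5 nearest minority
  neighbors, until counts are equal. A singleton minority class is
  duplicated verbatim (degenerate fallback).
* **Feature selection** — five methods: variance floor, greedy
  correlation pruning (keep the higher-variance member of each |r| >
  0.95 pair), uniform random subsets (sizes 2–16), top-k ANOVA F, and
  nonzero coefficients of an L1 linear SVM.
* **Grid** — 3 algorithms (logistic regression, ridge classifier, linear
  SVM) × 3 regularization strengths × ~18 feature subsets ≈ 162 models
  by default, mirroring the few-hundred-model scale of real runs.
  Margin classifiers are squashed through a logistic so every model
  meets the score contract (0 = confident WT, 1 = confident mutant).
  Singular or failed fits are flagged and excluded from selection.
* **Meta-feature** — per unlabeled well, the predicted positive fraction
  is the share of cells scoring > 0.5 after dropping scores in
  [0.4, 0.6] (consistent with the pick-time exclusion band); the meta
  deviation is the mean absolute error against the expected proportions.
  A well whose scores are all excluded contributes the worst case 1.0.
* **Selection** — real screens select the pick model semi-manually; a
  deterministic stand-in is used here: among models within δ = 0.02 of
  the best test AUC, prefer the smallest train−test gap, then smallest
  meta deviation, then fewest features, then lowest spec hash. The rule
  is config-overridable and every term is exported per model.

## Anomaly detection (screen mode)

Detectors are fit on control cells only. Each detector draws a random
subset of 8 features and stores their control median and σ-scaled MAD;
its raw score for a cell is the Euclidean norm of the robustly
standardized subset. The published screening workflow does not name its
detector algorithms; this family was chosen for determinism and
analyzability, and the scoring layer accepts any detector exposing raw
scores. A cell's anomaly score counts the detectors placing it in the
top 5% (and 10%) *of all scored cells* — thresholds are population
percentiles of the deployment set, not of the controls — with ties at a
threshold falling below it (strict inequality). By construction the
control-only flag rate is 5%/10% and n_top5 ≤ n_top10 always.

## Picking

Per raft the score is the mean over member cells; a raft is vetoed if
two members conflict confidently (one ≤ 1 − t while another ≥ t, default
t = 0.8) or if the mean lies inside the open band (0.4, 0.6) — boundary
scores stay eligible. Survivors are ranked by |score − 0.5| with raft-ID
tie-breaks, the top n per predicted class are taken, and destinations
are assigned row-major A1..H12 across 96-well plates, with optional
labeled-well control rafts interleaved every 8th slot. Multi-cell raft
handling (mean + veto) is a design decision; the source workflow picks
"cells (rafts)" without specifying it.

## Genotyping

Read pairs are 3'-quality-trimmed (floor Q10), merged on the largest
overlap ≥ 20 bp with mismatch rate ≤ 0.1 (disagreements resolved by base
quality), and adapter tags are stripped by exact prefix/suffix match;
unmergeable pairs contribute both mates to counting. Fragment counting
is exact 20-mer substring search on both strands, at most one increment
per read per fragment — exactness keeps the caller auditable, and the
panel fragments are designed to be discriminating. Per locus, %mutant =
mutant/(mutant + WT) reads; loci under 10 reads are ignored (a
config-exposed depth floor added to forbid single-read calls); a well is
WT iff no informative locus exceeds 50%, otherwise the unique
argmax-locus mutant (ties within 1e-9 → ambiguous; no informative locus
→ no-data). The depth floor, tie policy and zero-mismatch matching are
documented decisions where the published description is silent.

gRNA identification extracts the spacer between the U6/scaffold vector
flanks on either strand, exact-matches it against the library, and
assigns the majority spacer; wells where two spacers each hold ≥ 20% of
spacer reads are reported multi-infected.

## Evaluation

Predictions join genotype calls on the destination well; ambiguous and
no-data calls, and scores inside [0.4, 0.6], leave the metrics. ROC/AUC
use the rank statistic with tie credit ½; noise baselines are built by
shuffling genotype labels. Confidence-band metrics restrict to scores
≥ b or ≤ 1 − b for b ∈ {0.7, 0.8, 0.9}. Per-gRNA significance is a
one-sample *t* test against the control-cell median score (the null
value is unreported in screen descriptions; the control median is the
default and is config-overridable), corrected by Benjamini–Hochberg
step-up at FDR 0.2 — the only multiple-testing correction applied
anywhere. Replicate reproducibility deems a gRNA measurable with ≥ 3
cells in ≥ 2 replicates and reproducible when the sign of (replicate
mean − replicate median score) agrees across its replicates — a
documented stand-in for an unreported criterion. The frameshift
comparison is a two-sided rank-sum test of anomaly scores above vs
below each frameshift-probability threshold; the test family is a choice,
as published threshold-wise p-values do not name one.

## Numerical conventions

Scores are float64 throughout; AUC ties get exactly 0.5 credit; MCC uses
the 0.5 threshold. All stochastic steps take explicit seeds, and
stage-level outputs are deterministic given (config, seed): tables are
written with fixed column order, gzip streams with zero mtime, and
manifest digests verify reruns. Degenerate cases are handled as data,
not exceptions, wherever a screen could plausibly produce them (constant
features, empty wells, all-excluded score sets, zero-read wells).

## Problem sizes

The test suite and acceptance script run the generator at desk scale:
8–16 wells of 60–300 cells (up to ~4,800 cells per experiment),
162-model grids, 100–500 picked rafts, 20–30 read pairs per cell and
locus, 10,000 cells × 100 detectors for anomaly calibration. These sizes
were chosen so every statistical property they probe (binomial bounds,
AUC windows, calibration rates) has adequate power while a full run of
everything stays in the minutes range.

## Known limitations

* The feature model is linear-Gaussian; nonlinear phenotype structure
  (which would favor the SVM/nonlinear members of a real grid) is not
  represented.
* Indel-aware alignment is absent by design: a real edited locus can
  escape both 20-mers, which this caller reports as reduced depth rather
  than as an edit.
* The anomaly ensemble detects radial outliers in feature space;
  anomalies expressed purely as altered feature *correlations* at normal
  marginals are invisible to it.
* Published headline accuracies from real cell lines are not
  reproducible here — the cells, images and sequencing runs behind them
  are not deposited — and appear only as qualitative patterns on
  synthetic data (e.g. accuracy rising with confidence band).
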