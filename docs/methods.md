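# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the limitations of `histotx`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The prediction problem

Intrahepatic cholangiocarcinoma admits five transcriptomic classes —
hepatic stem-like, tumour classical, inflammatory stroma, immune classical,
desert-like — defined on bulk RNA by signature scoring. The imaging task is
weakly supervised: a class label attaches to a patient (via one RNA-profiled
block), patients contribute several slides, and nothing marks which tiles of
a slide carry class-relevant morphology. The package treats each class as a
one-vs-rest binary task, with the hepatic stem-like class (the most
prevalent, ~37%) as the default target.

## Slide pre-processing

Tissue detection converts the slide to grey by the unweighted channel mean,
takes the 256-bin histogram, and applies Otsu's criterion: the threshold
`t` maximizes the between-class variance of the split `[0, t) / [t, 256)`,
with ties resolved to the lowest maximizing level (plateaus are exact in
real arithmetic, so the tie rule uses a 1e-9 relative tolerance). Tissue is
the darker class; background is assumed bright. A uniform image has no
threshold and raises an error rather than returning a degenerate mask.

Tessellation enumerates the regular non-overlapping grid anchored at pixel
(0, 0); partial cells at the right/bottom margins are clipped, never padded.
A grid cell is a tissue tile when its tissue fraction is ≥ 0.5 (the
`min_tissue_fraction` default; the value is a choice, not an inference — no
border-patch rule is prescribed by the task). The three ROI protocols are
restrictions of the tissue grid:

* **none** — every tissue tile;
* **mask** — tissue tiles whose tumour-annotation fraction is ≥ 0.5
  (`min_tumour_fraction`, same status as above); a slide whose annotation
  overlaps no tile at that threshold keeps its single highest-fraction tile
  (guard for small tumours at coarse grids), and a slide with no annotated
  tumour at all is an error;
* **learned** — tiles accepted by an L2 logistic tumour/non-tumour
  classifier trained on a labelled tile sample capped at 3,000 tiles,
  probability cutoff 0.5.

Synthetic slides are treated as already at working magnification; the
tessellation unit in the pipeline defaults to 112 px on 448-px slides (a 4×4
grid), keeping the grid geometry of 224-px patches at half scale.

## Tile descriptor and slide embedding

No pretrained encoder is used anywhere; tiles are summarized by a
deterministic 64-dimensional handcrafted descriptor: per-channel mean and
standard deviation (6), 8-bin per-channel intensity histograms (24), an
8-bin gradient-magnitude histogram (8), and 26 grey-level co-occurrence
summaries (contrast, dissimilarity, homogeneity, ASM, energy, correlation at
4 offsets on a 32-level quantization, plus co-occurrence entropy and
grey-level entropy). The descriptor is position-independent and its
histogram blocks are invariant to dihedral transforms.

The slide representation honours the ensemble-then-normalize contract of
view-ensembled self-supervised slide encoders: a *view* is a random
ceil(25%) subset of the kept tiles with an independent random dihedral
transform per tile, mean-pooled; 100 views are averaged and the result is
L2-normalized to unit norm. View construction inside such encoders is not
public contract, so this definition is a transparent, seedable stand-in:
what is preserved is (i) ensembling over 100 randomized views, (ii) mean
pooling within a view, (iii) final L2 normalization. Per-slide featurization
caches (tile, transform) pairs, bounding work at 8 featurizations per tile
regardless of the number of views.

## Classification heads and evaluation

End classifiers are scikit-learn logistic regressions with L2 penalty,
C = 7, max_iter = 10,000 and balanced class weights. Cross-validation uses
K = 5 folds stratified on the binary output *at the patient level*; every
slide of a patient lands in one fold (asserted at run time on every split),
and the identical fold plan is reused across protocols and model families so
comparisons share train/test partitions. Slide-level metrics (AUC, balanced
accuracy at threshold 0.5, macro-F1) are reported per fold as mean ± sd;
patient-level metrics pool the out-of-fold probabilities after averaging
each patient's slides (the mean is the simplest order-preserving
aggregation; the slide-to-patient rule is otherwise unconstrained).
External inference averages the probabilities of the five fold models.

## Attention MIL baseline

The MIL baseline is the gated attention construction: instance scores
`s_k = wᵀ(tanh(V h_k) ⊙ σ(U h_k))`, attention `a = softmax(s)`, bag vector
`z = Σ a_k h_k`, logistic head on `z`. Hidden width 64, single attention
head. Training minimizes binary cross-entropy with Adam (learning rate
1e-3, 30 epochs, batch size 8) on analytically derived gradients; the test
suite checks the gradients against central finite differences and the exact
permutation/duplication invariance of the forward pass. Bags are built from
the kept tiles of the active ROI protocol, one bag per slide, labelled with
the patient's one-vs-rest class; instance features are standardized with
training-fold statistics.

## Synthetic cohort generator

The generator produces the statistical structure the downstream analysis
assumes, not photorealistic histology.

**Patients and slides.** Class prevalences default to
(0.37, 0.13, 0.21, 0.25, 0.04); the two extreme values follow the reported
discovery-cohort frequencies of the hepatic stem-like and desert-like
classes, and the remaining mass is split plausibly across the other three
classes (per-class discovery counts are not all reported; these defaults
are flagged approximate and configurable). A patient is a biopsy case with
probability 0.3 (one small-strip slide, RNA+) or a surgical case with
Uniform{1..5} slides (first slide RNA+, the rest RNA−). Biopsy strips are
painted strictly smaller than the surgical tissue minimum (30% of the
canvas).

**Slide painting.** Background is near-white; tissue is an ellipse
(surgical) or strip (biopsy); a tumour disc covering a configurable fraction
of the tissue (default 0.3–0.6) is recorded pixel-for-pixel as the
ground-truth mask. Tumour texture is the class signal: each class has a
canonical hue offset, dot density (immune infiltrate motif) and streak
density (fibrosis motif) relative to a shared base; `texture_effect` scales
all class-specific deviations, so 0 yields class-identical tumours. The
motif vocabulary mirrors the histological correlates of the classes
qualitatively — dense basophilic dots for the immune classical class,
streaks plus dots for inflammatory stroma, a pale cell-poor palette for
desert-like.

Three nuisance structures make the cohort behave like a weakly-supervised
problem rather than a template-matching exercise:

1. *Within-class heterogeneity*: each slide's tumour additionally jitters
   its hue (±12 per channel) and motif densities (±0.005), bounding the
   class signal-to-noise at slide level regardless of tile count.
2. *Stromal heterogeneity and mimicry*: the non-tumour compartment is
   class-independent but varies per slide; on 60% of slides it adopts the
   full tumour palette (hue and motif densities) of a *random* class — the
   analogue of normal parenchyma resembling hepatic stem-like tumour or
   reactive stroma resembling the fibrotic classes. This is the structure
   that makes ROI filtering matter: without it, every protocol is
   equivalent and the protocol comparison the pipeline exists to run would
   be vacuous.
3. *Imperfect tile-level tumour-ness*: per-slide pixel-noise scales are
   drawn from overlapping ranges (tumour 8–14, stroma 6–13), so micro-
   texture distinguishes the compartments statistically but not per tile.
   A supervised filter trained on thousands of labelled tiles recovers the
   boundary well; bag-level supervision recovers it only partially.

Under these conditions the tumour-ROI protocol outperforms no filtering for
both model families. The effect is large for the embedding + head route and
directional-but-small for attention MIL, whose instance weighting actively
compensates for dilution; the MIL contrast is accordingly the most fragile
quantity the acceptance script reports (its sign can flip on individual
cohort replicates, and the fixed-seed tests average it over three).

**Expression.** Genes (default 2,000) carry log-scale means Uniform(1, 4);
a sample's value is `round(exp(N(μ_g + Δ·1[gene ∈ own signature], 1)))`
with Δ = `expression_effect`; entries drop to zero independently with
probability `dropout_rate` (default 0.2). Five disjoint signatures of 50
genes are planted and shipped as a GMT file. A log-normal-rounded model was
chosen over a negative binomial for transparency; the signature classifier
uses only rank/mean structure, so the tail family is immaterial here.

**Survival.** Event times are exponential with per-class hazards whose
medians (49, 21, 31, 43, 43 months) reproduce the direction of the reported
contrasts: best survival in hepatic stem-like, worst in tumour classical
and inflammatory stroma. Censoring is independent exponential with its rate
set so the marginal censoring probability equals `censor_rate` (default
0.3); `censor_rate = 1` yields an all-censored cohort on which the log-rank
test correctly refuses to run.

## Statistics toolkit

Chi-squared is Pearson's statistic without continuity correction — the
convention validated by recovering the printed three-decimal p-values of
the cohort-description tables (immune infiltration 0.011, sex 0.099, well
differentiated 0.253, moderately differentiated 0.426). Fisher's exact test
is two-sided by the point-probability rule (sum of hypergeometric
probabilities ≤ the observed table's), validated against the printed
primary sclerosing cholangitis p-value (0.035) and full enumeration. When a
2×2 table has any expected cell below 5 the helper `choose_categorical_test`
prefers Fisher, else chi-squared. Student's t is the pooled-variance
two-sided test; a zero-variance comparison with equal means returns p = 1
and with unequal means is an error. Kaplan-Meier and the (multi-group)
log-rank test are delegated to lifelines behind the module surface, with
hand product-limit arithmetic and a permutation null as independent test
oracles. Cox hazard ratios are deliberately out of scope.

## Problem sizes and determinism

Every generator and training is deterministic given its seed; slide
embeddings derive per-slide seeds from a base seed and the slide's sorted
index. The shipped experiments use desk-scale sizes chosen to exercise the
full pipeline in minutes on one CPU: 60-patient cohorts (~130–150 slides)
for pipeline experiments, 448-px slides with 112-px tiles (4×4 grid),
100 views per slide, 200-sample expression cohorts, 100 replicates for
power estimates.

## Limitations

* The synthetic textures are low-dimensional; passing tests demonstrate the
  pipeline's correctness and the qualitative protocol/effect structure, not
  performance on real histology. Real-cohort AUCs and survival medians are
  not reproducible without the original slides and are not targeted.
* Stain simulation (H&E vs HES) is out of scope; colour normalization and
  WSI container parsing (SVS/NDPI pyramids) are not implemented.
* The learned filter and the MIL model see the same 64 descriptor
  dimensions; their contrast therefore reflects supervision strength, not
  encoder quality.
* The published signature gene lists are not redistributed; the GMT shipped
  with a synthetic cohort contains planted synthetic signatures.
* Quantile normalization operates on the matrix as provided; whether it
  precedes or follows any log transform is the caller's responsibility.
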