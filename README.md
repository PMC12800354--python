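# histotx

Predicting intrahepatic cholangiocarcinoma (iCCA) transcriptomic classes from
whole-slide histology, at desk scale.

iCCA tumours fall into five expression-defined classes — *hepatic stem-like*,
*tumour classical*, *inflammatory stroma*, *immune classical* and
*desert-like* — that carry prognostic information but normally require RNA
sequencing to call. `histotx` implements a weakly-supervised imaging pipeline
that predicts these classes from routine histology slides, together with the
RNA-side classifier that defines the labels and the cohort statistics used to
describe such studies. A built-in synthetic cohort generator (slides with
ground-truth tumour masks, class-structured expression counts, survival
times, clinical covariates) makes every stage testable end to end without any
external data.

## What is implemented

**Imaging pipeline.** Tissue is detected by Otsu thresholding on the grey
channel mean and exhaustively tessellated into non-overlapping square patches
(default 224 px). Three region-of-interest protocols decide which tiles feed
the models: *no filter* (all tissue tiles), *mask filter* (tiles overlapping
a tumour annotation), and *learned filter* (a logistic tumour/non-tumour tile
classifier trained on a 3,000-tile labelled sample). Each slide is embedded
by ensembling 100 randomized *views* — random 25% tile subsets with dihedral
augmentation, mean-pooled over a deterministic 64-dimensional tile descriptor
— and L2-normalizing the ensemble mean. End classifiers are L2-regularised
logistic regressions (C = 7, max_iter = 10,000, balanced class weights).
A gated attention multiple-instance-learning baseline
(softmax over wᵀ(tanh(V h) ⊙ σ(U h)), trained from scratch with Adam on
analytic gradients) is provided for comparison. All models are evaluated by
5-fold cross-validation stratified on the output variable *at the patient
level*, with one fold plan shared across every training; external cohorts
are scored by averaging the probabilities of the five fold models. Metrics:
AUC, balanced accuracy, macro-F1, at slide and patient level.

**RNA classifier.** Genes quantified (value > 0) in ≥ 50% of samples are
retained; profiles are quantile-normalized; each gene is centred across
samples without variance scaling; the mean centred expression of each class
signature (GMT format) is computed per sample; the class with the highest
signature mean is assigned, with exact ties flagged.

**Cohort statistics.** Pearson chi-squared (no continuity correction),
two-sided Fisher exact (2×2), pooled-variance Student t, Kaplan-Meier
product-limit curves and the log-rank test.

## Worked example

Simulate a 20-patient cohort with strong class-conditional tumour texture,
then cross-validate the embedding + logistic-head model on the dominant
(hepatic stem-like) class under the tumour-ROI protocol:

```bash
$ cat cfg.yaml
n_patients: 20
texture_effect: 2.0
$ histotx simulate --config cfg.yaml --out cohort/ --seed 0
wrote 39 slides for 20 patients to cohort/
$ histotx evaluate --cohort cohort/ --task hepatic_stem_like \
      --protocol mask --model head --seed 0 --report report.json
{
  "slide_auc_mean": 0.9333333333333333,
  "slide_auc_sd": 0.13333333333333333,
  "slide_balanced_accuracy_mean": 0.8666666666666668,
  "slide_f1_macro_mean": 0.8666666666666668,
  "patient_auc": 0.9560439560439561,
  "patient_balanced_accuracy": 0.8901098901098901,
  "patient_f1_macro": 0.8901098901098901
}
```

`slide_auc_mean` is the mean over the five folds of the held-out slide-level
AUC; `patient_auc` pools the out-of-fold probabilities after averaging each
patient's slides. On this small cohort the planted texture signal is
recovered almost perfectly; at `texture_effect: 0` the same command yields
chance-level AUC.

The RNA side works from the files the simulator writes:

```bash
$ histotx rna-classify --expr cohort/expression.tsv \
      --signatures cohort/signatures.gmt --out calls.csv
$ printf '166,80\n13,19\n18,11\n' > immune_table.csv
$ histotx stats --table immune_table.csv --test chi2
{
  "statistic": 8.943187028207085,
  "df": 2,
  "p": 0.011429088917544544
}
```

## Layout

| Module | Contents |
| --- | --- |
| `histotx.synthetic` | cohort configuration and the slide/expression/survival generator |
| `histotx.preproc` | Otsu tissue detection, tessellation, ROI protocols |
| `histotx.features` | tile descriptors, views, slide embeddings |
| `histotx.mil` | gated attention MIL (NumPy, analytic gradients) |
| `histotx.heads` | logistic heads, patient-stratified CV, fold ensembling, metrics |
| `histotx.rna` | expression containers, GMT, signature class assignment |
| `histotx.stats` | contingency, t, Kaplan-Meier, log-rank |
| `histotx.pipeline` | cohort-level plumbing used by the CLI and experiments |
| `histotx.cli` | `histotx` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
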