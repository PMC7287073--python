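# Methods

This note documents the models, procedures and defaults implemented in
`priorselect`, the choices made where the design was genuinely open, and
what the synthetic benchmark does and does not establish about real screens.

## Data model

A screen is a set of cell lines with four modalities: continuous log-scale
gene expression, binary per-gene mutation calls, binary copy-number calls on
genomic segments (each segment mapping to the set of genes it covers), and a
categorical tissue label.  All matrices share one ordered cell-line universe;
a line missing a modality keeps its (zero-filled) row but is flagged in a
per-modality availability mask, and downstream feature construction drops
such lines rather than imputing.  Responses are AUC values in [0, 1], lower
meaning stronger efficacy, one record per (drug, cell line).  Gene
identifiers are opaque case-sensitive strings; no identifier mapping is
attempted.

## Feature-set strategies

For a drug with annotated target genes T:

* **OT** — expression of each target present in the expression matrix, the
  mutation call of each target present in the mutation panel, each CNV
  segment covering at least one target, plus a full one-hot encoding of
  tissue (all levels kept; the motivating screen reports one binary feature
  per tissue site).  A drug is *ineligible* when no feature beyond tissue
  exists.
* **PG** — the same extraction over the union of T with the members of every
  pathway containing at least one target.  T is kept in the universe even if
  no pathway matches, so the OT columns are always a subset of the PG
  columns.
* **OT+S / PG+S** — the above plus one activity column per retained
  signature (below).
* **GW** — all expression columns, nothing else; the data-driven strategies
  *GW_SEL_EN* / *GW_SEL_RF* start from GW and select at modeling time.

Sample restriction is per strategy: a line must carry a response for the
drug and every modality that actually contributes at least one column.  A
drug with no CNV feature therefore does not lose CNV-masked lines, and GW
retains every expression-profiled line — the genome-wide models always see
at least as many samples as the biologically driven ones.

## Signature scoring

A signature S with genes g₁…gᵢ is scored on the expression matrix X two
ways.  The *coherence score* CS(S) is the mean pairwise Pearson correlation
between the gene rows across samples, in [−1, 1]; signatures with CS below a
threshold (default 0.1) are dropped as incoherently expressed.  The
*activity* of S in a sample is the mean over its genes of the per-gene
z-score.  One wording of the coherence definition in circulation reads as
correlating the sample columns of the i×n signature block; we correlate
genes, which matches the score's interpretation as co-expression and the
coherence-score literature, and expose the sample-axis reading as a
non-default option.

Z-scoring statistics default to the full sample set ("global" scope),
matching the usual practice of scoring a complete screen before any
train/test split; this is a deliberate, documented exception to the
no-leakage rule below, and a `train_only` scope is available.  Zero-variance
and absent genes are dropped (with warnings/logs) rather than failing the
signature; a signature with no usable gene is excluded.

## Data-driven selection

*Stability selection.*  100 subsamples of ⌊n/2⌋ lines drawn without
replacement (with-replacement bootstrap available); per subsample a lasso
path over 30 log-spaced penalties below the data's critical penalty
α_max, with each feature's penalty reweighted by a random factor drawn
uniformly from [0.5, 1] (the randomized-lasso "weakness").  A feature's
score is the maximum, over the penalty region in which the average model
size stays below q = √(0.2·p), of the fraction of subsamples selecting it.
Both refinements are part of the cited stability-selection construction and
are needed for its defining property: without the randomization, a noise
feature that happens to correlate with the response in the observed data is
selected in nearly every subsample at some penalty, and without the bounded
penalty region the small-penalty end of the path selects everything.  The
default q bounds the expected number of falsely stable features (at a 0.6
frequency threshold) near one.  Ties are broken by mean absolute
coefficient, then feature id.

*Forest importance.*  Mean impurity-decrease importances of a random-forest
regressor (500 trees by default); permutation importance is not used.  Ties
break lexically.

*Choice of k.*  For each candidate k in a grid (default 10/30/70/150/500,
clipped to the feature count), the downstream model family is evaluated by
3-fold cross-validated MSE on the top-k features; the smallest k within
numerical noise (relative 1e−9) of the minimum wins.  The selected set is
always a prefix of the ranking.

## Modeling protocol

Per (drug, strategy, family): 30% of the strategy's samples are held out,
hyperparameters are tuned by 3-fold cross-validation on the training 70%
minimizing MSE, the tuned model is refit on the full training set and
evaluated on the test set, and the whole procedure is repeated 5 times with
different splits.  Splits are deterministic functions of (seed, repetition).

* Elastic net: mixing parameter grid 0.1…1.0 in steps of 0.1, 30 penalties
  along the path.  Continuous columns are z-scored with training statistics
  (applied unchanged to the test rows); binary columns stay 0/1 so their
  coefficients read as group contrasts.  Constant columns are dropped with a
  warning.  Feature effects are |coefficients| on the standardized scale.
* Random forest: 500 trees; grid over max depth {∞, 10, 20} and features
  per split {√p, p/3, p}.  Effects are impurity importances.

All grid sizes are fields of `ExperimentProtocol` and are deliberately
reduced in the test suite, which trades grid resolution for breadth of
scenarios; the protocol's scientific structure (split fraction, folds,
repetitions, nesting) is never reduced.

For GW_SEL strategies, ranking and the choice of k are nested inside each
repetition's training partition; corrupting test responses provably (and
testedly) changes nothing about the selection.  The one documented leakage
exception is the global signature-scoring scope above.

## Evaluation

RelRMSE = RMSE_dummy / RMSE_model on the test set, the dummy predicting the
training-mean response; 1 is the no-learning baseline.  A perfect model
yields +∞ with a warning; a zero-variance test set with a perfect dummy is
an undefined score and raises.  Correlation significance uses the exact
t-transform t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom, two-sided.

Aggregation over repetitions is the arithmetic mean.  A drug is excluded
when the maximum over its models of mean RelRMSE is ≤ 1 + ε; the wording
this rule operationalizes ("fails to reach, or is very close to, the
baseline") names no number, so ε defaults to 0.01 and is config-exposed,
with the excluded count reported.  Best-model-per-drug is the argmax of mean
correlation, ties resolved toward fewer features then lexical names.  The
per-pathway comparison takes each drug's best genome-wide-group and best
biologically-driven-group correlation and applies a one-sided
Mann–Whitney–Wilcoxon test in the direction of the larger group median;
because the direction is data-chosen, these p-values are conservative
(stochastically ≥ uniform) under exchangeability — they are reported per
pathway with direction and group size, not globally corrected.  Feature-type
frequencies tabulate, for the best-performing drugs under biologically
driven strategies, the share of each feature type among every model's top-k
effects.

## Synthetic screens

The generator emulates the structure of a ~1,000-line screen at configurable
scale; defaults are roughly 1/10 scale (500 lines, 2,000 genes, 150 mutation
genes, 60 CNV segments, 13 tissues, 24 pathways, 20 drugs), preserving the
real screen's proportions between modalities.  Expression is Gaussian around
per-gene baselines drawn from [3, 11] (log2-intensity-like); each signature
is a disjoint gene block sharing a latent factor with pairwise correlation
`signature_rho` (default 0.5, comfortably above the 0.1 coherence
threshold).  Mutations are Bernoulli with gene-wise prevalence in
[0.01, 0.2]; CNV segments cover contiguous 5-gene blocks so the
segment-covers-a-target rule meets both hit and miss cases; tissues are
multinomial.  Modalities are masked at 10% per line by default.

Drugs draw 1–3 targets from an assigned pathway and one of four mechanisms
(default mix 30/20/20/30% expression-driven / mutation-driven / polygenic /
null).  Responses follow AUC = clip(base − Σ wⱼ·driverⱼ + ε, 0, 1) with
standardized drivers, per-drug base in [0.55, 0.9], default effect size 0.3
and noise SD 0.05 — a signal-to-noise ratio at which a planted marker is
clearly recoverable, chosen to test the machinery rather than its detection
limit.  Drivers *lower* AUC (lower AUC = stronger efficacy).  A `narrow`
regime over-expresses the expression driver by +6 units in a 10% outlier
subpopulation only, mimicking receptor-amplified subgroups.  All randomness
derives from one seed via named substreams; identical configs regenerate
byte-identical bundles.

What the generator does **not** emulate: correlation between modalities
(mutations and CNVs are independent of expression), tissue-specific
expression programs, dose-response curve fitting noise, batch effects, or
realistic AUC marginals beyond the clip-Gaussian shape.  Passing tests
therefore demonstrate that the pipeline recovers the signal classes it
models — not that any strategy ranking would transfer to a particular real
screen.

## Numerical choices and degenerate inputs

Matrix writers emit shortest round-trippable float representations and the
readers parse with round-trip precision, so write→read is bit-exact.
Coherence excludes zero-variance genes (undefined Pearson r) and raises only
when no pair remains.  Forest-importance ties are compared after rounding to
1e−12.  Result tables are written with deterministic formatting; two runs
with one seed are byte-identical, regardless of worker count.

## Known limitations

Eligibility mirrors the annotation-driven rules only; there is no minimum
response-variance filter beyond the RelRMSE exclusion.  The per-pathway test
is skipped below two drugs per pathway rather than pooled.  `resume`
verification is whole-run (config hash + file checksums), not per-stage.
Elastic-net paths warn about convergence on near-degenerate folds; the
warnings are suppressed inside the tuners and the refit result is used as
is.
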