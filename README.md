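# priorselect

Feature-selection strategies for drug-sensitivity prediction in cancer cell
lines: does prior biological knowledge about a compound beat genome-wide,
purely data-driven feature selection?

Large pharmacogenomic screens characterize hundreds of cell lines by tens of
thousands of molecular features (gene expression, mutation calls, copy-number
segments, tissue of origin) and measure each drug's efficacy as the area
under its dose-response curve (AUC ∈ [0, 1], lower = stronger effect).  With
samples in the hundreds and features in the tens of thousands, per-drug
regression models overfit unless the feature space is restricted.
`priorselect` implements and compares two families of restrictions:

* **biologically driven** — *OT* (only the drug's annotated target genes,
  plus tissue one-hots), *PG* (the union of the targets with every pathway
  containing a target), and *OT+S* / *PG+S* (either set extended with
  gene-expression-signature activity scores); and
* **data-driven** — the genome-wide expression baseline *GW*, and *GW SEL
  EN* / *GW SEL RF*, which rank the genome-wide features by stability
  selection (randomized lasso over subsamples) or random-forest importance
  and keep the top *k* chosen by inner cross-validation.

Per drug and strategy, an elastic net or random forest is tuned by 3-fold
cross-validated MSE on 70% of the samples and evaluated on the held-out 30%,
repeated five times.  Performance is reported as Pearson correlation *r* with
the test responses and as the **relative RMSE**

```
RelRMSE = RMSE_dummy / RMSE_model
```

where the dummy model always predicts the training-mean AUC: RelRMSE = 1
means nothing was learned, larger is better, and — unlike raw RMSE — the
score is comparable across drugs with different response spreads.  Drugs
whose *best* model stays at the baseline are excluded from comparative
analyses; the remaining drugs feed best-model-per-drug summaries, per-pathway
one-sided Mann–Whitney–Wilcoxon comparisons of the two strategy families,
and feature-type frequency tables over the top-ranked model effects.

Because the real screens live behind external downloads, the package ships a
**synthetic screen generator** that emulates their structure at configurable
scale and plants known response mechanisms (target-expression-driven,
target-mutation-driven, polygenic, pure noise), so every stage is testable
against ground truth.

## Worked example

```
priorselect run-all --config configs/example.yaml --out demo/
```

simulates a 50-line × 200-gene screen with six drugs (two pure-noise, one
polygenic, one mutation-driven, two expression-driven) and fits elastic nets
over five strategies.  It prints

```
{
 "n_models": 30,
 "n_excluded_drugs": 2,
 "elapsed_seconds": 3.5
}
```

The two excluded drugs (`demo/excluded_drugs.tsv`) are exactly the two
planted noise drugs — no model beat the dummy baseline for them.
`demo/best_models.tsv` shows which strategy won each remaining drug:

```
drug_id strategy model_family  pearson_r  rel_rmse  n_features
   D002       GW           en      0.384     1.033       200.0
   D003       PG           en      0.976     3.694        33.0
   D004       OT           en      0.959     3.252         6.0
   D005     OT+S           en      0.931     2.599        17.0
```

The polygenic drug (D002) is best served by the genome-wide space, while the
target-driven drugs (D003–D005) are predicted essentially perfectly from a
handful of prior-knowledge features — 6 columns instead of 200 for D004.
`demo/records_aggregated.tsv` holds every drug × strategy mean (RelRMSE,
*r*, p-value, sample and feature counts), `demo/pathway_tests.tsv` the
per-pathway group comparisons, and `demo/feature_type_frequencies.tsv` the
share of expression/mutation/CNV/tissue/signature features among top-ranked
effects.

Every stage is also available on its own (`priorselect simulate`,
`signatures`, `features`, `select`, `run`, `report`, `validate`) and as
library functions (`priorselect.generate`, `score_signatures`,
`build_strategy`, `stability_select`, `run_drug`, `rel_rmse`, ...).

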