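# indikit

Indication-selection statistics and annotated figures for bulk expression
data.

Early target-discovery teams face a recurring question: given a candidate
target gene (or a target pair, for bispecific antibodies and ADCs), **which
disease indications express it highly enough to be worth pursuing?** indikit
answers this from bulk RNA expression tables (log2 TPM or any log2-scale
unit) with a small set of threshold-based statistics and the annotated
figures that go with them, plus a seeded cohort simulator that serves as a
reference fixture.

## The statistics

All values are log2-scale expression; "above" always means *strictly*
greater.

- **Global thresholds.** For each gene g, a cut-off t_g = mean, median or
  75% quantile of g over **all** samples — never over a displayed subset.
- **Percent above / category flags.** For a group (e.g. an indication) c,
  `percent_above` = 100 · #{samples in c with x > t_g} / n_c, and c is *of
  interest* when median(x | c) > t_g (the per-category dichotomization
  Median^category > Median^All).
- **Quadrant co-expression.** For a feature pair (x, y), each sample is
  gated flow-cytometry-style at (t_x, t_y): Q2 = high/high (upper right),
  Q1 upper left, Q3 lower left, Q4 lower right; boundaries fall to the low
  side. Per group we report quadrant counts/percentages and the Spearman
  (or Pearson) correlation with a two-sided p-value.
- **Composite scores.** For one anchor target against many genes or pathway
  scores, a groups × features matrix whose cell is the percent of the
  group's samples in a chosen quadrant (default Q2, highlight ≥ 20%).
- **Pathway scores.** Per-sample arithmetic mean of log2 expression over a
  gene set (GMT or JSON).
- **Group comparisons.** Fold change FC = 2^(median(level) − median(ref))
  reported on the linear scale, and the tie-corrected Kruskal-Wallis test
  (raw p-values; no multiplicity correction anywhere). The paired pre/post
  variant validates that every patient has exactly one sample per arm and
  returns the pairing.
- **Figures.** Boxplots, paired pre/post boxes with connectors, split
  boxes, quadrant scatters, expression / percent / composite heatmaps and
  quadrant-percentage bars — each built as a `FigureSpec` whose annotation
  strings are formatted directly from the statistics above and only then
  rendered (PNG/SVG/PDF).

## Worked example

```python
import indikit as ik

tbl = ik.simulate()                                # reference cohort
ts  = ik.compute_thresholds(tbl, method="median")  # global per-gene cut-offs

flags = ik.flag_categories_of_interest(tbl, "Tumor target",
                                       ts["Tumor target"], ["indication"])
print(sorted(flags.loc[flags.of_interest, "indication"]))
# ['CRC', 'NET', 'PRAD', 'SCLC', 'STAD', 'UTEN']

cmp_, pairing = ik.paired_pre_post(tbl, "Tumor target", "treatment",
                                   ts, ["indication"])
print(pairing.groupby("indication").size().unique())   # [50] pairs each
stad = cmp_.table.set_index("indication").loc["STAD"]
print(round(stad["fold_change"], 3), f'{stad["kw_pvalue"]:.1e}')
# 0.308 2.1e-12
```

The simulated cohort holds 16 solid-tumor indications × 100 samples (50
patients, paired pre/post) × 35 genes. The global median of `"Tumor
target"` is 3.17 log2 TPM; the six indications flagged above have cohort
medians of 5.25–6.17 (92–100% of samples above the global median) versus
2.44–2.67 elsewhere. The STAD fold change of 0.31 (KW p ≈ 2e-12) is the
post-treatment drop built into the cohort: a target whose expression falls
after therapy, arguing for pre-treatment patients in that indication.

The `examples/` directory walks through each capability (simulation and
harmonization, threshold triage, pre/post and database comparisons,
quadrant co-expression, pathway composite scores, overview heatmaps); each
script prints the numbers it computes and what they mean. A thin CLI mirrors
the library (`indikit simulate|harmonize|thresholds|percent-above|quadrant|
composite|compare|plot`, see `indikit --help`); every run writes a config
echo and log beside its outputs so it can be reproduced exactly.

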