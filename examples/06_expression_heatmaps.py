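"""Overview heatmaps: mean expression and percent-above-threshold.

The percent heatmap carries a quartile bar per column: how many of the shown
genes fall in each percentage quartile (Q1 0-25% ... Q4 75-100%) for that
cohort. Columns are ordered by hierarchical clustering (Euclidean distance,
complete linkage).
"""

import indikit as ik

tbl = ik.simulate()
ts = ik.compute_thresholds(tbl, method="median")
genes = ["Tumor target", "Immune target", "TCA_g01", "TEX_g01", "TIN_g01", "NKS_g01"]

expr = ik.heatmap_sample_expression(tbl, genes, ["indication"], out="scratch_hm_expr.png")
print("column order (clustered):", expr.groups)

pct = ik.heatmap_samples_above_median(tbl, genes, ["indication"], ts,
                                      out="scratch_hm_pct.png")
print("\nquartile bins per indication (counts of genes):")
for g in pct.groups[:4]:
    print(f"  {g}: {pct.data['bins'][g]}")
print("\nCells are % of samples above each gene's global median; the bins",
      "summarize each column's distribution.")
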