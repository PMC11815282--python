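"""Pathway scores and the composite heatmap.

Gene signatures are collapsed to per-sample mean log2 expression, then each
pathway is scored against the anchor target: the percent of each cohort's
samples in the high/high quadrant (anchor on the y-axis). Cells at or above
the highlight threshold (20%) mark candidate indications.
"""

import pandas as pd

import indikit as ik

tbl = ik.simulate()
sets = ik.pathway_sets()
print("signatures:", {k: len(v) for k, v in sets.items()})

scores = ik.aggregate_gene_sets(tbl, sets)         # per-sample mean log2 TPM
both = pd.concat([tbl, scores], ignore_index=True)
ts = ik.compute_thresholds(both, method="median")  # thresholds on everything

csm = ik.composite_scores(
    both, anchor="Tumor target", columns=list(sets), thresholds=ts,
    group_cols=["indication", "treatment"], quadrant="Q2", highlight=20.0,
)
hot = csm.matrix[(csm.matrix >= 20.0).any(axis=1)]
print("\ncohorts with >=20% of samples high for the target AND a pathway:")
print(hot.round(1).to_string())
print("\nEach cell: % of that cohort's samples above the global median of",
      "both the pathway score and 'Tumor target'.")

ik.heatmap_composite_scores(csm, out="scratch_composite.png")
print("wrote scratch_composite.png")
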