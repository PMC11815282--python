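"""Simulate the reference cohort and show the harmonized table contract.

Every analysis in this package starts from a long-format table with one row
per (sample, feature) measurement plus grouping metadata.
"""

import indikit as ik

tbl = ik.simulate()  # 16 indications x 50 pre/post pairs x 35 genes
print(tbl.head())
print(f"\n{len(tbl):,} records, "
      f"{tbl['sample_id'].nunique()} samples, "
      f"{tbl['feature'].nunique()} genes, "
      f"{tbl['indication'].nunique()} indications")

# harmonize_table is the entry point for user data: rename raw columns to the
# canonical schema and keep chosen grouping columns. Here we re-harmonize the
# simulator's own output with an identity map and build a combined
# indication_treatment ("intr") display column.
canon = ik.harmonize_table(
    tbl,
    column_map={c: c for c in ("patient_id", "sample_id", "feature", "value", "unit")},
    keep_groups=["indication", "treatment"],
    combine_groups=["indication", "treatment"],
)
print("\ncombined grouping column:", canon["intr"].iloc[0],
      "… (one label per indication/treatment cell, used for display)")
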