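import numpy as np
import pandas as pd
import pytest

from indikit import compute_thresholds, simulate


def long_table(samples, unit="log2 TPM", **extra_cols):
    """Build a small harmonized table from {sample_id: {feature: value}}.

    ``extra_cols`` maps a group-column name to {sample_id: value}; patient_id
    defaults to the sample id.
    """
    rows = []
    for sid, feats in samples.items():
        for feature, value in feats.items():
            row = {
                "patient_id": extra_cols.get("patient_id", {}).get(sid, sid),
                "sample_id": sid,
                "feature": feature,
                "value": value,
                "unit": unit,
            }
            for col, mapping in extra_cols.items():
                if col != "patient_id":
                    row[col] = mapping[sid]
            rows.append(row)
    return pd.DataFrame(rows)


def random_table(rng, n_samples, features=("gA", "gB"), n_groups=2):
    """Random small harmonized table with a 'grp' column."""
    samples = {}
    groups = {}
    for i in range(n_samples):
        sid = f"s{i}"
        samples[sid] = {f: float(rng.normal()) for f in features}
        groups[sid] = f"g{rng.integers(n_groups)}"
    return long_table(samples, grp=groups)


@pytest.fixture(scope="session")
def sim_table():
    return simulate()


@pytest.fixture(scope="session")
def median_thresholds(sim_table):
    return compute_thresholds(sim_table, method="median")
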