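"""Recompute group statistics from an external per-subject table.

Writes a synthetic per-subject table in the documented supplementary
schema (subject, condition, per-network gradient means, CAP occurrence
rates), imports it, and recomputes the paired contrasts — the path one
would use to reproduce published statistics from released per-subject
values.
"""
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from gradcap.io import import_supplementary_tables
from gradcap.stats import network_contrast_table

rng = np.random.default_rng(0)
rows = []
for i in range(16):
    for cond in ("baseline", "drug"):
        shift = -0.03 if cond == "drug" else 0.0
        rows.append({
            "subject": f"sub-{i:02d}", "condition": cond,
            "SMN": -0.10 - shift + rng.normal(0, 0.01),
            "FPN": 0.10 + shift + rng.normal(0, 0.01),
            "DMN": 0.12 + shift / 2 + rng.normal(0, 0.01),
            "FPN+": 0.16 + shift + rng.normal(0, 0.01),
            "SMN+": 0.16 + shift + rng.normal(0, 0.01),
            "GN+": 0.06 - 2 * shift + rng.normal(0, 0.01),
        })

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "synthetic_supplementary.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    tables = import_supplementary_tables(path)
    print(f"recognized sub-tables: {sorted(tables)}")
    for kind, df in tables.items():
        cols = [c for c in df.columns if c not in ("subject", "condition")]
        contrast = network_contrast_table(df, cols)
        print(f"\nrecomputed paired contrasts ({kind}):")
        print(contrast[["measure", "t", "df", "p_bonf", "significant"]]
              .to_string(index=False))
print("\nwith the real per-subject tables in this schema, the same call "
      "reproduces published t statistics to printed precision")
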