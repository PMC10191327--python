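"""Discriminant classification of grains into barley categories.

Runs leave-one-out cross-validated linear discriminant analysis for
several contrasts and feature sets, with bootstrap confidence intervals,
and reports the cross-validation percentages (CVP).
"""

import pandas as pd

from caryomorph import SynthConfig, generate_dataset
from caryomorph.classify import contrast_suite, reports_table
from caryomorph.eft import records_to_coefficients

records, _ = generate_dataset(
    SynthConfig(n_varieties_per_category=3, grains_per_accession=30, seed=11)
)
coeffs = records_to_coefficients(records)
sizes = pd.DataFrame([{"grain_id": r.grain_id, **r.sizes.as_dict()} for r in records])
meta = pd.DataFrame(
    {"grain_id": r.grain_id, "accession_id": r.metadata.accession_id,
     "variety": r.metadata.variety, "row_type": r.metadata.row_type,
     "hull_type": r.metadata.hull_type, "sowing": r.metadata.sowing,
     "year": r.metadata.year}
    for r in records
)

reports = contrast_suite(
    coeffs, sizes, meta,
    contrasts=["four_group", "row_type", "hull_type"],
    feature_sets=["length", "lateral_shape", "ventral_shape", "combined_shape"],
    ci=True, B=50, seed=0,
)
table = reports_table(reports)
print(table[["contrast", "feature_set", "cvp", "ci_low", "ci_high", "n"]]
      .round(1).to_string(index=False))

print("\nReading the table: shape outperforms the single size index; the")
print("row-number contrast is carried by the ventral view and the")
print("hulled/naked contrast by the lateral view; combining both views")
print("matches or beats the better single view.")
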