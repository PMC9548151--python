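"""Generate a synthetic annotation bundle and apply the training-set filters.

Builds a dbNSFP-like per-allele annotation table with ClinVar-style
clinical records, then shows how the curation rules (conflict removal and
the population-presence filter) shape the training set.
"""

import pandas as pd

from flankrnn.curation import filter_training_snvs, resolve_clinical_label
from flankrnn.simulate import (
    SyntheticConfig,
    generate_annotation_table,
    generate_clinvar_records,
    generate_transcript_layout,
)

cfg = SyntheticConfig(n_transcripts=10, codons_per_transcript=50, seed=42)
layouts = generate_transcript_layout(cfg)
table, truth = generate_annotation_table(cfg, layouts)
records, _ = generate_clinvar_records(cfg, truth)

print(f"annotation table: {len(table)} allele rows over {len(layouts)} transcripts")
print(f"clinical records: {len(records)} (one per missense variant)")

outcomes = pd.Series([resolve_clinical_label(r) for r in records]).value_counts()
print("\nlabel resolution outcomes (conflicting/VUS-only records are removed):")
print(outcomes.to_string())

labeled = filter_training_snvs(records)
n_tp = sum(l.label for l in labeled)
print(
    f"\nafter the presence filter (absent from >=1 population dataset AND "
    f"present in >=1): {len(labeled)} training variants "
    f"({n_tp} pathogenic, {len(labeled) - n_tp} benign)"
)
print(
    "the removed remainder is either conflicting/VUS, observed in every "
    "dataset ('easy' benign), or observed in none (no AF information)."
)
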