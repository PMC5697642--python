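"""Simulate a linked dispensing / hospital / demographics extract.

Builds a 300-patient synthetic AF cohort under the default study
conditions (Sep 2011 - Jun 2014, rivaroxaban-dominated drug mix, 28-day
packs) and prints the shape of each table plus the hidden ground truth
that the analysis pipeline never sees.
"""

from oacdur import GeneratorConfig, generate_linked_tables

config = GeneratorConfig(n_patients=300, seed=42)
tables = generate_linked_tables(config)

print(f"dispensing rows:   {len(tables.dispensing):6d}")
print(f"hospital episodes: {len(tables.hospital):6d}")
print(f"patients:          {len(tables.demographics):6d}")
print()
print(tables.dispensing.head(8).to_string(index=False))
print()
print("latent truth (never read by the pipeline):")
print(tables.truth["true_pathway"].value_counts().to_string())
# 'persist' = still on treatment at end of follow-up; the other labels
# say what a patient truly did after their latent stopping day.
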