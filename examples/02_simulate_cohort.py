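"""Generate a synthetic weaning cohort and write it as CSV.

The default generative spec reproduces the reference study's structure:
71 T-piece trials in 51 patients, ~45% failures, covariate prevalences
and per-index pre/change distributions per group.  Same seed, same bytes.
"""

import modrer as m

spec = m.CohortSpec(seed=42)
cohort = m.generate_cohort(spec)
m.write_cohort_csv(cohort, "synthetic_cohort.csv")

df = cohort.to_dataframe()
print(f"wrote synthetic_cohort.csv: {len(cohort)} trials, "
      f"{cohort.n_failures} failures ({100 * cohort.n_failures / len(cohort):.1f}%), "
      f"{df['patient_id'].nunique()} patients")
print("\nfirst rows (selected columns):")
cols = ["trial_id", "patient_id", "outcome", "age", "pre_pao2", "pre_pcvco2",
        "post_pcvco2", "post_scvo2"]
print(df[cols].head(5).to_string(index=False))
print("\nEach row carries full pre/post gas panels, so every derived index "
      "is recomputable downstream.")
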