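"""Generate a small synthetic accelerometer cohort and summarise it.

Builds 4 subjects x 3 activities x 2 repetitions of 30 s wrist-accelerometer
recordings (+/-2 g, 0.015 g resolution, 32 Hz) and prints the per-subject
instance counts.  Every value is reproducible from the seed.
"""

from privhar import GeneratorConfig, cohort_summary, generate_dataset

config = GeneratorConfig(
    n_subjects=4, n_activities=3, reps_per_activity=2, n_age_bins=2, seed=42
)
sequences = generate_dataset(config)

print(f"{len(sequences)} sequences of {config.n_samples} samples each")
print("first sequence:", sequences[0].sequence_id,
      f"(gender {sequences[0].gender}, age bin {sequences[0].age_group})")
print("\ninstances per (subject, activity) — every cell is reps_per_activity:")
print(cohort_summary(sequences))
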