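"""Baseline wrapper evaluation: how much do unweighted features leak?

Trains the three 90-tree random forests (gender, age group, action) with
subject-grouped cross-validation on a small synthetic cohort, all feature
weights at 1.0, and compares each accuracy to its random-choice chance
level.  Accuracies well above chance mean the feature set leaks the trait.
Runs in about half a minute.
"""

import numpy as np

from privhar import InductorSpec, chance_levels, run_baseline, sequences_to_matrix
from privhar.benchmark import benchmark_generator_config
from privhar.simulate import generate_dataset

matrix = sequences_to_matrix(generate_dataset(benchmark_generator_config(seed=1)))
spec = InductorSpec(n_trees=90, k_folds=3, seed=1, group_by_subject=True)
accs, _ = run_baseline(matrix, spec)
chance = chance_levels(matrix)

print(f"{len(matrix)} windows, subject-grouped 3-fold cross-validation")
for task, label in (("gender", "gender"), ("age_group", "age group"),
                    ("activity", "action")):
    print(f"  {label:10s} accuracy {100 * accs[task]:5.1f}%   "
          f"chance {100 * chance[task]:5.1f}%")
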