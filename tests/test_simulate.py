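"""Synthetic cohort generator: counts, determinism, sensor quantization,
label-dependent separability and the chance-level contract."""

import numpy as np
import pandas as pd
import pytest

from privhar import (
    GeneratorConfig,
    TraitEffects,
    cohort_summary,
    evaluate_objectives,
    generate_dataset,
    sequences_to_matrix,
)
from privhar.config import InductorSpec
from privhar.simulate import ACTIVITY_CATALOGUE, make_subjects


def test_dataset_size_and_labels(tiny_config, tiny_sequences):
    assert len(tiny_sequences) == 4 * 3 * 2
    for seq in tiny_sequences:
        assert seq.samples.shape == (tiny_config.n_samples, 3)
        assert seq.activity in ACTIVITY_CATALOGUE[:3]
    genders = {s.subject_id: s.gender for s in tiny_sequences}
    assert sorted(genders.values()) == ["F", "F", "M", "M"]


def test_generation_is_bit_reproducible(tiny_config, tiny_sequences):
    again = generate_dataset(GeneratorConfig(**{**tiny_config.__dict__}))
    for a, b in zip(tiny_sequences, again):
        assert a.sequence_id == b.sequence_id
        np.testing.assert_array_equal(a.samples, b.samples)


def test_sensor_quantization_and_range(tiny_config, tiny_sequences):
    res = tiny_config.resolution_g
    for seq in tiny_sequences:
        assert np.all(np.abs(seq.samples) <= tiny_config.accel_range_g)
        steps = seq.samples / res
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)


def test_age_bins_round_robin_and_histogram():
    cfg = GeneratorConfig(n_subjects=6, n_activities=1, reps_per_activity=1,
                          n_age_bins=4, seed=0)
    subjects = make_subjects(cfg, np.random.default_rng(0))
    # bins fill in M/F pairs so age never confounds gender
    assert [s.age_group for s in subjects] == [0, 0, 1, 1, 2, 2]
    cfg = GeneratorConfig(n_subjects=6, n_activities=1, reps_per_activity=1,
                          n_age_bins=3, age_histogram=[3, 2, 1], seed=0)
    subjects = make_subjects(cfg, np.random.default_rng(0))
    assert [s.age_group for s in subjects] == [0, 0, 0, 1, 1, 2]


def test_cohort_summary_counts(tiny_sequences):
    table = cohort_summary(tiny_sequences)
    counts = table.drop(columns="total")
    assert counts.shape == (4, 3)
    assert (counts.values == 2).all()
    assert (table["total"] == 6).all()
    assert counts.values.sum() == len(tiny_sequences)


def test_cohort_summary_matches_brute_force(tiny_sequences):
    table = cohort_summary(tiny_sequences)
    brute: dict = {}
    for s in tiny_sequences:
        brute[(s.subject_id, s.activity)] = brute.get((s.subject_id, s.activity), 0) + 1
    for (subj, act), n in brute.items():
        assert table.loc[subj, act] == n


def test_cohort_summary_empty_cell(tiny_sequences):
    subset = [
        s for s in tiny_sequences
        if not (s.subject_id == "S00" and s.activity == ACTIVITY_CATALOGUE[0])
    ]
    table = cohort_summary(subset)
    assert table.loc["S00", ACTIVITY_CATALOGUE[0]] == 0
    with pytest.raises(ValueError):
        cohort_summary([])


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_activities": 25},
        {"n_subjects": 5},
        {"sequence_duration_s": -1.0},
        {"sample_rate_hz": 0.0},
        {"resolution_g": 0.0},
        {"age_histogram": [1, 1], "n_age_bins": 7},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        GeneratorConfig(**kwargs)


def test_short_sequences_warn():
    cfg = GeneratorConfig(
        n_subjects=2, n_activities=1, reps_per_activity=1,
        sequence_duration_s=2.0, seed=0,
    )
    with pytest.warns(UserWarning, match="shorter"):
        sequences = generate_dataset(cfg)
    assert len(sequences) == 2


def _small_cv_accuracies(config, k=2, n_trees=25, grouped=False):
    matrix = sequences_to_matrix(generate_dataset(config))
    spec = InductorSpec(n_trees=n_trees, k_folds=k, seed=0, group_by_subject=grouped)
    obj = evaluate_objectives(matrix, np.ones(62), spec)
    return {
        "gender": obj.gender_obj,
        "age_group": obj.age_obj,
        "activity": 1.0 - obj.action_obj,
    }, len(matrix)


def _chance_band(p, n, k=3.0):
    se = np.sqrt(p * (1 - p) / n)
    return p - k * se, p + k * se


def test_all_zero_effects_give_chance_accuracy():
    """With every trait effect at zero the signal is pure sensor noise, so
    all three classifiers sit at their chance levels."""
    cfg = GeneratorConfig(
        n_subjects=8, n_activities=3, reps_per_activity=2, n_age_bins=4,
        trait_effect_sizes=TraitEffects(gender=0.0, age=0.0, activity=0.0),
        seed=11,
    )
    accs, n = _small_cv_accuracies(cfg)
    for task, chance in (("gender", 0.5), ("age_group", 0.25), ("activity", 1 / 3)):
        lo, hi = _chance_band(chance, n)
        assert lo <= accs[task] <= hi, f"{task}: {accs[task]} outside {lo}-{hi}"


def test_zero_gender_effect_hides_gender_only():
    """Without a gender signature, gender prediction on held-out subjects is
    chance.  Folds are grouped by subject: ungrouped folds would let the
    forest recognise the source sequence (random per-sequence phases and
    jitters) and read gender off the subject's identity."""
    cfg = GeneratorConfig(
        n_subjects=24, n_activities=3, reps_per_activity=1, n_age_bins=4,
        sequence_duration_s=20.0,
        trait_effect_sizes=TraitEffects(gender=0.0, age=0.3, activity=1.0),
        seed=11,
    )
    accs, _ = _small_cv_accuracies(cfg, k=3, grouped=True)
    # the independent unit for trait accuracy is the held-out subject
    lo, hi = _chance_band(0.5, cfg.n_subjects)
    assert lo <= accs["gender"] <= hi
    # the separability dial: activity structure is intact
    assert accs["activity"] > 0.9


def test_separability_dial_action_accuracy(tiny_matrix):
    spec = InductorSpec(n_trees=25, k_folds=2, seed=0)
    obj = evaluate_objectives(tiny_matrix, np.ones(62), spec)
    assert 1.0 - obj.action_obj > 0.9
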