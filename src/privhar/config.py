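"""Configuration dataclasses and YAML loading.

Every tunable of the pipeline lives in one of the spec-level config objects
below; the CLI and the structured YAML config file both map onto them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import yaml


@dataclass
class TraitEffects:
    """Effect sizes of the three label-dependent signal components.

    gender : log-amplitude gap between genders (0 = no gender signature)
    age : scale of the age-dependent tremor / smoothing terms
    activity : scale of the activity-specific oscillatory template
    """

    gender: float = 0.3
    age: float = 0.3
    activity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gender", "age", "activity"):
            if getattr(self, name) < 0:
                raise ValueError(f"trait effect size {name} must be >= 0")


@dataclass
class GeneratorConfig:
    """Synthetic-cohort generator settings.

    Defaults emulate the study conditions of the real recording campaign:
    52 participants (balanced genders), 24 activities of daily living, an
    average of 5 repetitions per (subject, activity), a wrist accelerometer
    with +/-2 g range, 0.015 g resolution, 32 Hz capture rate.
    """

    n_subjects: int = 52
    n_activities: int = 24
    reps_per_activity: int = 5
    n_age_bins: int = 7
    sample_rate_hz: float = 32.0
    sequence_duration_s: float = 30.0
    accel_range_g: float = 2.0
    resolution_g: float = 0.015
    trait_effect_sizes: TraitEffects = field(default_factory=TraitEffects)
    noise_sd_g: float = 0.05
    amp_jitter_sd: float = 0.1
    motion_scale_sd: float = 0.0
    age_histogram: list[int] | None = None
    seed: int = 0

    MAX_ACTIVITIES = 24

    def __post_init__(self) -> None:
        if isinstance(self.trait_effect_sizes, dict):
            self.trait_effect_sizes = TraitEffects(**self.trait_effect_sizes)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_subjects % 2 != 0:
            raise ValueError(
                "n_subjects must be even so genders can be balanced "
                f"(got {self.n_subjects})"
            )
        if not 1 <= self.n_activities <= self.MAX_ACTIVITIES:
            raise ValueError(
                f"n_activities must be in [1, {self.MAX_ACTIVITIES}] (the activity "
                f"catalogue holds {self.MAX_ACTIVITIES} classes), got {self.n_activities}"
            )
        if self.reps_per_activity < 1:
            raise ValueError("reps_per_activity must be >= 1")
        if self.n_age_bins < 1:
            raise ValueError("n_age_bins must be >= 1")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not self.sequence_duration_s > 0:
            raise ValueError(
                f"sequence_duration_s must be > 0, got {self.sequence_duration_s}"
            )
        if not self.resolution_g > 0:
            raise ValueError(f"resolution_g must be > 0, got {self.resolution_g}")
        if not self.accel_range_g > 0:
            raise ValueError("accel_range_g must be > 0")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be >= 0")
        if self.age_histogram is not None:
            if len(self.age_histogram) != self.n_age_bins:
                raise ValueError("age_histogram must have n_age_bins entries")
            if sum(self.age_histogram) != self.n_subjects:
                raise ValueError("age_histogram must sum to n_subjects")

    @property
    def n_samples(self) -> int:
        return int(round(self.sequence_duration_s * self.sample_rate_hz))


@dataclass
class FilterSpec:
    """Low-pass + despiking filter settings (applied in this order)."""

    butterworth_order: int = 4
    cutoff_hz: float = 15.0
    median_order: int = 3
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.butterworth_order < 1:
            raise ValueError("butterworth_order must be >= 1")
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be > 0")
        if self.median_order % 2 != 1:
            raise ValueError(f"median_order must be odd, got {self.median_order}")


@dataclass
class WindowSpec:
    """Sliding-window segmentation: 5 s windows (160 samples at 32 Hz),
    20% overlap between adjacent windows."""

    window_samples: int = 160
    overlap_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ValueError("window_samples must be >= 2")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def stride(self) -> int:
        """Stride in samples; fractional strides round to nearest, ties down."""
        import math

        exact = self.window_samples * (1.0 - self.overlap_fraction)
        return int(math.ceil(exact - 0.5))


@dataclass
class InductorSpec:
    """Wrapper-fitness classifier settings: a 90-tree random forest
    evaluated with stratified k-fold cross-validation (k=10)."""

    n_trees: int = 90
    k_folds: int = 10
    seed: int = 0
    stratify_by: str = "activity"
    group_by_subject: bool = False
    weight_quantization_step: float | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.weight_quantization_step is not None and not self.weight_quantization_step > 0:
            raise ValueError("weight_quantization_step must be > 0 when set")


@dataclass
class EvolutionConfig:
    """NSGA-III settings.

    The study conditions: population 50, M=3 objectives, p=8 partitions
    (45 reference directions), 10 new offspring per generation, SBX +
    polynomial mutation on a 62-gene weight vector bounded in [0, 1].
    """

    population_size: int = 50
    n_offspring: int = 10
    p: int = 8
    M: int = 3
    generations: int = 50
    n_genes: int = 62
    sbx_eta: float = 30.0
    sbx_prob: float = 1.0
    sbx_exchange_prob: float = 0.5
    pm_eta: float = 20.0
    pm_prob: float | None = None  # default 1 / n_genes
    lower: float = 0.0
    upper: float = 1.0
    init: str = "uniform"  # or "loguniform": genes ~ 10**U[log10(init_floor), 0]
    init_floor: float = 1e-2
    seed_with_ones: bool = False
    canonical_offspring: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.init not in ("uniform", "loguniform"):
            raise ValueError("init must be 'uniform' or 'loguniform'")
        if not 0 < self.init_floor < 1:
            raise ValueError("init_floor must be in (0, 1)")
        n_ref = self.n_reference_directions
        if n_ref > self.population_size:
            raise ValueError(
                f"{n_ref} reference directions (M={self.M}, p={self.p}) exceed the "
                f"population size {self.population_size}; reduce p or grow the "
                "population (larger p results in unexpected niching behaviour)"
            )

    @property
    def n_reference_directions(self) -> int:
        return comb(self.M + self.p - 1, self.p)

    @property
    def mutation_prob(self) -> float:
        return self.pm_prob if self.pm_prob is not None else 1.0 / self.n_genes


_SECTIONS = {
    "generator": GeneratorConfig,
    "filter": FilterSpec,
    "window": WindowSpec,
    "inductor": InductorSpec,
    "evolution": EvolutionConfig,
}


def load_config(path: str | Path) -> dict:
    """Load a structured YAML config file into the dataclasses above.

    The file may contain any subset of the sections ``generator``, ``filter``,
    ``window``, ``inductor`` and ``evolution``; missing sections get defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    for name, cls in _SECTIONS.items():
        out[name] = cls(**(raw.get(name) or {}))
    return out


def dump_config(configs: dict, path: str | Path) -> None:
    """Serialize a dict of config dataclasses back to YAML (run metadata)."""
    payload = {
        name: dataclasses.asdict(cfg)
        for name, cfg in configs.items()
        if dataclasses.is_dataclass(cfg)
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
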