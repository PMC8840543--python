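"""Core domain containers shared across the package.

A :class:`RawSequence` is one labelled recording of one activity repetition
by one subject (tri-axial acceleration in g).  A :class:`Window` is a
fixed-length slice of a filtered sequence, carrying the sequence's labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Label columns carried alongside features throughout the pipeline.
LABEL_COLUMNS = ("subject_id", "gender", "age_group", "activity")

#: Task names (label columns) for the three wrapper classifiers.
TASKS = ("gender", "age_group", "activity")

GENDERS = ("M", "F")


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated participant.

    Parameters
    ----------
    subject_id : str
        Stable identifier, e.g. ``"S03"``.
    gender : str
        One of ``"M"`` / ``"F"``.
    age_group : int
        Age-bin index in ``[0, n_age_bins)``.
    motion_scale : float
        Positive idiosyncrasy multiplier applied to the subject's
        deterministic motion components (1.0 = population average).
    """

    subject_id: str
    gender: str
    age_group: int
    motion_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.age_group < 0:
            raise ValueError(f"age_group must be >= 0, got {self.age_group}")
        if not self.motion_scale > 0:
            raise ValueError(f"motion_scale must be > 0, got {self.motion_scale}")


@dataclass
class RawSequence:
    """One labelled tri-axial acceleration recording.

    ``samples`` is an ``(n, 3)`` float array of x/y/z acceleration in g.
    """

    subject_id: str
    gender: str
    age_group: int
    activity: str
    samples: np.ndarray
    sample_rate_hz: float
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got shape {self.samples.shape}")
        if len(self.samples) < 1:
            raise ValueError("sequence must contain at least one sample")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not self.sequence_id:
            self.sequence_id = f"{self.subject_id}-{self.activity}"

    def __len__(self) -> int:
        return len(self.samples)

    def with_samples(self, samples: np.ndarray) -> "RawSequence":
        """Copy of this sequence with new sample values (labels preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class Window:
    """A fixed-size slice of a sequence, inheriting its labels."""

    subject_id: str
    gender: str
    age_group: int
    activity: str
    samples: np.ndarray  # (window_samples, 3)
    sample_rate_hz: float
    sequence_id: str
    start: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"window samples must be (n, 3), got {self.samples.shape}")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ObjectiveVector:
    """The three minimised objectives of the de-identification problem.

    ``gender_obj`` and ``age_obj`` are the cross-validated accuracies of the
    gender and age classifiers (lower = better concealed); ``action_obj`` is
    ``1 - action accuracy`` (lower = better utility).
    """

    gender_obj: float
    age_obj: float
    action_obj: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gender_obj, self.age_obj, self.action_obj], dtype=float)

    @property
    def gender_accuracy(self) -> float:
        return self.gender_obj

    @property
    def age_accuracy(self) -> float:
        return self.age_obj

    @property
    def action_accuracy(self) -> float:
        return 1.0 - self.action_obj
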