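"""Signal conditioning and window segmentation.

The fixed pipeline order is: Butterworth low-pass, then median despiking,
then sliding-window segmentation.  Filtering is label- and
length-preserving; windows inherit the labels of their source sequence.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, signal

from .config import FilterSpec, WindowSpec
from .types import RawSequence, Window

logger = logging.getLogger(__name__)


def butterworth_lowpass(sequence: RawSequence, spec: FilterSpec | None = None) -> RawSequence:
    """Apply a low-pass Butterworth filter per axis.

    Single-pass causal IIR by default, so the effective response is the
    stated filter order; set ``spec.zero_phase`` for forward-backward
    filtering.  DC gain is 1.
    """
    spec = spec or FilterSpec()
    nyquist = sequence.sample_rate_hz / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz (sample rate {sequence.sample_rate_hz} Hz)"
        )
    b, a = signal.butter(spec.butterworth_order, spec.cutoff_hz / nyquist, btype="low")
    if spec.zero_phase:
        filtered = signal.filtfilt(b, a, sequence.samples, axis=0)
    else:
        filtered = signal.lfilter(b, a, sequence.samples, axis=0)
    return sequence.with_samples(filtered)


def median_filter(sequence: RawSequence, spec: FilterSpec | None = None) -> RawSequence:
    """Sliding-median despiking per axis; edges handled by edge replication."""
    spec = spec or FilterSpec()
    if spec.median_order % 2 != 1:
        raise ValueError(f"median_order must be odd, got {spec.median_order}")
    if spec.median_order > len(sequence):
        raise ValueError(
            f"median_order {spec.median_order} exceeds sequence length {len(sequence)}"
        )
    filtered = ndimage.median_filter(
        sequence.samples, size=(spec.median_order, 1), mode="nearest"
    )
    return sequence.with_samples(filtered)


def segment_windows(sequence: RawSequence, spec: WindowSpec | None = None) -> list[Window]:
    """Cut a sequence into fixed-size overlapping windows.

    Windows start at 0, stride, 2*stride, ...; the trailing partial window
    is discarded.  A sequence shorter than one window yields zero windows
    (with a logged warning), not an error.
    """
    spec = spec or WindowSpec()
    n = len(sequence)
    w = spec.window_samples
    if n < w:
        logger.warning(
            "sequence %s has %d samples, shorter than one %d-sample window; "
            "yielding no windows",
            sequence.sequence_id,
            n,
            w,
        )
        return []
    stride = spec.stride
    starts = range(0, n - w + 1, stride)
    return [
        Window(
            subject_id=sequence.subject_id,
            gender=sequence.gender,
            age_group=sequence.age_group,
            activity=sequence.activity,
            samples=sequence.samples[start : start + w].copy(),
            sample_rate_hz=sequence.sample_rate_hz,
            sequence_id=sequence.sequence_id,
            start=start,
        )
        for start in starts
    ]


def n_windows(sequence_length: int, spec: WindowSpec) -> int:
    """Closed-form window count: floor((L - w) / stride) + 1, or 0 if L < w."""
    if sequence_length < spec.window_samples:
        return 0
    return (sequence_length - spec.window_samples) // spec.stride + 1


def preprocess(
    sequence: RawSequence,
    filter_spec: FilterSpec | None = None,
    window_spec: WindowSpec | None = None,
) -> list[Window]:
    """Butterworth, then median, then segmentation (fixed order)."""
    filtered = median_filter(butterworth_lowpass(sequence, filter_spec), filter_spec)
    return segment_windows(filtered, window_spec)
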