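"""The 62-dimensional per-window feature space.

48 time-domain and 14 frequency-domain statistics computed on the three
acceleration axes and on the signal magnitude vector (SMV), in a canonical
order that also defines the gene order of the evolutionary genome.

Estimator conventions (package conventions where the field is silent):

* sigma is the population standard deviation (divide by N);
* skewness / kurtosis are standardized moments, kurtosis reported as excess;
* degenerate zero-variance windows map correlation, CV, skewness, kurtosis
  and autocorrelation to 0 rather than NaN — feature vectors are always
  finite;
* autocorrelation is the lag-1 autocorrelation of the SMV;
* number of peaks counts strict local maxima of the SMV whose prominence
  exceeds the window's SMV standard deviation (threshold configurable);
* percentiles use linear interpolation between order statistics;
* the spectrum is the one-sided FFT magnitude excluding the DC bin, scaled
  by 2/N so a unit-amplitude sinusoid has peak magnitude ~1; no taper;
  spectral entropy uses the power spectrum normalised to sum 1, natural log.
"""

from __future__ import annotations

import numpy as np

from .types import LABEL_COLUMNS, Window

_AXES = ("x", "y", "z", "smv")

TIME_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"mean_{a}" for a in _AXES)
    + tuple(f"median_{a}" for a in _AXES)
    + tuple(f"std_{a}" for a in _AXES)
    + tuple(f"max_{a}" for a in _AXES)
    + tuple(f"min_{a}" for a in _AXES)
    + tuple(f"range_{a}" for a in _AXES)
    + ("corr_xy", "corr_yz", "corr_zx")
    + ("sma",)
    + tuple(f"cv_{a}" for a in _AXES)
    + tuple(f"mad_{a}" for a in _AXES)
    + ("skewness_smv", "kurtosis_smv", "autocorr_smv")
    + ("p20_smv", "p50_smv", "p80_smv", "p90_smv")
    + ("iqr_smv",)
    + ("n_peaks_smv", "ptp_smv")
    + ("energy_smv", "rms_smv")
)

FREQUENCY_FEATURE_NAMES: tuple[str, ...] = (
    ("spectral_entropy_smv", "spectral_energy_smv", "spectral_centroid_smv")
    + tuple(f"freq_mean_{a}" for a in _AXES)
    + tuple(f"freq_std_{a}" for a in _AXES)
    + ("freq_p25_smv", "freq_p50_smv", "freq_p75_smv")
)

#: Canonical order of the 62 features; also the genome's gene order.
FEATURE_NAMES: tuple[str, ...] = TIME_FEATURE_NAMES + FREQUENCY_FEATURE_NAMES

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 62 and len(TIME_FEATURE_NAMES) == 48


def smv(window: Window | np.ndarray) -> np.ndarray:
    """Per-sample signal magnitude vector sqrt(x^2 + y^2 + z^2)."""
    samples = window.samples if isinstance(window, Window) else np.asarray(window)
    if samples.size == 0:
        raise ValueError("smv requires a non-empty window")
    return np.sqrt(np.sum(samples**2, axis=1))


_DEGENERATE_STD = 1e-12


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa <= _DEGENERATE_STD or sb <= _DEGENERATE_STD:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _cv(v: np.ndarray) -> float:
    mu = v.mean()
    s = v.std()
    if mu == 0.0 or s <= _DEGENERATE_STD:
        return 0.0
    return float(s / abs(mu))


def _skewness(v: np.ndarray) -> float:
    s = v.std()
    if s <= _DEGENERATE_STD:
        return 0.0
    return float(np.mean((v - v.mean()) ** 3) / s**3)


def _excess_kurtosis(v: np.ndarray) -> float:
    s = v.std()
    if s <= _DEGENERATE_STD:
        return 0.0
    return float(np.mean((v - v.mean()) ** 4) / s**4 - 3.0)


def _autocorr_lag1(v: np.ndarray) -> float:
    if len(v) < 2:
        return 0.0
    return _pearson(v[:-1], v[1:])


def count_peaks(v: np.ndarray, prominence: float | None = None) -> int:
    """Strict local maxima of ``v`` with prominence above the threshold
    (default: the population standard deviation of ``v``)."""
    from scipy.signal import find_peaks

    if prominence is None:
        prominence = float(np.std(v))
    if prominence <= 0.0:
        peaks, _ = find_peaks(v)
    else:
        peaks, _ = find_peaks(v, prominence=prominence)
    return int(len(peaks))


def time_features(window: Window, peak_prominence: float | None = None) -> np.ndarray:
    """The 48 time-domain features, in canonical order."""
    s = window.samples
    x, y, z = s[:, 0], s[:, 1], s[:, 2]
    m = smv(window)
    channels = (x, y, z, m)

    out: list[float] = []
    out += [float(c.mean()) for c in channels]
    out += [float(np.median(c)) for c in channels]
    out += [float(c.std()) for c in channels]
    out += [float(c.max()) for c in channels]
    out += [float(c.min()) for c in channels]
    out += [float(c.max() - c.min()) for c in channels]
    out += [_pearson(x, y), _pearson(y, z), _pearson(z, x)]
    out += [float(np.mean(np.abs(x) + np.abs(y) + np.abs(z)))]  # SMA
    out += [_cv(c) for c in channels]
    out += [float(np.median(np.abs(c - np.median(c)))) for c in channels]  # MAD
    out += [_skewness(m), _excess_kurtosis(m), _autocorr_lag1(m)]
    out += [float(np.percentile(m, q)) for q in (20, 50, 80, 90)]
    out += [float(np.percentile(m, 75) - np.percentile(m, 25))]
    out += [float(count_peaks(m, peak_prominence)), float(m.max() - m.min())]
    out += [float(np.mean(m**2)), float(np.sqrt(np.mean(m**2)))]
    return np.asarray(out)


def magnitude_spectrum(v: np.ndarray, sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT magnitude spectrum of ``v`` excluding the DC bin.

    Magnitudes are scaled by 2/N (amplitude units); returns (freqs_hz, mags).
    """
    n = len(v)
    mags = np.abs(np.fft.rfft(v))[1:] * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)[1:]
    return freqs, mags


def _spectral_entropy(mags: np.ndarray) -> float:
    power = mags**2
    total = power.sum()
    if total == 0.0:
        return 0.0
    p = power / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _spectral_centroid(freqs: np.ndarray, mags: np.ndarray) -> float:
    total = mags.sum()
    if total == 0.0:
        return 0.0
    return float(np.sum(freqs * mags) / total)


def frequency_features(window: Window) -> np.ndarray:
    """The 14 frequency-domain features, in canonical order."""
    s = window.samples
    m = smv(window)
    rate = window.sample_rate_hz
    freqs, smv_mags = magnitude_spectrum(m, rate)
    axis_mags = [magnitude_spectrum(s[:, ax], rate)[1] for ax in range(3)]
    spectra = axis_mags + [smv_mags]

    out: list[float] = [
        _spectral_entropy(smv_mags),
        float(np.sum(smv_mags**2)),
        _spectral_centroid(freqs, smv_mags),
    ]
    out += [float(sp.mean()) for sp in spectra]
    out += [float(sp.std()) for sp in spectra]
    out += [float(np.percentile(smv_mags, q)) for q in (25, 50, 75)]
    return np.asarray(out)


def extract_features(window: Window, peak_prominence: float | None = None) -> np.ndarray:
    """Full 62-dimensional feature vector (time ++ frequency), always finite."""
    fv = np.concatenate(
        [time_features(window, peak_prominence), frequency_features(window)]
    )
    assert fv.shape == (N_FEATURES,)
    return fv


def apply_weights(features: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Element-wise product of a feature vector (or matrix rows) with the
    62-gene weight vector."""
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = features.shape[-1]
    if weights.shape != (n,):
        raise ValueError(
            f"weight length {weights.shape} does not match feature length {n}"
        )
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    return features * weights


def extract_matrix(windows: list[Window], peak_prominence: float | None = None):
    """Feature matrix for a collection of windows: the 62 canonical feature
    columns plus the label columns gender / age_group / activity / subject_id."""
    import pandas as pd

    if not windows:
        raise ValueError("extract_matrix requires at least one window")
    rows = np.vstack([extract_features(w, peak_prominence) for w in windows])
    matrix = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    matrix["subject_id"] = [w.subject_id for w in windows]
    matrix["gender"] = [w.gender for w in windows]
    matrix["age_group"] = [w.age_group for w in windows]
    matrix["activity"] = [w.activity for w in windows]
    return matrix
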