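"""Independent brute-force oracles used by the unit and acceptance tests.

Every statistic here is computed from its textbook definition with code
paths disjoint from the package (explicit sums, sort-and-interpolate
percentiles, a dense DFT matrix instead of an FFT), so agreement with the
implementation is a genuine cross-check.
"""

import math

import numpy as np


def oracle_mean(v):
    return sum(float(x) for x in v) / len(v)


def oracle_percentile(v, q):
    """Linear interpolation between order statistics."""
    s = sorted(float(x) for x in v)
    pos = (len(s) - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return s[lo] * (1.0 - frac) + s[hi] * frac


def oracle_median(v):
    return oracle_percentile(v, 50.0)


def oracle_std(v):
    mu = oracle_mean(v)
    return math.sqrt(sum((float(x) - mu) ** 2 for x in v) / len(v))


def oracle_pearson(a, b):
    sa, sb = oracle_std(a), oracle_std(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    ma, mb = oracle_mean(a), oracle_mean(b)
    cov = sum((float(x) - ma) * (float(y) - mb) for x, y in zip(a, b)) / len(a)
    return cov / (sa * sb)


def oracle_mad(v):
    med = oracle_median(v)
    return oracle_median([abs(float(x) - med) for x in v])


def oracle_moment(v, k):
    mu = oracle_mean(v)
    return sum((float(x) - mu) ** k for x in v) / len(v)


def oracle_skewness(v):
    s = oracle_std(v)
    return oracle_moment(v, 3) / s**3 if s > 0 else 0.0


def oracle_excess_kurtosis(v):
    s = oracle_std(v)
    return oracle_moment(v, 4) / s**4 - 3.0 if s > 0 else 0.0


def oracle_autocorr_lag1(v):
    return oracle_pearson(list(v)[:-1], list(v)[1:])


def oracle_peak_prominences(v):
    """Strict local maxima and their prominences (lowest-contour definition:
    walk out on each side until a higher sample or the edge, take the
    minimum of each excursion, prominence = height - max(side minima))."""
    v = [float(x) for x in v]
    peaks = []
    for i in range(1, len(v) - 1):
        if v[i - 1] < v[i] > v[i + 1]:
            left = v[:i]
            left_min = v[i]
            for x in reversed(left):
                if x > v[i]:
                    break
                left_min = min(left_min, x)
            right_min = v[i]
            for x in v[i + 1 :]:
                if x > v[i]:
                    break
                right_min = min(right_min, x)
            peaks.append((i, v[i] - max(left_min, right_min)))
    return peaks


def oracle_n_peaks(v, prominence):
    return sum(1 for _, p in oracle_peak_prominences(v) if p >= prominence)


def oracle_magnitude_spectrum(v, rate):
    """One-sided DFT magnitudes (dense matrix product), DC excluded, 2/N."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    k = np.arange(n // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    mags = np.abs(dft @ v)[1:] * 2.0 / n
    freqs = k[1:] * rate / n
    return freqs, mags


def oracle_feature_vector(window):
    """All 62 features recomputed from definitions; order matches the
    package's canonical feature order."""
    s = window.samples
    x, y, z = s[:, 0], s[:, 1], s[:, 2]
    m = [math.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)]
    chans = (x, y, z, m)

    out = []
    out += [oracle_mean(c) for c in chans]
    out += [oracle_median(c) for c in chans]
    out += [oracle_std(c) for c in chans]
    out += [max(c) for c in chans]
    out += [min(c) for c in chans]
    out += [max(c) - min(c) for c in chans]
    out += [oracle_pearson(x, y), oracle_pearson(y, z), oracle_pearson(z, x)]
    out += [oracle_mean([abs(a) + abs(b) + abs(c) for a, b, c in zip(x, y, z)])]
    for c in chans:
        mu = oracle_mean(c)
        out.append(oracle_std(c) / abs(mu) if mu != 0 else 0.0)
    out += [oracle_mad(c) for c in chans]
    out += [oracle_skewness(m), oracle_excess_kurtosis(m), oracle_autocorr_lag1(m)]
    out += [oracle_percentile(m, q) for q in (20, 50, 80, 90)]
    out += [oracle_percentile(m, 75) - oracle_percentile(m, 25)]
    out += [float(oracle_n_peaks(m, oracle_std(m)))]
    out += [max(m) - min(m)]
    energy = oracle_mean([v * v for v in m])
    out += [energy, math.sqrt(energy)]

    freqs, smv_mags = oracle_magnitude_spectrum(m, window.sample_rate_hz)
    spectra = [oracle_magnitude_spectrum(c, window.sample_rate_hz)[1] for c in (x, y, z)]
    spectra.append(smv_mags)
    power = smv_mags**2
    total = power.sum()
    p = power / total
    entropy = float(-(p[p > 0] * np.log(p[p > 0])).sum()) if total > 0 else 0.0
    centroid = float((freqs * smv_mags).sum() / smv_mags.sum()) if smv_mags.sum() > 0 else 0.0
    out += [entropy, float(total), centroid]
    out += [oracle_mean(sp) for sp in spectra]
    out += [oracle_std(sp) for sp in spectra]
    out += [oracle_percentile(smv_mags, q) for q in (25, 50, 75)]
    return np.asarray(out)


def oracle_nondominated_sort(points):
    """Front peeling by definition: repeatedly remove the set of points not
    dominated by any remaining point."""
    points = [tuple(map(float, p)) for p in points]
    remaining = list(range(len(points)))
    fronts = []

    def dominates(a, b):
        return all(ai <= bi for ai, bi in zip(a, b)) and any(
            ai < bi for ai, bi in zip(a, b)
        )

    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(points[j], points[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


def oracle_ray_association(point, directions):
    """Closest reference ray by explicit distance-to-line minimisation."""
    best, best_d = None, None
    for j, d in enumerate(np.asarray(directions, dtype=float)):
        u = d / np.linalg.norm(d)
        proj = float(np.dot(point, u))
        dist = float(np.linalg.norm(np.asarray(point) - proj * u))
        if best_d is None or dist < best_d:
            best, best_d = j, dist
    return best, best_d


def oracle_das_dennis(M, p):
    """All lattice points with coordinates i/p summing to 1, by filtering
    the full integer grid."""
    import itertools

    pts = [
        tuple(c / p for c in combo)
        for combo in itertools.product(range(p + 1), repeat=M)
        if sum(combo) == p
    ]
    return set(pts)
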