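import numpy as np
import pytest

from rumibolus.kinematics import ScalarSeries


def make_series(values, fs=12.5, t0=0.0, kind="smoothed_variance"):
    return ScalarSeries(t0=t0, fs=fs, values=np.asarray(values, dtype=float), kind=kind)


def brute_force_peaks(v):
    """Exhaustive neighbour-comparison local maxima, plateau midpoint."""
    v = np.asarray(v, dtype=float)
    peaks = []
    i = 1
    while i < len(v) - 1:
        if v[i - 1] < v[i]:
            j = i
            while j < len(v) - 1 and v[j + 1] == v[i]:
                j += 1
            if j < len(v) - 1 and v[j + 1] < v[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.array(peaks, dtype=int)


def brute_force_prominence(v, i):
    """Contour-lowering scan outward from peak i; ends are low terrain."""
    v = np.asarray(v, dtype=float)
    h = v[i]
    lmin = h
    j = i - 1
    while j >= 0 and v[j] <= h:
        lmin = min(lmin, v[j])
        j -= 1
    rmin = h
    j = i + 1
    while j < len(v) and v[j] <= h:
        rmin = min(rmin, v[j])
        j += 1
    return h - max(lmin, rmin)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
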