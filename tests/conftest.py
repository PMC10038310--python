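import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_runs(mask):
    """Independent run-length scanner: maximal True runs, half-open."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def brute_force_peaks(values, min_prominence):
    """O(n^2) topographic prominence oracle.

    Local maxima (plateaus reported at their left-most index) keep their
    prominence: height minus the higher of the two lowest points separating
    the peak from strictly higher terrain (or the series ends).
    """
    v = list(values)
    n = len(v)
    peaks = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j + 1 < n and v[j + 1] < v[i]:
                h = v[i]
                left_min = h
                for k in range(i - 1, -1, -1):
                    if v[k] > h:
                        break
                    left_min = min(left_min, v[k])
                right_min = h
                for k in range(j + 1, n):
                    if v[k] > h:
                        break
                    right_min = min(right_min, v[k])
                prom = h - max(left_min, right_min)
                if prom >= min_prominence:
                    peaks.append((i, prom))
            i = j + 1
        else:
            i += 1
    return peaks
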