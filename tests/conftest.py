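import numpy as np
import pandas as pd
import pytest

from driftknn.localization_io import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(x, y, frame, dataset, z=None, **extra):
    return LocalizationTable.from_arrays(
        np.asarray(x, float), np.asarray(y, float),
        np.asarray(frame), np.asarray(dataset),
        z=None if z is None else np.asarray(z, float), **extra)


@pytest.fixture
def small_table():
    return make_table(
        x=[1.0, 2.5, 3.0, 4.5], y=[0.5, 1.5, 2.5, 3.5],
        frame=[0, 1, 0, 2], dataset=[0, 0, 1, 1])


def brute_force_nnd_sum(query, reference, l, exclude_self=False):
    """O(n^2) oracle for the thresholded nearest-neighbor distance sum."""
    query = np.asarray(query, float)
    reference = np.asarray(reference, float)
    if len(query) == 0:
        return 0.0
    if exclude_self and len(query) < 2:
        return len(query) * l
    total = 0.0
    for i, q in enumerate(query):
        d = np.sqrt(((reference - q) ** 2).sum(axis=1))
        if exclude_self:
            d = np.delete(d, i)
        total += min(d.min(), l)
    return total


def brute_force_scaled_xcorr(ref, new):
    """Sliding-window linear cross-correlation with overlap scaling.

    Output index (i, j, k) corresponds to lag (i, j, k) - (shape - 1);
    cc[lag] = sum over the overlap of ref[p] * new[p + lag], scaled by
    N_total / overlap_count.
    """
    ref = np.asarray(ref, float)
    new = np.asarray(new, float)
    n = np.array(ref.shape)
    out = np.zeros(2 * n - 1)
    ntot = ref.size
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            for k in range(out.shape[2]):
                lag = np.array([i, j, k]) - (n - 1)
                lo = np.maximum(0, -lag)
                hi = np.minimum(n, n - lag)
                r = ref[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                m = new[lo[0] + lag[0]:hi[0] + lag[0],
                        lo[1] + lag[1]:hi[1] + lag[1],
                        lo[2] + lag[2]:hi[2] + lag[2]]
                count = r.size
                if count:
                    out[i, j, k] = (r * m).sum() * ntot / count
    return out
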