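"""Independent brute-force references for the PCANet stages.

Everything here is written with explicit Python loops and direct
formulas, deliberately sharing no code with the package, so that the
vectorized implementations can be checked stage by stage.
"""

import numpy as np


def naive_patches(arr, k1, k2):
    """All k1 x k2 windows, column-major vectorized, mean removed."""
    arr = np.asarray(arr, dtype=float)
    m, n = arr.shape
    cols = []
    for i in range(m - k1 + 1):
        for j in range(n - k2 + 1):
            w = arr[i : i + k1, j : j + k2]
            v = w.flatten(order="F")
            cols.append(v - v.mean())
    return np.array(cols).T


def naive_filters(patch_matrices, L, k1, k2):
    """Top-L eigenvectors of the explicitly formed pooled covariance."""
    X = np.hstack([np.asarray(p, dtype=float) for p in patch_matrices])
    cov = (X @ X.T) / X.shape[1]
    eigvals, eigvecs = np.linalg.eig(cov)
    order = np.argsort(eigvals.real)[::-1]
    filters = []
    for idx in order[:L]:
        v = eigvecs[:, idx].real
        k = int(np.argmax(np.abs(v)))
        if v[k] < 0:
            v = -v
        filters.append(v.reshape(k1, k2, order="F"))
    return filters


def naive_conv_same(arr, filt):
    """Per-pixel sliding cross-correlation with zero padding."""
    arr = np.asarray(arr, dtype=float)
    filt = np.asarray(filt, dtype=float)
    m, n = arr.shape
    k1, k2 = filt.shape
    p1, p2 = (k1 - 1) // 2, (k2 - 1) // 2
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            acc = 0.0
            for a in range(k1):
                for b in range(k2):
                    ii, jj = i + a - p1, j + b - p2
                    if 0 <= ii < m and 0 <= jj < n:
                        acc += arr[ii, jj] * filt[a, b]
            out[i, j] = acc
    return out


def naive_hash(maps):
    """Per-cell integer from the sign bits of the stacked maps."""
    maps = [np.asarray(m) for m in maps]
    m, n = maps[0].shape
    out = np.zeros((m, n), dtype=int)
    for i in range(m):
        for j in range(n):
            val = 0
            for p, mp in enumerate(maps):
                if mp[i, j] > 0:
                    val += 2**p
            out[i, j] = val
    return out


def naive_block_histogram(hash_map, block_h, block_w, L2):
    """Non-overlapping tiling, hand-counted histograms, row-major."""
    hm = np.asarray(hash_map)
    m, n = hm.shape
    hists = []
    for i in range(0, m - block_h + 1, block_h):
        for j in range(0, n - block_w + 1, block_w):
            counts = [0] * (2**L2)
            for a in range(block_h):
                for b in range(block_w):
                    counts[int(hm[i + a, j + b])] += 1
            hists.extend(counts)
    return np.array(hists, dtype=float)


def naive_transform(arr, bank1, bank2, block_h, block_w, L2):
    """Full chain from learned banks: conv -> conv -> hash -> histogram."""
    feats = []
    for w1 in bank1:
        m1 = naive_conv_same(arr, w1)
        maps2 = [naive_conv_same(m1, w2) for w2 in bank2]
        hashed = naive_hash(maps2)
        feats.append(naive_block_histogram(hashed, block_h, block_w, L2))
    return np.concatenate(feats)


def band_power_welch(x, rate, low, high, nperseg=1024):
    """Integrated Welch PSD in [low, high] Hz — periodogram oracle."""
    from scipy import signal

    f, p = signal.welch(x, fs=rate, nperseg=min(nperseg, len(x)))
    sel = (f >= low) & (f <= high)
    return float(np.trapezoid(p[sel], f[sel]))
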