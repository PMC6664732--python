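"""Two-layer PCANet feature extractor.

PCANet is a convolutional network whose kernels are not trained by
gradient descent: they are the leading eigenvectors of the covariance of
mean-removed image patches.  The cascade implemented here is

1. dense k1 x k2 sliding windows, per-patch mean removal;
2. layer-1 filter bank: top-L1 eigenvectors of the pooled patch
   covariance, applied as same-size (zero-padded) convolutions;
3. layer-2 bank learned the same way from patches of all layer-1 output
   maps, applied to each layer-1 map giving L2 responses per map;
4. binary hashing: at each cell the L2 response signs form the bits of
   an integer in [0, 2^L2 - 1] (bit p has weight 2^(p-1), set iff the
   p-th response is strictly positive);
5. blockwise histograms: each hash map is tiled into B blocks, the
   2^L2-bin histogram of each block is computed, and everything is
   concatenated into a feature vector of length 2^L2 * L1 * B.

Hashing keeps only response signs, so the features are invariant to a
global positive rescaling of the input.  "Convolution" throughout means
sliding cross-correlation (no kernel flip); the convention is fixed and
applied consistently in learning and inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError
from .pca import ReducedEpoch

__all__ = [
    "PCANetSpec",
    "PatchMatrix",
    "FilterBank",
    "PCANetModel",
    "extract_patches",
    "learn_filters",
    "convolve_same",
    "binary_hash",
    "block_histogram",
    "fit",
    "transform",
    "fit_transform",
]


@dataclass
class PCANetSpec:
    """Geometry and size knobs of the network.

    ``k1 x k2`` is the patch (filter) size, odd so that same-size
    zero-padded convolution is centered.  ``L1``/``L2`` are the filter
    counts of the two layers.  ``block_h x block_w`` is the histogram
    block; blocks advance by ``block * (1 - block_overlap)`` and a
    trailing partial block is dropped.  ``layer2_mode`` is ``"pooled"``
    (one bank learned from all layer-1 maps) or ``"per_map"`` (one bank
    per layer-1 filter).
    """

    k1: int = 5
    k2: int = 5
    L1: int = 8
    L2: int = 8
    block_h: int = 8
    block_w: int = 5
    block_overlap: float = 0.0
    layer2_mode: str = "pooled"

    def __post_init__(self) -> None:
        if self.k1 % 2 == 0 or self.k2 % 2 == 0:
            raise ConfigurationError("patch dimensions k1, k2 must be odd")
        if self.k1 < 1 or self.k2 < 1:
            raise ConfigurationError("patch dimensions must be positive")
        d = self.k1 * self.k2
        if not 1 <= self.L1 <= d or not 1 <= self.L2 <= d:
            raise ConfigurationError(
                f"filter counts must be in [1, k1*k2={d}]"
            )
        if self.block_h < 1 or self.block_w < 1:
            raise ConfigurationError("block dimensions must be positive")
        if not 0 <= self.block_overlap < 1:
            raise ConfigurationError("block_overlap must be in [0, 1)")
        if self.layer2_mode not in ("pooled", "per_map"):
            raise ConfigurationError(f"unknown layer2_mode {self.layer2_mode!r}")

    @property
    def patch_dim(self) -> int:
        return self.k1 * self.k2


@dataclass
class PatchMatrix:
    """Mean-removed vectorized patches of one map, (k1*k2) x c columns."""

    columns: np.ndarray

    @property
    def c(self) -> int:
        return self.columns.shape[1]


@dataclass
class FilterBank:
    """Ordered k1 x k2 kernels; vectorized filters are orthonormal."""

    filters: list[np.ndarray]
    layer: int

    def __len__(self) -> int:
        return len(self.filters)

    def as_matrix(self) -> np.ndarray:
        """(k1*k2) x L matrix, one column-major vectorized filter per column."""
        return np.stack([f.ravel(order="F") for f in self.filters], axis=1)


@dataclass
class PCANetModel:
    """Learned two-layer model tied to one input geometry (m, n)."""

    spec: PCANetSpec
    bank1: FilterBank
    bank2: FilterBank | list[FilterBank]
    input_shape: tuple[int, int]

    def bank2_for(self, l: int) -> FilterBank:
        if isinstance(self.bank2, list):
            return self.bank2[l]
        return self.bank2

    def save(self, path) -> None:
        import json

        banks2 = self.bank2 if isinstance(self.bank2, list) else [self.bank2]
        arrays = {"bank1": np.stack(self.bank1.filters)}
        for i, b in enumerate(banks2):
            arrays[f"bank2_{i}"] = np.stack(b.filters)
        meta = {
            "spec": {k: getattr(self.spec, k) for k in (
                "k1", "k2", "L1", "L2", "block_h", "block_w",
                "block_overlap", "layer2_mode")},
            "input_shape": list(self.input_shape),
            "n_bank2": len(banks2),
        }
        np.savez_compressed(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "PCANetModel":
        import json

        with np.load(path) as z:
            meta = json.loads(str(z["meta"]))
            spec = PCANetSpec(**meta["spec"])
            bank1 = FilterBank([f for f in z["bank1"]], layer=1)
            banks2 = [
                FilterBank([f for f in z[f"bank2_{i}"]], layer=2)
                for i in range(meta["n_bank2"])
            ]
        bank2 = banks2 if spec.layer2_mode == "per_map" else banks2[0]
        return cls(spec=spec, bank1=bank1, bank2=bank2,
                   input_shape=tuple(meta["input_shape"]))


def _as_array(x) -> np.ndarray:
    if isinstance(x, ReducedEpoch):
        return np.asarray(x.scores, dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def extract_patches(map_like, spec: PCANetSpec) -> PatchMatrix:
    """All dense stride-1 k1 x k2 windows, vectorized column-major with
    the per-patch mean removed.  Column count c = (m-k1+1)*(n-k2+1)."""
    arr = _as_array(map_like)
    m, n = arr.shape
    if m < spec.k1 or n < spec.k2:
        raise GeometryError(
            f"map {m}x{n} smaller than patch {spec.k1}x{spec.k2}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(arr, (spec.k1, spec.k2))
    # (m-k1+1, n-k2+1, k1, k2) -> columns in row-major window order,
    # each window vectorized column-major (MATLAB-style)
    cols = windows.transpose(2, 3, 0, 1).reshape(
        spec.k1, spec.k2, -1
    ).reshape(spec.patch_dim, -1, order="F")
    # F-order reshape of the (k1, k2, c) block flattens k1 fastest then k2:
    # exactly column-major vectorization of each window.
    cols = cols - cols.mean(axis=0, keepdims=True)
    return PatchMatrix(columns=np.ascontiguousarray(cols))


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] *= -1.0
    return out


def _filters_from_cov(cov: np.ndarray, L: int, k1: int, k2: int,
                      layer: int) -> FilterBank:
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:L]
    top = _fix_signs(eigvecs[:, order])
    filters = [top[:, j].reshape(k1, k2, order="F") for j in range(L)]
    return FilterBank(filters=filters, layer=layer)


def learn_filters(
    patch_matrices: list[PatchMatrix], L: int, spec: PCANetSpec, layer: int = 1
) -> FilterBank:
    """Top-L eigenvectors of the pooled patch covariance, as kernels.

    The covariance is sum_i X_i X_i^T over all patch matrices divided by
    the total number of columns; eigenvectors are ordered by decreasing
    eigenvalue and reshaped column-major to k1 x k2.
    """
    if not patch_matrices:
        raise ConfigurationError("need at least one patch matrix")
    d = spec.patch_dim
    if L > d:
        raise ConfigurationError(f"L={L} exceeds patch dimension {d}")
    cov = np.zeros((d, d))
    total = 0
    for pm in patch_matrices:
        if pm.columns.shape[0] != d:
            raise GeometryError("patch matrix row count != k1*k2")
        cov += pm.columns @ pm.columns.T
        total += pm.c
    if total == 0:
        raise ConfigurationError("no patch columns")
    cov /= total
    return _filters_from_cov(cov, L, spec.k1, spec.k2, layer)


def convolve_same(map_like, filt: np.ndarray) -> np.ndarray:
    """Same-size sliding cross-correlation with zero padding.

    The filter is not flipped; output shape equals input shape.
    """
    arr = _as_array(map_like)
    filt = np.asarray(filt, dtype=np.float64)
    if filt.shape[0] % 2 == 0 or filt.shape[1] % 2 == 0:
        raise GeometryError("filter dimensions must be odd")
    return _conv_bank(arr, filt[:, :, None])[:, :, 0]


def _conv_bank(arr: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Cross-correlate one map with a (k1, k2, L) stack of kernels.

    im2col formulation: zero-pad, extract all windows, single matmul.
    Returns (m, n, L).
    """
    k1, k2, L = filters.shape
    m, n = arr.shape
    p1, p2 = (k1 - 1) // 2, (k2 - 1) // 2
    padded = np.pad(arr, ((p1, p1), (p2, p2)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, (k1, k2))
    cols = windows.reshape(m * n, k1 * k2)
    w = filters.reshape(k1 * k2, L)
    return (cols @ w).reshape(m, n, L)


def _bank_tensor(bank: FilterBank) -> np.ndarray:
    return np.stack(bank.filters, axis=-1)


def fit(train_epochs: list, spec: PCANetSpec | None = None) -> PCANetModel:
    """Learn both filter banks from training epochs only.

    Layer 1 pools patches over all training epochs; layer 2 pools (or,
    in ``per_map`` mode, separates by layer-1 filter) the patches of all
    L1 layer-1 output maps of all training epochs.  Deterministic.
    """
    spec = spec if spec is not None else PCANetSpec()
    if not train_epochs:
        raise ConfigurationError("empty training set")
    arrays = [_as_array(e) for e in train_epochs]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise GeometryError("training epochs have heterogeneous shapes")

    bank1 = learn_filters(
        [extract_patches(a, spec) for a in arrays], spec.L1, spec, layer=1
    )
    w1 = _bank_tensor(bank1)

    d = spec.patch_dim
    if spec.layer2_mode == "pooled":
        cov = np.zeros((d, d))
        total = 0
        for a in arrays:
            maps = _conv_bank(a, w1)
            for l in range(spec.L1):
                pm = extract_patches(maps[:, :, l], spec)
                cov += pm.columns @ pm.columns.T
                total += pm.c
        bank2: FilterBank | list[FilterBank] = _filters_from_cov(
            cov / total, spec.L2, spec.k1, spec.k2, layer=2
        )
    else:
        covs = [np.zeros((d, d)) for _ in range(spec.L1)]
        totals = [0] * spec.L1
        for a in arrays:
            maps = _conv_bank(a, w1)
            for l in range(spec.L1):
                pm = extract_patches(maps[:, :, l], spec)
                covs[l] += pm.columns @ pm.columns.T
                totals[l] += pm.c
        bank2 = [
            _filters_from_cov(covs[l] / totals[l], spec.L2, spec.k1, spec.k2, 2)
            for l in range(spec.L1)
        ]
    return PCANetModel(spec=spec, bank1=bank1, bank2=bank2, input_shape=shape)


def binary_hash(layer2_maps: list[np.ndarray]) -> np.ndarray:
    """Sign pattern of the L2 responses at each cell as one integer.

    Bit p (weight 2^(p-1)) is set iff the p-th map is strictly positive
    there; zero counts as negative.
    """
    if not layer2_maps:
        raise ConfigurationError("need at least one layer-2 map")
    shape = np.asarray(layer2_maps[0]).shape
    out = np.zeros(shape, dtype=np.int64)
    for p, m in enumerate(layer2_maps):
        m = np.asarray(m)
        if m.shape != shape:
            raise GeometryError("layer-2 maps have heterogeneous shapes")
        out += (1 << p) * (m > 0)
    return out


def block_histogram(hash_map: np.ndarray, spec: PCANetSpec, L2: int) -> np.ndarray:
    """Per-block counts of the 2^L2 hash values, blocks concatenated
    row-major.  Blocks advance by block*(1-overlap); trailing partial
    blocks are dropped."""
    hm = np.asarray(hash_map)
    m, n = hm.shape
    if spec.block_h > m or spec.block_w > n:
        raise GeometryError(
            f"block {spec.block_h}x{spec.block_w} larger than map {m}x{n}"
        )
    step_h = max(1, int(round(spec.block_h * (1 - spec.block_overlap))))
    step_w = max(1, int(round(spec.block_w * (1 - spec.block_overlap))))
    n_bins = 1 << L2
    hists = []
    for i in range(0, m - spec.block_h + 1, step_h):
        for j in range(0, n - spec.block_w + 1, step_w):
            block = hm[i : i + spec.block_h, j : j + spec.block_w]
            hists.append(np.bincount(block.ravel(), minlength=n_bins)[:n_bins])
    return np.concatenate(hists).astype(np.float64)


def n_blocks(spec: PCANetSpec, shape: tuple[int, int]) -> int:
    """Number of histogram blocks B for a given map shape."""
    m, n = shape
    step_h = max(1, int(round(spec.block_h * (1 - spec.block_overlap))))
    step_w = max(1, int(round(spec.block_w * (1 - spec.block_overlap))))
    if spec.block_h > m or spec.block_w > n:
        raise GeometryError("block larger than map")
    return len(range(0, m - spec.block_h + 1, step_h)) * len(
        range(0, n - spec.block_w + 1, step_w)
    )


def transform(model: PCANetModel, epoch) -> np.ndarray:
    """Feature vector of one epoch: length 2^L2 * L1 * B."""
    arr = _as_array(epoch)
    if arr.shape != tuple(model.input_shape):
        raise GeometryError(
            f"epoch shape {arr.shape} != model geometry {model.input_shape}"
        )
    spec = model.spec
    maps1 = _conv_bank(arr, _bank_tensor(model.bank1))
    feats = []
    for l in range(spec.L1):
        maps2 = _conv_bank(maps1[:, :, l], _bank_tensor(model.bank2_for(l)))
        hashed = binary_hash([maps2[:, :, p] for p in range(spec.L2)])
        feats.append(block_histogram(hashed, spec, spec.L2))
    return np.concatenate(feats)


def fit_transform(train_epochs: list, spec: PCANetSpec | None = None):
    """Convenience: fit on ``train_epochs`` and return (model, features)."""
    model = fit(train_epochs, spec)
    features = np.stack([transform(model, e) for e in train_epochs])
    return model, features
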