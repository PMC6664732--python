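"""Per-sample PCA compression of epochs.

Each m x n epoch (32 channels x 2000 time-points by default) is treated
as m observations of an n-dimensional variable: PCA over the time-point
variables yields at most m - 1 non-trivial components, and keeping the
leading r gives an m x r score matrix.  The retained count r is either
fixed (default 20) or the smallest r whose components explain at least a
variance fraction threshold (default 99%).

Because the rank is bounded by the channel count, the decomposition is
computed from the economy SVD of the centered m x n matrix — an n x n
covariance is never formed.

PCA is fit independently per epoch by default; score columns of
different epochs therefore live in *different* bases and are not
directly comparable across epochs.  Downstream feature extraction that
operates on local structure of the score matrix (PCANet) is unaffected;
anything that would compare a given score column across epochs would
need the optional pooled-basis mode instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, GeometryError
from .preprocess import Epoch

__all__ = [
    "ReductionSpec",
    "ReducedEpoch",
    "choose_r",
    "reduce_epoch",
    "reduce_dataset",
]


@dataclass
class ReductionSpec:
    """How many components to retain.

    ``variance_threshold`` keeps the smallest r explaining at least
    ``threshold`` of total variance; ``fixed_r`` always keeps ``fixed_r``.
    """

    mode: str = "fixed_r"
    threshold: float = 0.99
    fixed_r: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("variance_threshold", "fixed_r"):
            raise ConfigurationError(f"unknown reduction mode {self.mode!r}")
        if not 0 < self.threshold <= 1:
            raise ConfigurationError("threshold must be in (0, 1]")
        if self.fixed_r < 1:
            raise ConfigurationError("fixed_r must be >= 1")


@dataclass
class ReducedEpoch:
    """PCA scores of one epoch: channels x retained components.

    ``loadings`` (r x n right singular vectors) are kept only on request;
    with them, ``scores @ loadings`` reconstructs the centered epoch.
    """

    scores: np.ndarray
    r: int
    explained_ratio: float
    label: str | None = None
    subject_id: str | None = None
    loadings: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


def choose_r(eigenvalues: np.ndarray, threshold: float) -> int:
    """Smallest r with (sum of first r eigenvalues)/total >= threshold.

    Eigenvalues must be non-negative and non-increasing.
    """
    ev = np.asarray(eigenvalues, dtype=np.float64)
    if ev.ndim != 1 or ev.size == 0:
        raise ConfigurationError("eigenvalues must be a non-empty 1-D sequence")
    if np.any(ev < -1e-12 * max(ev.max(initial=0.0), 1.0)):
        raise ConfigurationError("eigenvalues must be non-negative")
    if np.any(np.diff(ev) > 1e-9 * max(ev.max(initial=0.0), 1.0)):
        raise ConfigurationError("eigenvalues must be non-increasing")
    total = ev.sum()
    if total <= 0:
        raise DegenerateInputError("all eigenvalues are zero")
    ratio = np.cumsum(ev) / total
    # tiny slack so threshold=1.0 is met once all positive eigenvalues are in
    idx = np.flatnonzero(ratio >= threshold - 1e-12)
    return int(idx[0]) + 1


def _svd_scores(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered economy SVD with a deterministic sign convention.

    Returns (scores = U*S, singular values, loadings Vt).  Each
    component is flipped so its largest-magnitude loading is positive.
    """
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for j in range(s.size):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    return u * s, s, vt


def reduce_epoch(
    epoch: Epoch,
    spec: ReductionSpec | None = None,
    keep_loadings: bool = False,
) -> ReducedEpoch:
    """Compress one epoch to its leading principal-component scores."""
    spec = spec if spec is not None else ReductionSpec()
    data = np.asarray(epoch.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ConfigurationError("epoch contains non-finite values")
    m = data.shape[0]
    scores, s, vt = _svd_scores(data)
    eigvals = s**2
    total = eigvals.sum()
    if spec.mode == "fixed_r":
        if spec.fixed_r >= m:
            raise GeometryError(
                f"fixed_r={spec.fixed_r} must be < channel count {m} "
                "(centering removes one degree of freedom)"
            )
        r = spec.fixed_r
    else:
        r = choose_r(eigvals, spec.threshold)
    explained = float(eigvals[:r].sum() / total) if total > 0 else 0.0
    return ReducedEpoch(
        scores=scores[:, :r].copy(),
        r=r,
        explained_ratio=explained,
        label=epoch.label,
        subject_id=epoch.subject_id,
        loadings=vt[:r].copy() if keep_loadings else None,
    )


def reduce_dataset(
    epochs: list[Epoch],
    spec: ReductionSpec | None = None,
    harmonize: str = "max",
    basis: str = "per_epoch",
) -> list[ReducedEpoch]:
    """Reduce every epoch, enforcing one common r across the dataset.

    In threshold mode different epochs can demand different r; PCANet
    needs a fixed input geometry, so the per-epoch choices are
    harmonized: ``"max"`` re-reduces everything to the largest r seen
    (each epoch then meets the threshold), ``"min"`` to the smallest.

    ``basis="pooled"`` fits one basis on the channel rows of all epochs
    stacked, making score columns comparable across epochs (at the cost
    of a cross-epoch dependence in the fit).
    """
    spec = spec if spec is not None else ReductionSpec()
    if basis == "pooled":
        return _reduce_pooled(epochs, spec)
    if basis != "per_epoch":
        raise ConfigurationError(f"unknown basis mode {basis!r}")
    reduced = [reduce_epoch(e, spec) for e in epochs]
    if spec.mode == "variance_threshold" and reduced:
        rs = {re.r for re in reduced}
        if len(rs) > 1:
            if harmonize not in ("max", "min"):
                raise ConfigurationError(f"unknown harmonize rule {harmonize!r}")
            r_common = max(rs) if harmonize == "max" else min(rs)
            fixed = ReductionSpec(mode="fixed_r", fixed_r=r_common)
            reduced = [reduce_epoch(e, fixed) for e in epochs]
    return reduced


def _reduce_pooled(epochs: list[Epoch], spec: ReductionSpec) -> list[ReducedEpoch]:
    """One basis from all epochs' channel rows stacked, applied to each."""
    if not epochs:
        return []
    stacked = np.vstack([np.asarray(e.data, dtype=np.float64) for e in epochs])
    if not np.all(np.isfinite(stacked)):
        raise ConfigurationError("epoch contains non-finite values")
    mean = stacked.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(stacked - mean, full_matrices=False)
    for j in range(s.size):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] *= -1.0
    eigvals = s**2
    if spec.mode == "fixed_r":
        if spec.fixed_r > s.size:
            raise GeometryError("fixed_r exceeds pooled rank")
        r = spec.fixed_r
    else:
        r = choose_r(eigvals, spec.threshold)
    total = eigvals.sum()
    explained = float(eigvals[:r].sum() / total) if total > 0 else 0.0
    basis = vt[:r]
    return [
        ReducedEpoch(
            scores=(np.asarray(e.data, dtype=np.float64) - mean) @ basis.T,
            r=r,
            explained_ratio=explained,
            label=e.label,
            subject_id=e.subject_id,
        )
        for e in epochs
    ]
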