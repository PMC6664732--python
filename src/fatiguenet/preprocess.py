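"""Raw-recording preprocessing: crop, downsample, bandpass, epoch.

The canonical pipeline turns a continuous multichannel recording into
fixed-size classification samples: crop to the analysis span, polyphase
downsample 500 -> 200 Hz, third-order Butterworth bandpass 0.1-45 Hz,
then non-overlapping 10-s segmentation, which at 200 Hz yields
32 x 2000 epochs (120 per 20-minute recording).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import ConfigurationError, GeometryError

__all__ = [
    "EEGRecording",
    "Epoch",
    "EpochSet",
    "crop",
    "downsample",
    "bandpass",
    "segment",
    "preprocess_recording",
]


@dataclass
class EEGRecording:
    """A continuous multichannel EEG recording in microvolts.

    ``data`` is channels x time-points; ``rate`` in Hz; ``channel_names``
    parallel to the rows of ``data``.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise GeometryError("recording data must be 2-D (channels x time)")
        if self.rate <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class Epoch:
    """One fixed-duration segment treated as a single classification sample."""

    data: np.ndarray
    rate: float
    label: str | None = None
    subject_id: str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class EpochSet:
    """Ordered epochs with parallel labels."""

    epochs: list[Epoch]

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i: int) -> Epoch:
        return self.epochs[i]

    @property
    def labels(self) -> list[str | None]:
        return [e.label for e in self.epochs]


def crop(rec: EEGRecording, seconds: float) -> EEGRecording:
    """Keep the first ``seconds`` of the recording (shorter input unchanged)."""
    if seconds <= 0:
        raise ConfigurationError("crop span must be positive")
    n = min(rec.n_samples, int(round(seconds * rec.rate)))
    return replace(rec, data=rec.data[:, :n].copy())


def downsample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Polyphase anti-aliased resampling to ``target_rate``.

    Upsampling is refused; an equal rate returns the recording unchanged.
    """
    if target_rate > rec.rate:
        raise ConfigurationError(
            f"upsampling not supported ({rec.rate} -> {target_rate} Hz)"
        )
    if target_rate == rec.rate:
        return rec
    ratio = Fraction(target_rate).limit_denominator(10**6) / Fraction(
        rec.rate
    ).limit_denominator(10**6)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    n_keep = int(np.floor(rec.n_samples * float(ratio)))
    return replace(rec, data=out[:, :n_keep], rate=float(target_rate))


def bandpass(
    rec: EEGRecording,
    low: float = 0.1,
    high: float = 45.0,
    order: int = 3,
    zero_phase: bool = False,
) -> EEGRecording:
    """Butterworth bandpass applied per channel.

    ``order`` is the prototype order (3 pole pairs for the default).
    Causal single-pass filtering by default; ``zero_phase=True`` switches to
    forward-backward filtering (effective order doubled, no group delay).
    """
    nyq = rec.rate / 2.0
    if not 0 < low < high:
        raise ConfigurationError("need 0 < low < high")
    if high >= nyq:
        raise ConfigurationError(
            f"high cutoff {high} Hz not below Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    out = filt(sos, rec.data, axis=1)
    return replace(rec, data=np.ascontiguousarray(out))


def segment(rec: EEGRecording, window: float = 10.0,
            label: str | None = None, subject_id: str | None = None) -> EpochSet:
    """Cut into consecutive non-overlapping windows; a trailing partial
    window is discarded. A recording shorter than one window yields an
    empty set."""
    if window <= 0:
        raise ConfigurationError("window must be positive")
    n_win = int(round(window * rec.rate))
    n_epochs = rec.n_samples // n_win
    epochs = [
        Epoch(
            data=rec.data[:, i * n_win : (i + 1) * n_win].copy(),
            rate=rec.rate,
            label=label,
            subject_id=subject_id,
        )
        for i in range(n_epochs)
    ]
    return EpochSet(epochs)


def preprocess_recording(
    rec: EEGRecording,
    target_rate: float = 200.0,
    low: float = 0.1,
    high: float = 45.0,
    order: int = 3,
    window: float = 10.0,
    analysis_span: float | None = 1200.0,
    zero_phase: bool = False,
    label: str | None = None,
    subject_id: str | None = None,
) -> EpochSet:
    """Full preprocessing chain: crop -> downsample -> bandpass -> segment."""
    if analysis_span is not None:
        rec = crop(rec, analysis_span)
    rec = downsample(rec, target_rate)
    rec = bandpass(rec, low=low, high=high, order=order, zero_phase=zero_phase)
    return segment(rec, window=window, label=label, subject_id=subject_id)
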