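"""Comparison feature extractors: STFT band power and wavelet packets.

Two conventional EEG feature sets used as baselines for the PCANet
pipeline:

* ``stft_band_power`` — per channel, the power spectral density is
  estimated by a short-time Fourier transform (128-point Hann window,
  50% overlap) and averaged within the five canonical EEG bands
  (delta/theta/alpha/beta/gamma), giving 5 x 32 = 160 features for a
  default epoch.
* ``wpd_features`` — per channel, a full wavelet-packet tree (default
  Daubechies-4, 3 levels, symmetric extension) whose 2^3 = 8
  terminal-node coefficient vectors are concatenated.  For a 2000-point
  channel each node carries 256 coefficients, 65536 features per epoch.

Daubechies-4 is the order for which a 2000-point signal yields exactly
256 coefficients per level-3 node under symmetric extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from .errors import ConfigurationError, GeometryError
from .preprocess import Epoch

__all__ = [
    "StftSpec",
    "Band",
    "BandTable",
    "DEFAULT_BANDS",
    "WpdSpec",
    "stft_band_power",
    "psd_feature_names",
    "wpd_features",
]


@dataclass
class StftSpec:
    n_fft: int = 128
    window: str = "hann"
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ConfigurationError("overlap must be in [0, 1)")
        if self.n_fft < 2:
            raise ConfigurationError("n_fft must be >= 2")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.n_fft * (1 - self.overlap))))


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float


@dataclass
class BandTable:
    """Ordered, non-overlapping, ascending frequency bands."""

    bands: list[Band]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("band table is empty")
        prev_high = 0.0
        for b in self.bands:
            if not 0 <= b.low < b.high:
                raise ConfigurationError(f"band {b.name}: need 0 <= low < high")
            if b.low < prev_high:
                raise ConfigurationError(
                    f"band {b.name} overlaps the previous band"
                )
            prev_high = b.high

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def validate_rate(self, rate: float) -> None:
        if self.bands[-1].high > rate / 2:
            raise ConfigurationError(
                f"band {self.bands[-1].name} exceeds Nyquist {rate / 2} Hz"
            )


DEFAULT_BANDS = BandTable(
    bands=[
        Band("delta", 0.1, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha", 8.0, 13.0),
        Band("beta", 13.0, 20.0),
        Band("gamma", 20.0, 45.0),
    ]
)


@dataclass
class WpdSpec:
    wavelet: str = "db4"
    level: int = 3
    extension: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ConfigurationError("level must be >= 1")
        if self.wavelet not in pywt.wavelist(kind="discrete"):
            raise ConfigurationError(f"unknown wavelet {self.wavelet!r}")


def stft_band_power(
    epoch: Epoch,
    stft: StftSpec | None = None,
    bands: BandTable | None = None,
) -> np.ndarray:
    """Mean in-band PSD per channel, channel-major concatenation.

    Each channel is framed (Hann taper, 50% overlap by default) and the
    squared STFT magnitudes are averaged over frames and over the FFT
    bins whose center frequency f satisfies low <= f < high (the last
    band is closed at its upper edge).  Output length = channels x bands,
    ordered channel-major: all bands of channel 0 first.
    """
    stft = stft if stft is not None else StftSpec()
    bands = bands if bands is not None else DEFAULT_BANDS
    data = np.asarray(epoch.data, dtype=np.float64)
    if data.shape[1] < stft.n_fft:
        raise GeometryError("epoch shorter than one STFT window")
    bands.validate_rate(epoch.rate)

    noverlap = stft.n_fft - stft.hop
    freqs, _, sxx = signal.spectrogram(
        data,
        fs=epoch.rate,
        window=stft.window,
        nperseg=stft.n_fft,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
        axis=-1,
    )
    # sxx: (channels, freqs, frames); average over frames first
    mean_psd = sxx.mean(axis=-1)
    last = bands.bands[-1]
    out = np.empty((data.shape[0], len(bands)))
    for bi, b in enumerate(bands):
        if b is last:
            sel = (freqs >= b.low) & (freqs <= b.high)
        else:
            sel = (freqs >= b.low) & (freqs < b.high)
        if not np.any(sel):
            raise ConfigurationError(
                f"band {b.name} contains no FFT bins at rate {epoch.rate}"
            )
        out[:, bi] = mean_psd[:, sel].mean(axis=1)
    return out.ravel()


def psd_feature_names(channel_names: list[str],
                      bands: BandTable | None = None) -> list[str]:
    bands = bands if bands is not None else DEFAULT_BANDS
    return [f"{ch}:{b.name}" for ch in channel_names for b in bands]


def n_stft_frames(n_samples: int, stft: StftSpec | None = None) -> int:
    """Frames produced for an n-sample channel: floor((n-nfft)/hop)+1."""
    stft = stft if stft is not None else StftSpec()
    if n_samples < stft.n_fft:
        return 0
    return (n_samples - stft.n_fft) // stft.hop + 1


def wpd_features(epoch: Epoch, spec: WpdSpec | None = None) -> np.ndarray:
    """Terminal-node wavelet-packet coefficients, channels concatenated.

    Per channel: the full packet tree to ``spec.level`` is built and the
    2^level leaf coefficient vectors are concatenated in natural node
    order; channel blocks are then concatenated in channel order.
    """
    spec = spec if spec is not None else WpdSpec()
    data = np.asarray(epoch.data, dtype=np.float64)
    if data.shape[1] < 2**spec.level:
        raise GeometryError("epoch too short for the requested level")
    feats = []
    for ch in data:
        wp = pywt.WaveletPacket(
            data=ch, wavelet=spec.wavelet, mode=spec.extension,
            maxlevel=spec.level,
        )
        nodes = wp.get_level(spec.level, order="natural")
        feats.append(np.concatenate([node.data for node in nodes]))
    return np.concatenate(feats)


def wpd_node_length(n_samples: int, spec: WpdSpec | None = None) -> int:
    """Coefficient count per terminal node, by the recursive
    half-length rule len -> floor((len + filter_len - 1) / 2)."""
    spec = spec if spec is not None else WpdSpec()
    flen = pywt.Wavelet(spec.wavelet).dec_len
    n = n_samples
    for _ in range(spec.level):
        n = pywt.dwt_coeff_len(n, flen, mode=spec.extension)
    return n
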