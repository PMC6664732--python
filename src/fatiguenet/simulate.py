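"""Synthetic 32-channel EEG with an awake/fatigue spectral contrast.

Real drowsiness recordings show elevated alpha (8-13 Hz) and beta
(13-20 Hz) power over parietal-occipital sites.  The generator emulates
exactly that phenomenology: each channel is Gaussian 1/f background
activity plus band-limited alpha and beta oscillations; in the fatigue
state the oscillation amplitudes on the affected (posterior) channels
are multiplied by configurable gains > 1.

All randomness is drawn in a state-independent order, so an awake and a
fatigue recording built from the same seed share background and
oscillation waveforms bit-for-bit and differ only in the deterministic
gain pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .preprocess import EEGRecording

__all__ = [
    "STANDARD_32",
    "DEFAULT_AFFECTED",
    "SimulationConfig",
    "LabelledRecording",
    "generate_recording",
    "generate_dataset",
]

# Brain Products style 32-electrode montage, international 10-20 labels.
STANDARD_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]

DEFAULT_AFFECTED = ["P3", "Pz", "P4", "O1", "Oz", "O2"]

_BANDS = {"alpha": (8.0, 13.0), "beta": (13.0, 20.0)}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    Amplitudes are RMS microvolts.  ``band_gains`` maps a band name to a
    pair ``(affected_gain, other_gain)`` applied in *both* states — it
    encodes the physiological posterior dominance of the alpha rhythm —
    while ``fatigue_*_gain`` are the state contrast multipliers applied
    on affected channels only when ``state == "fatigue"``.
    """

    n_channels: int = 32
    channel_names: list[str] = field(default_factory=lambda: list(STANDARD_32))
    rate: float = 500.0
    duration: float = 10.0
    state: str = "awake"
    background_exponent: float = 1.0
    noise_sd: float = 10.0
    alpha_amp: float = 5.0
    beta_amp: float = 2.5
    band_gains: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (1.5, 1.0), "beta": (1.2, 1.0)}
    )
    affected_channels: list[str] = field(default_factory=lambda: list(DEFAULT_AFFECTED))
    fatigue_alpha_gain: float = 2.0
    fatigue_beta_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.rate <= 0:
            raise ConfigurationError("rate must be positive")
        if self.state not in ("awake", "fatigue"):
            raise ConfigurationError(f"unknown state {self.state!r}")
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError(
                "channel_names length must equal n_channels"
            )
        if self.fatigue_alpha_gain < 1 or self.fatigue_beta_gain < 1:
            raise ConfigurationError("fatigue gains must be >= 1")
        if self.noise_sd < 0 or self.alpha_amp < 0 or self.beta_amp < 0:
            raise ConfigurationError("amplitudes must be non-negative")


@dataclass
class LabelledRecording:
    recording: EEGRecording
    state: str
    subject_id: str


def _one_over_f(rng: np.random.Generator, n: int, rate: float,
                exponent: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^exponent amplitude spectrum."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n=n)
    return x / np.std(x)


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                low: float, high: float) -> np.ndarray:
    """Unit-RMS noise confined to [low, high] Hz (frequency-domain mask)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    mask = (freqs >= low) & (freqs <= high)
    x = np.fft.irfft(spec * mask, n=n)
    return x / np.std(x)


def _oscillation(rng: np.random.Generator, t: np.ndarray, rate: float,
                 low: float, high: float) -> np.ndarray:
    """Unit-RMS rhythm: random-frequency sinusoid plus narrowband noise."""
    f0 = rng.uniform(low, high)
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * f0 * t + phase)
    wave = wave / np.std(wave) + _band_noise(rng, t.size, rate, low, high)
    return wave / np.std(wave)


def generate_recording(config: SimulationConfig) -> EEGRecording:
    """Synthesize one recording according to ``config``.

    Deterministic: the output is a pure function of the config including
    its seed, and the state only modulates deterministic gains.
    """
    n = int(round(config.duration * config.rate))
    t = np.arange(n) / config.rate
    rng = np.random.default_rng(config.seed)
    affected = np.array(
        [name in set(config.affected_channels) for name in config.channel_names]
    )

    data = np.empty((config.n_channels, n))
    amps = {"alpha": config.alpha_amp, "beta": config.beta_amp}
    fat = {"alpha": config.fatigue_alpha_gain, "beta": config.fatigue_beta_gain}
    for ch in range(config.n_channels):
        x = config.noise_sd * _one_over_f(
            rng, n, config.rate, config.background_exponent
        )
        for band, (low, high) in _BANDS.items():
            g_aff, g_oth = config.band_gains.get(band, (1.0, 1.0))
            gain = g_aff if affected[ch] else g_oth
            if config.state == "fatigue" and affected[ch]:
                gain *= fat[band]
            x = x + amps[band] * gain * _oscillation(rng, t, config.rate, low, high)
        data[ch] = x
    return EEGRecording(data=data, rate=config.rate,
                        channel_names=list(config.channel_names))


def generate_dataset(
    n_subjects: int,
    per_state_duration: float,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
) -> list[LabelledRecording]:
    """One awake plus one fatigue recording per subject.

    Per-subject oscillation amplitudes are jittered by +-10% (the same
    jitter for both states, so the awake/fatigue contrast is untouched)
    and per-(subject, state) seeds are derived deterministically from the
    master seed.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    base = base_config if base_config is not None else SimulationConfig()
    out: list[LabelledRecording] = []
    ss = np.random.SeedSequence(seed)
    for subj_idx, child in enumerate(ss.spawn(n_subjects)):
        jitter_rng = np.random.default_rng(child)
        ja, jb = jitter_rng.uniform(0.9, 1.1, size=2)
        state_seeds = [int(s.generate_state(1)[0] % 2**31) for s in child.spawn(2)]
        subject_id = f"S{subj_idx + 1:02d}"
        for state, sd in zip(("awake", "fatigue"), state_seeds):
            cfg = replace(
                base,
                duration=per_state_duration,
                state=state,
                alpha_amp=base.alpha_amp * ja,
                beta_amp=base.beta_amp * jb,
                seed=sd,
            )
            out.append(
                LabelledRecording(
                    recording=generate_recording(cfg),
                    state=state,
                    subject_id=subject_id,
                )
            )
    return out
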