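"""Synthetic sEMG with known synergy structure and programmable fatigue.

Surface EMG is modelled with the standard amplitude-cascade picture: a slow
non-negative synergy envelope (muscle weights x temporal activations)
multiplies a fast, zero-mean, band-limited stochastic carrier.  Fatigue
sessions additionally apply a time-varying spectral compression (first-order
low-pass whose cutoff tracks the median-frequency ramp) plus a slowly growing
deterministic component, so that RMS drifts up while median frequency,
permutation entropy and fractal dimension drift down coherently.

Every generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .recording import EMGRecording

__all__ = [
    "SynergyGroundTruth",
    "FatigueProgram",
    "make_activation_waveforms",
    "generate_synergy_emg",
    "generate_fatigue_emg",
    "band_limited_noise",
]

#: Band (Hz) holding the bulk of sEMG energy; default carrier band.
DEFAULT_CARRIER_BAND = (20.0, 150.0)

FEATURE_NAMES = ("RMS", "MF", "PE", "FD")


@dataclass
class SynergyGroundTruth:
    """Latent synergy model generating a multichannel recording.

    ``muscle_weights`` (channels x R, non-negative, unit-norm columns) and
    ``activations`` (R x samples, non-negative) define the per-channel
    envelope ``env_i(t) = sum_r W[i, r] H[r, t]``.
    """

    muscle_weights: np.ndarray
    activations: np.ndarray
    carrier_band: tuple[float, float] = DEFAULT_CARRIER_BAND
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.muscle_weights = np.asarray(self.muscle_weights, dtype=float)
        self.activations = np.asarray(self.activations, dtype=float)
        if self.muscle_weights.ndim != 2 or self.activations.ndim != 2:
            raise ValueError("muscle_weights and activations must be 2-D")
        if self.muscle_weights.shape[1] != self.activations.shape[0]:
            raise ValueError("rank mismatch between weights and activations")
        if np.any(self.muscle_weights < 0) or np.any(self.activations < 0):
            raise ValueError("synergy factors must be non-negative")
        if not np.all(np.isfinite(self.activations)):
            raise ValueError("activations must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        norms = np.linalg.norm(self.muscle_weights, axis=0)
        if np.any(norms == 0):
            raise ValueError("muscle-weight columns must be non-zero")
        self.muscle_weights = self.muscle_weights / norms

    @property
    def rank(self) -> int:
        return self.muscle_weights.shape[1]

    @property
    def n_channels(self) -> int:
        return self.muscle_weights.shape[0]

    @classmethod
    def random(
        cls,
        rank: int = 3,
        channels: int = 4,
        samples: int = 1200,
        fs: float = 400.0,
        noise_sd: float = 0.0,
        seed: int = 0,
    ) -> "SynergyGroundTruth":
        """Random but identifiable ground truth.

        Each synergy is dominated by a distinct muscle (plus small random
        co-activation), as in physiological synergies; fully random positive
        weight columns are near-collinear and would leave the latent rank
        unrecoverable by any reconstruction-quality criterion.
        """
        rng = np.random.default_rng(seed)
        w = 0.15 * np.abs(rng.normal(size=(channels, rank)))
        for r in range(rank):
            w[r % channels, r] += 1.0
        h = make_activation_waveforms(rank, samples, fs, seed=seed + 1)
        return cls(w, h, noise_sd=noise_sd, seed=seed)


@dataclass
class FatigueProgram:
    """Programmed drift of the four fatigue features over a session.

    ``ramp`` maps each of RMS, MF, PE, FD to (start, end) multipliers applied
    linearly over ``duration_s``.  The default session mirrors a 3-minute
    piano-playing task with rising effort: amplitude up 50%, spectrum
    compressed to 70%, complexity down to 80%.
    """

    duration_s: float = 180.0
    ramp: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "RMS": (1.0, 1.5),
            "MF": (1.0, 0.7),
            "PE": (1.0, 0.8),
            "FD": (1.0, 0.8),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in FEATURE_NAMES:
            self.ramp.setdefault(name, (1.0, 1.0))
        for name, (a, b) in self.ramp.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} multipliers must be positive")

    def multipliers(self, name: str, n: int) -> np.ndarray:
        """Per-sample multiplier track for feature ``name`` over n samples."""
        a, b = self.ramp[name]
        return a + (b - a) * np.linspace(0.0, 1.0, n)


def make_activation_waveforms(
    R: int, samples: int, fs: float, seed: int = 0
) -> np.ndarray:
    """Smooth non-negative burst waveforms, one row per synergy, peak value 1.

    Each component gets a main Gaussian burst at a distinct time plus two
    smaller seeded side bursts, emulating repeated key-press activations.
    """
    if R < 1 or samples < 1:
        raise ValueError("R and samples must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(samples)
    out = np.zeros((R, samples))
    for r in range(R):
        center = (r + 0.5) / R * samples
        width = max(4.0, 0.06 * samples) * (0.8 + 0.4 * rng.random())
        out[r] = np.exp(-0.5 * ((t - center) / width) ** 2)
        for _ in range(2):
            c2 = rng.uniform(0, samples)
            w2 = max(3.0, 0.04 * samples) * (0.8 + 0.4 * rng.random())
            out[r] += rng.uniform(0.1, 0.3) * np.exp(-0.5 * ((t - c2) / w2) ** 2)
        out[r] /= out[r].max()
    return out


def band_limited_noise(
    samples: int,
    fs: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (4th order, zero-phase)."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"carrier band {band} must lie inside (0, {fs / 2})")
    x = rng.standard_normal(samples)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_synergy_emg(
    truth: SynergyGroundTruth, fs: float = 400.0, samples: int | None = None
) -> EMGRecording:
    """Render a recording from a synergy ground truth.

    Channel i is ``sum_r W[i,r] H[r,t] * c_i(t) + eps`` with ``c_i`` an
    independent unit-variance carrier per channel and ``eps ~ N(0, noise_sd^2)``.
    """
    if samples is None:
        samples = truth.activations.shape[1]
    if samples != truth.activations.shape[1]:
        raise ValueError("samples must match activation length")
    low, high = truth.carrier_band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"carrier band {truth.carrier_band} exceeds Nyquist {fs / 2}")
    rng = np.random.default_rng(truth.seed)
    env = truth.muscle_weights @ truth.activations  # channels x samples
    out = np.empty_like(env)
    for i in range(truth.n_channels):
        carrier = band_limited_noise(samples, fs, truth.carrier_band, rng)
        out[i] = env[i] * carrier
    if truth.noise_sd > 0:
        out = out + rng.normal(scale=truth.noise_sd, size=out.shape)
    names = [f"ch{i}" for i in range(truth.n_channels)]
    return EMGRecording(out, fs=fs, channel_names=names)


def generate_fatigue_emg(
    program: FatigueProgram,
    channels: int = 4,
    fs: float = 400.0,
) -> tuple[EMGRecording, np.ndarray]:
    """Render a fatigue session and its programmed fatigue level.

    Mechanism, per channel: a band-limited carrier is passed through a
    first-order low-pass whose cutoff tracks the MF ramp (spectral
    compression), amplitude-whitened, mixed with a slow deterministic
    oscillation whose share grows as the PE/FD ramps fall, then scaled by the
    RMS ramp.  Returns ``(recording, level)`` where ``level`` is the
    programmed fatigue progress in [0, 1] per sample.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    n = int(round(program.duration_s * fs))
    if n < 2:
        raise ValueError("session too short")
    rng = np.random.default_rng(program.seed)
    level = np.linspace(0.0, 1.0, n)

    rms_m = program.multipliers("RMS", n)
    mf_m = program.multipliers("MF", n)
    pe_m = program.multipliers("PE", n)
    fd_m = program.multipliers("FD", n)

    # low-pass cutoff tracks the MF ramp; quadratic map sharpens the shift
    high = min(150.0, 0.45 * fs)
    cutoff = np.clip(high * mf_m**2, 5.0, 0.49 * fs)
    g = 1.0 - np.exp(-2.0 * np.pi * cutoff / fs)
    # deterministic-component share grows as complexity ramps fall
    mix = np.clip(1.25 * (1.0 - 0.5 * (pe_m + fd_m)), 0.0, 0.95)
    smooth_len = max(3, int(round(fs)))  # ~1 s amplitude-whitening window

    t = np.arange(n) / fs
    out = np.empty((channels, n))
    base_amp = 0.5  # mV scale
    for c in range(channels):
        x = band_limited_noise(n, fs, DEFAULT_CARRIER_BAND, rng)
        y = np.empty(n)
        acc = x[0]
        for i in range(n):  # time-varying one-pole low-pass
            acc += g[i] * (x[i] - acc)
            y[i] = acc
        env = np.sqrt(uniform_filter1d(y**2, size=smooth_len, mode="nearest"))
        y = y / np.maximum(env, 1e-12)
        d = np.sqrt(2.0) * np.sin(2.0 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi))
        z = np.sqrt(1.0 - mix) * y + np.sqrt(mix) * d
        amp = base_amp * rng.uniform(0.7, 1.3)
        out[c] = amp * rms_m * z

    names = [f"ch{i}" for i in range(channels)]
    return EMGRecording(out, fs=fs, channel_names=names), level
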