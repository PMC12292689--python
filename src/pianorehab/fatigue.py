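"""Windowed fatigue features, DMWCM and the Comprehensive Muscle Fatigue Index.

Per-muscle fatigue is summarized by four windowed features — RMS amplitude,
median frequency (MF), permutation entropy (PE) and Higuchi fractal
dimension (FD).  With fatigue, RMS rises while MF, PE and FD fall, so after
min-max normalization the three decreasing features are inverted and the
four are combined into a per-muscle index

    I_FMI = TR*rf + TM*mf + TP*pf + TF*ff

with convex weights.  The duration multi-muscle weight coefficient matrix
(DMWCM) — the muscle-weight column of the momentarily dominant NMF synergy
mode, renormalized to sum 1 — then mixes the per-muscle indices into the
scalar CMFI used for threshold-based rest prompting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import factorial, log

import numpy as np
from scipy import signal as sps
from scipy.optimize import nnls

from .decomposition import nmf
from .recording import EMGRecording

__all__ = [
    "FeatureWindows",
    "FatigueWeights",
    "DominantModeSeries",
    "CMFISeries",
    "window_features",
    "normalize_features",
    "single_muscle_fmi",
    "dominant_modes",
    "window_modes",
    "dmwcm",
    "cmfi",
    "calibrate_weights",
    "monitor",
    "fatigue_pipeline",
    "permutation_entropy",
    "higuchi_fd",
]


@dataclass
class FatigueWeights:
    """Convex weights (TR, TM, TP, TF) for RMS, MF, PE and FD."""

    tr: float = 0.25
    tm: float = 0.25
    tp: float = 0.25
    tf: float = 0.25

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0):
            raise ValueError("weights must be non-negative")
        total = vals.sum()
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"weights sum to {total:.4f}; renormalizing to 1", stacklevel=2
            )
            if total <= 0:
                raise ValueError("weights must not all be zero")
            self.tr, self.tm, self.tp, self.tf = (vals / total).tolist()

    def as_array(self) -> np.ndarray:
        return np.array([self.tr, self.tm, self.tp, self.tf], dtype=float)

    @classmethod
    def equal(cls) -> "FatigueWeights":
        return cls()


@dataclass
class FeatureWindows:
    """Windowed fatigue features, per channel per window."""

    window_s: float
    step_s: float
    fs: float
    times: np.ndarray  # window centers, seconds
    rms: np.ndarray  # (channels, windows)
    mf: np.ndarray
    pe: np.ndarray
    fd: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    # normalized, fatigue-aligned variants (set by normalize_features)
    rf: np.ndarray | None = None
    mf_n: np.ndarray | None = None
    pf: np.ndarray | None = None
    ff: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.times.size

    @property
    def normalized(self) -> bool:
        return self.rf is not None


@dataclass
class DominantModeSeries:
    """Per-sample (or per-window) index of the dominant synergy mode, 1-based."""

    modes: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=int)
        if self.modes.size and not (
            self.modes.min() >= 1 and self.modes.max() <= self.rank
        ):
            raise ValueError("mode indices must lie in [1, rank]")


@dataclass
class CMFISeries:
    """CMFI trajectory with its ingredients and rest flags."""

    times: np.ndarray
    ifmi: np.ndarray  # (channels, windows)
    dmwcm: np.ndarray  # (channels, windows)
    cmfi: np.ndarray  # (windows,)
    threshold: float | None = None
    rest_flags: np.ndarray | None = None


# ---------------------------------------------------------------- features


def permutation_entropy(x: np.ndarray, order: int = 4, delay: int = 1) -> float:
    """Normalized permutation entropy in [0, 1].

    Ordinal patterns of ``order`` successive (delayed) samples are counted
    and their Shannon entropy is normalized by log(order!).  A signal with a
    single ordinal pattern (constant or strictly monotone) scores 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * delay
    if n < 1:
        raise ValueError("window too short for the requested order/delay")
    idx = np.arange(order) * delay
    emb = x[np.arange(n)[:, None] + idx]
    ranks = np.argsort(emb, axis=1, kind="stable")
    codes = (ranks * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / log(factorial(order)))


def higuchi_fd(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension of a 1-D series (1 for a straight line)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < k_max + 2:
        raise ValueError("window too short for k_max")
    logs_k, logs_l = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        if lengths:
            mean_l = np.mean(lengths)
            if mean_l > 0:
                logs_k.append(log(1.0 / k))
                logs_l.append(log(mean_l))
    if len(logs_k) < 2:
        return 1.0  # degenerate (e.g. constant) series: treat as a line
    slope = np.polyfit(logs_k, logs_l, 1)[0]
    return float(slope)


def _median_frequency(window: np.ndarray, fs: float) -> float:
    nperseg = min(256, window.size)
    freqs, psd = sps.welch(window, fs=fs, nperseg=nperseg)
    cum = np.cumsum(psd)
    total = cum[-1]
    if total <= 0:
        return 0.0
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(freqs[0])
    # linear interpolation of the cumulative-power crossing
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(freqs[i - 1] + frac * (freqs[i] - freqs[i - 1]))


def window_features(
    rec: EMGRecording,
    window_s: float = 1.0,
    step_s: float = 0.5,
    pe_order: int = 4,
    pe_delay: int = 1,
    fd_kmax: int = 8,
) -> FeatureWindows:
    """Sliding-window RMS, median frequency, permutation entropy and Higuchi FD."""
    wlen = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    if wlen < 64:
        raise ValueError("window must cover at least 64 samples")
    if step < 1 or step > wlen:
        raise ValueError("step must satisfy 0 < step_s <= window_s")
    if wlen > rec.n_samples:
        raise ValueError("window longer than recording")
    starts = np.arange(0, rec.n_samples - wlen + 1, step)
    nw = starts.size
    nc = rec.n_channels
    rms = np.empty((nc, nw))
    mf = np.empty((nc, nw))
    pe = np.empty((nc, nw))
    fd = np.empty((nc, nw))
    for c in range(nc):
        sig = rec.samples[c]
        for k, s0 in enumerate(starts):
            w = sig[s0 : s0 + wlen]
            rms[c, k] = np.sqrt(np.mean(w**2))
            mf[c, k] = _median_frequency(w, rec.fs)
            pe[c, k] = permutation_entropy(w, pe_order, pe_delay)
            fd[c, k] = higuchi_fd(w, fd_kmax)
    times = (starts + wlen / 2.0) / rec.fs
    return FeatureWindows(
        window_s=window_s, step_s=step_s, fs=rec.fs, times=times,
        rms=rms, mf=mf, pe=pe, fd=fd, channel_names=list(rec.channel_names),
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=1, keepdims=True)
    rng = np.ptp(x, axis=1, keepdims=True)
    out = np.zeros_like(x)
    ok = rng[:, 0] > 0
    if not np.all(ok):
        warnings.warn("zero-range feature normalized to 0", stacklevel=3)
    out[ok] = (x[ok] - lo[ok]) / rng[ok]
    return out


def _baseline(x: np.ndarray, increasing: bool) -> np.ndarray:
    k = min(3, x.shape[1])
    base = x[:, :k].mean(axis=1, keepdims=True)
    dev = (x - base) if increasing else (base - x)
    rng = np.abs(x - base).max(axis=1, keepdims=True)
    out = np.zeros_like(x)
    ok = rng[:, 0] > 0
    if not np.all(ok):
        warnings.warn("zero-range feature normalized to 0", stacklevel=3)
    out[ok] = np.clip(dev[ok] / rng[ok], 0.0, 1.0)
    return out


def normalize_features(
    fw: FeatureWindows, mode: str = "recording_minmax"
) -> FeatureWindows:
    """Map features to [0, 1] and align their fatigue direction.

    RMS rises with fatigue, so rf = minmax(RMS); MF, PE and FD fall, so their
    normalized variants are inverted (1 - minmax) — every returned feature
    increases with fatigue.  ``baseline_relative`` instead measures signed
    deviation from the first-windows baseline, clipped to [0, 1].
    """
    if fw.n_windows < 2:
        raise ValueError("need at least 2 windows to normalize")
    if mode == "recording_minmax":
        rf = _minmax(fw.rms)
        mf_n = 1.0 - _minmax(fw.mf)
        pf = 1.0 - _minmax(fw.pe)
        ff = 1.0 - _minmax(fw.fd)
        # a zero-range feature inverts to all-1; keep the degenerate-to-0 contract
        for raw, arr in ((fw.mf, mf_n), (fw.pe, pf), (fw.fd, ff)):
            dead = np.ptp(raw, axis=1) == 0
            arr[dead] = 0.0
    elif mode == "baseline_relative":
        rf = _baseline(fw.rms, increasing=True)
        mf_n = _baseline(fw.mf, increasing=False)
        pf = _baseline(fw.pe, increasing=False)
        ff = _baseline(fw.fd, increasing=False)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = FeatureWindows(
        window_s=fw.window_s, step_s=fw.step_s, fs=fw.fs, times=fw.times,
        rms=fw.rms, mf=fw.mf, pe=fw.pe, fd=fw.fd,
        channel_names=list(fw.channel_names),
    )
    out.rf, out.mf_n, out.pf, out.ff = rf, mf_n, pf, ff
    return out


# ------------------------------------------------------------ fatigue index


def single_muscle_fmi(fw: FeatureWindows, w: FatigueWeights | None = None) -> np.ndarray:
    """Per-muscle fatigue index: convex combination of the normalized features."""
    if not fw.normalized:
        raise ValueError("call normalize_features first")
    w = w or FatigueWeights.equal()
    return w.tr * fw.rf + w.tm * fw.mf_n + w.tp * fw.pf + w.tf * fw.ff


def dominant_modes(H: np.ndarray) -> DominantModeSeries:
    """Index (1-based) of the maximal activation coefficient per sample.

    Ties break toward the lower mode index.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    return DominantModeSeries(modes=np.argmax(H, axis=0) + 1, rank=H.shape[0])


def window_modes(
    modes: DominantModeSeries, n_samples: int, window_s: float, step_s: float, fs: float
) -> DominantModeSeries:
    """Window-level dominant mode by majority vote (ties to the lower index)."""
    wlen = int(round(window_s * fs))
    step = int(round(step_s * fs))
    starts = np.arange(0, n_samples - wlen + 1, step)
    out = np.empty(starts.size, dtype=int)
    for k, s0 in enumerate(starts):
        chunk = modes.modes[s0 : s0 + wlen]
        counts = np.bincount(chunk, minlength=modes.rank + 1)
        out[k] = int(np.argmax(counts[1:])) + 1
    return DominantModeSeries(modes=out, rank=modes.rank)


def dmwcm(
    W: np.ndarray, modes: DominantModeSeries, normalize: bool = True
) -> np.ndarray:
    """Duration multi-muscle weight coefficient matrix.

    Column t of the output is the muscle-weight column of the dominant mode
    at t; with ``normalize`` each column is rescaled to sum 1 so the CMFI is
    a convex combination of per-muscle indices.
    """
    W = np.asarray(W, dtype=float)
    if modes.modes.size and modes.modes.max() > W.shape[1]:
        raise RuntimeError("mode index exceeds number of weight columns")
    out = W[:, modes.modes - 1].astype(float)
    if normalize:
        sums = out.sum(axis=0, keepdims=True)
        dead = sums[0] <= 0
        out[:, ~dead] /= sums[:, ~dead]
        out[:, dead] = 1.0 / W.shape[0]
    return out


def cmfi(dmwcm_w: np.ndarray, ifmi: np.ndarray, times: np.ndarray | None = None) -> CMFISeries:
    """CMFI trajectory: DMWCM-weighted sum of per-muscle fatigue indices."""
    dmwcm_w = np.asarray(dmwcm_w, dtype=float)
    ifmi = np.asarray(ifmi, dtype=float)
    if dmwcm_w.shape != ifmi.shape:
        raise ValueError(
            f"misaligned DMWCM {dmwcm_w.shape} and IFMI {ifmi.shape}"
        )
    series = (dmwcm_w * ifmi).sum(axis=0)
    if times is None:
        times = np.arange(series.size, dtype=float)
    return CMFISeries(times=np.asarray(times, float), ifmi=ifmi,
                      dmwcm=dmwcm_w, cmfi=series)


def calibrate_weights(
    features: FeatureWindows, ground_truth: np.ndarray
) -> FatigueWeights:
    """Non-negative least-squares fit of feature weights to a fatigue reference.

    Regresses the ground-truth fatigue series on the channel-averaged
    normalized features and renormalizes the non-negative solution to sum 1.
    Falls back to equal weights (with a warning) on degenerate designs.
    """
    if not features.normalized:
        features = normalize_features(features)
    y = np.asarray(ground_truth, dtype=float)
    if features.n_windows < 8:
        raise ValueError("need at least 8 windows to calibrate")
    if y.size != features.n_windows:
        raise ValueError("ground truth must align with the feature windows")
    X = np.column_stack([
        features.rf.mean(axis=0),
        features.mf_n.mean(axis=0),
        features.pf.mean(axis=0),
        features.ff.mean(axis=0),
    ])
    if np.linalg.matrix_rank(X) < 4:
        warnings.warn("rank-deficient feature design; using equal weights",
                      stacklevel=2)
        return FatigueWeights.equal()
    coef, _ = nnls(X, y)
    total = coef.sum()
    if total <= 1e-12:
        warnings.warn("degenerate calibration (all-zero fit); using equal weights",
                      stacklevel=2)
        return FatigueWeights.equal()
    coef = coef / total
    return FatigueWeights(*coef.tolist())


def monitor(
    series: CMFISeries, threshold: float = 0.7, resume_below: float = 0.6
) -> CMFISeries:
    """Hysteresis rest prompting on a CMFI trajectory.

    The rest flag is raised when the CMFI first reaches ``threshold`` and is
    cleared once it drops below ``resume_below`` (<= threshold).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if resume_below > threshold:
        raise ValueError("resume_below must be <= threshold")
    flags = np.zeros(series.cmfi.size, dtype=bool)
    active = False
    for i, v in enumerate(series.cmfi):
        if not active and v >= threshold:
            active = True
        elif active and v < resume_below:
            active = False
        flags[i] = active
    return CMFISeries(times=series.times, ifmi=series.ifmi, dmwcm=series.dmwcm,
                      cmfi=series.cmfi, threshold=threshold, rest_flags=flags)


# ---------------------------------------------------------------- pipeline


def fatigue_pipeline(
    rec: EMGRecording,
    rank: int = 2,
    weights: FatigueWeights | None = None,
    window_s: float = 1.0,
    step_s: float = 0.5,
    seed: int = 0,
    threshold: float | None = None,
    resume_below: float = 0.6,
    envelope_hz: float = 5.0,
) -> CMFISeries:
    """Full CMFI computation from a raw recording.

    Rectifies and low-pass envelopes the EMG, runs rank-``rank`` NMF to get
    muscle weights and activations, derives the window-level DMWCM by
    majority vote over per-sample dominant modes, computes normalized
    windowed features and their convex combination, and mixes them through
    the DMWCM into the CMFI.  Optionally applies threshold monitoring.
    """
    rect = np.abs(rec.samples)
    sos = sps.butter(4, envelope_hz, btype="low", fs=rec.fs, output="sos")
    env = np.maximum(sps.sosfiltfilt(sos, rect, axis=1), 0.0)
    model = nmf(env, rank=rank, seed=seed)
    modes = dominant_modes(model.H)
    wmodes = window_modes(modes, rec.n_samples, window_s, step_s, rec.fs)
    fw = normalize_features(window_features(rec, window_s, step_s))
    ifmi = single_muscle_fmi(fw, weights)
    weights_mat = dmwcm(model.W, wmodes)
    series = cmfi(weights_mat, ifmi, times=fw.times)
    if threshold is not None:
        series = monitor(series, threshold, resume_below)
    return series
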