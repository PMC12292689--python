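"""Reading, writing and preprocessing of EMG recordings.

Recordings live in delimited text (CSV/TSV, first column time in seconds,
one column per muscle) with an optional JSON sidecar holding the sampling
rate, channel names and generator seed.  Preprocessing is the chain the
tensorization assumes: anti-aliased downsampling to the analysis rate,
zero-phase band-pass, optional mains notch.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FormatError
from .recording import EMGRecording

__all__ = ["PreprocessConfig", "read_emg", "write_emg", "preprocess"]


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    target_fs : analysis sampling rate (Hz); recordings are downsampled to it.
    bandpass : (low, high) pass band in Hz, 4th-order Butterworth.
    notch_hz : optional mains frequency to notch out (None disables).
    zero_phase : forward-backward filtering (no phase distortion).
    rectify : full-wave rectification after filtering; required before NMF,
        leave off before the wavelet transform.
    """

    target_fs: float = 400.0
    bandpass: tuple[float, float] = (20.0, 150.0)
    notch_hz: float | None = None
    zero_phase: bool = True
    rectify: bool = False

    def __post_init__(self) -> None:
        low, high = self.bandpass
        if not 0 < low < high < self.target_fs / 2:
            raise ValueError(
                f"bandpass {self.bandpass} must satisfy 0 < low < high < target_fs/2"
            )


def _sniff_sep(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text, delimiters=",;\t ").delimiter
    except csv.Error:
        return ","


def read_emg(path: str | Path, fs_override: float | None = None) -> EMGRecording:
    """Read a delimited-text recording.

    The first column is interpreted as time in seconds when strictly
    monotone; otherwise ``fs_override`` (or a JSON sidecar) must supply the
    sampling rate.  Channel labels come from the header row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    head = path.read_text().splitlines()
    if len(head) < 2:
        raise FormatError(f"{path}: need at least two rows")
    sep = _sniff_sep("\n".join(head[:10]))

    first = head[0].split(sep)
    has_header = not all(_is_number(tok) for tok in first)

    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
        data = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cells ({exc})") from exc
    if data.shape[1] < 2:
        raise FormatError(f"{path}: need >= 2 columns (time + channels)")
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: non-finite values")

    t = data[:, 0]
    monotone = np.all(np.diff(t) > 0)
    fs = fs_override or meta.get("fs")
    if monotone and fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    if fs is None:
        raise FormatError(
            f"{path}: first column is not a monotone time axis and no "
            "sampling rate was supplied (fs_override or JSON sidecar)"
        )
    if monotone:
        samples = data[:, 1:].T
        names = list(df.columns[1:]) if has_header else None
    else:  # every column is a channel
        samples = data.T
        names = list(df.columns) if has_header else None
    if not has_header:
        raise FormatError(
            f"{path}: headerless files are not supported (channel labels "
            "are required); add a header row"
        )
    names = meta.get("channel_names", [str(n) for n in names])
    return EMGRecording(samples, fs=float(fs), channel_names=names)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_emg(rec: EMGRecording, path: str | Path, seed: int | None = None) -> Path:
    """Write a recording as CSV (`time_s, <channel>...`) plus JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
    df.insert(0, "time_s", rec.times)
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {"fs": rec.fs, "channel_names": rec.channel_names}
    if seed is not None:
        meta["seed"] = seed
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def preprocess(rec: EMGRecording, cfg: PreprocessConfig | None = None) -> EMGRecording:
    """Resample to the analysis rate and band-pass filter.

    Raises ``ValueError`` if the recording is sampled below ``target_fs``
    (no upsampling).
    """
    cfg = cfg or PreprocessConfig()
    if rec.fs < cfg.target_fs:
        raise ValueError(
            f"recording at {rec.fs} Hz cannot be upsampled to {cfg.target_fs} Hz"
        )
    x = rec.samples
    if rec.fs != cfg.target_fs:
        frac = Fraction(cfg.target_fs / rec.fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    sos = sps.butter(4, cfg.bandpass, btype="bandpass", fs=cfg.target_fs, output="sos")
    if cfg.zero_phase:
        x = sps.sosfiltfilt(sos, x, axis=1)
    else:
        x = sps.sosfilt(sos, x, axis=1)
    if cfg.notch_hz is not None:
        b, a = sps.iirnotch(cfg.notch_hz, Q=30.0, fs=cfg.target_fs)
        if cfg.zero_phase:
            x = sps.filtfilt(b, a, x, axis=1)
        else:
            x = sps.lfilter(b, a, x, axis=1)
    if not cfg.rectify:
        # filtfilt edge transients leave a small residual offset; remove it
        x = x - x.mean(axis=1, keepdims=True)
    else:
        x = np.abs(x)
    return EMGRecording(np.ascontiguousarray(x), fs=cfg.target_fs,
                        channel_names=list(rec.channel_names))
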