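"""Spectrotemporal representation layer: waveform -> CF x time rate matrix.

The default front end is a gammatone-style bandpass filterbank on a
log-spaced characteristic-frequency (CF) grid, followed by half-wave
rectification, low-pass envelope extraction, anti-aliased decimation to the
frame rate, and optional power-law compression.  The front end is pluggable:
any callable mapping ``(samples, sample_rate, cfs) -> channel envelopes at
the input rate`` can be substituted for the built-in filterbank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import signal

from .calls import AnnotatedCall

__all__ = [
    "CochleagramParams",
    "Cochleagram",
    "make_cf_grid",
    "compute_cochleagram",
    "normalize_rows",
    "save_cochleagram",
    "load_cochleagram",
]

NOISE_FLOOR = 1e-12  # added before normalizations to avoid divide-by-zero


@dataclass(frozen=True)
class CochleagramParams:
    n_channels: int = 67
    f_min: float = 200.0
    f_max: float = 20_000.0
    frame_rate: float = 1000.0
    front_end: str = "gammatone"
    compression: float | None = 0.3  # power-law exponent; None disables
    envelope_cutoff: float = 250.0  # Hz, < frame_rate / 2

    def __post_init__(self) -> None:
        if self.f_min >= self.f_max:
            raise ValueError("f_min must be < f_max")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


@dataclass
class Cochleagram:
    """Nonnegative [n_channels x n_frames] rate matrix, rows by ascending CF."""

    values: np.ndarray
    cfs: np.ndarray
    frame_rate: float
    source_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def make_cf_grid(params: CochleagramParams) -> np.ndarray:
    """Geometrically spaced CF grid with exact endpoints."""
    return np.geomspace(params.f_min, params.f_max, params.n_channels)


def _gammatone_filterbank(samples: np.ndarray, sample_rate: int, cfs: np.ndarray) -> np.ndarray:
    out = np.empty((len(cfs), len(samples)))
    for i, cf in enumerate(cfs):
        b, a = signal.gammatone(cf, "iir", fs=sample_rate)
        out[i] = signal.lfilter(b, a, samples)
    return out


_FRONT_ENDS: dict[str, Callable] = {"gammatone": _gammatone_filterbank}


def register_front_end(name: str, fn: Callable) -> None:
    """Register a substitute periphery front end under ``name``."""
    _FRONT_ENDS[name] = fn


def compute_cochleagram(
    call: AnnotatedCall,
    params: CochleagramParams = CochleagramParams(),
) -> Cochleagram:
    """Bandpass filter, rectify, envelope-extract and decimate to frames.

    Raises if the waveform's sample rate cannot represent ``f_max``.
    """
    if call.sample_rate < 2 * params.f_max:
        raise ValueError(
            f"sample rate {call.sample_rate} too low for f_max {params.f_max}"
        )
    cfs = make_cf_grid(params)
    front_end = _FRONT_ENDS[params.front_end]
    channels = front_end(call.samples, call.sample_rate, cfs)
    channels = np.maximum(channels, 0.0)  # half-wave rectification

    # low-pass envelope, then polyphase decimation to the frame rate
    sos = signal.butter(4, params.envelope_cutoff, fs=call.sample_rate, output="sos")
    env = signal.sosfilt(sos, channels, axis=1)
    decim = call.sample_rate / params.frame_rate
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError("sample_rate must be an integer multiple of frame_rate")
    frames = signal.resample_poly(env, 1, int(round(decim)), axis=1)
    frames = np.maximum(frames, 0.0)
    if params.compression is not None:
        frames = np.power(frames + NOISE_FLOOR, params.compression)
        frames -= NOISE_FLOOR**params.compression
        frames = np.maximum(frames, 0.0)
    return Cochleagram(values=frames, cfs=cfs, frame_rate=params.frame_rate, source_id=call.exemplar_id)


def normalize_rows(c: Cochleagram) -> Cochleagram:
    """Scale each row to max 1 (all-zero rows unchanged).  Display only;
    never used in training or detection."""
    vals = c.values.copy()
    rowmax = vals.max(axis=1, keepdims=True)
    nonzero = rowmax[:, 0] > 0
    vals[nonzero] /= rowmax[nonzero]
    return Cochleagram(values=vals, cfs=c.cfs.copy(), frame_rate=c.frame_rate, source_id=c.source_id)


def save_cochleagram(path, c: Cochleagram, params: CochleagramParams | None = None) -> None:
    """Portable array container (.npz) with a JSON header."""
    header = {
        "cfs": list(map(float, c.cfs)),
        "frame_rate": c.frame_rate,
        "source_id": c.source_id,
        "params": None if params is None else params.__dict__,
    }
    np.savez(Path(path), values=c.values, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8))


def load_cochleagram(path) -> Cochleagram:
    with np.load(Path(path)) as z:
        header = json.loads(bytes(z["header"]).decode())
        return Cochleagram(
            values=z["values"],
            cfs=np.asarray(header["cfs"]),
            frame_rate=header["frame_rate"],
            source_id=header["source_id"],
        )
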