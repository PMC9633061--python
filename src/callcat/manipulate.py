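"""The stimulus-manipulation battery applied to calls before model evaluation.

Seven paradigms: additive noise at fixed SNR, onset-aligned truncation,
tempo change (phase-vocoder time stretch), F0 shift (resample + stretch,
duration preserving), temporal reversal, low-pass filtering, and
inter-syllable-interval (ISI) surgery including chimeric calls.

Sign convention for tempo: a change of ``t`` percent multiplies the call
duration by ``100 / (100 - t)`` (so +80 -> 5x longer, -100 -> 0.5x).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .calls import AnnotatedCall

__all__ = [
    "ManipulationSpec",
    "mix_noise_snr",
    "truncate_segment",
    "change_tempo",
    "shift_f0",
    "reverse_call",
    "lowpass_call",
    "manipulate_isi",
    "apply_manipulation",
    "tempo_duration_factor",
]

SNR_GRID_DB = (-18.0, -12.0, -6.0, -3.0, 0.0, 3.0, 6.0, 12.0)
SEGMENT_GRID_MS = (50, 75, 100, 125, 150, 175, 200, 300, 400, 500, 600, 700, 800)
TEMPO_GRID_PCT = (-120, -100, -80, -60, -30, 30, 60, 80)
F0_GRID_PCT = (-50, -40, -30, -20, 20, 40, 50, 100)


@dataclass(frozen=True)
class ManipulationSpec:
    kind: Literal["none", "snr", "segment", "tempo", "f0", "reverse", "lowpass", "isi"]
    parameter: float | str | None = None  # dB, ms, %, Hz, or isi mode
    seed: int = 0


def tempo_duration_factor(t_percent: float) -> float:
    if t_percent >= 100:
        raise ValueError("tempo change must be < 100 % (infinite stretch)")
    return 100.0 / (100.0 - t_percent)


def mix_noise_snr(call: AnnotatedCall, snr_db: float, seed: int = 0) -> AnnotatedCall:
    """Add gated white Gaussian noise spanning the whole call at a given SNR.

    SNR is defined over rms amplitudes: ``20 log10(rms_signal / rms_noise)``.
    ``snr_db = +inf`` returns the clean call.
    """
    if np.isposinf(snr_db):
        return call.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(call.samples))
    target_noise_rms = call.rms() / (10.0 ** (snr_db / 20.0))
    noise *= target_noise_rms / np.sqrt(np.mean(noise**2))
    out = call.copy()
    out.samples = call.samples + noise
    return out


def truncate_segment(call: AnnotatedCall, length_ms: float) -> AnnotatedCall:
    """Keep the first ``length_ms`` from call onset; clip annotation."""
    if length_ms <= 0:
        raise ValueError("length_ms must be > 0")
    n = int(round(length_ms / 1000.0 * call.sample_rate))
    n = min(n, len(call.samples))
    end = n / call.sample_rate
    syl = [(a, min(b, end)) for a, b in call.syllables if a < end]
    return AnnotatedCall(call.samples[:n].copy(), call.sample_rate, syl, call.category, call.exemplar_id)


# -- phase vocoder -----------------------------------------------------------

def _stft(x, n_fft, hop):
    win = signal.get_window("hann", n_fft)
    n_frames = 1 + (len(x) - n_fft) // hop if len(x) >= n_fft else 1
    pad = max(0, (n_frames - 1) * hop + n_fft - len(x))
    x = np.pad(x, (0, pad))
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.fft.rfft(x[idx] * win, axis=1)


def _phase_vocoder_stretch(x: np.ndarray, factor: float, n_fft: int = 2048, hop: int = 512) -> np.ndarray:
    """Time-stretch ``x`` by ``factor`` (>1 lengthens) preserving pitch."""
    if factor == 1.0:
        return x.copy()
    D = _stft(x, n_fft, hop)
    n_frames, n_bins = D.shape
    steps = np.arange(0, n_frames - 1, 1.0 / factor)
    omega = 2 * np.pi * hop * np.arange(n_bins) / n_fft  # expected phase advance

    mag0, mag1 = np.abs(D[:-1]), np.abs(D[1:])
    dphi = np.angle(D[1:]) - np.angle(D[:-1]) - omega
    dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
    inst = omega + dphi  # true per-hop phase advance

    out = np.empty((len(steps), n_bins), dtype=complex)
    phase = np.angle(D[0]).astype(float)
    for k, s in enumerate(steps):
        i = int(s)
        frac = s - i
        mag = (1 - frac) * mag0[i] + frac * mag1[i]
        out[k] = mag * np.exp(1j * phase)
        phase += inst[i]

    win = signal.get_window("hann", n_fft)
    y = np.zeros((len(steps) - 1) * hop + n_fft)
    wsum = np.zeros_like(y)
    frames = np.fft.irfft(out, n=n_fft, axis=1)
    for k in range(len(steps)):
        sl = slice(k * hop, k * hop + n_fft)
        y[sl] += frames[k] * win
        wsum[sl] += win**2
    y[wsum > 1e-8] /= wsum[wsum > 1e-8]
    return y


def _fit_length(y: np.ndarray, n: int) -> np.ndarray:
    if len(y) >= n:
        return y[:n]
    return np.pad(y, (0, n - len(y)))


def change_tempo(call: AnnotatedCall, t_percent: float) -> AnnotatedCall:
    """Stretch/compress the call in time without altering its spectrum."""
    factor = tempo_duration_factor(t_percent)
    if t_percent == 0:
        return call.copy()
    y = _phase_vocoder_stretch(call.samples, factor)
    y = _fit_length(y, int(round(len(call.samples) * factor)))
    syl = [(a * factor, b * factor) for a, b in call.syllables]
    return AnnotatedCall(y, call.sample_rate, syl, call.category, call.exemplar_id)


def shift_f0(call: AnnotatedCall, p_percent: float) -> AnnotatedCall:
    """Shift fundamental frequency by ``p_percent`` with length and tempo
    preserved (time-stretch then resample)."""
    if p_percent <= -100:
        raise ValueError("F0 shift must be > -100 %")
    if p_percent == 0:
        return call.copy()
    ratio = 1.0 + p_percent / 100.0
    frac = Fraction(ratio).limit_denominator(1000)
    stretched = _phase_vocoder_stretch(call.samples, float(frac))
    y = signal.resample_poly(stretched, frac.denominator, frac.numerator)
    y = _fit_length(y, len(call.samples))
    return AnnotatedCall(y, call.sample_rate, [tuple(s) for s in call.syllables], call.category, call.exemplar_id)


def reverse_call(call: AnnotatedCall) -> AnnotatedCall:
    """Temporal reversal; annotation intervals mirrored."""
    dur = call.duration
    syl = sorted((dur - b, dur - a) for a, b in call.syllables)
    return AnnotatedCall(call.samples[::-1].copy(), call.sample_rate, syl, call.category, call.exemplar_id)


def lowpass_call(call: AnnotatedCall, cutoff_hz: float = 3000.0, n_taps: int = 256) -> AnnotatedCall:
    """Linear-phase FIR low-pass (defaults: 3 kHz cutoff, 256 taps)."""
    nyq = call.sample_rate / 2
    if not (0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff must be in (0, {nyq})")
    h = signal.firwin(n_taps, cutoff_hz, fs=call.sample_rate)
    y_full = np.convolve(call.samples, h, mode="full")
    delay = (n_taps - 1) // 2
    y = y_full[delay : delay + len(call.samples)]
    out = call.copy()
    out.samples = y
    return out


def manipulate_isi(
    call: AnnotatedCall,
    mode: Literal["silent", "random", "chimeric"],
    donor_isis: Sequence[float] | np.ndarray | None = None,
    n_variants: int = 5,
    seed: int = 0,
) -> list[AnnotatedCall]:
    """ISI surgery keeping syllable audio sample-exact.

    ``silent`` zeroes all inter-syllable samples (one variant).  ``random``
    and ``chimeric`` rebuild the call with ISI durations drawn with
    replacement from ``donor_isis`` (seconds): same-category donors for
    ``random``, other-category donors for ``chimeric``.  Chimeric calls keep
    the syllable donor's label as nominal category.
    """
    if not call.syllables:
        raise ValueError("call has no syllable annotation")
    sr = call.sample_rate
    if mode == "silent":
        out = call.copy()
        for (a, b), (a2, _) in zip(call.syllables[:-1], call.syllables[1:]):
            out.samples[int(round(b * sr)) : int(round(a2 * sr))] = 0.0
        return [out]

    if mode not in ("random", "chimeric"):
        raise ValueError(f"unknown ISI mode {mode!r}")
    donors = np.asarray(donor_isis if donor_isis is not None else [])
    if donors.size == 0:
        raise ValueError("random/chimeric ISI modes need a non-empty donor set")

    rng = np.random.default_rng(seed)
    lead = call.samples[: int(round(call.syllables[0][0] * sr))]
    syl_audio = [
        call.samples[int(round(a * sr)) : int(round(b * sr))] for a, b in call.syllables
    ]
    variants = []
    for v in range(n_variants):
        pieces = [lead]
        syl_out: list[tuple[float, float]] = []
        cursor = len(lead)
        for i, audio in enumerate(syl_audio):
            syl_out.append((cursor / sr, (cursor + len(audio)) / sr))
            pieces.append(audio)
            cursor += len(audio)
            if i < len(syl_audio) - 1:
                isi = float(rng.choice(donors))
                gap = np.zeros(int(round(isi * sr)))
                pieces.append(gap)
                cursor += len(gap)
        pieces.append(np.zeros(int(round(0.02 * sr))))
        y = np.concatenate(pieces)
        variants.append(
            AnnotatedCall(y, sr, syl_out, call.category, f"{call.exemplar_id}-{mode}{v}")
        )
    return variants


def apply_manipulation(call: AnnotatedCall, spec: ManipulationSpec, donor_isis=None) -> AnnotatedCall:
    """Dispatch a single-output manipulation (ISI variants pick variant 0...
    callers wanting all variants should use :func:`manipulate_isi`)."""
    if spec.kind == "none":
        return call.copy()
    if spec.kind == "snr":
        return mix_noise_snr(call, float(spec.parameter), seed=spec.seed)
    if spec.kind == "segment":
        return truncate_segment(call, float(spec.parameter))
    if spec.kind == "tempo":
        return change_tempo(call, float(spec.parameter))
    if spec.kind == "f0":
        return shift_f0(call, float(spec.parameter))
    if spec.kind == "reverse":
        return reverse_call(call)
    if spec.kind == "lowpass":
        return lowpass_call(call, float(spec.parameter) if spec.parameter else 3000.0)
    if spec.kind == "isi":
        return manipulate_isi(call, str(spec.parameter), donor_isis=donor_isis, n_variants=1, seed=spec.seed)[0]
    raise ValueError(f"unknown manipulation kind {spec.kind!r}")
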