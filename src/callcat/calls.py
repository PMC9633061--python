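"""Synthetic vocalization corpus: harmonic-stack calls with annotated syllables.

Calls are built as trains of harmonic-stack syllables separated by silent
inter-syllable intervals (ISIs).  Category archetypes are controlled by a
:class:`CallCategorySpec`; exemplar-to-exemplar variability comes from
jittering F0, syllable durations and ISIs with a seeded generator, so every
call is a pure function of (spec, seed).
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "CallCategorySpec",
    "AnnotatedCall",
    "CallCorpus",
    "DEFAULT_SPECS",
    "default_category_specs",
    "generate_call",
    "generate_corpus",
    "segment_syllables",
    "read_wav",
    "write_wav",
    "read_annotation",
    "write_annotation",
    "write_corpus",
    "read_corpus",
]

DEFAULT_SAMPLE_RATE = 48_000
DEFAULT_REF_RMS = 0.05
RAMP_MS = 5.0  # raised-cosine on/offset ramp per syllable, avoids clicks


class ConfigurationError(ValueError):
    """Raised when a category spec or distribution parameter is invalid."""


@dataclass(frozen=True)
class Distribution:
    """Uniform distribution on [low, high] with finite positive support."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ConfigurationError("distribution bounds must be finite")
        if self.low <= 0 or self.high < self.low:
            raise ConfigurationError(
                f"invalid distribution bounds ({self.low}, {self.high})"
            )

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


def _as_dist(x) -> Distribution:
    if isinstance(x, Distribution):
        return x
    if np.isscalar(x):
        return Distribution(float(x), float(x))
    low, high = x
    return Distribution(float(low), float(high))


@dataclass(frozen=True)
class CallCategorySpec:
    """Statistical description of one synthetic call category."""

    name: str
    f0_base: float
    f0_jitter: float = 0.0  # fractional range, e.g. 0.1 -> +-10 %
    f0_contour: Literal["flat", "rising", "falling"] = "flat"
    n_harmonics: int = 8
    harmonic_rolloff: float = 6.0  # dB per harmonic step
    syllable_dur: Distribution = field(default_factory=lambda: Distribution(80, 120))
    isi_dur: Distribution = field(default_factory=lambda: Distribution(40, 80))
    n_syllables: Distribution = field(default_factory=lambda: Distribution(3, 5))
    spectral_emphasis: tuple[float, float] | None = None  # (lo, hi) Hz band boost
    background_noise: float = 0.0  # white-noise rms relative to syllable rms

    def __post_init__(self) -> None:
        if self.f0_base <= 0:
            raise ConfigurationError("f0_base must be > 0")
        if self.f0_jitter < 0:
            raise ConfigurationError("f0_jitter must be >= 0")
        if self.n_harmonics < 1:
            raise ConfigurationError("n_harmonics must be >= 1")
        object.__setattr__(self, "syllable_dur", _as_dist(self.syllable_dur))
        object.__setattr__(self, "isi_dur", _as_dist(self.isi_dur))
        object.__setattr__(self, "n_syllables", _as_dist(self.n_syllables))
        if self.n_syllables.low < 1:
            raise ConfigurationError("n_syllables must be >= 1")

    def spec_hash(self) -> str:
        payload = json.dumps(self.__dict__, default=str, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class AnnotatedCall:
    """A mono waveform with syllable on/offset annotation and a category label."""

    samples: np.ndarray
    sample_rate: int
    syllables: list[tuple[float, float]]
    category: str
    exemplar_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AnnotatedCall requires a mono (1-D) waveform")
        self.validate()

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def validate(self) -> None:
        prev_off = 0.0
        for onset, offset in self.syllables:
            if onset < prev_off - 1e-9 or offset <= onset:
                raise ValueError("syllable intervals must be disjoint and ordered")
            if offset > self.duration + 1e-9:
                raise ValueError("syllable interval exceeds call duration")
            prev_off = offset

    def copy(self) -> "AnnotatedCall":
        return AnnotatedCall(
            self.samples.copy(),
            self.sample_rate,
            [tuple(s) for s in self.syllables],
            self.category,
            self.exemplar_id,
        )


@dataclass
class CallCorpus:
    calls: list[AnnotatedCall]
    split: dict[str, str]  # exemplar_id -> "train" | "holdout"

    def subset(self, split: str | None = None, category: str | None = None) -> list[AnnotatedCall]:
        out = []
        for c in self.calls:
            if split is not None and self.split.get(c.exemplar_id) != split:
                continue
            if category is not None and c.category != category:
                continue
            out.append(c)
        return out

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.calls:
            seen.setdefault(c.category, None)
        return list(seen)

    def isi_values(self, category: str, split: str | None = "train") -> np.ndarray:
        """Pooled empirical ISI durations (seconds) for one category."""
        vals = []
        for c in self.subset(split=split, category=category):
            for (a, b), (a2, _b2) in zip(c.syllables[:-1], c.syllables[1:]):
                vals.append(a2 - b)
        return np.asarray(vals)


def default_category_specs() -> list[CallCategorySpec]:
    """Four archetypes: two sharing long-term spectra but differing in ISI
    structure (chut-like vs purr-like), two sharing envelopes but differing
    in spectral content incl. harmonics above 3 kHz (wheek-like vs whine-like).
    """
    return [
        CallCategorySpec(
            name="chut",
            f0_base=500.0,
            f0_jitter=0.06,
            f0_contour="flat",
            n_harmonics=6,
            harmonic_rolloff=6.0,
            syllable_dur=Distribution(70, 110),
            isi_dur=Distribution(120, 220),
            n_syllables=Distribution(3, 5),
        ),
        CallCategorySpec(
            name="purr",
            f0_base=500.0,
            f0_jitter=0.06,
            f0_contour="flat",
            n_harmonics=6,
            harmonic_rolloff=6.0,
            syllable_dur=Distribution(35, 55),
            isi_dur=Distribution(20, 40),
            n_syllables=Distribution(9, 13),
        ),
        CallCategorySpec(
            name="wheek",
            f0_base=900.0,
            f0_jitter=0.08,
            f0_contour="flat",
            n_harmonics=14,  # harmonics well above 3 kHz
            harmonic_rolloff=1.5,
            syllable_dur=Distribution(220, 320),
            isi_dur=Distribution(80, 140),
            n_syllables=Distribution(2, 3),
            spectral_emphasis=(3000.0, 14000.0),
        ),
        CallCategorySpec(
            name="whine",
            f0_base=550.0,
            f0_jitter=0.08,
            f0_contour="falling",
            n_harmonics=4,  # energy confined below ~3 kHz
            harmonic_rolloff=8.0,
            syllable_dur=Distribution(220, 320),
            isi_dur=Distribution(80, 140),
            n_syllables=Distribution(2, 3),
        ),
    ]


DEFAULT_SPECS = default_category_specs()


def _synth_syllable(
    spec: CallCategorySpec,
    f0: float,
    dur_s: float,
    sample_rate: int,
) -> np.ndarray:
    n = int(round(dur_s * sample_rate))
    t = np.arange(n) / sample_rate
    if spec.f0_contour == "rising":
        f0_t = f0 * (1.0 + 0.2 * t / dur_s)
    elif spec.f0_contour == "falling":
        f0_t = f0 * (1.0 - 0.2 * t / dur_s)
    else:
        f0_t = np.full(n, f0)
    # integrate instantaneous frequency for a smooth phase track
    phase0 = 2 * np.pi * np.cumsum(f0_t) / sample_rate
    y = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        amp = 10 ** (-(h - 1) * spec.harmonic_rolloff / 20.0)
        fh = h * f0
        if fh >= sample_rate / 2:
            break
        if spec.spectral_emphasis is not None:
            lo, hi = spec.spectral_emphasis
            if lo <= fh <= hi:
                amp *= 4.0
        y += amp * np.sin(h * phase0)
    ramp = int(round(RAMP_MS / 1000.0 * sample_rate))
    ramp = min(ramp, n // 2)
    if ramp > 0:
        w = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        y[:ramp] *= w
        y[-ramp:] *= w[::-1]
    return y


def generate_call(
    spec: CallCategorySpec,
    seed: int,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    ref_rms: float = DEFAULT_REF_RMS,
    min_duration_s: float = 0.8,
    exemplar_id: str | None = None,
) -> AnnotatedCall:
    """Synthesize one rms-normalized call; deterministic given (spec, seed).

    Syllable count, durations, ISIs and F0 are drawn from the spec's
    distributions.  The syllable annotation matches the synthesis exactly.
    The call is padded with trailing silence to at least ``min_duration_s``.
    """
    rng = np.random.default_rng(seed)
    n_syll = int(round(spec.n_syllables.sample(rng)))
    n_syll = max(1, n_syll)
    f0 = spec.f0_base * (1.0 + spec.f0_jitter * rng.uniform(-1, 1))

    lead_s = 0.02
    pieces: list[np.ndarray] = [np.zeros(int(round(lead_s * sample_rate)))]
    syllables: list[tuple[float, float]] = []
    cursor = len(pieces[0])
    for i in range(n_syll):
        dur_s = spec.syllable_dur.sample(rng) / 1000.0
        syl = _synth_syllable(spec, f0, dur_s, sample_rate)
        syllables.append((cursor / sample_rate, (cursor + len(syl)) / sample_rate))
        pieces.append(syl)
        cursor += len(syl)
        if i < n_syll - 1:
            isi_s = spec.isi_dur.sample(rng) / 1000.0
            gap = np.zeros(int(round(isi_s * sample_rate)))
            pieces.append(gap)
            cursor += len(gap)
    pieces.append(np.zeros(int(round(0.02 * sample_rate))))
    y = np.concatenate(pieces)
    if len(y) < int(min_duration_s * sample_rate):
        y = np.pad(y, (0, int(min_duration_s * sample_rate) - len(y)))
    if spec.background_noise > 0:
        voiced_rms = np.sqrt(np.mean(np.square(y))) or 1.0
        y = y + spec.background_noise * voiced_rms * rng.standard_normal(len(y))

    # rms normalization comes last so the invariant holds with noise included
    rms = np.sqrt(np.mean(np.square(y)))
    if rms > 0:
        y = y * (ref_rms / rms)
    return AnnotatedCall(
        samples=y,
        sample_rate=sample_rate,
        syllables=syllables,
        category=spec.name,
        exemplar_id=exemplar_id or f"{spec.name}-{seed}",
    )


def generate_corpus(
    specs: Sequence[CallCategorySpec],
    n_train: int = 8,
    n_holdout: int = 8,
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    ref_rms: float = DEFAULT_REF_RMS,
) -> CallCorpus:
    """Reproducible labeled corpus with disjoint train/holdout splits."""
    if len(specs) < 2:
        raise ValueError("need at least two category specs")
    if n_train < 1 or n_holdout < 1:
        raise ValueError("n_train and n_holdout must be >= 1")
    root = np.random.SeedSequence(seed)
    calls: list[AnnotatedCall] = []
    split: dict[str, str] = {}
    for spec in specs:
        child_seeds = root.spawn(1)[0].generate_state(n_train + n_holdout)
        for i, s in enumerate(child_seeds):
            which = "train" if i < n_train else "holdout"
            eid = f"{spec.name}-{which}-{i if which == 'train' else i - n_train}"
            call = generate_call(
                spec, int(s), sample_rate=sample_rate, ref_rms=ref_rms, exemplar_id=eid
            )
            calls.append(call)
            split[eid] = which
    return CallCorpus(calls=calls, split=split)


def segment_syllables(
    samples: np.ndarray,
    sample_rate: int,
    energy_threshold: float = 0.05,
    min_gap_ms: float = 15.0,
    win_ms: float = 5.0,
) -> list[tuple[float, float]]:
    """Automatic syllable segmentation by short-time energy thresholding.

    Frames whose RMS exceeds ``energy_threshold`` times the peak frame RMS
    are marked active; active runs separated by gaps shorter than
    ``min_gap_ms`` are merged.  All-silent input yields an empty annotation.
    """
    x = np.asarray(samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    win = max(1, int(round(win_ms / 1000 * sample_rate)))
    pad = (-len(x)) % win
    frames = np.pad(x, (0, pad)).reshape(-1, win)
    energy = np.sqrt(np.mean(frames**2, axis=1))
    peak = energy.max(initial=0.0)
    if peak <= 0:
        return []
    active = energy > energy_threshold * peak
    intervals: list[list[float]] = []
    for i, a in enumerate(active):
        t0, t1 = i * win / sample_rate, (i + 1) * win / sample_rate
        if a:
            if intervals and t0 - intervals[-1][1] < min_gap_ms / 1000.0:
                intervals[-1][1] = t1
            else:
                intervals.append([t0, t1])
    end = len(x) / sample_rate
    return [(a, min(b, end)) for a, b in intervals]


# ---------------------------------------------------------------------------
# audio + annotation I/O

def write_wav(path, call: AnnotatedCall, subtype: str = "float32") -> None:
    """Write a call to WAV (``float32`` or ``pcm16``) plus no sidecar."""
    p = Path(path)
    if subtype == "float32":
        wavfile.write(p, call.sample_rate, call.samples.astype(np.float32))
    elif subtype == "pcm16":
        scaled = np.clip(call.samples, -1.0, 1.0)
        wavfile.write(p, call.sample_rate, (scaled * 32767).astype(np.int16))
    else:
        raise IOError(f"unsupported WAV subtype {subtype!r}")


def read_wav(path, category: str = "", exemplar_id: str = "") -> AnnotatedCall:
    """Read a mono WAV file.  Stereo input is rejected, never down-mixed."""
    sr, data = wavfile.read(Path(path))
    if data.ndim != 1:
        raise IOError("stereo/multichannel WAV input is not supported")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise IOError(f"unsupported WAV encoding {data.dtype}")
    ann_path = Path(path).with_suffix(".syl.csv")
    syllables = read_annotation(ann_path) if ann_path.exists() else []
    return AnnotatedCall(samples, int(sr), syllables, category, exemplar_id or Path(path).stem)


def write_annotation(path, syllables: Sequence[tuple[float, float]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "offset_s"])
        for a, b in syllables:
            w.writerow([f"{a:.9f}", f"{b:.9f}"])


def read_annotation(path) -> list[tuple[float, float]]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out.append((float(row["onset_s"]), float(row["offset_s"])))
    return out


def write_corpus(directory, corpus: CallCorpus, specs: Sequence[CallCategorySpec] = (), seed: int | None = None) -> None:
    """Write every call as WAV + annotation sidecar + a JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "calls": [], "specs": {s.name: s.spec_hash() for s in specs}}
    for call in corpus.calls:
        stem = call.exemplar_id
        write_wav(d / f"{stem}.wav", call)
        write_annotation(d / f"{stem}.syl.csv", call.syllables)
        manifest["calls"].append(
            {
                "exemplar_id": call.exemplar_id,
                "category": call.category,
                "split": corpus.split[call.exemplar_id],
                "file": f"{stem}.wav",
            }
        )
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_corpus(directory) -> CallCorpus:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    calls, split = [], {}
    for entry in manifest["calls"]:
        call = read_wav(d / entry["file"], category=entry["category"], exemplar_id=entry["exemplar_id"])
        calls.append(call)
        split[entry["exemplar_id"]] = entry["split"]
    return CallCorpus(calls=calls, split=split)
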