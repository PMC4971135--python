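"""Corpus I/O: WAV audio, segment label files, and corpus manifests.

Cry recordings arrive as PCM WAV files plus a per-recording label file
marking the manually segmented cry units (EXP, INSV, ...) with start/end
times.  A corpus manifest ties recordings to infants, health classes and
train/test splits; splits must be infant-disjoint so no infant
contributes to both model building and evaluation.
"""

from __future__ import annotations

import io
import wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Segment label vocabulary.  EXP/INSV are the voiced expiratory and
#: inspiratory cry units the detectors consume; the rest mark material
#: excluded from modeling (unvoiced phases, speech, NICU noise, probes).
LABEL_VOCABULARY = frozenset(
    {
        "EXP",
        "EXPN",
        "INS",
        "INSV",
        "EXP2",
        "INS2",
        "PSEUDOCRY",
        "Speech",
        "Background",
        "NoisyCry",
        "NoisyPseudoCry",
        "Noise",
        "BIP",
    }
)

#: Health-condition categories a recording may be tagged with.
HEALTH_CLASSES = frozenset({"Healthy", "Heart", "Neurological", "Respiratory", "Blood", "Other"})

SPLIT_TAGS = frozenset({"ubm", "adapt", "test"})


class CorpusFormatError(ValueError):
    """Raised for malformed WAV payloads, label files or manifests."""


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform with amplitudes in ~[-1, 1].

    ``samples`` has shape ``(n,)`` for mono or ``(n_channels, n)`` for
    multi-channel audio.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.size == 0:
            raise ValueError("AudioSignal requires at least one sample")
        if samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (channels x samples)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class SegmentLabel:
    """A labeled time interval ``[start_s, end_s)`` within a recording."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in LABEL_VOCABULARY:
            raise CorpusFormatError(
                f"unknown segment label {self.label!r}; expected one of {sorted(LABEL_VOCABULARY)}"
            )
        if not (0.0 <= self.start_s < self.end_s):
            raise CorpusFormatError(
                f"invalid segment interval [{self.start_s}, {self.end_s}) for label {self.label!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CryRecording:
    """One recorded cry: audio, its segment labels and the health tag."""

    audio: AudioSignal
    labels: list[SegmentLabel]
    health_class: str
    infant_id: str
    file_id: str = ""

    def __post_init__(self) -> None:
        if self.health_class not in HEALTH_CLASSES:
            raise ValueError(f"unknown health class {self.health_class!r}")
        if not self.infant_id:
            raise ValueError("infant_id must be non-empty")


# ---------------------------------------------------------------------------
# WAV I/O (stdlib wave module; PCM 16/24/32-bit)

_PCM_SCALE = {2: 32768.0, 3: 8388608.0, 4: 2147483648.0}


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file into floats in [-1, 1].

    int16 samples are divided by 32768 (silence maps to exactly 0.0);
    24- and 32-bit PCM scale analogously.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with wave.open(str(path), "rb") as wf:
            n_channels = wf.getnchannels()
            sampwidth = wf.getsampwidth()
            sample_rate = wf.getframerate()
            n_frames = wf.getnframes()
            raw = wf.readframes(n_frames)
    except wave.Error as exc:
        raise CorpusFormatError(f"{path} is not an uncompressed PCM WAV file: {exc}") from exc
    if sampwidth not in _PCM_SCALE:
        raise CorpusFormatError(f"unsupported sample width {sampwidth} bytes in {path}")
    if sampwidth == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        ints = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int8).astype(np.int32) << 16)
        )
    else:
        ints = np.frombuffer(raw, dtype=np.int16 if sampwidth == 2 else np.int32)
    data = ints.astype(np.float64) / _PCM_SCALE[sampwidth]
    if n_channels > 1:
        data = data.reshape(-1, n_channels).T
    return AudioSignal(samples=data, sample_rate=sample_rate)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write an :class:`AudioSignal` as 16-bit PCM WAV (clipping to full scale)."""
    samples = signal.samples
    if samples.ndim == 1:
        interleaved = samples
    else:
        interleaved = samples.T.reshape(-1)
    ints = np.clip(np.round(interleaved * 32768.0), -32768, 32767).astype(np.int16)
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(signal.n_channels)
        wf.setsampwidth(2)
        wf.setframerate(signal.sample_rate)
        wf.writeframes(ints.tobytes())


def to_mono(signal: AudioSignal) -> AudioSignal:
    """Average channels into a single channel (identity on mono input)."""
    if signal.n_channels == 1:
        return signal
    return AudioSignal(samples=signal.samples.mean(axis=0), sample_rate=signal.sample_rate)


# ---------------------------------------------------------------------------
# Segment label files (Audacity dialect: start<TAB>end<TAB>label)


def read_segment_labels(path: str | Path) -> list[SegmentLabel]:
    """Parse a tab-separated label file, validate, and sort by start time.

    Unknown labels and overlapping intervals are rejected.
    """
    text = Path(path).read_text()
    return parse_segment_labels(text, source=str(path))


def parse_segment_labels(text: str, source: str = "<string>") -> list[SegmentLabel]:
    labels: list[SegmentLabel] = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CorpusFormatError(
                f"{source}:{lineno}: expected 'start<TAB>end<TAB>label', got {line!r}"
            )
        start_s, end_s, label = float(parts[0]), float(parts[1]), parts[2].strip()
        labels.append(SegmentLabel(label=label, start_s=start_s, end_s=end_s))
    labels.sort(key=lambda seg: seg.start_s)
    for prev, nxt in zip(labels, labels[1:]):
        if nxt.start_s < prev.end_s - 1e-9:
            raise CorpusFormatError(
                f"{source}: overlapping segments {prev.label}[{prev.start_s},{prev.end_s}) and "
                f"{nxt.label}[{nxt.start_s},{nxt.end_s})"
            )
    return labels


def write_segment_labels(path: str | Path, labels: Iterable[SegmentLabel]) -> None:
    lines = [f"{seg.start_s:.6f}\t{seg.end_s:.6f}\t{seg.label}" for seg in labels]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def extract_segments(recording: CryRecording, target: str) -> list[AudioSignal]:
    """Slice out all audio segments carrying the ``target`` label.

    Segments are half-open sample intervals ``[round(start*fs),
    round(end*fs))`` so adjacent labels never share a boundary sample.
    """
    if target not in {"EXP", "INSV"}:
        raise ValueError(f"target must be EXP or INSV, got {target!r}")
    audio = to_mono(recording.audio)
    fs = audio.sample_rate
    out: list[AudioSignal] = []
    for seg in recording.labels:
        if seg.label != target:
            continue
        lo = int(round(seg.start_s * fs))
        hi = min(int(round(seg.end_s * fs)), audio.n_samples)
        if hi > lo:
            out.append(AudioSignal(samples=audio.samples[lo:hi], sample_rate=fs))
    return out


# ---------------------------------------------------------------------------
# Corpus manifest

MANIFEST_COLUMNS = ["wav", "labels", "health_class", "infant_id", "split"]


@dataclass
class CorpusManifest:
    """Table of corpus records with infant-disjoint ubm/adapt/test splits."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.records.columns)
        if missing:
            raise CorpusFormatError(f"manifest missing columns: {sorted(missing)}")
        self.validate()

    def validate(self) -> None:
        bad_split = set(self.records["split"]) - SPLIT_TAGS
        if bad_split:
            raise CorpusFormatError(f"unknown split tags: {sorted(bad_split)}")
        bad_class = set(self.records["health_class"]) - HEALTH_CLASSES
        if bad_class:
            raise CorpusFormatError(f"unknown health classes: {sorted(bad_class)}")
        per_infant = self.records.groupby("infant_id")["split"].nunique()
        leaky = per_infant[per_infant > 1]
        if len(leaky):
            raise CorpusFormatError(
                f"infants appear in multiple splits: {sorted(leaky.index.tolist())}"
            )

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split]

    @classmethod
    def read_csv(cls, path: str | Path) -> "CorpusManifest":
        return cls(records=pd.read_csv(path, dtype=str))

    def write_csv(self, path: str | Path) -> None:
        self.records[MANIFEST_COLUMNS].to_csv(path, index=False)
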