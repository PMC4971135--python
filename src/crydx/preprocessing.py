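"""Short-term preprocessing of cry segments.

Pre-emphasis with P(z) = 1 - 0.97 z^-1, framing into 10/30-ms windows
with 30% overlap, Hamming windowing, cumulative-power band analysis of
the usable cry bandwidth, and splitting labeled segments into ~3-s cry
units (the scoring granule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from crydx.corpus_io import AudioSignal

DEFAULT_PREEMPHASIS = 0.97
DEFAULT_OVERLAP = 0.30
DEFAULT_UNIT_SECONDS = 3.0


@dataclass(frozen=True)
class FrameSequence:
    """N frames of L samples each, cut with a fixed hop.

    ``hop = round(L * (1 - overlap_frac))``; trailing samples that do not
    fill a frame are dropped.
    """

    frames: np.ndarray
    frame_ms: float
    overlap_frac: float
    sample_rate: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_len(self) -> int:
        return self.frames.shape[1] if self.frames.ndim == 2 else frame_length(self.frame_ms, self.sample_rate)

    @property
    def hop(self) -> int:
        return frame_hop(self.frame_len, self.overlap_frac)


@dataclass(frozen=True)
class CryUnit:
    """An ~3-s chunk of one EXP or INSV segment.

    ``partial`` flags a trailing remainder shorter than the unit target;
    partial units are kept so short-evidence files stay scoreable.
    """

    audio: AudioSignal
    cry_type: str
    source_file: str = ""
    unit_index: int = 0
    partial: bool = False

    @property
    def duration_s(self) -> float:
        return self.audio.duration_s


@dataclass(frozen=True)
class BandAnalysis:
    """Cumulative power fraction over frequency, for bandwidth selection."""

    freqs: np.ndarray
    cumulative_fraction: np.ndarray

    def cutoff_hz(self, fraction: float) -> float:
        """Smallest grid frequency where the cumulative fraction reaches ``fraction``."""
        idx = int(np.searchsorted(self.cumulative_fraction, fraction))
        idx = min(idx, len(self.freqs) - 1)
        return float(self.freqs[idx])


def frame_length(frame_ms: float, sample_rate: int) -> int:
    return int(round(frame_ms * sample_rate / 1000.0))


def frame_hop(frame_len: int, overlap_frac: float) -> int:
    return max(1, int(round(frame_len * (1.0 - overlap_frac))))


def pre_emphasize(signal: AudioSignal, coeff: float = DEFAULT_PREEMPHASIS) -> AudioSignal:
    """First-order high-pass pre-emphasis y[n] = x[n] - coeff*x[n-1].

    The first sample passes through unchanged (no x[-1] needed), which
    flattens the glottal-source spectral tilt before cepstral analysis.
    """
    if not (0.0 <= coeff < 1.0):
        raise ValueError("pre-emphasis coefficient must be in [0, 1)")
    x = signal.samples
    y = np.empty_like(x)
    y[..., 0] = x[..., 0]
    y[..., 1:] = x[..., 1:] - coeff * x[..., :-1]
    return AudioSignal(samples=y, sample_rate=signal.sample_rate)


def frame_signal(signal: AudioSignal, frame_ms: float, overlap_frac: float = DEFAULT_OVERLAP) -> FrameSequence:
    """Cut a mono signal into overlapping frames.

    A signal shorter than one frame yields an empty FrameSequence (N=0).
    """
    if signal.samples.ndim != 1:
        raise ValueError("frame_signal requires mono audio; call to_mono first")
    if frame_ms <= 0:
        raise ValueError("frame_ms must be positive")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0, 1)")
    x = signal.samples
    L = frame_length(frame_ms, signal.sample_rate)
    hop = frame_hop(L, overlap_frac)
    if len(x) < L:
        frames = np.empty((0, L))
    else:
        n = (len(x) - L) // hop + 1
        idx = hop * np.arange(n)[:, None] + np.arange(L)[None, :]
        frames = x[idx]
    return FrameSequence(frames=frames, frame_ms=frame_ms, overlap_frac=overlap_frac, sample_rate=signal.sample_rate)


def apply_hamming(frames: FrameSequence) -> FrameSequence:
    """Multiply each frame by a symmetric Hamming window."""
    if frames.n_frames == 0:
        return frames
    window = np.hamming(frames.frames.shape[1])
    return FrameSequence(
        frames=frames.frames * window[None, :],
        frame_ms=frames.frame_ms,
        overlap_frac=frames.overlap_frac,
        sample_rate=frames.sample_rate,
    )


def cumulative_power_fraction(
    signal: AudioSignal, n_fft: int = 4096, welch_nperseg: int = 1024
) -> BandAnalysis:
    """Welch-averaged power spectrum, cumulated over frequency.

    Used to find the upper cutoff of the usable cry band (e.g. the
    frequency below which 94% of the energy lies); the curve ends at 1.
    """
    if signal.samples.ndim != 1:
        raise ValueError("band analysis requires mono audio")
    x = signal.samples
    if not np.any(x):
        raise ValueError("zero-power signal")
    nperseg = min(welch_nperseg, len(x))
    freqs, psd = sps.welch(x, fs=signal.sample_rate, nperseg=nperseg, nfft=max(n_fft, nperseg))
    cum = np.cumsum(psd)
    cum /= cum[-1]
    return BandAnalysis(freqs=freqs, cumulative_fraction=cum)


def split_cry_units(
    segments: list[AudioSignal],
    cry_type: str,
    unit_s: float = DEFAULT_UNIT_SECONDS,
    source_file: str = "",
    keep_partial: bool = True,
) -> list[CryUnit]:
    """Tile segments into consecutive non-overlapping ~unit_s chunks.

    The trailing remainder of each segment is kept as a partial unit
    (dropped when ``keep_partial`` is false); total duration is conserved
    exactly in samples when partials are kept.  Unit indices increment
    across all segments of the source file.
    """
    if unit_s <= 0:
        raise ValueError("unit_s must be positive")
    units: list[CryUnit] = []
    index = 0
    for seg in segments:
        step = int(round(unit_s * seg.sample_rate))
        n = seg.n_samples
        for lo in range(0, n, step):
            hi = min(lo + step, n)
            partial = (hi - lo) < step
            if partial and not keep_partial:
                continue
            units.append(
                CryUnit(
                    audio=AudioSignal(samples=seg.samples[lo:hi], sample_rate=seg.sample_rate),
                    cry_type=cry_type,
                    source_file=source_file,
                    unit_index=index,
                    partial=partial,
                )
            )
            index += 1
    return units
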