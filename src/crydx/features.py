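"""MFCC + delta + acceleration feature extraction.

Each windowed frame yields 12 mel-frequency cepstral coefficients from a
24-filter triangular mel bank plus log frame energy; first and second
time derivatives (delta and acceleration) are appended, giving the
39-dimensional vectors x_t that all downstream GMM modeling consumes.

The cepstrum uses the plain DCT-II form

    C_i = sum_{k=1..K} S_k cos(i (k - 1/2) pi / K),   i = 1..M

with no orthonormal scaling (any constant is absorbed by the GMMs), and
deltas use the standard regression window

    D_n = sum_{t=1..Theta} t (C_{n+t} - C_{n-t}) / (2 sum t^2)

with edge frames replicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from crydx.corpus_io import AudioSignal
from crydx.preprocessing import (
    DEFAULT_OVERLAP,
    DEFAULT_PREEMPHASIS,
    apply_hamming,
    frame_signal,
    pre_emphasize,
)

LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class FeatureConfig:
    """Front-end configuration.

    Defaults follow the cry-diagnostics setup: 24 mel filters over
    0-4 kHz (the band holding ~94% of cry energy), 12 cepstra + log
    energy, 10-ms frames with 30% overlap, delta window Theta=2.
    """

    n_filters: int = 24
    n_cepstra: int = 12
    f_low_hz: float = 0.0
    f_high_hz: float = 4000.0
    frame_ms: float = 10.0
    overlap_frac: float = DEFAULT_OVERLAP
    preemphasis_coeff: float = DEFAULT_PREEMPHASIS
    delta_window: int = 2
    include_energy: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.n_cepstra < self.n_filters):
            raise ValueError("need 1 <= n_cepstra < n_filters")
        if not (0.0 <= self.f_low_hz < self.f_high_hz):
            raise ValueError("need 0 <= f_low_hz < f_high_hz")
        if self.delta_window < 1:
            raise ValueError("delta_window must be >= 1")

    @property
    def n_static(self) -> int:
        return self.n_cepstra + (1 if self.include_energy else 0)

    @property
    def n_features(self) -> int:
        return 3 * self.n_static

    def column_names(self) -> list[str]:
        static = [f"c{i}" for i in range(1, self.n_cepstra + 1)]
        if self.include_energy:
            static.append("e")
        d = [f"d{i}" for i in range(1, len(static) + 1)]
        a = [f"a{i}" for i in range(1, len(static) + 1)]
        return static + d + a


@dataclass
class FeatureSequence:
    """T x D matrix of feature vectors for one cry unit."""

    X: np.ndarray
    cry_type: str = ""
    source_file: str = ""
    unit_index: int = 0
    partial: bool = False

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(config: FeatureConfig, n_fft: int, sample_rate: int) -> np.ndarray:
    """K x (n_fft//2 + 1) matrix of triangular filters, mel-equispaced.

    Filter k rises from edge k to center k and falls to edge k+2; all
    support lies strictly inside [f_low_hz, f_high_hz].
    """
    if config.f_high_hz > sample_rate / 2:
        raise ValueError(
            f"f_high_hz={config.f_high_hz} exceeds Nyquist {sample_rate / 2}"
        )
    K = config.n_filters
    edges_mel = np.linspace(hz_to_mel(config.f_low_hz), hz_to_mel(config.f_high_hz), K + 2)
    edges_hz = np.asarray(mel_to_hz(edges_mel))
    freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    bank = np.zeros((K, len(freqs)))
    for k in range(K):
        lo, center, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        rise = (freqs - lo) / (center - lo)
        fall = (hi - freqs) / (hi - center)
        bank[k] = np.clip(np.minimum(rise, fall), 0.0, None)
    return bank


def filterbank_centers_hz(config: FeatureConfig) -> np.ndarray:
    edges_mel = np.linspace(
        hz_to_mel(config.f_low_hz), hz_to_mel(config.f_high_hz), config.n_filters + 2
    )
    return np.asarray(mel_to_hz(edges_mel[1:-1]))


def mfcc_from_logfb(S: np.ndarray, n_cepstra: int) -> np.ndarray:
    """Cepstra C_i = sum_k S_k cos(i (k - 1/2) pi / K) for i = 1..M.

    ``S`` may be a single K-vector of log filterbank energies or an N x K
    matrix (one row per frame).
    """
    S = np.asarray(S, dtype=np.float64)
    was_vector = S.ndim == 1
    S = np.atleast_2d(S)
    K = S.shape[1]
    if not (1 <= n_cepstra <= K):
        raise ValueError("need 1 <= n_cepstra <= n_filters")
    i = np.arange(1, n_cepstra + 1)[:, None]
    k = np.arange(1, K + 1)[None, :]
    dct = np.cos(i * (k - 0.5) * np.pi / K)  # M x K
    C = S @ dct.T
    return C[0] if was_vector else C


def frame_log_energy(frames: np.ndarray) -> np.ndarray:
    """log of the frame's sum of squares, floored so silence stays finite."""
    frames = np.atleast_2d(frames)
    e = np.sum(frames * frames, axis=1)
    return np.log(np.maximum(e, LOG_FLOOR))


def delta(C: np.ndarray, window: int = 2) -> np.ndarray:
    """Regression-window time derivative per column, edges replicated.

    Applying it twice yields the acceleration coefficients.
    """
    C = np.atleast_2d(np.asarray(C, dtype=np.float64))
    T = C.shape[0]
    denom = 2.0 * sum(t * t for t in range(1, window + 1))
    padded = np.concatenate(
        [np.repeat(C[:1], window, axis=0), C, np.repeat(C[-1:], window, axis=0)], axis=0
    )
    out = np.zeros_like(C)
    for t in range(1, window + 1):
        out += t * (padded[window + t : window + t + T] - padded[window - t : window - t + T])
    return out / denom


def fft_size_for(frame_len: int) -> int:
    n = 1
    while n < frame_len:
        n *= 2
    return n


def extract_features(segment: AudioSignal, config: FeatureConfig = FeatureConfig()) -> FeatureSequence:
    """Full front end: pre-emphasis -> framing -> Hamming -> |FFT|^2 ->
    mel filterbank -> log -> DCT cepstra + log energy -> delta, delta-delta.

    A segment shorter than one frame yields an empty sequence (T=0).
    """
    emphasized = pre_emphasize(segment, config.preemphasis_coeff)
    frames = apply_hamming(frame_signal(emphasized, config.frame_ms, config.overlap_frac))
    if frames.n_frames == 0:
        return FeatureSequence(X=np.empty((0, config.n_features)))
    n_fft = fft_size_for(frames.frames.shape[1])
    spectrum = np.abs(np.fft.rfft(frames.frames, n=n_fft, axis=1)) ** 2
    bank = mel_filterbank(config, n_fft, segment.sample_rate)
    logfb = np.log(np.maximum(spectrum @ bank.T, LOG_FLOOR))
    static = mfcc_from_logfb(logfb, config.n_cepstra)
    static = np.atleast_2d(static)
    if config.include_energy:
        static = np.column_stack([static, frame_log_energy(frames.frames)])
    d1 = delta(static, config.delta_window)
    d2 = delta(d1, config.delta_window)
    return FeatureSequence(X=np.column_stack([static, d1, d2]))


def features_for_unit(unit, config: FeatureConfig = FeatureConfig()) -> FeatureSequence:
    """Extract features from a :class:`~crydx.preprocessing.CryUnit`."""
    seq = extract_features(unit.audio, config)
    seq.cry_type = unit.cry_type
    seq.source_file = unit.source_file
    seq.unit_index = unit.unit_index
    seq.partial = unit.partial
    return seq
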