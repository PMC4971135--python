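"""Synthetic cry corpora for end-to-end testing without clinical data.

Two generation modes:

* **feature mode** — samples 39-dimensional feature sequences directly
  from class-conditional GMMs derived from a common base model, so the
  GMM/adaptation/scoring/fusion stages are exercised exactly.  Class
  differences are mean shifts of magnitude ``separation`` (in units of
  the per-dimension standard deviation) along a seeded random direction
  per component.  Between-infant, between-recording and between-unit
  random effects plus additive white feature noise emulate the nuisance
  structure that limits real detectors: the class shift competes with
  infant variability rather than with frame noise alone.

* **audio mode** — renders cry-like waveforms (glottal pulse train with
  jitter/shimmer, formant resonators, amplitude envelope, NICU-like
  additive noise) plus segment label files, so the preprocessing and
  feature front end are exercised too.

Both modes emit infant-disjoint ubm/adapt/test splits; everything is
bit-reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import signal as sps

from crydx.corpus_io import AudioSignal, CorpusManifest, SegmentLabel, write_segment_labels, write_wav
from crydx.features import FeatureSequence
from crydx.gmm_core import GMMParams

CRY_TYPES = ("EXP", "INSV")


# ---------------------------------------------------------------------------
# GMM-level sampling


def sample_gmm(gmm: GMMParams, T: int, seed: int | np.random.Generator = 0) -> FeatureSequence:
    """Draw T i.i.d. frames from a diagonal GMM (component by weight,
    then Gaussian)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comps = rng.choice(gmm.K, size=T, p=gmm.weights / gmm.weights.sum())
    X = gmm.means[comps] + rng.standard_normal((T, gmm.dim)) * np.sqrt(gmm.variances[comps])
    return FeatureSequence(X=X)


def make_random_ubm(n_components: int, dim: int, seed: int = 0, spread: float = 3.0) -> GMMParams:
    """A seeded base mixture: random simplex weights, means scattered by
    ``spread``, log-uniform variances around 1."""
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(n_components, 5.0))
    means = rng.standard_normal((n_components, dim)) * spread
    variances = np.exp(rng.uniform(-0.5, 0.5, size=(n_components, dim)))
    return GMMParams(weights=w, means=means, variances=variances, tag="base")


def make_class_models(ubm: GMMParams, separation: float, n_classes: int, seed: int = 0) -> list[GMMParams]:
    """Class models = base model with a per-component mean shift of
    magnitude ``separation * sqrt(variance)`` along a seeded random unit
    direction; ``separation = 0`` returns exact copies."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    models = []
    for c in range(n_classes):
        m = ubm.copy(tag=f"class{c}")
        direction = rng.standard_normal(m.means.shape)
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        m.means = m.means + separation * direction * np.sqrt(m.variances)
        models.append(m)
    return models


# ---------------------------------------------------------------------------
# Feature-mode corpus


@dataclass
class SyntheticCorpusSpec:
    """Study conditions for the synthetic corpus.

    Class layout emulates a healthy cohort plus two enrolled
    pathologies; separations make the EXP expert stronger than the INSV
    expert, and INSV material is scarcer (fewer, shorter units, possibly
    absent), matching how real cry recordings behave.  Random-effect
    scales are in units of the per-dimension standard deviation.
    """

    classes: tuple[str, ...] = ("Healthy", "Neurological", "Respiratory")
    n_infants: dict[str, int] = field(
        default_factory=lambda: {"Healthy": 60, "Neurological": 30, "Respiratory": 30}
    )
    recordings_per_infant: int = 2
    split_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)  # ubm / adapt / test
    dim: int = 39
    n_base_components: int = 8
    separation: dict[str, float] = field(default_factory=lambda: {"EXP": 1.15, "INSV": 0.85})
    infant_effect: float = 0.75
    recording_effect: float = 0.3
    unit_effect: float = 0.4
    noise_level: float = 0.3
    frames_per_unit: int = 120
    exp_units_range: tuple[int, int] = (1, 8)
    insv_units_range: tuple[int, int] = (0, 4)
    partial_unit_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_infants) != set(self.classes):
            raise ValueError("n_infants must cover exactly the declared classes")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(v < 0 for v in self.separation.values()):
            raise ValueError("separation must be >= 0")


@dataclass
class CorpusRecord:
    """One synthetic recording: per-cry-type unit feature sequences."""

    file_id: str
    infant_id: str
    health_class: str
    split: str
    units: dict[str, list[FeatureSequence]]


@dataclass
class FeatureCorpus:
    """In-memory feature-mode corpus with infant-disjoint splits."""

    records: list[CorpusRecord]
    spec: SyntheticCorpusSpec

    def subset(self, split: str) -> list[CorpusRecord]:
        return [r for r in self.records if r.split == split]

    def frames_by_class(self, split: str, cry_type: str) -> dict[str, np.ndarray]:
        """Stack all unit frames per health class within a split."""
        out: dict[str, list[np.ndarray]] = {}
        for rec in self.subset(split):
            for seq in rec.units.get(cry_type, []):
                out.setdefault(rec.health_class, []).append(seq.X)
        return {c: np.vstack(mats) for c, mats in out.items() if mats}

    def manifest(self) -> CorpusManifest:
        rows = [
            {
                "wav": f"{r.file_id}.features",
                "labels": "",
                "health_class": r.health_class,
                "infant_id": r.infant_id,
                "split": r.split,
            }
            for r in self.records
        ]
        return CorpusManifest(records=pd.DataFrame(rows))


def _split_infants(n: int, fractions: tuple[float, float, float], rng: np.random.Generator) -> list[str]:
    n_ubm = max(1, int(round(fractions[0] * n)))
    n_adapt = max(1, int(round(fractions[1] * n)))
    n_test = max(1, n - n_ubm - n_adapt)
    tags = ["ubm"] * n_ubm + ["adapt"] * n_adapt + ["test"] * n_test
    tags = tags[:n]
    rng.shuffle(tags)
    return tags


def make_feature_corpus(spec: SyntheticCorpusSpec) -> FeatureCorpus:
    """Generate the feature-mode corpus described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    base = {
        ct: make_random_ubm(spec.n_base_components, spec.dim, seed=int(rng.integers(2**31)))
        for ct in CRY_TYPES
    }
    class_models = {
        ct: dict(
            zip(
                spec.classes,
                make_class_models(
                    base[ct], spec.separation[ct], len(spec.classes), seed=int(rng.integers(2**31))
                ),
            )
        )
        for ct in CRY_TYPES
    }
    sd = {ct: np.sqrt(base[ct].variances) for ct in CRY_TYPES}

    records: list[CorpusRecord] = []
    for cls in spec.classes:
        tags = _split_infants(spec.n_infants[cls], spec.split_fractions, rng)
        for i, split in enumerate(tags):
            infant_id = f"{cls[:4].lower()}{i:03d}"
            infant_shift = {
                ct: spec.infant_effect * rng.standard_normal(base[ct].means.shape) * sd[ct]
                for ct in CRY_TYPES
            }
            for rec_idx in range(spec.recordings_per_infant):
                file_id = f"{infant_id}_r{rec_idx}"
                rec_shift = {
                    ct: spec.recording_effect * rng.standard_normal(base[ct].means.shape) * sd[ct]
                    for ct in CRY_TYPES
                }
                units: dict[str, list[FeatureSequence]] = {}
                for ct, (lo, hi) in (("EXP", spec.exp_units_range), ("INSV", spec.insv_units_range)):
                    n_units = int(rng.integers(lo, hi + 1))
                    seqs = []
                    for u in range(n_units):
                        model = class_models[ct][cls].copy()
                        model.means = (
                            model.means
                            + infant_shift[ct]
                            + rec_shift[ct]
                            + spec.unit_effect * rng.standard_normal(model.means.shape) * sd[ct]
                        )
                        partial = rng.random() < spec.partial_unit_prob and u == n_units - 1
                        T = (
                            int(rng.integers(max(10, spec.frames_per_unit // 4), spec.frames_per_unit))
                            if partial
                            else spec.frames_per_unit
                        )
                        seq = sample_gmm(model, T, seed=rng)
                        seq.X = seq.X + spec.noise_level * rng.standard_normal(seq.X.shape) * sd[ct].mean()
                        seq.cry_type = ct
                        seq.source_file = file_id
                        seq.unit_index = u
                        seq.partial = partial
                        seqs.append(seq)
                    units[ct] = seqs
                records.append(
                    CorpusRecord(
                        file_id=file_id,
                        infant_id=infant_id,
                        health_class=cls,
                        split=split,
                        units=units,
                    )
                )
    return FeatureCorpus(records=records, spec=spec)


def write_feature_corpus(corpus: FeatureCorpus, out_dir: str | Path) -> Path:
    """Write per-unit feature CSVs plus manifest.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in corpus.records:
        for ct, seqs in rec.units.items():
            for seq in seqs:
                name = f"{rec.file_id}_{ct}_{seq.unit_index}{'p' if seq.partial else ''}.csv"
                np.savetxt(out_dir / name, seq.X, delimiter=",")
        rows.append(
            {
                "wav": rec.file_id,
                "labels": "",
                "health_class": rec.health_class,
                "infant_id": rec.infant_id,
                "split": rec.split,
            }
        )
    manifest = CorpusManifest(records=pd.DataFrame(rows))
    manifest.write_csv(out_dir / "manifest.csv")
    return out_dir / "manifest.csv"


# ---------------------------------------------------------------------------
# Audio-mode synthesis


@dataclass(frozen=True)
class SyntheticAudioParams:
    """Source-filter parameters for one cry-like sound.

    Newborn phonation sits near 450 Hz with formants far above adult
    values; INSV units are modeled as shorter, breathier (higher noise
    fraction), lower-amplitude sounds.
    """

    f0_hz: float = 450.0
    formants_hz: tuple[float, ...] = (1100.0, 3300.0)
    formant_bw_hz: float = 200.0
    jitter: float = 0.01
    shimmer: float = 0.05
    noise_fraction: float = 0.05
    amplitude: float = 0.5
    snr_db: float = 20.0

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def _rosenberg_pulse(n_open: int) -> np.ndarray:
    # Smooth glottal pulse; its spectrum decays with frequency so the
    # fundamental dominates an unfiltered pulse train.
    t = np.linspace(0.0, 1.0, n_open, endpoint=False)
    return 3.0 * t**2 - 2.0 * t**3


def synth_cry_audio(
    params: SyntheticAudioParams, duration_s: float, sample_rate: int = 44100, seed: int = 0
) -> AudioSignal:
    """Render one cry-like unit by source-filter synthesis.

    Glottal pulses at f0 (periods perturbed by ``jitter``, amplitudes by
    ``shimmer``) are mixed with aspiration noise, passed through
    second-order formant resonators, amplitude-enveloped, and buried in
    white noise at ``snr_db``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if params.f0_hz >= sample_rate / 4:
        raise ValueError("f0 too high for the sample rate")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    source = np.zeros(n)
    period = sample_rate / params.f0_hz
    pulse = _rosenberg_pulse(max(4, int(0.6 * period)))
    pos = 0.0
    while pos < n:
        i = int(round(pos))
        amp = 1.0 + params.shimmer * rng.standard_normal()
        end = min(i + len(pulse), n)
        source[i:end] += amp * pulse[: end - i]
        pos += period * (1.0 + params.jitter * rng.standard_normal())
    if params.noise_fraction > 0:
        noise = rng.standard_normal(n)
        noise *= np.sqrt(np.mean(source**2) / max(np.mean(noise**2), 1e-30))
        source = (1.0 - params.noise_fraction) * source + params.noise_fraction * noise
    out = source
    for f in params.formants_hz:
        r = np.exp(-np.pi * params.formant_bw_hz / sample_rate)
        theta = 2.0 * np.pi * f / sample_rate
        out = sps.lfilter([1.0 - r], [1.0, -2.0 * r * np.cos(theta), r * r], out)
    ramp = min(n // 10, int(0.05 * sample_rate))
    if ramp > 0:
        env = np.ones(n)
        env[:ramp] = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp) / ramp)
        env[-ramp:] = env[:ramp][::-1]
        out = out * env
    peak = np.max(np.abs(out))
    if peak > 0:
        out = params.amplitude * out / peak
    if np.isfinite(params.snr_db) and params.snr_db < 200:
        sig_pow = np.mean(out**2)
        noise = rng.standard_normal(n)
        noise *= np.sqrt(sig_pow / 10.0 ** (params.snr_db / 10.0))
        out = out + noise
    return AudioSignal(samples=out, sample_rate=sample_rate)


@dataclass
class AudioCorpusSpec:
    """Layout of a small audio-mode corpus."""

    classes: tuple[str, ...] = ("Healthy", "Neurological")
    n_infants: dict[str, int] = field(default_factory=lambda: {"Healthy": 4, "Neurological": 4})
    recordings_per_infant: int = 1
    split_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    exp_segments: tuple[int, int] = (2, 3)
    exp_duration_s: tuple[float, float] = (1.0, 4.0)
    insv_segments: tuple[int, int] = (1, 2)
    insv_duration_s: tuple[float, float] = (0.3, 1.0)
    gap_s: float = 0.2
    f0_offset_per_class_hz: float = 60.0
    sample_rate: int = 16000
    snr_db: float = 20.0
    seed: int = 0


def make_audio_corpus(spec: AudioCorpusSpec, out_dir: str | Path) -> CorpusManifest:
    """Write WAVs + Audacity-style label files + manifest.csv.

    Class identity offsets the fundamental frequency; recordings
    alternate EXP and INSV segments separated by low-level noise gaps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for c_idx, cls in enumerate(spec.classes):
        tags = _split_infants(spec.n_infants[cls], spec.split_fractions, rng)
        f0 = 450.0 + c_idx * spec.f0_offset_per_class_hz
        for i, split in enumerate(tags):
            infant_id = f"{cls[:4].lower()}{i:03d}"
            for rec_idx in range(spec.recordings_per_infant):
                file_id = f"{infant_id}_r{rec_idx}"
                pieces: list[np.ndarray] = []
                labels: list[SegmentLabel] = []
                t = 0.0
                n_exp = int(rng.integers(*spec.exp_segments, endpoint=True))
                n_insv = int(rng.integers(*spec.insv_segments, endpoint=True))
                order = ["EXP"] * n_exp + ["INSV"] * n_insv
                rng.shuffle(order)
                for seg_type in order:
                    gap = np.zeros(int(spec.gap_s * spec.sample_rate))
                    pieces.append(gap)
                    t += spec.gap_s
                    if seg_type == "EXP":
                        dur = float(rng.uniform(*spec.exp_duration_s))
                        params = SyntheticAudioParams(f0_hz=f0, snr_db=spec.snr_db)
                    else:
                        dur = float(rng.uniform(*spec.insv_duration_s))
                        params = SyntheticAudioParams(
                            f0_hz=f0 * 1.15, noise_fraction=0.25, amplitude=0.25, snr_db=spec.snr_db
                        )
                    audio = synth_cry_audio(
                        params, dur, sample_rate=spec.sample_rate, seed=int(rng.integers(2**31))
                    )
                    pieces.append(audio.samples)
                    labels.append(SegmentLabel(label=seg_type, start_s=t, end_s=t + audio.duration_s))
                    t += audio.duration_s
                samples = np.concatenate(pieces) if pieces else np.zeros(spec.sample_rate)
                wav_path = out_dir / f"{file_id}.wav"
                lbl_path = out_dir / f"{file_id}.txt"
                write_wav(wav_path, AudioSignal(samples=samples, sample_rate=spec.sample_rate))
                write_segment_labels(lbl_path, labels)
                rows.append(
                    {
                        "wav": wav_path.name,
                        "labels": lbl_path.name,
                        "health_class": cls,
                        "infant_id": infant_id,
                        "split": split,
                    }
                )
    manifest = CorpusManifest(records=pd.DataFrame(rows))
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest
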