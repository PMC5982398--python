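"""DEAP-shaped synthetic datasets with planted valence/arousal structure.

Each simulated trial reproduces the layout of the DEAP preprocessed release
(40 channels x 60 s at 128 Hz by default; 32 EEG rows in Geneva order, GSR at
row 36) and carries a latent emotion quadrant that leaves fingerprints the
pipeline can recover:

* EEG rows are 1/f background noise plus band-limited alpha (8-13 Hz) and
  beta (14-30 Hz) oscillations.  Beta amplitude scales with latent arousal
  scalp-wide, most strongly on the frontal channels F3/F4/AF3/AF4 (full
  modulation depth frontally, half the log-depth elsewhere — arousal-linked
  beta changes are widespread with frontal prominence).  The right-frontal
  (F4/AF4) alpha amplitude scales with latent valence, so valence appears
  as a frontal alpha asymmetry.  Modulation depth is ``eeg_effect``; 0
  plants no class information.
* The GSR row is a slowly drifting tonic conductance plus Poisson-arriving
  phasic responses (fast rise, exponential decay) whose arrival rate grows
  with latent arousal, scaled by ``gsr_effect``.
* Ratings are the latent (valence, arousal) plus Gaussian noise, clipped to
  [1, 9]; latent values keep a margin from the (5, 5) threshold, so with
  ``rating_noise_sd=0`` the labeling stage recovers the planted classes
  exactly.

Every trial is generated from its own ``SeedSequence(seed, subject, video)``
stream, so datasets are bitwise reproducible and subjects can be generated
independently (streaming) with identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deap_io import (
    DEAP_EEG_CHANNELS,
    DEFAULT_GSR_CHANNEL_INDEX,
    DatasetMeta,
    TrialRecord,
    write_dataset,
)
from .errors import ValidationError
from .labeling import SCHEME_CLASSES, SelfAssessment

QUADRANTS = SCHEME_CLASSES["quadrant4"]  # (HAHV, HALV, LALV, LAHV)

# conventional modulation depths used throughout the package's experiments
EFFECT_NONE = 0.0
EFFECT_MODERATE = 0.5
EFFECT_LARGE = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 32
    n_videos: int = 40
    duration_s: float = 60.0
    fs: float = 128.0
    seed: int = 0
    eeg_effect: float = 1.0
    gsr_effect: float = 1.0
    rating_noise_sd: float = 0.5
    class_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_channels: int = 40

    def __post_init__(self) -> None:
        if self.eeg_effect < 0 or self.gsr_effect < 0:
            raise ValidationError("effect sizes must be >= 0")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.class_mix):
            raise ValidationError("class_mix must be non-negative and sum to 1")
        if self.n_channels < 33:
            raise ValidationError("need >= 33 channels (32 EEG + GSR)")
        if self.rating_noise_sd < 0:
            raise ValidationError("rating_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted per-trial class and latent affect coordinates."""

    classes: list[str] = field(default_factory=list)  # quadrant name per trial
    latents: list[tuple[float, float]] = field(default_factory=list)  # (valence, arousal)
    subject_ids: list[str] = field(default_factory=list)
    video_ids: list[int] = field(default_factory=list)


_FRONTAL_RIGHT = [DEAP_EEG_CHANNELS.index(c) for c in ("AF4", "F4")]
_FRONTAL_LEFT = [DEAP_EEG_CHANNELS.index(c) for c in ("AF3", "F3")]
_FRONTAL = _FRONTAL_RIGHT + _FRONTAL_LEFT

# fixed signal conventions (microvolt-scale EEG, arbitrary conductance units)
_BG_RMS = 10.0  # 1/f background RMS per EEG channel
_ALPHA_RMS = 4.0
_BETA_RMS = 5.0
_SCR_BASE_RATE_HZ = 0.1  # ~6 phasic responses per minute at neutral arousal
_SCR_AMP = 0.4
_TONIC_LEVEL = 4.0
_TONIC_DRIFT = 0.25
# latent affect enters amplitudes/rates as (1 + effect) ** ((latent - 5) / _EFFECT_SCALE);
# scale 2 puts a latent at the scale extremes (1 or 9) at (1+effect)^±2
_EFFECT_SCALE = 2.0


def _band_noise(rng, n, fs, f_lo, f_hi, n_rows):
    """Gaussian noise band-limited to [f_lo, f_hi], unit RMS per row."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    spec = np.zeros((n_rows, freqs.size), dtype=complex)
    k = int(mask.sum())
    spec[:, mask] = rng.standard_normal((n_rows, k)) + 1j * rng.standard_normal((n_rows, k))
    x = np.fft.irfft(spec, n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _pink_noise(rng, n, fs, n_rows):
    """1/f-amplitude background noise, unit RMS per row."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (
        rng.standard_normal((n_rows, freqs.size)) + 1j * rng.standard_normal((n_rows, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _scr_kernel(fs: float) -> np.ndarray:
    """Phasic skin-conductance response: fast rise (0.7 s), slow decay (3 s)."""
    t = np.arange(0, int(15 * fs)) / fs
    k = (1.0 - np.exp(-t / 0.7)) * np.exp(-t / 3.0)
    return k / k.max()

def _latent_for_class(rng, cls: str) -> tuple[float, float]:
    # margins keep noiseless ratings on the correct side of the (5,5) threshold
    hv = cls in ("HAHV", "LAHV")
    ha = cls in ("HAHV", "HALV")
    v = rng.uniform(6.0, 8.5) if hv else rng.uniform(1.5, 4.0)
    a = rng.uniform(6.0, 8.5) if ha else rng.uniform(1.5, 4.0)
    return float(v), float(a)


def _subject_classes(cfg: SimulationConfig, subject: int) -> list[str]:
    """Planted class per video for one subject: class_mix proportions are hit
    as exactly as rounding allows (balanced design), in a seeded shuffle."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject]))
    counts = np.floor(np.asarray(cfg.class_mix) * cfg.n_videos).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = np.asarray(cfg.class_mix) * cfg.n_videos - counts
    for i in np.argsort(-frac)[: cfg.n_videos - counts.sum()]:
        counts[i] += 1
    classes = [q for q, c in zip(QUADRANTS, counts) for _ in range(c)]
    rng.shuffle(classes)
    return classes


def simulate_trial(cfg: SimulationConfig, subject: int, video: int):
    """One trial's (signals, quadrant class, latent (v, a), SelfAssessment).

    ``subject`` and ``video`` are 1-based; they key the per-trial RNG stream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject, video]))
    n = int(round(cfg.duration_s * cfg.fs))
    cls = _subject_classes(cfg, subject)[video - 1]
    v, a = _latent_for_class(rng, cls)

    signals = np.empty((cfg.n_channels, n), dtype=np.float32)
    n_eeg = 32
    bg = _pink_noise(rng, n, cfg.fs, cfg.n_channels) * _BG_RMS
    alpha = _band_noise(rng, n, cfg.fs, 8.0, 13.0, n_eeg)
    beta = _band_noise(rng, n, cfg.fs, 14.0, 30.0, n_eeg)

    alpha_amp = np.full(n_eeg, _ALPHA_RMS)
    beta_amp = np.full(n_eeg, _BETA_RMS)
    f_val = (1.0 + cfg.eeg_effect) ** ((v - 5.0) / _EFFECT_SCALE)
    f_aro = (1.0 + cfg.eeg_effect) ** ((a - 5.0) / _EFFECT_SCALE)
    alpha_amp[_FRONTAL_RIGHT] *= f_val  # frontal alpha asymmetry tracks valence
    # arousal raises beta power scalp-wide (half log-depth) with the frontal
    # channels modulated most strongly (full depth)
    beta_amp *= np.sqrt(f_aro)
    beta_amp[_FRONTAL] *= f_aro / np.sqrt(f_aro)

    eeg = bg[:n_eeg] + alpha_amp[:, None] * alpha + beta_amp[:, None] * beta
    signals[:n_eeg] = eeg.astype(np.float32)

    # peripheral rows: plain noise placeholders except the GSR row
    signals[n_eeg:] = (bg[n_eeg:]).astype(np.float32)

    rate = _SCR_BASE_RATE_HZ * (1.0 + cfg.gsr_effect) ** ((a - 5.0) / _EFFECT_SCALE)
    n_events = rng.poisson(rate * cfg.duration_s)
    gsr = np.full(n, _TONIC_LEVEL)
    drift = _band_noise(rng, n, cfg.fs, 1.0 / cfg.duration_s, 0.05, 1)[0]
    gsr = gsr + _TONIC_DRIFT * drift
    kernel = _scr_kernel(cfg.fs)
    for t0 in rng.uniform(0, cfg.duration_s, size=n_events):
        i0 = int(t0 * cfg.fs)
        amp = _SCR_AMP * rng.uniform(0.5, 1.5)
        seg = kernel[: n - i0]
        gsr[i0 : i0 + seg.size] += amp * seg
    signals[DEFAULT_GSR_CHANNEL_INDEX] = gsr.astype(np.float32)

    noise = rng.normal(0.0, cfg.rating_noise_sd, size=2) if cfg.rating_noise_sd > 0 else np.zeros(2)
    ratings = SelfAssessment(
        valence=float(np.clip(v + noise[0], 1.0, 9.0)),
        arousal=float(np.clip(a + noise[1], 1.0, 9.0)),
        dominance=float(rng.uniform(1.0, 9.0)),
        liking=float(rng.uniform(1.0, 9.0)),
    )
    return signals, cls, (v, a), ratings


def iter_subject_trials(cfg: SimulationConfig, subject: int):
    """Yield the TrialRecords (with truth rows) of one 1-based subject."""
    sid = f"s{subject:02d}"
    for video in range(1, cfg.n_videos + 1):
        signals, cls, latent, ratings = simulate_trial(cfg, subject, video)
        rec = TrialRecord(
            subject_id=sid,
            video_id=video,
            signals=signals,
            sampling_rate_hz=cfg.fs,
            ratings=ratings,
        )
        yield rec, cls, latent


def simulate_dataset(cfg: SimulationConfig = SimulationConfig()):
    """Full synthetic dataset: (list of TrialRecord, GroundTruth)."""
    trials: list[TrialRecord] = []
    truth = GroundTruth()
    for s in range(1, cfg.n_subjects + 1):
        for rec, cls, latent in iter_subject_trials(cfg, s):
            trials.append(rec)
            truth.classes.append(cls)
            truth.latents.append(latent)
            truth.subject_ids.append(rec.subject_id)
            truth.video_ids.append(rec.video_id)
    return trials, truth


def default_meta(cfg: SimulationConfig = SimulationConfig()) -> DatasetMeta:
    return DatasetMeta(
        n_subjects=cfg.n_subjects,
        n_videos=cfg.n_videos,
        eeg_channel_names=DEAP_EEG_CHANNELS,
        gsr_channel_index=DEFAULT_GSR_CHANNEL_INDEX,
    )


def export_as_deap(trials, path, fmt: str = "h5"):
    """Write the synthetic set in a dialect ``deap_io`` reads; round-trips
    exactly (same dtypes on disk as in memory)."""
    return write_dataset(trials, path, fmt=fmt)
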