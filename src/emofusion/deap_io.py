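"""Reading and writing DEAP-style preprocessed datasets.

The DEAP preprocessed release ships one file per subject, each holding a
``data`` array of shape (40 trials x 40 channels x 8064 samples) at 128 Hz and
a ``labels`` array of shape (40 x 4) with self-assessed valence, arousal,
dominance and liking on a 1-9 scale.  The first 32 channel rows are EEG in the
Geneva 10-20 order; the peripheral rows follow, with galvanic skin response at
0-based row 36.

Three on-disk dialects are supported, inferred from the file extension:

* ``.mat`` (MATLAB v7) via :func:`scipy.io.loadmat`;
* ``.mat`` (MATLAB v7.3 / HDF5) via h5py, with the column-major axis reversal
  undone;
* ``.h5`` / ``.hdf5`` — the package's own dialect: datasets ``/data`` and
  ``/ratings`` plus attributes ``subject_id``, ``sampling_rate_hz``.

All format knowledge lives here; nothing downstream touches files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.io

from .errors import (
    ConfigurationError,
    DatasetIncompleteError,
    FormatError,
    InputError,
)
from .labeling import SelfAssessment

#: The 32 EEG channels of the DEAP preprocessed release, in on-disk row order
#: (Geneva order, 10-20 labels).
DEAP_EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

DEFAULT_SAMPLING_RATE_HZ = 128.0
#: GSR row in the 40-channel preprocessed layout (0-based).
DEFAULT_GSR_CHANNEL_INDEX = 36

_EXTENSIONS = (".h5", ".hdf5", ".mat")


@dataclass(frozen=True)
class TrialRecord:
    """One subject x video trial: the raw multichannel block plus ratings."""

    subject_id: str
    video_id: int
    signals: np.ndarray  # (n_channels, n_samples)
    sampling_rate_hz: float
    ratings: SelfAssessment

    def __post_init__(self) -> None:
        sig = self.signals
        if sig.ndim != 2:
            raise FormatError(
                f"trial signals must be 2-D (channels x samples), got rank {sig.ndim}"
            )
        if sig.shape[0] < 33:
            raise FormatError(
                f"expected >= 33 channels (32 EEG + GSR), found {sig.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class DatasetMeta:
    """Layout of a DEAP-style dataset: channel naming and counts."""

    n_subjects: int = 32
    n_videos: int = 40
    eeg_channel_names: tuple[str, ...] = DEAP_EEG_CHANNELS
    gsr_channel_index: int = DEFAULT_GSR_CHANNEL_INDEX

    def __post_init__(self) -> None:
        if len(self.eeg_channel_names) != 32:
            raise ConfigurationError(
                f"expected 32 EEG channel names, got {len(self.eeg_channel_names)}"
            )
        if self.gsr_channel_index < len(self.eeg_channel_names):
            raise ConfigurationError(
                f"gsr_channel_index={self.gsr_channel_index} points at an EEG row "
                f"(rows 0..{len(self.eeg_channel_names) - 1} are EEG)"
            )


def _subject_stem(i: int) -> str:
    return f"s{i:02d}"


def _read_mat_v7(path: Path):
    mat = scipy.io.loadmat(path)
    return np.asarray(mat["data"]), np.asarray(mat["labels"])


def _read_mat_v73(path: Path):
    # MATLAB v7.3 stores arrays column-major; h5py sees reversed axes.
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"]).transpose()
        labels = np.asarray(f["labels"]).transpose()
    return data, labels


def _read_subject_file(path: Path):
    """Returns (data, ratings_array, sampling_rate or None)."""
    if path.suffix == ".mat":
        try:
            data, labels = _read_mat_v7(path)
        except NotImplementedError:  # loadmat refuses v7.3
            data, labels = _read_mat_v73(path)
        except KeyError as e:
            raise FormatError(f"{path.name}: missing variable {e}") from e
        return data, labels, None
    with h5py.File(path, "r") as f:
        if "data" not in f or "ratings" not in f:
            raise FormatError(
                f"{path.name}: expected datasets /data and /ratings, "
                f"found {sorted(f.keys())}"
            )
        data = np.asarray(f["data"])
        ratings = np.asarray(f["ratings"])
        fs = float(f.attrs.get("sampling_rate_hz", DEFAULT_SAMPLING_RATE_HZ))
    return data, ratings, fs


def read_preprocessed_dataset(path, meta: DatasetMeta) -> list[TrialRecord]:
    """Load every subject file under *path* into TrialRecords.

    Trials and channels are returned exactly in on-disk order; signals are
    never rescaled.  Missing subject files raise
    :class:`DatasetIncompleteError` naming the subject; malformed arrays raise
    :class:`FormatError` with the expected vs found shape.
    """
    root = Path(path)
    trials: list[TrialRecord] = []
    for i in range(1, meta.n_subjects + 1):
        stem = _subject_stem(i)
        fpath = next(
            (root / (stem + ext) for ext in _EXTENSIONS if (root / (stem + ext)).exists()),
            None,
        )
        if fpath is None:
            raise DatasetIncompleteError(
                f"dataset at {root} is incomplete: no file for subject {stem!r}"
            )
        data, ratings, fs = _read_subject_file(fpath)
        fs = DEFAULT_SAMPLING_RATE_HZ if fs is None else fs
        if data.ndim != 3:
            raise FormatError(
                f"{fpath.name}: data must be rank 3 (trials x channels x samples), "
                f"got rank {data.ndim} with shape {data.shape}"
            )
        if data.shape[0] != meta.n_videos:
            raise FormatError(
                f"{fpath.name}: expected {meta.n_videos} trials, found {data.shape[0]}"
            )
        if ratings.ndim != 2 or ratings.shape[0] != data.shape[0] or ratings.shape[1] < 4:
            raise FormatError(
                f"{fpath.name}: expected ratings shape ({data.shape[0]}, >=4), "
                f"found {ratings.shape}"
            )
        for v in range(data.shape[0]):
            # order fixed by the release: valence, arousal, dominance, liking;
            # a 5th familiarity column, when present, is ignored.
            sa = SelfAssessment(
                valence=ratings[v, 0],
                arousal=ratings[v, 1],
                dominance=ratings[v, 2],
                liking=ratings[v, 3],
            )
            trials.append(
                TrialRecord(
                    subject_id=stem,
                    video_id=v + 1,
                    signals=data[v],
                    sampling_rate_hz=fs,
                    ratings=sa,
                )
            )
    return trials


def select_channels(trial: TrialRecord, meta: DatasetMeta):
    """Split a trial into the ordered 32-row EEG block and the GSR trace."""
    n_eeg = len(meta.eeg_channel_names)
    if meta.gsr_channel_index >= trial.n_channels:
        raise ConfigurationError(
            f"gsr_channel_index={meta.gsr_channel_index} out of range for "
            f"{trial.n_channels}-channel trial"
        )
    eeg_block = trial.signals[:n_eeg]
    gsr_trace = trial.signals[meta.gsr_channel_index]
    return eeg_block, gsr_trace


def write_dataset(trials, path, fmt: str = "h5") -> list[Path]:
    """Serialize trials losslessly, one file per subject.

    ``fmt='h5'`` writes the package dialect; ``fmt='mat'`` writes MATLAB v7
    files readable by :func:`read_preprocessed_dataset` (and by DEAP tooling).
    Returns the written paths.
    """
    trials = list(trials)
    if not trials:
        raise InputError("refusing to write an empty dataset")
    if fmt not in ("h5", "mat"):
        raise ConfigurationError(f"unknown format {fmt!r}")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    written = []
    for sid, recs in by_subject.items():
        recs = sorted(recs, key=lambda t: t.video_id)
        data = np.stack([t.signals for t in recs])
        ratings = np.array(
            [
                (t.ratings.valence, t.ratings.arousal, t.ratings.dominance, t.ratings.liking)
                for t in recs
            ]
        )
        if fmt == "h5":
            fpath = root / f"{sid}.h5"
            with h5py.File(fpath, "w") as f:
                f.create_dataset("data", data=data)
                f.create_dataset("ratings", data=ratings)
                f.attrs["subject_id"] = sid
                f.attrs["sampling_rate_hz"] = recs[0].sampling_rate_hz
        else:
            fpath = root / f"{sid}.mat"
            scipy.io.savemat(fpath, {"data": data, "labels": ratings})
        written.append(fpath)
    return written
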