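"""Training and evaluation of the fusion model.

Training is maximum-likelihood: softmax cross-entropy minimized by plain
stochastic gradient descent (W <- W - lr * dL/dW), one trial per step (a
batch of 32 electrode spectrograms sharing the trial's GSR vector and label).
Validation loss is measured every ``eval_interval`` iterations; the returned
parameters are the snapshot at the minimum validation loss (early stopping),
and training halts once no improvement has been seen for
``early_stop_patience`` iterations.

Two evaluation protocols are provided:

* hold-out — a per-class-stratified 9:1:1 train/validation/test split of
  trials;
* leave-one-video-out — each fold holds out every subject's trial of one
  stimulus, trains on the remaining videos, and the reported accuracy is the
  mean over folds.

Accuracy is trial-level: the 32 electrode probability rows of a test trial
are averaged and the argmax is compared with the true class (electrode-level
accuracy is also computed for reference).  Splits are checked for
(subject, video) leakage programmatically.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .deap_io import DatasetMeta, select_channels
from .eeg_spectrogram import SpectrogramConfig, normalize_spectrogram, transform_dataset
from .errors import DivergenceError, InputError, LeakageError, ValidationError
from .fusion_model import FusionCNN, FusionModelConfig, aggregate_trial_prediction
from .gsr_features import STZCRConfig, extract_features
from .labeling import DEFAULT_THRESHOLD, EmotionLabel, assign_label

# ---------------------------------------------------------------------------
# configuration and containers


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    max_iterations: int = 400
    early_stop_patience: int = 100
    eval_interval: int = 10
    batch_trials: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "holdout"  # or "loocv_video"
    ratios: tuple[int, int, int] = (9, 1, 1)  # train : val : test
    per_subject: bool = False  # loocv variant: fold by (video, subject)

    def __post_init__(self) -> None:
        if self.mode not in ("holdout", "loocv_video"):
            raise ValidationError(f"unknown split mode {self.mode!r}")
        if any(r <= 0 for r in self.ratios):
            raise ValidationError("split ratios must be positive")


@dataclass
class EvalReport:
    scheme: str
    mode: str
    accuracy: float
    n_test: int
    electrode_accuracy: float | None = None
    fold_accuracies: list[float] = field(default_factory=list)
    loss_curve: list[tuple[int, float, float]] = field(default_factory=list)
    stopped_at: int = 0
    best_iteration: int = 0

    def to_json(self) -> str:
        d = {
            "scheme": self.scheme,
            "mode": self.mode,
            "accuracy": self.accuracy,
            "n_test": self.n_test,
            "electrode_accuracy": self.electrode_accuracy,
            "fold_accuracies": self.fold_accuracies,
            "stopped_at": self.stopped_at,
            "best_iteration": self.best_iteration,
            "loss_curve": [list(x) for x in self.loss_curve],
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class TrialFeatures:
    """Model-ready features for one trial."""

    subject_id: str
    video_id: int
    spectrograms: np.ndarray  # (32, n_freqs, n_times), z-scored, float32
    gsr: np.ndarray  # (gsr_dim,) thresholded STZCR values
    label: EmotionLabel


# ---------------------------------------------------------------------------
# losses and updates


def cross_entropy(p, q) -> float:
    """L(p, q) = -sum_i p_i ln q_i, with q clamped at 1e-12."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.size != q.size:
        raise InputError(f"length mismatch: p has {p.size}, q has {q.size}")
    return float(-(p * np.log(np.clip(q, 1e-12, None))).sum())


def sgd_step(params: dict, grads: dict, learning_rate: float) -> dict:
    """One gradient-descent update; pure function of its inputs."""
    out = {}
    for name, w in params.items():
        g = grads.get(name)
        if g is None:
            out[name] = w.copy()
            continue
        if not np.all(np.isfinite(g)):
            raise DivergenceError(f"non-finite gradient for parameter {name!r}")
        out[name] = w - learning_rate * g
    return out


# ---------------------------------------------------------------------------
# feature preparation


def prepare_trial_features(
    trials,
    meta: DatasetMeta,
    scheme: str,
    spec_cfg: SpectrogramConfig = SpectrogramConfig(),
    stzcr_cfg: STZCRConfig = STZCRConfig(),
    threshold=DEFAULT_THRESHOLD,
) -> list[TrialFeatures]:
    """Run the preprocessing front end over trials, in deterministic order."""
    ordered = sorted(trials, key=lambda t: (t.subject_id, t.video_id))
    out: list[TrialFeatures] = []
    stream = transform_dataset(ordered, meta, spec_cfg)
    for trial in ordered:
        specs = np.empty(
            (len(meta.eeg_channel_names), spec_cfg.n_freqs, spec_cfg.n_times),
            dtype=np.float32,
        )
        for ch in range(len(meta.eeg_channel_names)):
            _, _, _, sp = next(stream)
            specs[ch] = normalize_spectrogram(sp).values
        _, gsr = select_channels(trial, meta)
        fv = extract_features(gsr, stzcr_cfg)
        # feed the fusion head per-window crossing *counts* (rate x window
        # length): O(1) values commensurate with the z-scored spectrograms,
        # and a linear readout of their sum recovers the trial's total
        # supra-threshold crossing activity
        out.append(
            TrialFeatures(
                subject_id=trial.subject_id,
                video_id=trial.video_id,
                spectrograms=specs,
                gsr=fv.values.astype(np.float64) * stzcr_cfg.window_len,
                label=assign_label(trial.ratings, scheme, threshold),
            )
        )
    return out


# ---------------------------------------------------------------------------
# splitting


def make_holdout_split(data: list[TrialFeatures], ratios, rng: np.random.Generator):
    """Per-class proportional (stratified) trial split; returns index arrays."""
    r = np.asarray(ratios, dtype=float)
    fracs = r / r.sum()
    classes: dict[str, list[int]] = {}
    for i, t in enumerate(data):
        classes.setdefault(t.label.class_name, []).append(i)
    train, val, test = [], [], []
    for name in sorted(classes):
        idx = np.array(classes[name])
        rng.shuffle(idx)
        n = idx.size
        n_val = max(1, int(round(n * fracs[1]))) if n >= 3 else max(0, n - 2)
        n_test = max(1, int(round(n * fracs[2]))) if n >= 3 else min(1, n - 1)
        n_val = min(n_val, n - n_test - 1) if n - n_test - 1 > 0 else n_val
        test.extend(idx[:n_test])
        val.extend(idx[n_test : n_test + n_val])
        train.extend(idx[n_test + n_val :])
    if not train or not val or not test:
        raise InputError("holdout split produced an empty partition")
    return sorted(train), sorted(val), sorted(test)


def check_no_leakage(data: list[TrialFeatures], train_idx, test_idx) -> None:
    tr = {(data[i].subject_id, data[i].video_id) for i in train_idx}
    te = {(data[i].subject_id, data[i].video_id) for i in test_idx}
    overlap = tr & te
    if overlap:
        raise LeakageError(f"train and test share trials: {sorted(overlap)[:5]} ...")


# ---------------------------------------------------------------------------
# training


def _batch_loss(model, params, state, batch: list[TrialFeatures]):
    """Mean per-row cross-entropy over the electrode rows of *batch* trials."""
    losses = []
    for t in batch:
        probs = model.forward(t.spectrograms, t.gsr, params, state, mode="infer")
        y = np.array(t.label.onehot, dtype=float)
        losses.append(np.mean([cross_entropy(y, row) for row in probs]))
    return float(np.mean(losses))


def train(
    data: list[TrialFeatures],
    train_idx,
    val_idx,
    mcfg: FusionModelConfig,
    tcfg: TrainingConfig,
):
    """SGD with validation-based early stopping.

    Returns (params, state, report) where params/state are the snapshot at
    the minimum recorded validation loss and report carries the loss curves.
    """
    if not train_idx or not val_idx:
        raise InputError("train and validation sets must be non-empty")
    check_no_leakage(data, train_idx, val_idx)
    model = FusionCNN(mcfg)
    rng = np.random.default_rng(tcfg.seed)
    params, state = model.init_params(rng)

    order = np.array(train_idx)
    rng.shuffle(order)
    pos = 0

    best = (np.inf, copy.deepcopy(params), copy.deepcopy(state), 0)
    curve: list[tuple[int, float, float]] = []
    recent_train: list[float] = []
    stopped_at = tcfg.max_iterations

    for it in range(1, tcfg.max_iterations + 1):
        batch = []
        for _ in range(tcfg.batch_trials):
            if pos >= order.size:
                rng.shuffle(order)
                pos = 0
            batch.append(data[order[pos]])
            pos += 1
        x = np.concatenate([t.spectrograms for t in batch])
        g = np.concatenate(
            [np.broadcast_to(t.gsr, (t.spectrograms.shape[0], t.gsr.size)) for t in batch]
        )
        y = np.concatenate(
            [
                np.broadcast_to(
                    np.array(t.label.onehot, dtype=float),
                    (t.spectrograms.shape[0], len(t.label.onehot)),
                )
                for t in batch
            ]
        )
        loss, grads = model.loss_and_grads(x, g, y, params, state)
        if not np.isfinite(loss):
            raise DivergenceError(f"training loss became non-finite at iteration {it}")
        params = sgd_step(params, grads, tcfg.learning_rate)
        recent_train.append(loss)

        if it % tcfg.eval_interval == 0 or it == tcfg.max_iterations:
            val_loss = _batch_loss(model, params, state, [data[i] for i in val_idx])
            if not np.isfinite(val_loss):
                raise DivergenceError(f"validation loss became non-finite at iteration {it}")
            curve.append((it, float(np.mean(recent_train)), val_loss))
            recent_train = []
            if val_loss < best[0]:
                best = (val_loss, copy.deepcopy(params), copy.deepcopy(state), it)
            if it - best[3] >= tcfg.early_stop_patience:
                stopped_at = it
                break
    else:
        stopped_at = tcfg.max_iterations

    report = EvalReport(
        scheme=data[train_idx[0]].label.scheme,
        mode="train",
        accuracy=float("nan"),
        n_test=0,
        loss_curve=curve,
        stopped_at=stopped_at,
        best_iteration=best[3],
    )
    return best[1], best[2], report


# ---------------------------------------------------------------------------
# evaluation


def evaluate_trials(
    params, state, data: list[TrialFeatures], test_idx, mcfg: FusionModelConfig
):
    """Trial- and electrode-level accuracy on the given test trials."""
    if not test_idx:
        raise InputError("empty test set")
    model = FusionCNN(mcfg)
    correct = 0
    elec_correct = 0
    elec_total = 0
    for i in test_idx:
        t = data[i]
        probs = model.forward(t.spectrograms, t.gsr, params, state, mode="infer")
        pred = aggregate_trial_prediction(probs, n_rows=probs.shape[0])
        truth = t.label.class_index
        correct += int(pred == truth)
        elec_pred = np.argmax(probs, axis=1)
        elec_correct += int((elec_pred == truth).sum())
        elec_total += probs.shape[0]
    return correct / len(test_idx), elec_correct / elec_total


def evaluate_holdout(
    data: list[TrialFeatures],
    mcfg: FusionModelConfig,
    tcfg: TrainingConfig,
    split: SplitSpec = SplitSpec(mode="holdout"),
) -> tuple[dict, EvalReport]:
    """Stratified hold-out: train with early stopping, report test accuracy."""
    rng = np.random.default_rng(tcfg.seed)
    train_idx, val_idx, test_idx = make_holdout_split(data, split.ratios, rng)
    check_no_leakage(data, train_idx + val_idx, test_idx)
    params, state, rep = train(data, train_idx, val_idx, mcfg, tcfg)
    acc, eacc = evaluate_trials(params, state, data, test_idx, mcfg)
    report = EvalReport(
        scheme=data[0].label.scheme,
        mode="holdout",
        accuracy=acc,
        n_test=len(test_idx),
        electrode_accuracy=eacc,
        loss_curve=rep.loss_curve,
        stopped_at=rep.stopped_at,
        best_iteration=rep.best_iteration,
    )
    artifacts = {
        "params": params,
        "state": state,
        "split": {"train": train_idx, "val": val_idx, "test": test_idx},
    }
    return artifacts, report


def evaluate_loocv(
    data: list[TrialFeatures],
    mcfg: FusionModelConfig,
    tcfg: TrainingConfig,
    split: SplitSpec = SplitSpec(mode="loocv_video"),
) -> EvalReport:
    """Leave-one-video-out: one fold per stimulus, pooled across subjects.

    Within each fold a stratified slice of the training videos' trials serves
    as the validation set for early stopping.  With ``split.per_subject`` the
    folds are (video, subject) pairs instead.
    """
    rng = np.random.default_rng(tcfg.seed)
    if split.per_subject:
        folds = sorted({(t.video_id, t.subject_id) for t in data})
        in_fold = lambda t, f: (t.video_id, t.subject_id) == f  # noqa: E731
    else:
        folds = sorted({t.video_id for t in data})
        in_fold = lambda t, f: t.video_id == f  # noqa: E731
    accs: list[float] = []
    n_test_total = 0
    for f in folds:
        test_idx = [i for i, t in enumerate(data) if in_fold(t, f)]
        rest = [i for i, t in enumerate(data) if not in_fold(t, f)]
        sub_rng = np.random.default_rng(rng.integers(2**31))
        tr, va, spare = make_holdout_split([data[i] for i in rest], (9, 1, 1), sub_rng)
        # the sub-split's "test" share is unused here; fold it back into training
        train_idx = [rest[i] for i in tr] + [rest[i] for i in spare]
        val_idx = [rest[i] for i in va]
        check_no_leakage(data, train_idx + val_idx, test_idx)
        params, state, _rep = train(data, train_idx, val_idx, mcfg, tcfg)
        acc, _ = evaluate_trials(params, state, data, test_idx, mcfg)
        accs.append(acc)
        n_test_total += len(test_idx)
    return EvalReport(
        scheme=data[0].label.scheme,
        mode="loocv_video",
        accuracy=float(np.mean(accs)),
        n_test=n_test_total,
        fold_accuracies=accs,
    )
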