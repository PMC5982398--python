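"""The fusion convolutional network for EEG spectrograms + GSR features.

Architecture (reference configuration): four convolution layers with non-square
3 x 2 filters (3 along frequency, 2 along time), stride 1 along frequency and
2 along time, no padding, batch normalization + ReLU after every convolution
except the last, a 2 x 2 max pool, flattening, concatenation of the trial's
thresholded GSR STZCR feature vector, then seven fully connected ReLU layers
ending in a softmax over 2 or 4 emotion classes.  On a 42 x 200 input the
conv stack maps frequency 42 -> 40 -> 38 -> 36 -> 34 and time
200 -> 100 -> 50 -> 25 -> 12, and the pool yields 17 x 6 per feature map.

Everything — convolution, batch normalization, pooling, dense layers, softmax
cross-entropy and all gradients — is implemented directly in numpy, so the
backward pass can be audited against finite differences.  Parameters live in
a flat ``{name: array}`` dict; batch-norm running statistics live in a
separate state dict updated only in training mode.

Reduced configurations (fewer/smaller layers) are first-class: they are used
for gradient checking and fast experiments; ``validate(strict=True)`` pins
the reference geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError, ShapeError

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ConvLayerSpec:
    n_filters: int
    filter_h: int = 3  # spans the frequency axis
    filter_w: int = 2  # spans the time axis
    stride: tuple[int, int] = (1, 2)  # (s_freq, s_time)
    batch_norm: bool = True

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        oh = (h - self.filter_h) // self.stride[0] + 1
        ow = (w - self.filter_w) // self.stride[1] + 1
        if oh < 1 or ow < 1:
            raise ConfigurationError(
                f"conv filter {self.filter_h}x{self.filter_w} stride {self.stride} "
                f"does not fit input {h}x{w}"
            )
        return oh, ow


@dataclass(frozen=True)
class FusionModelConfig:
    conv_layers: tuple[ConvLayerSpec, ...]
    fc_sizes: tuple[int, ...]  # widths of the fully connected stack; last = n_classes
    n_classes: int
    gsr_dim: int
    input_shape: tuple[int, int] = (42, 200)
    pool: tuple[int, int] = (2, 2)
    bn_eps: float = 1e-5
    bn_momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if not self.conv_layers or not self.fc_sizes:
            raise ConfigurationError("need at least one conv and one FC layer")
        if self.fc_sizes[-1] != self.n_classes:
            raise ConfigurationError(
                f"last FC width {self.fc_sizes[-1]} must equal n_classes {self.n_classes}"
            )
        self.conv_output_shape()  # raises if any layer does not fit

    def validate(self, strict: bool = False) -> None:
        """``strict`` pins the reference architecture: 4 conv + 7 FC layers,
        3x2 filters, batch norm on every conv layer except the last."""
        if not strict:
            return
        if len(self.conv_layers) != 4:
            raise ConfigurationError(f"reference architecture has 4 conv layers, got {len(self.conv_layers)}")
        if len(self.fc_sizes) != 7:
            raise ConfigurationError(f"reference architecture has 7 FC layers, got {len(self.fc_sizes)}")
        for i, spec in enumerate(self.conv_layers):
            if (spec.filter_h, spec.filter_w) != (3, 2):
                raise ConfigurationError(f"conv layer {i} filter must be 3x2")
            want_bn = i < len(self.conv_layers) - 1
            if spec.batch_norm != want_bn:
                raise ConfigurationError(
                    f"conv layer {i}: batch_norm must be {want_bn} in the reference architecture"
                )
        if self.n_classes not in (2, 4):
            raise ConfigurationError("reference architecture uses 2 or 4 classes")

    def conv_output_shape(self) -> tuple[int, int, int]:
        """(channels, freq, time) after the conv stack and the pool."""
        h, w = self.input_shape
        c = 1
        for spec in self.conv_layers:
            h, w = spec.out_shape(h, w)
            c = spec.n_filters
        ph, pw = self.pool
        h, w = h // ph, w // pw
        if h < 1 or w < 1:
            raise ConfigurationError(f"{self.pool} pool does not fit conv output")
        return c, h, w

    @property
    def flat_dim(self) -> int:
        c, h, w = self.conv_output_shape()
        return c * h * w

    @classmethod
    def reference(
        cls,
        n_classes: int,
        gsr_dim: int = 60,
        n_filters: tuple[int, ...] = (32, 64, 128, 128),
        fc_widths: tuple[int, ...] = (1024, 512, 256, 128, 64, 32),
    ) -> "FusionModelConfig":
        convs = tuple(
            ConvLayerSpec(n_filters=f, batch_norm=(i < 3)) for i, f in enumerate(n_filters)
        )
        cfg = cls(
            conv_layers=convs,
            fc_sizes=fc_widths + (n_classes,),
            n_classes=n_classes,
            gsr_dim=gsr_dim,
        )
        cfg.validate(strict=True)
        return cfg

    @classmethod
    def reduced(
        cls,
        n_classes: int,
        gsr_dim: int = 60,
        n_filters: tuple[int, ...] = (4, 8, 8, 8),
        fc_widths: tuple[int, ...] = (64, 32, 24, 16, 12, 8),
    ) -> "FusionModelConfig":
        """Same topology as the reference architecture but narrow, for fast runs."""
        convs = tuple(
            ConvLayerSpec(n_filters=f, batch_norm=(i < len(n_filters) - 1))
            for i, f in enumerate(n_filters)
        )
        return cls(
            conv_layers=convs,
            fc_sizes=fc_widths + (n_classes,),
            n_classes=n_classes,
            gsr_dim=gsr_dim,
        )


# ---------------------------------------------------------------------------
# primitive ops (functional, with explicit backward passes)


def conv2d(x: np.ndarray, weights: np.ndarray, bias: np.ndarray, stride: tuple[int, int]):
    """Valid (no-padding) cross-correlation.

    x: (B, C, H, W); weights: (F, C, fh, fw); bias: (F,).
    Returns (out, cache) with out of shape (B, F, H', W') where
    H' = floor((H - fh)/sh) + 1 and likewise for W'.
    """
    B, C, H, W = x.shape
    F, Cw, fh, fw = weights.shape
    sh, sw = stride
    if Cw != C:
        raise ShapeError(f"conv2d: input has {C} channels, weights expect {Cw}")
    if H < fh or W < fw:
        raise ShapeError(f"conv2d: input {H}x{W} smaller than filter {fh}x{fw}")
    win = np.lib.stride_tricks.sliding_window_view(x, (fh, fw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # (B, C, H', W', fh, fw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    Ho, Wo = cols.shape[1], cols.shape[2]
    cols = cols.reshape(B, Ho, Wo, C * fh * fw)
    out = cols @ weights.reshape(F, -1).T + bias
    cache = (cols, weights, x.shape, stride)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), cache


def conv2d_backward(dout: np.ndarray, cache):
    cols, weights, x_shape, (sh, sw) = cache
    F, C, fh, fw = weights.shape
    B, Ho, Wo = cols.shape[0], cols.shape[1], cols.shape[2]
    d = dout.transpose(0, 2, 3, 1)  # (B, H', W', F)
    dw = np.tensordot(d, cols, axes=([0, 1, 2], [0, 1, 2])).reshape(weights.shape)
    db = d.sum(axis=(0, 1, 2))
    dcols = (d @ weights.reshape(F, -1)).reshape(B, Ho, Wo, C, fh, fw)
    dx = np.zeros(x_shape)
    for i in range(fh):
        for j in range(fw):
            dx[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += dcols[
                :, :, :, :, i, j
            ].transpose(0, 3, 1, 2)
    return dx, dw, db


@dataclass
class BatchNormState:
    """Running statistics for one batch-norm layer (inference mode)."""

    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.9
    initialized: bool = False


def batch_norm(
    x: np.ndarray,
    state: BatchNormState,
    gamma: np.ndarray,
    beta: np.ndarray,
    mode: str = "train",
):
    """Batch normalization: x_hat = (x - mu) / sqrt(var + eps); y = gamma*x_hat + beta.

    Statistics are per feature: over the batch axis for 2-D input, over
    (batch, height, width) for 4-D feature maps.  Training mode uses batch
    statistics and updates the exponential running averages in *state*;
    inference mode uses the running averages with the learned gamma, beta.
    Returns (y, cache).
    """
    axes = (0,) if x.ndim == 2 else (0, 2, 3)
    shape = (1, -1) if x.ndim == 2 else (1, -1, 1, 1)
    if mode == "train":
        if x.shape[0] < 2:
            raise InputError("batch norm in train mode needs batch size >= 2")
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        if state.initialized:
            m = state.momentum
            state.running_mean = m * state.running_mean + (1 - m) * mu
            state.running_var = m * state.running_var + (1 - m) * var
        else:
            state.running_mean = mu.copy()
            state.running_var = var.copy()
            state.initialized = True
    elif mode == "infer":
        mu, var = state.running_mean, state.running_var
    else:
        raise ConfigurationError(f"unknown batch norm mode {mode!r}")
    inv = 1.0 / np.sqrt(var + state.eps)
    xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
    y = gamma.reshape(shape) * xhat + beta.reshape(shape)
    cache = (xhat, inv, gamma, axes, shape)
    return y, cache


def batch_norm_backward(dout: np.ndarray, cache):
    xhat, inv, gamma, axes, shape = cache
    m = np.prod([dout.shape[a] for a in axes])
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    g = gamma.reshape(shape) * inv.reshape(shape)
    dx = g * (
        dout
        - dbeta.reshape(shape) / m
        - xhat * dgamma.reshape(shape) / m
    )
    return dx, dgamma, dbeta


def relu(u: np.ndarray) -> np.ndarray:
    """ReLU(u) = max(u, 0), elementwise."""
    return np.maximum(u, 0.0)


def max_pool(x: np.ndarray, pool: tuple[int, int]):
    """Non-overlapping max pool; trailing rows/cols that do not fill a window
    are dropped."""
    ph, pw = pool
    B, C, H, W = x.shape
    Ho, Wo = H // ph, W // pw
    xc = x[:, :, : Ho * ph, : Wo * pw]
    r = xc.reshape(B, C, Ho, ph, Wo, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Ho, Wo, ph * pw
    )
    idx = np.argmax(r, axis=4)
    out = np.take_along_axis(r, idx[..., None], axis=4)[..., 0]
    cache = (idx, x.shape, pool)
    return out, cache


def max_pool_backward(dout: np.ndarray, cache):
    idx, x_shape, (ph, pw) = cache
    B, C, H, W = x_shape
    Ho, Wo = dout.shape[2], dout.shape[3]
    dr = np.zeros((B, C, Ho, Wo, ph * pw))
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=4)
    dx = np.zeros(x_shape)
    dx[:, :, : Ho * ph, : Wo * pw] = (
        dr.reshape(B, C, Ho, Wo, ph, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, Ho * ph, Wo * pw
        )
    )
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the model


class FusionCNN:
    """Functional-style model: parameters and BN state are explicit dicts."""

    def __init__(self, config: FusionModelConfig):
        config.validate(strict=False)
        self.config = config

    # -- parameter management -------------------------------------------------

    def init_params(self, rng: np.random.Generator):
        """He-initialized parameters plus fresh batch-norm state."""
        cfg = self.config
        params: dict[str, np.ndarray] = {}
        state: dict[str, BatchNormState] = {}
        c_in = 1
        for i, spec in enumerate(cfg.conv_layers):
            fan_in = c_in * spec.filter_h * spec.filter_w
            params[f"conv{i}.w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (spec.n_filters, c_in, spec.filter_h, spec.filter_w)
            )
            params[f"conv{i}.b"] = np.zeros(spec.n_filters)
            if spec.batch_norm:
                params[f"conv{i}.gamma"] = np.ones(spec.n_filters)
                params[f"conv{i}.beta"] = np.zeros(spec.n_filters)
                state[f"conv{i}"] = BatchNormState(
                    running_mean=np.zeros(spec.n_filters),
                    running_var=np.ones(spec.n_filters),
                    eps=cfg.bn_eps,
                    momentum=cfg.bn_momentum,
                )
            c_in = spec.n_filters
        d_in = cfg.flat_dim + cfg.gsr_dim
        for i, width in enumerate(cfg.fc_sizes):
            params[f"fc{i}.w"] = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, width))
            params[f"fc{i}.b"] = np.zeros(width)
            d_in = width
        return params, state

    # -- forward / backward ---------------------------------------------------

    def _prepare_inputs(self, spectrogram_batch, gsr):
        x = np.asarray(spectrogram_batch, dtype=float)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2:] != tuple(self.config.input_shape):
            raise ShapeError(
                f"input: expected spectrograms of {self.config.input_shape}, "
                f"got {x.shape[2:]}"
            )
        g = np.asarray(getattr(gsr, "values", gsr), dtype=float)
        if g.ndim == 1:
            g = np.broadcast_to(g, (x.shape[0], g.size))
        if g.shape != (x.shape[0], self.config.gsr_dim):
            raise ShapeError(
                f"fusion: expected GSR features of shape ({x.shape[0]}, "
                f"{self.config.gsr_dim}), got {g.shape}"
            )
        return x, g

    def _forward(self, x, g, params, state, mode):
        cfg = self.config
        caches = []
        h = x
        for i, spec in enumerate(cfg.conv_layers):
            h, cc = conv2d(h, params[f"conv{i}.w"], params[f"conv{i}.b"], spec.stride)
            bc = None
            if spec.batch_norm:
                h, bc = batch_norm(
                    h, state[f"conv{i}"], params[f"conv{i}.gamma"], params[f"conv{i}.beta"], mode
                )
            mask = h > 0
            h = h * mask
            caches.append((cc, bc, mask))
        h, pc = max_pool(h, cfg.pool)
        pool_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        z = np.concatenate([flat, g], axis=1)
        fc_caches = []
        for i in range(len(cfg.fc_sizes)):
            a = z @ params[f"fc{i}.w"] + params[f"fc{i}.b"]
            if i < len(cfg.fc_sizes) - 1:
                mask = a > 0
                out = a * mask
            else:
                mask = None
                out = a
            fc_caches.append((z, mask))
            z = out
        probs = softmax(z)
        return probs, (caches, pc, pool_shape, flat.shape, fc_caches)

    def forward(self, spectrogram_batch, gsr, params, state, mode: str = "infer"):
        """Class probabilities, one row per spectrogram in the batch.

        In the standard batching, one batch is the 32 electrode spectrograms
        of a single trial, each fused with that trial's GSR feature vector
        (a 1-D ``gsr`` is broadcast across the batch).
        """
        x, g = self._prepare_inputs(spectrogram_batch, gsr)
        probs, _ = self._forward(x, g, params, state, mode)
        return probs

    def loss_and_grads(self, spectrogram_batch, gsr, y_onehot, params, state):
        """Mean cross-entropy over the batch and gradients for every parameter.

        Runs in training mode (batch statistics; running averages updated).
        """
        x, g = self._prepare_inputs(spectrogram_batch, gsr)
        y = np.atleast_2d(np.asarray(y_onehot, dtype=float))
        if y.shape[0] == 1 and x.shape[0] > 1:
            y = np.broadcast_to(y, (x.shape[0], y.shape[1]))
        if y.shape != (x.shape[0], self.config.n_classes):
            raise ShapeError(f"labels: expected ({x.shape[0]}, {self.config.n_classes}), got {y.shape}")
        probs, (caches, pc, pool_shape, flat_shape, fc_caches) = self._forward(
            x, g, params, state, "train"
        )
        B = x.shape[0]
        loss = float(-(y * np.log(np.clip(probs, 1e-12, None))).sum() / B)

        grads: dict[str, np.ndarray] = {}
        dz = (probs - y) / B  # softmax + cross-entropy combined
        for i in reversed(range(len(self.config.fc_sizes))):
            z_in, mask = fc_caches[i]
            grads[f"fc{i}.w"] = z_in.T @ dz
            grads[f"fc{i}.b"] = dz.sum(axis=0)
            dz = dz @ params[f"fc{i}.w"].T
            if i > 0 and fc_caches[i - 1][1] is not None:
                dz = dz * fc_caches[i - 1][1]  # ReLU mask of the upstream layer
        dflat = dz[:, : flat_shape[1]]
        dh = max_pool_backward(dflat.reshape(pool_shape), pc)
        for i in reversed(range(len(self.config.conv_layers))):
            cc, bc, mask = caches[i]
            dh = dh * mask
            if bc is not None:
                dh, dgamma, dbeta = batch_norm_backward(dh, bc)
                grads[f"conv{i}.gamma"] = dgamma
                grads[f"conv{i}.beta"] = dbeta
            dh, dw, db = conv2d_backward(dh, cc)
            grads[f"conv{i}.w"] = dw
            grads[f"conv{i}.b"] = db
        return loss, grads


def aggregate_trial_prediction(electrode_probs: np.ndarray, n_rows: int = 32) -> int:
    """Trial-level class from per-electrode probabilities.

    Averages the 32 electrode probability rows and takes the argmax; ties
    break toward the lowest class index.
    """
    p = np.asarray(electrode_probs, dtype=float)
    if p.ndim != 2 or p.shape[0] != n_rows:
        raise InputError(f"expected {n_rows} probability rows, got shape {p.shape}")
    return int(np.argmax(p.mean(axis=0)))


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, config: FusionModelConfig, params, state, extra: dict | None = None):
    """Single-file .npz archive: config as JSON, parameters, BN state."""
    import json
    from dataclasses import asdict

    arrays = {f"p_{k}": v for k, v in params.items()}
    for name, st in state.items():
        arrays[f"s_{name}.mean"] = st.running_mean
        arrays[f"s_{name}.var"] = st.running_var
        arrays[f"s_{name}.init"] = np.array(int(st.initialized))
    cfg_d = asdict(config)
    meta = {"schema_version": 1, "config": cfg_d}
    if extra:
        meta.update(extra)
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns (config, params, state, meta)."""
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        cfg_d = meta["config"]
        cfg = FusionModelConfig(
            conv_layers=tuple(ConvLayerSpec(**{**c, "stride": tuple(c["stride"])}) for c in cfg_d["conv_layers"]),
            fc_sizes=tuple(cfg_d["fc_sizes"]),
            n_classes=cfg_d["n_classes"],
            gsr_dim=cfg_d["gsr_dim"],
            input_shape=tuple(cfg_d["input_shape"]),
            pool=tuple(cfg_d["pool"]),
            bn_eps=cfg_d["bn_eps"],
            bn_momentum=cfg_d["bn_momentum"],
        )
        params = {k[2:]: z[k] for k in z.files if k.startswith("p_")}
        state: dict[str, BatchNormState] = {}
        for k in z.files:
            if k.startswith("s_") and k.endswith(".mean"):
                name = k[2:-5]
                state[name] = BatchNormState(
                    running_mean=z[f"s_{name}.mean"],
                    running_var=z[f"s_{name}.var"],
                    eps=cfg.bn_eps,
                    momentum=cfg.bn_momentum,
                    initialized=bool(int(z[f"s_{name}.init"])),
                )
    return cfg, params, state, meta
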