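"""Windowed neural network mapping sensor windows to source amplitudes.

The model takes an S x W window of multichannel sensor data (W odd) and
predicts the D-vector of dipole amplitudes at the window's center sample.
Architecture:

* a temporal block of 1-D convolutions whose weights are *shared across
  sensors* (each sensor is an independent instance of the same temporal
  feature extractor), with batch normalization between consecutive conv
  layers and a ReLU after each.  The kernel schedule exactly consumes the
  temporal axis, so the block ends with S rows of ``conv_feature_schedule[-1]``
  features and temporal extent 1;
* a spatial block: the S x F feature map is flattened and passed through
  ``fc_layers`` fully-connected layers of ``fc_width`` units with ReLU,
  followed by a final linear layer of D outputs.

Training is plain minibatch Adam on mean squared error.  Everything —
convolution, batch norm, dense layers, backpropagation, the optimizer — is
implemented here on NumPy arrays (float32), with im2col/GEMM convolutions so
the heavy lifting stays in BLAS.  Sliding the window across a recording
reconstructs full source time courses; edge columns where the window does not
fit are zero-filled and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidConfigError, InputContractError, MegInverseError
from .signals import SensorRecording, SourceActivity

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TrainedModel",
    "Reconstruction",
    "default_kernel_schedule",
    "build_network",
    "count_parameters",
    "train_model",
    "predict_window",
    "reconstruct_timeseries",
    "save_model",
    "load_model",
]

_DTYPE = np.float32
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def default_kernel_schedule(window_length: int, n_conv_layers: int) -> tuple[int, ...]:
    """Valid-mode kernel sizes that consume ``window_length`` down to 1.

    The first layers use small odd kernels (5, 5, 3, ...) and the last layer
    collapses whatever temporal extent remains with a full-width kernel.
    """
    kernels = []
    extent = window_length
    base = [5, 5] + [3] * max(0, n_conv_layers - 3)
    for i in range(n_conv_layers - 1):
        k = base[i]
        # keep at least 1 sample of shrinkage per remaining layer
        while extent - k + 1 < n_conv_layers - i and k > 1:
            k -= 2
        kernels.append(k)
        extent = extent - k + 1
    kernels.append(extent)
    return tuple(kernels)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults follow the reference design: 4 conv layers growing features
    16 -> 32 -> 64 -> 128 while shrinking the 21-sample window to extent 1,
    then 6 fully-connected layers of 500 units.
    """

    n_sensors: int
    n_sources: int
    window_length: int = 21
    conv_feature_schedule: tuple[int, ...] = (16, 32, 64, 128)
    conv_kernel_schedule: tuple[int, ...] | None = None
    fc_layers: int = 6
    fc_width: int = 500

    def __post_init__(self) -> None:
        if self.window_length % 2 != 1 or self.window_length < 1:
            raise InvalidConfigError("window_length must be a positive odd integer")
        if self.n_sensors < 1 or self.n_sources < 1:
            raise InvalidConfigError("n_sensors and n_sources must be positive")
        if self.fc_layers < 1 or self.fc_width < 1:
            raise InvalidConfigError("fc_layers and fc_width must be positive")
        if not self.conv_feature_schedule:
            raise InvalidConfigError("need at least one conv layer")
        kernels = self.conv_kernel_schedule
        if kernels is None:
            kernels = default_kernel_schedule(
                self.window_length, len(self.conv_feature_schedule)
            )
            object.__setattr__(self, "conv_kernel_schedule", tuple(kernels))
        if len(kernels) != len(self.conv_feature_schedule):
            raise InvalidConfigError(
                "conv_kernel_schedule and conv_feature_schedule lengths differ"
            )
        extents = [self.window_length]
        for k in kernels:
            extents.append(extents[-1] - k + 1)
        if any(e < 1 for e in extents) or extents[-1] != 1:
            raise InvalidConfigError(
                f"kernel schedule {tuple(kernels)} does not reduce the window "
                f"to temporal extent 1 (achieved extents {extents[1:]})"
            )

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_feature_schedule)

    @property
    def flat_features(self) -> int:
        return self.n_sensors * self.conv_feature_schedule[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters: Adam on mean squared error."""

    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 10
    seed: int = 0
    validation_fraction: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise InvalidConfigError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise InvalidConfigError("batch_size must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise InvalidConfigError("validation_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _ConvShared:
    """1-D valid convolution along time, weights shared across sensors.

    Input (N, S, C_in, L) -> output (N, S, C_out, L - K + 1) via im2col and a
    single GEMM per call.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel
        self.w = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            _DTYPE
        )
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, s, c, l = x.shape
        lout = l - self.kernel + 1
        cols = sliding_window_view(x, self.kernel, axis=3)  # (N,S,C,Lout,K)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2, 4)).reshape(
            n * s * lout, c * self.kernel
        )
        out = cols @ self.w + self.b
        if training:
            self._cache = (cols, (n, s, l, lout))
        return out.reshape(n, s, lout, self.c_out).transpose(0, 1, 3, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (n, s, l, lout) = self._cache
        gm = np.ascontiguousarray(g.transpose(0, 1, 3, 2)).reshape(-1, self.c_out)
        self.gw = cols.T @ gm
        self.gb = gm.sum(axis=0)
        dcols = (gm @ self.w.T).reshape(n, s, lout, self.c_in, self.kernel)
        dcols = dcols.transpose(0, 1, 3, 2, 4)  # (N,S,C_in,Lout,K)
        dx = np.zeros((n, s, self.c_in, l), dtype=_DTYPE)
        for k in range(self.kernel):
            dx[:, :, :, k : k + lout] += dcols[..., k]
        return dx

    def params(self):
        return [("w", self), ("b", self)]


class _BatchNorm:
    """Per-feature batch normalization over (batch, sensor, time) axes."""

    def __init__(self, n_features: int):
        self.gamma = np.ones(n_features, dtype=_DTYPE)
        self.beta = np.zeros(n_features, dtype=_DTYPE)
        self.running_mean = np.zeros(n_features, dtype=np.float64)
        self.running_var = np.ones(n_features, dtype=np.float64)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (N, S, C, L); normalize each feature channel C
        if training:
            mean = x.mean(axis=(0, 1, 3))
            var = x.var(axis=(0, 1, 3))
            self.running_mean = (
                (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mean
            )
            self.running_var = (
                (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            )
        else:
            mean = self.running_mean.astype(_DTYPE)
            var = self.running_var.astype(_DTYPE)
        inv_std = (1.0 / np.sqrt(var + _BN_EPS)).astype(_DTYPE)
        xhat = (x - mean.astype(_DTYPE)[None, :, None]) * inv_std[None, :, None]
        if training:
            self._cache = (xhat, inv_std, x.shape)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        n, s, c, l = shape
        m = n * s * l
        self.ggamma = (g * xhat).sum(axis=(0, 1, 3))
        self.gbeta = g.sum(axis=(0, 1, 3))
        gx = g * self.gamma[None, :, None]
        term = (
            m * gx
            - gx.sum(axis=(0, 1, 3), keepdims=True)
            - xhat * (gx * xhat).sum(axis=(0, 1, 3), keepdims=True)
        )
        return (inv_std[None, :, None] / m) * term

    def params(self):
        return [("gamma", self), ("beta", self)]

    def start_collect(self) -> None:
        self._acc = [0.0, 0.0, 0]  # sum, sum of squares, count

    def collect(self, x: np.ndarray) -> None:
        self._acc[0] = self._acc[0] + x.sum(axis=(0, 1, 3), dtype=np.float64)
        self._acc[1] = self._acc[1] + (
            np.square(x, dtype=np.float64).sum(axis=(0, 1, 3))
        )
        n, s, _, l = x.shape
        self._acc[2] += n * s * l

    def finish_collect(self) -> None:
        total, total_sq, count = self._acc
        mean = total / count
        self.running_mean = mean
        self.running_var = np.maximum(total_sq / count - mean**2, 0.0)
        del self._acc


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = g if g.flags.writeable else g.copy()
        g *= self._mask
        return g

    def params(self):
        return []


class _Flatten:
    """(N, S, C, 1) -> (N, S*C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._shape = x.shape
        else:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu_init=True):
        scale = np.sqrt(2.0 / n_in) if relu_init else np.sqrt(1.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gw = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.w.T

    def params(self):
        return [("w", self), ("b", self)]


class SourceNet:
    """The layer stack; built by :func:`build_network`."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = 1
        n_conv = config.n_conv_layers
        for i, (c_out, k) in enumerate(
            zip(config.conv_feature_schedule, config.conv_kernel_schedule)
        ):
            layers.append(_ConvShared(c_in, c_out, k, rng))
            if i < n_conv - 1:  # batch norm between consecutive conv layers
                layers.append(_BatchNorm(c_out))
            layers.append(_ReLU())
            c_in = c_out
        layers.append(_Flatten())
        n_in = config.flat_features
        for _ in range(config.fc_layers):
            layers.append(_Dense(n_in, config.fc_width, rng))
            layers.append(_ReLU())
            n_in = config.fc_width
        layers.append(_Dense(n_in, config.n_sources, rng, relu_init=False))
        self.layers = layers

    def forward(self, windows: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, S, W) standardized windows -> (N, D) normalized amplitudes."""
        x = windows.astype(_DTYPE, copy=False)[:, :, None, :]  # channel axis
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        g = grad.astype(_DTYPE, copy=False)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self) -> list[tuple[str, object]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def calibrate_batchnorm(self, windows: np.ndarray, batch_size: int = 256) -> None:
        """Re-estimate BN running statistics from a full data pass.

        During training the running statistics trail the moving weights; after
        the last update they are replaced by the exact feature statistics of
        ``windows`` under the final weights, so inference-mode normalization
        matches what the trained weights expect.
        """
        bns = [l for l in self.layers if isinstance(l, _BatchNorm)]
        if not bns:
            return
        for bn in bns:
            bn.start_collect()
        for start in range(0, len(windows), batch_size):
            x = windows[start : start + batch_size].astype(_DTYPE, copy=False)
            x = x[:, :, None, :]
            for layer in self.layers:
                if isinstance(layer, _BatchNorm):
                    layer.collect(x)
                if isinstance(layer, _Flatten):
                    break
                x = layer.forward(x, training=True)
        for bn in bns:
            bn.finish_collect()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters and BN running stats, by stable name."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, name):
                    out[f"layer{i:02d}.{name}"] = getattr(layer, name)
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            idx, name = key.split(".")
            layer = self.layers[int(idx[5:])]
            current = getattr(layer, name)
            if current.shape != value.shape:
                raise InputContractError(
                    f"state mismatch for {key}: {current.shape} vs {value.shape}"
                )
            setattr(layer, name, value.astype(current.dtype))


def build_network(config: NetworkConfig, seed: int = 0) -> SourceNet:
    """Instantiate an untrained network for the given architecture."""
    return SourceNet(config, seed=seed)


def count_parameters(net: SourceNet) -> int:
    """Number of learnable parameters (BN running stats excluded)."""
    total = 0
    for name, layer in net.parameters():
        total += getattr(layer, name).size
    return total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, config: TrainConfig):
        self.params = params
        self.cfg = config
        self.m = [np.zeros_like(getattr(layer, name)) for name, layer in params]
        self.v = [np.zeros_like(getattr(layer, name)) for name, layer in params]
        self.t = 0

    def step(self) -> None:
        cfg = self.cfg
        self.t += 1
        b1t = 1.0 - cfg.adam_beta1**self.t
        b2t = 1.0 - cfg.adam_beta2**self.t
        lr = np.float32(cfg.learning_rate / b1t)
        inv_sqrt_b2t = np.float32(1.0 / np.sqrt(b2t))
        for i, (name, layer) in enumerate(self.params):
            g = getattr(layer, "g" + name)
            m, v = self.m[i], self.v[i]
            # in-place moment updates; the step itself reuses g as scratch
            m *= np.float32(cfg.adam_beta1)
            m += np.float32(1 - cfg.adam_beta1) * g
            v *= np.float32(cfg.adam_beta2)
            np.multiply(g, g, out=g)
            v += np.float32(1 - cfg.adam_beta2) * g
            np.sqrt(v, out=g)
            g *= inv_sqrt_b2t
            g += np.float32(cfg.adam_eps)
            np.divide(m, g, out=g)
            value = getattr(layer, name)
            value -= lr * g


@dataclass
class TrainedModel:
    """A trained network with its normalization constants and history.

    The per-sensor input mean/std and the global target scale are estimated
    on the training set and stored with the model; inference standardizes
    inputs and de-scales outputs with exactly these constants.
    """

    net: SourceNet
    config: NetworkConfig
    train_config: TrainConfig
    input_mean: np.ndarray  # (S,)
    input_std: np.ndarray  # (S,)
    target_scale: float
    history: dict = field(default_factory=dict)


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    diff = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(diff**2))


def train_model(
    net: SourceNet,
    windows: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig,
    val_windows: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Minibatch Adam / MSE training; deterministic for a given seed.

    ``windows`` is (N, S, W), ``targets`` (N, D).  If no validation arrays
    are supplied and ``validation_fraction > 0``, a tail split of the
    (shuffled) training data is held out.  Per-epoch train/validation loss is
    recorded in the returned model's history.
    """
    windows = np.asarray(windows)
    targets = np.asarray(targets)
    if windows.ndim != 3 or targets.ndim != 2 or len(windows) != len(targets):
        raise InputContractError("windows (N,S,W) and targets (N,D) must align")
    if len(windows) == 0:
        raise InputContractError("training set is empty")
    s, w = windows.shape[1:]
    if (s, w) != (net.config.n_sensors, net.config.window_length):
        raise InputContractError(
            f"window shape {(s, w)} does not match network config "
            f"{(net.config.n_sensors, net.config.window_length)}"
        )

    rng = np.random.default_rng(config.seed)

    # scalers, estimated on the training portion only
    input_mean = windows.mean(axis=(0, 2))
    input_std = windows.std(axis=(0, 2))
    input_std = np.where(input_std > 0, input_std, 1.0)
    target_scale = float(np.max(np.abs(targets)))
    if target_scale == 0:
        target_scale = 1.0

    def standardize(x):
        return ((x - input_mean[None, :, None]) / input_std[None, :, None]).astype(
            _DTYPE
        )

    if val_windows is None and config.validation_fraction > 0 and len(windows) > 1:
        n_val = max(1, int(round(config.validation_fraction * len(windows))))
        perm = rng.permutation(len(windows))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        val_windows, val_targets = windows[val_idx], targets[val_idx]
        windows, targets = windows[train_idx], targets[train_idx]

    x_train = standardize(windows)
    y_train = (targets / target_scale).astype(_DTYPE)
    have_val = val_windows is not None and len(val_windows) > 0
    if have_val:
        x_val = standardize(np.asarray(val_windows))
        y_val = (np.asarray(val_targets) / target_scale).astype(_DTYPE)

    optimizer = _Adam(net.parameters(), config)
    n = len(x_train)
    history = {"epoch": [], "train_loss": [], "val_loss": []}

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            pred = net.forward(xb, training=True)
            loss = _mse(pred, yb)
            if not np.isfinite(loss):
                raise MegInverseError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"lr={config.learning_rate}, input scale "
                    f"mean|x|={np.abs(xb).mean():.3g}, "
                    f"target scale max|y|={np.abs(yb).max():.3g}; "
                    "reduce the learning rate or check input standardization"
                )
            grad = (2.0 / pred.size) * (pred - yb)
            net.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        val_loss = (
            _mse(net.forward(x_val, training=False), y_val) if have_val else np.nan
        )
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if verbose:
            print(
                f"epoch {epoch + 1}/{config.epochs}: "
                f"train {train_loss:.3e}  val {val_loss:.3e}"
            )

    net.calibrate_batchnorm(x_train, batch_size=max(config.batch_size, 256))

    return TrainedModel(
        net=net,
        config=net.config,
        train_config=config,
        input_mean=input_mean,
        input_std=input_std,
        target_scale=target_scale,
        history=history,
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict_window(model: TrainedModel, window: np.ndarray) -> np.ndarray:
    """Predict center-sample source amplitudes for one or many windows.

    Accepts an (S, W) window or a batch (N, S, W); returns (D,) or (N, D)
    amplitudes on the physical target scale.
    """
    x = np.asarray(window, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    expected = (model.config.n_sensors, model.config.window_length)
    if x.ndim != 3 or x.shape[1:] != expected:
        raise InputContractError(
            f"window shape {x.shape[-2:]} does not match model {expected}"
        )
    xs = ((x - model.input_mean[None, :, None]) / model.input_std[None, :, None]).astype(
        _DTYPE
    )
    pred = model.net.forward(xs, training=False).astype(np.float64)
    pred *= model.target_scale
    return pred[0] if single else pred


@dataclass(frozen=True)
class Reconstruction:
    """Sliding-window source estimate with its valid (non-edge) region."""

    activity: SourceActivity
    valid_start: int
    valid_stop: int  # exclusive

    @property
    def valid(self) -> slice:
        return slice(self.valid_start, self.valid_stop)

    @property
    def edge_columns(self) -> np.ndarray:
        t = self.activity.n_samples
        flags = np.ones(t, dtype=bool)
        flags[self.valid] = False
        return np.flatnonzero(flags)


def reconstruct_timeseries(
    model: TrainedModel,
    recording: SensorRecording,
    batch_size: int = 256,
) -> Reconstruction:
    """Slide the window across a recording to estimate full source traces.

    Column c of the estimate is the model's prediction for the window
    centered at c, for every c where the window fits; the (W-1)/2 edge
    columns at each end are zero-filled and reported via the valid region.
    """
    w = model.config.window_length
    samples = recording.samples
    t = samples.shape[1]
    if t < w:
        raise InputContractError(f"recording has {t} samples, window needs {w}")
    half = (w - 1) // 2
    centers = np.arange(half, t - half)
    est = np.zeros((model.config.n_sources, t))
    all_windows = sliding_window_view(samples, w, axis=1)  # (S, T-W+1, W)
    for start in range(0, centers.size, batch_size):
        chunk = slice(start, min(start + batch_size, centers.size))
        batch = np.ascontiguousarray(all_windows[:, chunk].transpose(1, 0, 2))
        est[:, centers[chunk]] = predict_window(model, batch).T
    return Reconstruction(
        activity=SourceActivity(amplitudes=est),
        valid_start=half,
        valid_stop=t - half,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(directory: str | Path, model: TrainedModel) -> None:
    """Save a model as a directory bundle (config JSON + weight arrays)."""
    from .bundle import ArrayBundle, save_bundle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "network": asdict(model.config),
        "train": asdict(model.train_config),
        "target_scale": model.target_scale,
        "history": model.history,
    }
    (directory / "config.json").write_text(json.dumps(payload, indent=2))
    arrays = {f"state.{k}": v for k, v in model.net.state_arrays().items()}
    arrays["input_mean"] = model.input_mean
    arrays["input_std"] = model.input_std
    save_bundle(directory / "weights.h5", ArrayBundle(arrays=arrays, meta={"kind": "model"}))


def load_model(directory: str | Path) -> TrainedModel:
    """Load a model bundle; predictions round-trip bit-exactly."""
    from .bundle import load_bundle

    directory = Path(directory)
    payload = json.loads((directory / "config.json").read_text())
    net_cfg = payload["network"]
    for key in ("conv_feature_schedule", "conv_kernel_schedule"):
        if net_cfg.get(key) is not None:
            net_cfg[key] = tuple(net_cfg[key])
    config = NetworkConfig(**net_cfg)
    net = SourceNet(config, seed=0)
    bundle = load_bundle(directory / "weights.h5")
    state = {
        k[len("state."):]: v for k, v in bundle.arrays.items() if k.startswith("state.")
    }
    net.load_state_arrays(state)
    return TrainedModel(
        net=net,
        config=config,
        train_config=TrainConfig(**payload["train"]),
        input_mean=bundle.arrays["input_mean"],
        input_std=bundle.arrays["input_std"],
        target_scale=float(payload["target_scale"]),
        history=payload["history"],
    )
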