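"""The Periodic-net: direct boundary-data-to-image reconstruction.

The network maps a (2, m, m-1) amplitude/phase stack straight to a pair of
64x64 optical-property maps through four module families:

* feature module - two 3x3, 8-channel convolutions (BN + ReLU) turning raw
  boundary readings into feature maps;
* efficient modules - four parallel 1x1 -> 3x3 -> 5x5 convolution blocks
  whose outputs concatenate on the channel axis (locally sparse structure
  extraction); two such modules are joined by a concatenation skip;
* escalate module - a strided 2x2 convolution branch and a 2x2 max-pool
  branch, concatenated to 24 channels at floor(m/2) x floor(n/2) (the only
  spatial reduction before reconstruction); an upsample module (parameter
  free, nearest-neighbor) lets the efficient stage be re-applied cyclically
  with shared weights;
* encompass module - dense layers of 64, 128, 256 and 4096 units (BN +
  ReLU) that reconstruct the image, reshaped to 64x64 and split into the
  two property channels by a final convolution.

The convolution widths are not free: they are reconciled against the
published trainable/nontrainable parameter counts (1,258,308 / 1,310,532 /
1,642,308 trainable for the 16x15, 20x19, 36x35 layouts and 9,892
nontrainable for all three).  ``reconcile_widths`` performs that integer
search; the defaults below are its solution.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .nn import DTYPE

ENCOMPASS_WIDTHS = (64, 128, 256, 4096)
ESCALATE_OUT_CHANNELS = 24
OUTPUT_GRID = 64

# conv-stack budgets implied by the published totals once the encompass
# chain (1,103,168 trainable, 4,544 BN channels) and the layout-dependent
# flatten term (floor(m/2)*floor(n/2)*24*64) are subtracted
CONV_TRAINABLE_BUDGET = 69_124
CONV_BN_CHANNEL_BUDGET = 402


class ConfigurationError(ValueError):
    """Network configuration violates a fixed architectural constraint."""


class TrainingError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history


@dataclass(frozen=True)
class NetworkConfig:
    """Architectural constants of the network for one boundary layout."""

    m: int = 16
    feature_channels: int = 8
    eff1_widths: tuple[int, int, int] = (5, 5, 2)
    eff2_widths: tuple[int, int, int] = (46, 34, 2)
    escalate_conv_channels: int = 8
    encompass_widths: tuple[int, ...] = ENCOMPASS_WIDTHS
    out_kernel: int = 5
    out_batchnorm: bool = True
    n_cycles: int = 1

    @property
    def n(self) -> int:
        return self.m - 1

    @property
    def skip_channels(self) -> int:
        return 4 * (self.eff1_widths[2] + self.eff2_widths[2])

    @property
    def flatten_size(self) -> int:
        return (self.m // 2) * (self.n // 2) * ESCALATE_OUT_CHANNELS

    def validate(self) -> None:
        if self.m < 4:
            raise ConfigurationError("need at least 4 boundary positions")
        if tuple(self.encompass_widths) != ENCOMPASS_WIDTHS:
            raise ConfigurationError(
                f"encompass widths are fixed at {ENCOMPASS_WIDTHS}"
            )
        if self.skip_channels + self.escalate_conv_channels != ESCALATE_OUT_CHANNELS:
            raise ConfigurationError(
                "escalate output must be exactly "
                f"{ESCALATE_OUT_CHANNELS} channels (conv branch + skip)"
            )
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")


def reconcile_widths(
    trainable_budget: int = CONV_TRAINABLE_BUDGET,
    bn_channel_budget: int = CONV_BN_CHANNEL_BUDGET,
    feature_channels: int = 8,
) -> dict | None:
    """Integer search for convolution widths meeting the published counts.

    The feature module and the dense chain are fixed by the architecture
    description, so the remaining trainable mass and batch-norm channels
    must be absorbed exactly by the two efficient modules, the escalate
    convolution branch and the output convolution.  Among exact solutions
    the one with the widest narrowest layer is chosen, then the cheapest in
    convolution multiply-accumulates, then the lexicographically smallest.
    """
    fc = feature_channels
    t_feat = (9 * 2 * fc + fc + 2 * fc) + (9 * fc * fc + fc + 2 * fc)
    bn_feat = 2 * fc

    def eff_trainable(cin, w1, w3, w5):
        return 4 * (
            cin * w1 + w1 + 2 * w1 + 9 * w1 * w3 + w3 + 2 * w3 + 25 * w3 * w5 + w5 + 2 * w5
        )

    sols = []
    for a5, b5 in itertools.product(range(1, 5), repeat=2):
        skip = 4 * (a5 + b5)
        c_conv = ESCALATE_OUT_CHANNELS - skip
        if c_conv < 1:
            continue
        esc_t = 4 * skip * c_conv + c_conv + 2 * c_conv
        for kout, fbn in itertools.product((1, 3, 5), (0, 1)):
            fin_t = 2 * kout * kout + 2 + (4 if fbn else 0)
            bn_rem = bn_channel_budget - bn_feat - 4 * (a5 + b5) - c_conv - 2 * fbn
            if bn_rem <= 0 or bn_rem % 4:
                continue
            ssum = bn_rem // 4
            t_rem = trainable_budget - t_feat - esc_t - fin_t
            for a1 in range(1, ssum - 2):
                for a3 in range(1, ssum - a1 - 1):
                    rem2 = t_rem - eff_trainable(fc, a1, a3, a5)
                    if rem2 <= 0:
                        continue
                    for b1 in range(1, ssum - a1 - a3):
                        b3 = ssum - a1 - a3 - b1
                        if eff_trainable(4 * a5, b1, b3, b5) == rem2:
                            sols.append((a1, a3, a5, b1, b3, b5, c_conv, kout, fbn))
    if not sols:
        return None

    def cost(s):
        a1, a3, a5, b1, b3, b5, *_ = s
        return (
            fc * a1 + 9 * a1 * a3 + 25 * a3 * a5
            + 4 * a5 * b1 + 9 * b1 * b3 + 25 * b3 * b5
        )

    best = min(sols, key=lambda s: (-min(s[:6]), cost(s), s))
    a1, a3, a5, b1, b3, b5, c_conv, kout, fbn = best
    return {
        "eff1_widths": (a1, a3, a5),
        "eff2_widths": (b1, b3, b5),
        "escalate_conv_channels": c_conv,
        "out_kernel": kout,
        "out_batchnorm": bool(fbn),
    }


# ---------------------------------------------------------------------------
# the layer graph


class _ConvBNReLU:
    def __init__(self, cin, cout, k, rng, stride=1, padding="same"):
        self.conv = nn.Conv2d(cin, cout, k, rng, stride, padding)
        self.bn = nn.BatchNorm(cout, spatial=True)
        self.act = nn.ReLU()

    def layers(self):
        return [self.conv, self.bn, self.act]

    def forward(self, x, training):
        return self.act(self.bn(self.conv(x, training), training), training)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.act.backward(g)))


class _EfficientModule:
    """Four parallel 1x1 -> 3x3 -> 5x5 blocks, channel-concatenated."""

    N_BLOCKS = 4

    def __init__(self, cin, widths, rng):
        w1, w3, w5 = widths
        self.out_channels = self.N_BLOCKS * w5
        self.blocks = [
            [
                _ConvBNReLU(cin, w1, 1, rng),
                _ConvBNReLU(w1, w3, 3, rng),
                _ConvBNReLU(w3, w5, 5, rng),
            ]
            for _ in range(self.N_BLOCKS)
        ]
        self.w5 = w5

    def layers(self):
        return [l for blk in self.blocks for stage in blk for l in stage.layers()]

    def forward(self, x, training):
        outs = []
        for blk in self.blocks:
            h = x
            for stage in blk:
                h = stage.forward(h, training)
            outs.append(h)
        return np.concatenate(outs, axis=-1)

    def backward(self, g):
        gx = 0.0
        for b, blk in enumerate(self.blocks):
            gb = g[..., b * self.w5 : (b + 1) * self.w5]
            for stage in reversed(blk):
                gb = stage.backward(gb)
            gx = gx + gb
        return gx


class PeriodicNetGraph:
    """The assembled network; forward/backward over numpy arrays."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        config.validate()
        self.config = c = config
        fc = c.feature_channels
        self.feature = [_ConvBNReLU(2, fc, 3, rng), _ConvBNReLU(fc, fc, 3, rng)]
        self.eff1 = _EfficientModule(fc, c.eff1_widths, rng)
        self.eff2 = _EfficientModule(self.eff1.out_channels, c.eff2_widths, rng)
        if self.eff2.out_channels != self.eff1.out_channels and c.n_cycles > 1:
            raise ConfigurationError(
                "cyclic reuse needs matching efficient-module channel counts"
            )
        self.upsample = nn.Upsample2x()
        self.cycle_pool = nn.MaxPool2x2()
        self.escalate_conv = _ConvBNReLU(
            c.skip_channels, c.escalate_conv_channels, 2, rng, stride=2, padding="valid"
        )
        self.escalate_pool = nn.MaxPool2x2()
        self.dense: list = []
        fin = c.flatten_size
        for width in c.encompass_widths:
            self.dense.append(
                (nn.Dense(fin, width, rng), nn.BatchNorm(width, spatial=False), nn.ReLU())
            )
            fin = width
        self.out_conv = nn.Conv2d(1, 2, c.out_kernel, rng)
        self.out_bn = nn.BatchNorm(2, spatial=True) if c.out_batchnorm else None

    # -- bookkeeping

    def module_map(self) -> dict:
        mods = {
            "feature": [l for st in self.feature for l in st.layers()],
            "efficient_1": self.eff1.layers(),
            "efficient_2": self.eff2.layers(),
            "escalate": self.escalate_conv.layers(),
            "encompass": [l for d, b, r in self.dense for l in (d, b, r)],
            "output": [self.out_conv] + ([self.out_bn] if self.out_bn else []),
        }
        return mods

    def all_layers(self):
        return [l for ls in self.module_map().values() for l in ls]

    def params(self):
        return [p for l in self.all_layers() for p in l.params()]

    def buffers(self):
        return [b for l in self.all_layers() for b in l.buffers()]

    # -- computation

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        c = self.config
        if x.shape[1:] != (2, c.m, c.n):
            raise ValueError(f"expected input (N, 2, {c.m}, {c.n}), got {x.shape}")
        # channels-last internally
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).astype(DTYPE, copy=False)
        for stage in self.feature:
            h = stage.forward(h, training)
        e1 = self.eff1.forward(h, training)
        h = e1
        for _ in range(c.n_cycles - 1):  # weight-shared periodic reuse
            h = self.cycle_pool(self.eff2.forward(self.upsample(h, training), training), training)
        e2 = self.eff2.forward(h, training)
        s = np.concatenate([e1, e2], axis=-1)
        a = self.escalate_conv.forward(s, training)
        b = self.escalate_pool(s, training)
        z = np.concatenate([a, b], axis=-1)
        self._esc_channels = a.shape[-1]
        z = z.reshape(z.shape[0], -1)
        for d, bn, act in self.dense:
            z = act(bn(d(z, training), training), training)
        img = z.reshape(-1, OUTPUT_GRID, OUTPUT_GRID, 1)
        y = self.out_conv(img, training)
        if self.out_bn is not None:
            y = self.out_bn(y, training)
        return y.transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> None:
        c = self.config
        g = np.ascontiguousarray(g.transpose(0, 2, 3, 1))
        if self.out_bn is not None:
            g = self.out_bn.backward(g)
        g = self.out_conv.backward(g)
        g = g.reshape(g.shape[0], -1)
        for d, bn, act in reversed(self.dense):
            g = d.backward(bn.backward(act.backward(g)))
        m2, n2 = c.m // 2, c.n // 2
        g = g.reshape(-1, m2, n2, ESCALATE_OUT_CHANNELS)
        ca = self._esc_channels
        gs = self.escalate_conv.backward(g[..., :ca])
        gs = gs + self.escalate_pool.backward(g[..., ca:])
        ge1 = gs[..., : self.eff1.out_channels]
        ge2 = gs[..., self.eff1.out_channels :]
        gh = self.eff2.backward(ge2)
        for _ in range(c.n_cycles - 1):
            gh = self.cycle_pool.backward(gh)
            gh = self.eff2.backward(gh)
            gh = self.upsample.backward(gh)
        gh = gh + ge1
        gh = self.eff1.backward(gh)
        for stage in reversed(self.feature):
            gh = stage.backward(gh)


@dataclass
class ParamCountReport:
    """Exact parameter census of a built network."""

    trainable: int
    nontrainable: int
    per_module: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.trainable + self.nontrainable


def count_parameters(net) -> ParamCountReport:
    """Count weights/biases/BN-affine (trainable) and BN running stats."""
    graph = net.graph_ if isinstance(net, PeriodicNet) else net
    per = {}
    for name, layers in graph.module_map().items():
        t = sum(p.size for l in layers for p in l.params())
        nt = sum(b.size for l in layers for b in l.buffers())
        per[name] = {"trainable": int(t), "nontrainable": int(nt)}
    return ParamCountReport(
        trainable=sum(v["trainable"] for v in per.values()),
        nontrainable=sum(v["nontrainable"] for v in per.values()),
        per_module=per,
    )


# ---------------------------------------------------------------------------
# estimator


class PeriodicNet(RegressorMixin, BaseEstimator):
    """Scikit-learn style regressor wrapping the network and its trainer.

    Parameters mirror the published training recipe: Adam with learning
    rate 1e-3 and first-moment decay 0.5, batch size 64, decoupled weight
    decay 1e-4, 20 epochs, MSE loss on [0,1]-normalized targets.

    Examples
    --------
    >>> model = PeriodicNet(m=16, epochs=20, seed=0)
    >>> model.fit(X_train, y_train)          # doctest: +SKIP
    >>> images = model.predict(X_test)       # doctest: +SKIP
    """

    def __init__(
        self,
        m: int = 16,
        epochs: int = 20,
        lr: float = 1e-3,
        beta1: float = 0.5,
        batch_size: int = 64,
        weight_decay: float = 1e-4,
        n_cycles: int = 1,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.m = m
        self.epochs = epochs
        self.lr = lr
        self.beta1 = beta1
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.n_cycles = n_cycles
        self.seed = seed
        self.verbose = verbose

    # -- internals

    def _build(self) -> None:
        cfg = NetworkConfig(m=self.m, n_cycles=self.n_cycles)
        rng = np.random.default_rng(self.seed)
        self.config_ = cfg
        self.graph_ = PeriodicNetGraph(cfg, rng)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=DTYPE)
        n = self.m - 1
        if X.ndim == 2 and X.shape[1] == 2 * self.m * n:
            X = X.reshape(-1, 2, self.m, n)
        if X.ndim != 4 or X.shape[1:] != (2, self.m, n):
            raise ValueError(
                f"X must be (S, 2, {self.m}, {n}) or flattened; got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    @staticmethod
    def _check_y(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=DTYPE)
        if y.ndim == 2 and y.shape[1] == 2 * OUTPUT_GRID * OUTPUT_GRID:
            y = y.reshape(-1, 2, OUTPUT_GRID, OUTPUT_GRID)
        if y.ndim != 4 or y.shape[1:] != (2, OUTPUT_GRID, OUTPUT_GRID):
            raise ValueError(f"y must be (S, 2, 64, 64) or flattened; got {y.shape}")
        return y

    # -- estimator API

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on normalized boundary data X and normalized target images y."""
        self._build()
        X = self._check_X(X)
        y = self._check_y(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in sample count")
        if self.graph_.out_bn is not None:
            # start the output scale at the target statistics so the first
            # iterates already sit in the data range (output-layer base-rate
            # initialization); the affine stays fully trainable
            self.graph_.out_bn.gamma.value[:] = y.std(axis=(0, 2, 3))
            self.graph_.out_bn.beta.value[:] = y.mean(axis=(0, 2, 3))
        opt = nn.Adam(
            self.graph_.params(),
            lr=self.lr,
            beta1=self.beta1,
            weight_decay=self.weight_decay,
        )
        rng = np.random.default_rng(self.seed + 1)
        S = X.shape[0]
        history = {"train_loss": [], "val_loss": []}
        for epoch in range(self.epochs):
            order = rng.permutation(S)
            losses = []
            for start in range(0, S, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                opt.zero_grad()
                pred = self.graph_.forward(xb, training=True)
                diff = pred - yb
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"training diverged at epoch {epoch}", history
                    )
                self.graph_.backward((2.0 / diff.size) * diff.astype(DTYPE))
                opt.step()
                losses.append(loss)
            history["train_loss"].append(float(np.mean(losses)))
            if X_val is not None and y_val is not None:
                pv = self._forward_eval(self._check_X(X_val))
                history["val_loss"].append(
                    float(np.mean((pv - self._check_y(y_val)) ** 2))
                )
            if self.verbose:
                msg = f"epoch {epoch + 1}/{self.epochs} train {history['train_loss'][-1]:.5f}"
                if history["val_loss"]:
                    msg += f" val {history['val_loss'][-1]:.5f}"
                print(msg)
        self.history_ = history
        self.n_iter_ = self.epochs
        return self

    def _forward_eval(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [
            self.graph_.forward(X[i : i + batch], training=False)
            for i in range(0, X.shape[0], batch)
        ]
        return np.concatenate(outs, axis=0)

    def predict(self, X) -> np.ndarray:
        """Normalized (S, 2, 64, 64) property-image predictions."""
        if not hasattr(self, "graph_"):
            raise RuntimeError("estimator is not fitted")
        return self._forward_eval(self._check_X(X))

    # -- persistence

    def save(self, path) -> None:
        """Single-file checkpoint: config JSON + weights + BN buffers."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.graph_.params())}
        arrays.update({f"b{i}": b for i, b in enumerate(self.graph_.buffers())})
        meta = {"config": asdict(self.config_), "params": self.get_params()}
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "PeriodicNet":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(**meta["params"])
        model._build()
        for i, p in enumerate(model.graph_.params()):
            p.value = data[f"p{i}"].astype(DTYPE)
        for i, b in enumerate(model.graph_.buffers()):
            b[...] = data[f"b{i}"]
        model.history_ = {"train_loss": [], "val_loss": []}
        return model
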