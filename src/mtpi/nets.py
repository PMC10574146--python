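"""Toy encoder-decoder segmentation networks with enumerable transfer points.

The networks are small pure-numpy CNNs (hand-written forward/backward):
a 3x3-conv stem, ``depth`` encoder stages (2x max-pool + 3x3 conv), a
mirrored decoder (2x nearest upsample + 3x3 conv) and a 1x1 classification
head. Every ReLU is an *activation layer* and defines one transfer point
(TP), counted 1..T from the input; freezing at TP x pins every convolution
up to and including the one feeding activation x. TP 0 freezes nothing and
TP -1 freezes everything except the head. The optional residual flag adds a
skip-connected same-channel convolution per stage.

Training minimises class-weighted softmax cross-entropy with plain
momentum SGD, honours freeze flags bit-exactly (frozen parameters are never
touched by an update), and is fully reproducible from the config seed.
Images enter as uint8 RGB and are standardised to [-0.5, 0.5] internally.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import confusion_matrix, weighted_metrics

logger = logging.getLogger(__name__)

N_CLASSES = 4
MIN_INPUT_SIZE = 64  # relaxed from the 224-px contract for desk-scale nets


@dataclass(frozen=True)
class NetSpec:
    """Architecture of a toy net.

    ``decoder_channels`` fixes the output width of each decoder convolution;
    ``None`` mirrors the encoder widths in reverse (a compressing decoder).
    """

    depth: int = 2
    base_channels: int = 8
    residual: bool = False
    decoder_channels: tuple | None = None
    n_classes: int = N_CLASSES
    input_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size < MIN_INPUT_SIZE:
            raise ValueError(f"input_size {self.input_size} below minimum {MIN_INPUT_SIZE}")
        if self.input_size % (2 ** self.depth):
            raise ValueError("input_size must be divisible by 2**depth")
        if self.decoder_channels is not None and len(self.decoder_channels) != self.depth:
            raise ValueError("decoder_channels must list one width per decoder stage")

    def as_dict(self) -> dict:
        return {
            "depth": self.depth, "base_channels": self.base_channels,
            "residual": self.residual,
            "decoder_channels": list(self.decoder_channels) if self.decoder_channels else None,
            "n_classes": self.n_classes,
            "input_size": self.input_size, "seed": self.seed,
        }


# ------------------------------------------------------------------- layers

class _Conv:
    """3x3 (or 1x1) same-padding convolution, channels-last, stride 1."""

    def __init__(self, rng, in_ch, out_ch, k=3, act_index=None, name=""):
        # He initialisation
        std = np.sqrt(2.0 / (k * k * in_ch))
        self.w = (rng.standard_normal((k, k, in_ch, out_ch)) * std).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.act_index = act_index  # TP segment this conv belongs to; None = head
        self.trainable = True
        self.name = name
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, train=False):
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        n, hp, wp, cin = xp.shape
        h, w = hp - 2 * p, wp - 2 * p
        if k == 1:
            out = xp @ self.w.reshape(cin, -1)
        else:
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            # win: (n, h, w, cin, k, k) -> (n*h*w, k*k*cin)
            cols = np.ascontiguousarray(np.moveaxis(win, 3, 5)).reshape(n * h * w, k * k * cin)
            out = (cols @ self.w.reshape(-1, self.w.shape[-1])).reshape(n, h, w, -1)
        out += self.b
        if train:
            self._cache = xp
        return out

    def backward(self, dout):
        xp = self._cache
        k, p = self.k, self.k // 2
        n, hp, wp, cin = xp.shape
        h, w = hp - 2 * p, wp - 2 * p
        cout = self.w.shape[-1]
        self.dw = np.zeros_like(self.w)
        self.db = dout.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        dflat = dout.reshape(n * h * w, cout)
        for ky in range(k):
            for kx in range(k):
                xs = xp[:, ky:ky + h, kx:kx + w, :].reshape(n * h * w, cin)
                self.dw[ky, kx] = xs.T @ dflat
                dxp[:, ky:ky + h, kx:kx + w, :] += (dflat @ self.w[ky, kx].T).reshape(n, h, w, cin)
        self._cache = None
        return dxp[:, p:hp - p, p:wp - p, :] if p else dxp

    def params(self):
        return {"w": self.w, "b": self.b}


class _ReLU:
    n_params = 0
    trainable = False

    def __init__(self, act_index, name=""):
        self.act_index = act_index
        self.name = name
        self._mask = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dout = dout * self._mask
        self._mask = None
        return dout


class _MaxPool2:
    n_params = 0
    trainable = False
    act_index = None

    def __init__(self, name=""):
        self.name = name
        self._cache = None

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, shape = self._cache
        n, h, w, c = shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._cache = None
        return dx.reshape(n, h, w, c)


class _Upsample2:
    n_params = 0
    trainable = False
    act_index = None

    def __init__(self, name=""):
        self.name = name

    def forward(self, x, train=False):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class _ResAdd:
    """Identity skip over the preceding same-channel conv (residual stages)."""

    n_params = 0
    trainable = False
    act_index = None

    def __init__(self, name=""):
        self.name = name
        self._skip = None

    def forward(self, x, train=False):  # pragma: no cover - driven via TrainedNet
        raise NotImplementedError


@dataclass
class TransferPoint:
    index: int          # 1-based TP index
    layer_name: str
    cum_frozen_params: int


@dataclass
class TransferPointCatalog:
    points: list

    def __len__(self):
        return len(self.points)

    @property
    def T(self) -> int:
        return len(self.points)


@dataclass
class LayerSizeTable:
    """LSx bookkeeping: trainable parameters remaining when TPs 1..x are frozen."""

    ls0: int                 # total trainable parameters
    ls_by_tp: dict           # x -> LSx for x = 1..T
    ls_head: int             # LS(-1): classification-head parameters

    def ls(self, x: int) -> int:
        if x == 0:
            return self.ls0
        if x == -1:
            return self.ls_head
        return self.ls_by_tp[x]


class TrainedNet:
    """A built (possibly trained) toy segmentation net."""

    def __init__(self, spec: NetSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        layers = []
        act = 0
        ch = spec.base_channels
        cap = 4 * spec.base_channels
        act += 1
        layers.append(_Conv(rng, 3, ch, 3, act_index=act, name=f"enc0.conv"))
        layers.append(_ReLU(act, name=f"enc0.relu"))
        enc_ch = [ch]
        for i in range(spec.depth):
            nxt = min(ch * 2, cap)
            layers.append(_MaxPool2(name=f"enc{i + 1}.pool"))
            act += 1
            layers.append(_Conv(rng, ch, nxt, 3, act_index=act, name=f"enc{i + 1}.conv"))
            layers.append(_ReLU(act, name=f"enc{i + 1}.relu"))
            if spec.residual:
                act += 1
                layers.append(_Conv(rng, nxt, nxt, 3, act_index=act, name=f"enc{i + 1}.resconv"))
                layers.append(_ResAdd(name=f"enc{i + 1}.resadd"))
                layers.append(_ReLU(act, name=f"enc{i + 1}.resrelu"))
            ch = nxt
            enc_ch.append(ch)
        for i in range(spec.depth):
            if spec.decoder_channels is not None:
                nxt = spec.decoder_channels[i]
            else:
                nxt = enc_ch[spec.depth - 1 - i]
            layers.append(_Upsample2(name=f"dec{i}.up"))
            act += 1
            layers.append(_Conv(rng, ch, nxt, 3, act_index=act, name=f"dec{i}.conv"))
            layers.append(_ReLU(act, name=f"dec{i}.relu"))
            ch = nxt
        self.head = _Conv(rng, ch, spec.n_classes, 1, act_index=None, name="head")
        self.layers = layers
        self.n_activations = act

    # ---------------------------------------------------------- forward pass

    def forward(self, x, train=False, capture_tp=None):
        """Logits for a standardised batch; optionally capture one TP's activations."""
        captured = None
        skip = None
        for layer in self.layers:
            if isinstance(layer, _ResAdd):
                x = x + skip
                continue
            if isinstance(layer, _Conv) and layer.name.endswith("resconv"):
                skip = x
            x = layer.forward(x, train=train)
            if capture_tp is not None and isinstance(layer, _ReLU) and layer.act_index == capture_tp:
                captured = x
        logits = self.head.forward(x, train=train)
        if capture_tp is not None:
            return logits, captured
        return logits

    def backward(self, dlogits):
        dx = self.head.backward(dlogits)
        dskip = None
        for layer in reversed(self.layers):
            if isinstance(layer, _ResAdd):
                dskip = dx
                continue
            dx = layer.backward(dx)
            if isinstance(layer, _Conv) and layer.name.endswith("resconv") and dskip is not None:
                dx = dx + dskip
                dskip = None
        return dx

    # -------------------------------------------------------------- plumbing

    def conv_layers(self):
        return [l for l in self.layers if isinstance(l, _Conv)] + [self.head]

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([p.ravel() for l in self.conv_layers() for p in (l.w, l.b)])

    def trainable_count(self) -> int:
        return sum(l.n_params for l in self.conv_layers() if l.trainable)

    def total_count(self) -> int:
        return sum(l.n_params for l in self.conv_layers())


def build_net(spec: NetSpec) -> TrainedNet:
    """Deterministically initialise a toy net from its spec."""
    return TrainedNet(spec)


def enumerate_tps(net: TrainedNet) -> TransferPointCatalog:
    """One catalog entry per activation layer, in forward order.

    TPs 0 (freeze nothing) and -1 (freeze all but the head) are virtual and
    handled by :func:`freeze` / :class:`LayerSizeTable` directly.
    """
    points = []
    cum = 0
    for layer in net.layers:
        if isinstance(layer, _Conv):
            cum += layer.n_params
        elif isinstance(layer, _ReLU):
            points.append(TransferPoint(layer.act_index, layer.name, cum))
    # collapse duplicate act indices (residual stages share one TP per conv)
    seen = {}
    for p in points:
        seen[p.index] = p
    ordered = [seen[i] for i in sorted(seen)]
    return TransferPointCatalog(ordered)


def layer_sizes(net: TrainedNet, catalog: TransferPointCatalog) -> LayerSizeTable:
    total = net.total_count()
    ls_by_tp = {p.index: total - p.cum_frozen_params for p in catalog.points}
    return LayerSizeTable(ls0=total, ls_by_tp=ls_by_tp, ls_head=net.head.n_params)


def freeze(net: TrainedNet, x: int) -> TrainedNet:
    """Return a copy of the net with TPs 1..x frozen (x=0 none, x=-1 all but head)."""
    T = net.n_activations
    if x != -1 and not (0 <= x <= T):
        raise ValueError(f"transfer point {x} outside {{-1, 0, 1..{T}}}")
    out = copy.deepcopy(net)
    for layer in out.conv_layers():
        if layer is out.head:
            layer.trainable = True
        elif x == -1:
            layer.trainable = False
        else:
            layer.trainable = layer.act_index is not None and layer.act_index > x
    return out


def class_weights(train_labels) -> np.ndarray:
    """Inverse-frequency class weights, normalised so they sum to C.

    ``train_labels`` is an iterable of label rasters (values 1..4); every
    class must be present somewhere in the training set.
    """
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    for lab in train_labels:
        counts += np.bincount(np.asarray(lab).ravel().astype(np.int64) - 1, minlength=N_CLASSES)
    if (counts == 0).any():
        from .scene_sim import CLASS_NAMES

        missing = [CLASS_NAMES[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"classes absent from the training labels: {missing}")
    w = 1.0 / counts
    return (w * N_CLASSES / w.sum()).astype(np.float64)


# ------------------------------------------------------------------ training

@dataclass(frozen=True)
class TrainConfig:
    max_iterations: int = 600
    batch_size: int = 4
    learning_rate: float = 0.08
    momentum: float = 0.9
    validation_cadence: int = 100
    convergence_tol: float = 1e-3   # relative loss change between window halves
    convergence_window: int = 100
    class_weights: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("max_iterations", "batch_size", "learning_rate", "validation_cadence",
                     "convergence_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainTrace:
    losses: list = field(default_factory=list)
    val_iterations: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    val_wks: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def _standardise(images: np.ndarray) -> np.ndarray:
    return images.astype(np.float32) / 255.0 - 0.5


def _weighted_ce(logits, labels, weights):
    """Class-weighted softmax cross-entropy and its logit gradient.

    ``labels`` are 1-based uint8 maps; ``weights`` has one entry per class.
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    idx = labels.astype(np.int64) - 1
    wpix = weights[idx]
    wsum = wpix.sum()
    logp = np.take_along_axis(z - np.log(ez.sum(axis=-1, keepdims=True)), idx[..., None], -1)[..., 0]
    loss = -(wpix * logp).sum() / wsum
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
    dlogits = (wpix[..., None] * (p - onehot) / wsum).astype(np.float32)
    return float(loss), dlogits


def train(net: TrainedNet, ds, config: TrainConfig, val=None):
    """Momentum-SGD training of the class-weighted cross-entropy.

    Returns ``(trained_net, trace)``; the input net is left untouched.
    Stops when the relative change between the means of the two halves of
    the trailing loss window drops below ``convergence_tol``, or at
    ``max_iterations``. Divergence (non-finite loss) raises with the trace
    attached.
    """
    samples = ds.samples if hasattr(ds, "samples") else list(ds)
    if not samples:
        raise ValueError("empty training set")
    net = copy.deepcopy(net)
    rng = np.random.default_rng(config.seed)
    if config.class_weights is not None:
        weights = np.asarray(config.class_weights, dtype=np.float64)
    else:
        weights = class_weights([s.label for s in samples])
    images = np.stack([s.image for s in samples])
    labels = np.stack([s.label for s in samples])
    n = len(samples)
    conv_layers = [l for l in net.conv_layers() if l.trainable]
    velocity = {id(l): (np.zeros_like(l.w), np.zeros_like(l.b)) for l in conv_layers}
    trace = TrainTrace()
    order = rng.permutation(n)
    cursor = 0
    win = config.convergence_window
    for it in range(1, config.max_iterations + 1):
        if cursor + config.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        take = order[cursor:cursor + config.batch_size]
        cursor += config.batch_size
        x = _standardise(images[take])
        y = labels[take]
        logits = net.forward(x, train=True)
        loss, dlogits = _weighted_ce(logits, y, weights)
        if not np.isfinite(loss):
            err = RuntimeError(f"training diverged at iteration {it}")
            err.trace = trace
            raise err
        trace.losses.append(loss)
        net.backward(dlogits)
        for layer in conv_layers:
            vw, vb = velocity[id(layer)]
            vw *= config.momentum
            vw -= config.learning_rate * layer.dw
            vb *= config.momentum
            vb -= config.learning_rate * layer.db
            layer.w += vw
            layer.b += vb
        trace.iterations = it
        if val is not None and it % config.validation_cadence == 0:
            acc, wks = _evaluate(net, val)
            trace.val_iterations.append(it)
            trace.val_accuracy.append(acc)
            trace.val_wks.append(wks)
        if it >= 2 * win:
            recent = np.asarray(trace.losses[-win:])
            prev = np.asarray(trace.losses[-2 * win:-win])
            denom = max(abs(prev.mean()), 1e-12)
            if abs(prev.mean() - recent.mean()) / denom < config.convergence_tol:
                trace.converged = True
                break
    return net, trace


def _evaluate(net: TrainedNet, scenes) -> tuple[float, float]:
    samples = scenes.samples if hasattr(scenes, "samples") else list(scenes)
    cm = None
    for s in samples:
        m = confusion_matrix(predict(net, s.image), s.label, N_CLASSES)
        cm = m if cm is None else cm + m
    rep = weighted_metrics(cm)
    return rep.po, rep.wks


def evaluate(net: TrainedNet, scenes):
    """Accumulated MetricReport of a net over a list of scenes."""
    samples = scenes.samples if hasattr(scenes, "samples") else list(scenes)
    cm = None
    for s in samples:
        m = confusion_matrix(predict(net, s.image), s.label, N_CLASSES)
        cm = m if cm is None else cm + m
    return weighted_metrics(cm), cm


def predict(net: TrainedNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class map (1-based); ties break toward the lower class id."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got {image.shape}")
    if image.shape[0] % (2 ** net.spec.depth) or image.shape[1] % (2 ** net.spec.depth):
        raise ValueError("image edges must be divisible by 2**depth")
    logits = net.forward(_standardise(image[None]))
    return (logits[0].argmax(axis=-1) + 1).astype(np.uint8)


# --------------------------------------------------------------- checkpoints

def save_checkpoint(net: TrainedNet, path, extra: dict | None = None) -> None:
    """Single-archive checkpoint: parameter arrays + spec + metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, layer in enumerate(net.conv_layers()):
        arrays[f"w{i}"] = layer.w
        arrays[f"b{i}"] = layer.b
    meta = {"spec": net.spec.as_dict(), "extra": extra or {}}
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainedNet:
    data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path,
                   allow_pickle=False)
    meta = json.loads(str(data["_meta"]))
    spec_kwargs = dict(meta["spec"])
    if spec_kwargs.get("decoder_channels") is not None:
        spec_kwargs["decoder_channels"] = tuple(spec_kwargs["decoder_channels"])
    net = build_net(NetSpec(**spec_kwargs))
    for i, layer in enumerate(net.conv_layers()):
        layer.w = data[f"w{i}"].astype(np.float32)
        layer.b = data[f"b{i}"].astype(np.float32)
    return net
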