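"""CNN architecture builders for Perugini-grade classification.

Two compact custom families are provided:

* **linear** — one stem convolution followed by four convolution blocks of
  six 3x3 stride-1 ReLU convolutions each, with a 2x2 average pool between
  blocks, then flatten -> dropout -> softmax head.
* **residual** — the same topology plus parameter-free identity skip
  connections: within each block the post-activation output from two
  convolutions earlier is added to the pre-activation of convolutions 2, 4
  and 6 (three skips per block), with ReLU applied after the addition.
  Where the channel width doubles at block entry the skip is carried through
  a zero-padded channel projection, so the two families always have exactly
  the same number of trainable parameters.

The default filter plan (stem 16; blocks 16/32/64/128) with a four-class
head on a 128x128 single-channel input totals 1,112,644 trainable
parameters, i.e. the ~1 million budget the compact models are designed for.

Four standard backbones (VGG16, ResNet50, InceptionV3, MobileNet) can be
built with the original classifier replaced by the same flatten/dropout/
softmax head, the single-channel input replicated to three channels. With
no pretrained weight source configured they are randomly initialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import backbones
from .nn import (
    Add,
    AvgPool2D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Network,
    PadChannels,
    ReLU,
    RepeatChannels,
    Softmax,
)

CUSTOM_FAMILIES = ("linear", "residual")
PRETRAINED_FAMILIES = ("vgg16", "resnet50", "inceptionv3", "mobilenet")


@dataclass
class ModelSpec:
    """Declarative description of a network."""

    family: str = "linear"
    n_classes: int = 4
    input_shape: tuple[int, int, int] = (128, 128, 1)
    stem_filters: int = 16
    block_filters: tuple[int, ...] = (16, 32, 64, 128)
    dropout: float = 0.2
    pool_stride: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if self.stem_filters <= 0 or any(f <= 0 for f in self.block_filters):
            raise ValueError("filter plan entries must be positive")
        if len(self.block_filters) != 4:
            raise ValueError("filter plan must specify four blocks")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_classes": self.n_classes,
            "input_shape": list(self.input_shape),
            "stem_filters": self.stem_filters,
            "block_filters": list(self.block_filters),
            "dropout": self.dropout,
            "pool_stride": self.pool_stride,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["input_shape"] = tuple(d.get("input_shape", (128, 128, 1)))
        d["block_filters"] = tuple(d.get("block_filters", (16, 32, 64, 128)))
        return cls(**d)


@dataclass
class NetworkHandle:
    """A constructed network plus its spec and semantic layer registry.

    ``registry`` maps semantic names (``stem``, ``blockK_convJ``, ``poolK``,
    ``flatten``, ``dropout``, ``head``) to graph node names;
    ``activation_of`` maps each convolution's semantic name to the node that
    produces its post-activation output (used for activation maps).
    """

    net: Network
    spec: ModelSpec
    registry: dict[str, str] = field(default_factory=dict)
    activation_of: dict[str, str] = field(default_factory=dict)
    snapshots: list | None = None  # optional weight snapshots for ensembling

    @property
    def conv_layer_names(self) -> list[str]:
        return [k for k in self.registry if k == "stem" or "_conv" in k]

    def _forward_batched(self, x: np.ndarray, batch_size: int) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.net.forward(x[i : i + batch_size], training=False))
        return np.concatenate(out, axis=0)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Predicted class probabilities on (n, H, W) or (n, H, W, C) images.

        If training stored weight snapshots, probabilities are averaged over
        them (snapshot ensembling); the current weights are restored after.
        """
        x = _as_nhwc(images, self.spec.input_shape[-1])
        if not self.snapshots:
            return self._forward_batched(x, batch_size)
        current = self.net.get_weights()
        acc = None
        for snap in self.snapshots:
            self.net.set_weights(snap)
            p = self._forward_batched(x, batch_size)
            acc = p if acc is None else acc + p
        self.net.set_weights(current)
        return acc / len(self.snapshots)


def _as_nhwc(images: np.ndarray, channels: int) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[-1] != channels:
        raise ValueError(f"expected {channels}-channel input, got {x.shape}")
    return x


def _build_custom(spec: ModelSpec, residual: bool) -> NetworkHandle:
    rng = np.random.default_rng(spec.seed)
    net = Network()
    reg: dict[str, str] = {}
    act: dict[str, str] = {}
    in_ch = spec.input_shape[-1]

    reg["stem"] = net.add("stem", Conv2D(in_ch, spec.stem_filters, rng=rng), "input")
    act["stem"] = net.add("stem_relu", ReLU(), "stem")
    prev = act["stem"]
    prev_ch = spec.stem_filters

    for b, ch in enumerate(spec.block_filters, start=1):
        block_in = prev          # post-activation block input (skip source)
        block_in_ch = prev_ch
        skip_src = block_in
        if residual and ch != block_in_ch:
            skip_src = net.add(f"block{b}_proj", PadChannels(ch - block_in_ch), block_in)
        for j in range(1, 7):
            name = f"block{b}_conv{j}"
            cin = block_in_ch if j == 1 else ch
            reg[name] = net.add(name, Conv2D(cin, ch, rng=rng), prev)
            pre_act = reg[name]
            if residual and j % 2 == 0:
                # skip: output of conv j-2 (block input for j=2) added
                # pre-activation, ReLU applied to the sum
                pre_act = net.add(f"block{b}_add{j}", Add(), [reg[name], skip_src])
            act[name] = net.add(f"block{b}_relu{j}", ReLU(), pre_act)
            prev = act[name]
            if residual and j % 2 == 0:
                skip_src = prev  # post-activation output feeds the next skip
        reg[f"pool{b}"] = net.add(
            f"pool{b}", AvgPool2D(pool=2, stride=spec.pool_stride), prev
        )
        prev = reg[f"pool{b}"]
        prev_ch = ch

    reg["flatten"] = net.add("flatten", Flatten(), prev)
    reg["dropout"] = net.add(
        "dropout", Dropout(spec.dropout, seed=spec.seed), "flatten"
    )
    h, w = spec.input_shape[:2]
    for _ in spec.block_filters:
        h = (h - 2) // spec.pool_stride + 1
        w = (w - 2) // spec.pool_stride + 1
    flat = h * w * spec.block_filters[-1]
    reg["head"] = net.add(
        "head", Dense(flat, spec.n_classes, rng=rng), "dropout"
    )
    net.add("softmax", Softmax(), "head")
    return NetworkHandle(net=net, spec=spec, registry=reg, activation_of=act)


def build_linear(spec: ModelSpec) -> NetworkHandle:
    """Build the Linear model: 1 stem conv + 4 blocks of 6 convs, no skips."""
    if spec.family != "linear":
        raise ValueError(f"build_linear requires family 'linear', got {spec.family!r}")
    return _build_custom(spec, residual=False)


def build_residual(spec: ModelSpec) -> NetworkHandle:
    """Build the Residual model: Linear topology + 3 identity skips per block."""
    if spec.family != "residual":
        raise ValueError(
            f"build_residual requires family 'residual', got {spec.family!r}"
        )
    return _build_custom(spec, residual=True)


def build_pretrained(spec: ModelSpec) -> NetworkHandle:
    """Build a standard backbone with the classifier replaced by a
    flatten -> dropout -> softmax head matching the custom models.

    The single-channel input is replicated to three channels. Weights are
    randomly initialised (no pretrained weight source is bundled).
    """
    if spec.family not in PRETRAINED_FAMILIES:
        raise ValueError(f"unknown pretrained family {spec.family!r}")
    rng = np.random.default_rng(spec.seed)
    net = Network()
    reg: dict[str, str] = {}
    net.add("gray_to_rgb", RepeatChannels(3), "input")
    builder = getattr(backbones, spec.family)
    h, w = spec.input_shape[:2]
    feat_name = builder(net, "gray_to_rgb", (h, w, 3), rng)
    # probe the feature shape with a dummy forward pass
    probe = net.forward(np.zeros((1, h, w, spec.input_shape[-1]), dtype=np.float32))
    reg["flatten"] = net.add("flatten", Flatten(), feat_name)
    reg["dropout"] = net.add("dropout", Dropout(spec.dropout, seed=spec.seed), "flatten")
    flat = int(np.prod(probe.shape[1:]))
    reg["head"] = net.add("head", Dense(flat, spec.n_classes, rng=rng), "dropout")
    net.add("softmax", Softmax(), "head")
    return NetworkHandle(net=net, spec=spec, registry=reg)


def build_model(spec: ModelSpec) -> NetworkHandle:
    """Dispatch on ``spec.family``."""
    if spec.family == "linear":
        return build_linear(spec)
    if spec.family == "residual":
        return build_residual(spec)
    if spec.family in PRETRAINED_FAMILIES:
        return build_pretrained(spec)
    raise ValueError(f"unknown model family {spec.family!r}")


def scale_init(handle: NetworkHandle, images, target_std: float = 1.0,
               tol: float = 0.05, max_iter: int = 3) -> NetworkHandle:
    """Data-dependent initialisation rescaling (layer-sequential unit
    variance): each convolutional/dense layer's weights are rescaled so its
    output standard deviation on ``images`` is ~``target_std``.

    Deep plain stacks otherwise drift toward vanishing or exploding
    activation scales, which at small step budgets traps training at the
    uniform-output saddle. Rescaling is deterministic given the images and
    leaves the parameter count and architecture untouched.
    """
    from .nn.layers import Conv2D, Dense, DepthwiseConv2D

    x = _as_nhwc(images, handle.spec.input_shape[-1])
    for node in handle.net.nodes:
        layer = node.layer
        if not isinstance(layer, (Conv2D, DepthwiseConv2D, Dense)):
            continue
        for _ in range(max_iter):
            out = handle.net.forward(x, stop_at=node.name)
            s = float(out.std())
            if s == 0.0 or abs(s - target_std) < tol:
                break
            layer.W /= s / target_std
    return handle


def count_parameters(handle) -> int:
    """Exact number of trainable scalar parameters in a network."""
    net = handle.net if isinstance(handle, NetworkHandle) else handle
    return net.n_params


def save_checkpoint(handle: NetworkHandle, path) -> None:
    """Save weights (npz) with the ModelSpec embedded, self-describing."""
    import json

    arrays = {f"w{i}": p for i, (p, _) in enumerate(handle.net.parameters())}
    np.savez(path, spec=json.dumps(handle.spec.to_dict()), **arrays)


def load_checkpoint(path) -> NetworkHandle:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        spec = ModelSpec.from_dict(json.loads(str(data["spec"])))
        handle = build_model(spec)
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    handle.net.set_weights(weights)
    return handle
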