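"""Re-creations of four standard image-classification backbones.

Each builder appends its layers to an existing :class:`~scintigrade.nn.Network`
and returns the name of its feature node (the tensor the replaced
classification head consumes). Only the VGG16 parameter count is pinned to
the published figure (138,357,544 with the original 224x224/1000-class head);
the other topologies follow their original papers' layouts.

No pretrained weights are bundled: initialisation is seeded-random.
"""

from __future__ import annotations

import itertools

import numpy as np

from .nn import (
    Add,
    AvgPool2D,
    BatchNorm,
    Concat,
    Conv2D,
    Dense,
    Flatten,
    GlobalAvgPool,
    MaxPool2D,
    Network,
    ReLU,
    Softmax,
)

_counter = itertools.count()


def _uid(prefix: str) -> str:
    return f"{prefix}_{next(_counter)}"


def _conv_bn_relu(net, x, in_ch, out_ch, kernel, stride, rng, padding="same",
                  prefix="cbr"):
    c = net.add(_uid(prefix), Conv2D(in_ch, out_ch, kernel, stride, padding,
                                     bias=False, rng=rng), x)
    b = net.add(_uid(prefix + "_bn"), BatchNorm(out_ch), c)
    return net.add(_uid(prefix + "_relu"), ReLU(), b)


# ---------------------------------------------------------------- VGG16 ----

_VGG16_PLAN = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]


def vgg16(net: Network, x: str, input_shape, rng) -> str:
    """VGG16 convolutional backbone (13 conv layers, 5 max pools)."""
    in_ch = input_shape[-1]
    for width, reps in _VGG16_PLAN:
        for _ in range(reps):
            c = net.add(_uid("vgg_conv"),
                        Conv2D(in_ch, width, (3, 3), 1, "same", bias=True, rng=rng), x)
            x = net.add(_uid("vgg_relu"), ReLU(), c)
            in_ch = width
        x = net.add(_uid("vgg_pool"), MaxPool2D(2, 2), x)
    return x


def vgg16_canonical(seed: int = 0) -> Network:
    """Full VGG16 with the original 224x224x3 input and 1000-class head.

    Used to check the published trainable-parameter count (138,357,544).
    """
    rng = np.random.default_rng(seed)
    net = Network()
    feat = vgg16(net, "input", (224, 224, 3), rng)
    f = net.add(_uid("vgg_flat"), Flatten(), feat)
    d1 = net.add(_uid("vgg_fc1"), Dense(7 * 7 * 512, 4096, rng=rng), f)
    r1 = net.add(_uid("vgg_fc1_relu"), ReLU(), d1)
    d2 = net.add(_uid("vgg_fc2"), Dense(4096, 4096, rng=rng), r1)
    r2 = net.add(_uid("vgg_fc2_relu"), ReLU(), d2)
    d3 = net.add(_uid("vgg_fc3"), Dense(4096, 1000, rng=rng), r2)
    net.add(_uid("vgg_softmax"), Softmax(), d3)
    return net


# -------------------------------------------------------------- ResNet50 ----


def _bottleneck(net, x, in_ch, filters, stride, rng, project):
    f1, f2, f3 = filters
    y = _conv_bn_relu(net, x, in_ch, f1, (1, 1), stride, rng, prefix="rn")
    y = _conv_bn_relu(net, y, f1, f2, (3, 3), 1, rng, prefix="rn")
    c = net.add(_uid("rn"), Conv2D(f2, f3, (1, 1), 1, "same", bias=False, rng=rng), y)
    y = net.add(_uid("rn_bn"), BatchNorm(f3), c)
    if project:
        sc = net.add(_uid("rn_proj"),
                     Conv2D(in_ch, f3, (1, 1), stride, "same", bias=False, rng=rng), x)
        shortcut = net.add(_uid("rn_proj_bn"), BatchNorm(f3), sc)
    else:
        shortcut = x
    a = net.add(_uid("rn_add"), Add(), [y, shortcut])
    return net.add(_uid("rn_out"), ReLU(), a), f3


def resnet50(net: Network, x: str, input_shape, rng) -> str:
    """ResNet-50: 7x7 stem, four bottleneck stages of depth 3/4/6/3, GAP."""
    in_ch = input_shape[-1]
    x = _conv_bn_relu(net, x, in_ch, 64, (7, 7), 2, rng, prefix="rn_stem")
    x = net.add(_uid("rn_pool"), MaxPool2D(3, 2, padding="same"), x)
    ch = 64
    stages = [((64, 64, 256), 3, 1), ((128, 128, 512), 4, 2),
              ((256, 256, 1024), 6, 2), ((512, 512, 2048), 3, 2)]
    for filters, depth, stride in stages:
        x, ch = _bottleneck(net, x, ch, filters, stride, rng, project=True)
        for _ in range(depth - 1):
            x, ch = _bottleneck(net, x, ch, filters, 1, rng, project=False)
    return net.add(_uid("rn_gap"), GlobalAvgPool(), x)


# ------------------------------------------------------------ InceptionV3 ----


def inceptionv3(net: Network, x: str, input_shape, rng) -> str:
    """InceptionV3-style tower: factorised stem, A/B/C inception blocks."""
    in_ch = input_shape[-1]
    x = _conv_bn_relu(net, x, in_ch, 32, (3, 3), 2, rng, "valid", prefix="iv")
    x = _conv_bn_relu(net, x, 32, 32, (3, 3), 1, rng, "valid", prefix="iv")
    x = _conv_bn_relu(net, x, 32, 64, (3, 3), 1, rng, "same", prefix="iv")
    x = net.add(_uid("iv_pool"), MaxPool2D(3, 2), x)
    x = _conv_bn_relu(net, x, 64, 80, (1, 1), 1, rng, "valid", prefix="iv")
    x = _conv_bn_relu(net, x, 80, 192, (3, 3), 1, rng, "valid", prefix="iv")
    x = net.add(_uid("iv_pool"), MaxPool2D(3, 2), x)
    ch = 192
    for pool_features in (32, 64, 64):
        x, ch = _inception_a_same(net, x, ch, pool_features, rng)
    # reduction A
    r3 = _conv_bn_relu(net, x, ch, 384, (3, 3), 2, rng, "valid", prefix="ra")
    rd = _conv_bn_relu(net, x, ch, 64, (1, 1), 1, rng, prefix="ra")
    rd = _conv_bn_relu(net, rd, 64, 96, (3, 3), 1, rng, prefix="ra")
    rd = _conv_bn_relu(net, rd, 96, 96, (3, 3), 2, rng, "valid", prefix="ra")
    rp = net.add(_uid("ra_pool"), MaxPool2D(3, 2), x)
    x = net.add(_uid("ra_cat"), Concat(), [r3, rd, rp])
    ch = 384 + 96 + ch
    for c7 in (128, 160, 160, 192):
        x, ch = _inception_b(net, x, ch, c7, rng)
    # reduction B
    t = _conv_bn_relu(net, x, ch, 192, (1, 1), 1, rng, prefix="rb")
    t = _conv_bn_relu(net, t, 192, 320, (3, 3), 2, rng, "valid", prefix="rb")
    u = _conv_bn_relu(net, x, ch, 192, (1, 1), 1, rng, prefix="rb")
    u = _conv_bn_relu(net, u, 192, 192, (1, 7), 1, rng, prefix="rb")
    u = _conv_bn_relu(net, u, 192, 192, (7, 1), 1, rng, prefix="rb")
    u = _conv_bn_relu(net, u, 192, 192, (3, 3), 2, rng, "valid", prefix="rb")
    rp = net.add(_uid("rb_pool"), MaxPool2D(3, 2), x)
    x = net.add(_uid("rb_cat"), Concat(), [t, u, rp])
    ch = 320 + 192 + ch
    for _ in range(2):
        x, ch = _inception_c(net, x, ch, rng)
    return net.add(_uid("iv_gap"), GlobalAvgPool(), x)


def _same_avgpool3(net, x):
    """3x3/1 average pool with 'same' extent via explicit zero padding."""
    from .nn.layers import Layer

    class _PadHW(Layer):
        def forward(self, t, training=False):
            return np.pad(t, ((0, 0), (1, 1), (1, 1), (0, 0)))

        def backward(self, dy):
            return dy[:, 1:-1, 1:-1, :]

    p = net.add(_uid("padhw"), _PadHW(), x)
    return net.add(_uid("avg3"), AvgPool2D(3, 1), p)


def _inception_a_same(net, x, in_ch, pool_features, rng):
    b1 = _conv_bn_relu(net, x, in_ch, 64, (1, 1), 1, rng, prefix="ia")
    b5 = _conv_bn_relu(net, x, in_ch, 48, (1, 1), 1, rng, prefix="ia")
    b5 = _conv_bn_relu(net, b5, 48, 64, (5, 5), 1, rng, prefix="ia")
    b3 = _conv_bn_relu(net, x, in_ch, 64, (1, 1), 1, rng, prefix="ia")
    b3 = _conv_bn_relu(net, b3, 64, 96, (3, 3), 1, rng, prefix="ia")
    b3 = _conv_bn_relu(net, b3, 96, 96, (3, 3), 1, rng, prefix="ia")
    p = _same_avgpool3(net, x)
    p = _conv_bn_relu(net, p, in_ch, pool_features, (1, 1), 1, rng, prefix="ia")
    out = net.add(_uid("ia_cat"), Concat(), [b1, b5, b3, p])
    return out, 64 + 64 + 96 + pool_features


def _inception_b(net, x, in_ch, c7, rng):
    b1 = _conv_bn_relu(net, x, in_ch, 192, (1, 1), 1, rng, prefix="ib")
    b7 = _conv_bn_relu(net, x, in_ch, c7, (1, 1), 1, rng, prefix="ib")
    b7 = _conv_bn_relu(net, b7, c7, c7, (1, 7), 1, rng, prefix="ib")
    b7 = _conv_bn_relu(net, b7, c7, 192, (7, 1), 1, rng, prefix="ib")
    d7 = _conv_bn_relu(net, x, in_ch, c7, (1, 1), 1, rng, prefix="ib")
    d7 = _conv_bn_relu(net, d7, c7, c7, (7, 1), 1, rng, prefix="ib")
    d7 = _conv_bn_relu(net, d7, c7, c7, (1, 7), 1, rng, prefix="ib")
    d7 = _conv_bn_relu(net, d7, c7, c7, (7, 1), 1, rng, prefix="ib")
    d7 = _conv_bn_relu(net, d7, c7, 192, (1, 7), 1, rng, prefix="ib")
    p = _same_avgpool3(net, x)
    p = _conv_bn_relu(net, p, in_ch, 192, (1, 1), 1, rng, prefix="ib")
    out = net.add(_uid("ib_cat"), Concat(), [b1, b7, d7, p])
    return out, 192 * 4


def _inception_c(net, x, in_ch, rng):
    b1 = _conv_bn_relu(net, x, in_ch, 320, (1, 1), 1, rng, prefix="ic")
    b3 = _conv_bn_relu(net, x, in_ch, 384, (1, 1), 1, rng, prefix="ic")
    b3a = _conv_bn_relu(net, b3, 384, 384, (1, 3), 1, rng, prefix="ic")
    b3b = _conv_bn_relu(net, b3, 384, 384, (3, 1), 1, rng, prefix="ic")
    d3 = _conv_bn_relu(net, x, in_ch, 448, (1, 1), 1, rng, prefix="ic")
    d3 = _conv_bn_relu(net, d3, 448, 384, (3, 3), 1, rng, prefix="ic")
    d3a = _conv_bn_relu(net, d3, 384, 384, (1, 3), 1, rng, prefix="ic")
    d3b = _conv_bn_relu(net, d3, 384, 384, (3, 1), 1, rng, prefix="ic")
    p = _same_avgpool3(net, x)
    p = _conv_bn_relu(net, p, in_ch, 192, (1, 1), 1, rng, prefix="ic")
    out = net.add(_uid("ic_cat"), Concat(), [b1, b3a, b3b, d3a, d3b, p])
    return out, 320 + 384 * 4 + 192


# -------------------------------------------------------------- MobileNet ----

_MOBILENET_PLAN = [
    (64, 1), (128, 2), (128, 1), (256, 2), (256, 1), (512, 2),
    (512, 1), (512, 1), (512, 1), (512, 1), (512, 1), (1024, 2), (1024, 1),
]


def mobilenet(net: Network, x: str, input_shape, rng) -> str:
    """MobileNetV1 (width multiplier 1): depthwise-separable stacks, GAP."""
    from .nn import DepthwiseConv2D

    in_ch = input_shape[-1]
    x = _conv_bn_relu(net, x, in_ch, 32, (3, 3), 2, rng, prefix="mb_stem")
    ch = 32
    for width, stride in _MOBILENET_PLAN:
        d = net.add(_uid("mb_dw"),
                    DepthwiseConv2D(ch, (3, 3), stride, "same", rng=rng), x)
        b = net.add(_uid("mb_dw_bn"), BatchNorm(ch), d)
        x = net.add(_uid("mb_dw_relu"), ReLU(), b)
        x = _conv_bn_relu(net, x, ch, width, (1, 1), 1, rng, prefix="mb_pw")
        ch = width
    return net.add(_uid("mb_gap"), GlobalAvgPool(), x)
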