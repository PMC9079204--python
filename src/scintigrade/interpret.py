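"""Maximum-activation maps: where in the image a trained network responds.

For a given input, the map of a convolutional layer is the channel-wise
maximum of its post-ReLU feature maps at each spatial location, upsampled
bilinearly to the input resolution and min-max rescaled to [0, 1]. The four
block-entry convolutions (the first convolution of each block) are the
canonical layers to visualise; a quantitative cardiac-focus score (mean map
value inside the cardiac region over mean outside) summarises whether the
model attends to the heart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .models import CUSTOM_FAMILIES, NetworkHandle
from .preprocess import PreprocessedImage

__all__ = ["ActivationMap", "select_block_entry_layers", "max_activation_map",
           "cardiac_focus_score", "activation_montage"]


@dataclass
class ActivationMap:
    """Non-negative [0, 1] activation heatmap at input resolution."""

    values: np.ndarray
    source_layer: str
    input_id: str = ""


def select_block_entry_layers(handle: NetworkHandle) -> list[str]:
    """Semantic names of the first convolution of each block, in order."""
    if handle.spec.family not in CUSTOM_FAMILIES:
        raise ValueError(
            "block-entry layer selection is defined for the custom families "
            f"only, not {handle.spec.family!r}")
    names = [f"block{b}_conv1" for b in range(1, 5)]
    missing = [n for n in names if n not in handle.registry]
    if missing:
        raise ValueError(f"network registry lacks block entries: {missing}")
    return names


def max_activation_map(handle: NetworkHandle, layer: str, image,
                       input_id: str | None = None) -> ActivationMap:
    """Channel-wise maximum activation of ``layer`` for one (normalised)
    preprocessed image, upsampled to the input shape and min-max rescaled.

    Constant maps (e.g. a dead layer) rescale to all-zero by convention.
    """
    if layer not in handle.activation_of:
        raise ValueError(f"layer {layer!r} not in network")
    if isinstance(image, PreprocessedImage):
        input_id = input_id if input_id is not None else image.source_id
        image = image.pixels
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, :, :, None]
    node = handle.activation_of[layer]
    _, captured = handle.net.forward(x, training=False, capture=[node])
    act = captured[node][0]                      # (h, w, channels), post-ReLU
    m = act.max(axis=-1).astype(np.float64)
    m = resize(m, x.shape[1:3], order=1, anti_aliasing=False)
    lo, hi = m.min(), m.max()
    m = (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)
    return ActivationMap(values=m, source_layer=layer, input_id=input_id or "")


def cardiac_focus_score(amap: ActivationMap, cardiac_mask: np.ndarray,
                        cap: float = 100.0) -> float:
    """Mean map value inside the cardiac mask over mean outside (> 1 means
    the map concentrates on the heart). Divergent ratios are capped."""
    mask = np.asarray(cardiac_mask, dtype=bool)
    if mask.shape != amap.values.shape:
        raise ValueError("mask and map shapes differ")
    if not mask.any():
        raise ValueError("cardiac mask is empty")
    inside = float(amap.values[mask].mean())
    outside = float(amap.values[~mask].mean()) if (~mask).any() else 0.0
    if outside <= 0.0:
        return cap if inside > 0 else 0.0
    return min(inside / outside, cap)


def activation_montage(image, maps: list[ActivationMap], path,
                       title: str = "") -> None:
    """Save a figure of the input plus its activation maps side by side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(image, PreprocessedImage):
        image = image.pixels
    fig, axes = plt.subplots(1, 1 + len(maps), figsize=(3 * (1 + len(maps)), 3.2))
    axes = np.atleast_1d(axes)
    axes[0].imshow(image, cmap="gray_r")
    axes[0].set_title("input")
    for ax, m in zip(axes[1:], maps):
        ax.imshow(m.values, cmap="inferno", vmin=0, vmax=1)
        ax.set_title(m.source_layer, fontsize=9)
    for ax in axes:
        ax.axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
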