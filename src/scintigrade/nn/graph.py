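"""A small directed-acyclic network container over the NHWC layers.

Nodes are added in topological order; each names its input nodes, which is
enough to express the residual skip connections and the inception-style
branch/concat patterns. ``forward`` can capture intermediate activations by
node name (used by the activation-map visualisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Dropout, Layer

INPUT = "input"


@dataclass
class _Node:
    name: str
    layer: Layer
    inputs: list[str]


@dataclass
class Network:
    nodes: list[_Node] = field(default_factory=list)
    _by_name: dict[str, _Node] = field(default_factory=dict)

    def add(self, name: str, layer: Layer, inputs) -> str:
        if isinstance(inputs, str):
            inputs = [inputs]
        if name in self._by_name or name == INPUT:
            raise ValueError(f"duplicate node name {name!r}")
        for inp in inputs:
            if inp != INPUT and inp not in self._by_name:
                raise ValueError(f"unknown input node {inp!r} for {name!r}")
        node = _Node(name, layer, list(inputs))
        self.nodes.append(node)
        self._by_name[name] = node
        return name

    def __contains__(self, name: str) -> bool:
        return name == INPUT or name in self._by_name

    def layer(self, name: str) -> Layer:
        return self._by_name[name].layer

    @property
    def output_name(self) -> str:
        return self.nodes[-1].name

    def forward(self, x: np.ndarray, training: bool = False, capture=(),
                stop_at: str | None = None):
        """Run the network; returns output (and captured activations if asked).

        ``capture`` is an iterable of node names whose outputs are returned in
        a dict alongside the final output. ``stop_at`` ends the pass after
        the named node (its output is then the returned output).
        """
        values = {INPUT: x}
        last = INPUT
        for node in self.nodes:
            args = [values[i] for i in node.inputs]
            values[node.name] = node.layer.forward(*args, training=training)
            last = node.name
            if stop_at is not None and node.name == stop_at:
                break
        out = values[last]
        if capture:
            return out, {k: values[k] for k in capture}
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate from the output; returns gradient w.r.t. the input.

        Must follow a ``forward(..., training=True)`` call on the same batch.
        """
        acc: dict[str, np.ndarray] = {self.output_name: dout}
        for node in reversed(self.nodes):
            dy = acc.pop(node.name, None)
            if dy is None:
                continue
            dxs = node.layer.backward(dy)
            if not isinstance(dxs, tuple):
                dxs = (dxs,)
            for inp, dx in zip(node.inputs, dxs):
                if inp in acc:
                    acc[inp] = acc[inp] + dx
                else:
                    acc[inp] = dx
        return acc.get(INPUT)

    def parameters(self):
        """Yield (param, grad) pairs for all trainable parameters."""
        for node in self.nodes:
            yield from zip(node.layer.params, node.layer.grads)

    @property
    def n_params(self) -> int:
        return int(sum(l.n_params for l in (n.layer for n in self.nodes)))

    def reseed_dropout(self, seed: int) -> None:
        for node in self.nodes:
            if isinstance(node.layer, Dropout):
                node.layer.reseed(seed)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights) -> None:
        for (p, _), w in zip(self.parameters(), weights, strict=True):
            p[...] = w
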