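"""Layer graph of the spectral-spatial CNN and its closed-form audit.

The network interleaves a spatial convolutional trunk with a parameter-free
Haar wavelet pyramid of the input: levels 1-4 of the pyramid are tapped at
matched resolutions and concatenated with the convolutional features at
three fusion points.  All convolutions are 3x3 with "same" padding; spatial
halving happens only at four stride-2 convolutions.  Every convolution is
followed by batch normalization and ReLU; the classifier head is
flatten -> dense(2048) -> BN -> ReLU -> dropout, twice, then a dense layer
with one unit per class.

At the default configuration (4 classes, 512x512x3 input, width multiplier
1) the graph has 76,289,732 trainable and 13,440 non-trainable parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import AuditError, DimensionError, ShapeError

LAYER_KINDS = (
    "input",
    "wavelet",
    "conv",
    "batchnorm",
    "relu",
    "avgpool",
    "concat",
    "flatten",
    "dense",
    "dropout",
)

N_WAVELET_LEVELS = 4


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str
    hyper: dict = field(default_factory=dict)
    inputs: tuple[str, ...] = ()


@dataclass(frozen=True)
class ArchitectureGraph:
    layers: tuple[LayerSpec, ...]
    num_classes: int
    input_size: tuple[int, int, int]

    def __post_init__(self):
        seen: set[str] = set()
        for layer in self.layers:
            if layer.name in seen:
                raise ShapeError(f"duplicate layer name {layer.name!r}")
            if layer.kind not in LAYER_KINDS:
                raise AuditError(f"unknown layer kind {layer.kind!r} in {layer.name!r}")
            for inp in layer.inputs:
                if inp not in seen:
                    raise ShapeError(
                        f"layer {layer.name!r} consumes {inp!r} before it is defined"
                    )
            seen.add(layer.name)

    def __getitem__(self, name: str) -> LayerSpec:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(layer.name for layer in self.layers)

    def to_manifest(self) -> list[dict]:
        """JSON-serializable architecture description."""
        return [
            {
                "name": l.name,
                "kind": l.kind,
                "hyper": dict(l.hyper),
                "inputs": list(l.inputs),
            }
            for l in self.layers
        ]


@dataclass(frozen=True)
class ParameterAudit:
    per_layer: dict[str, tuple[int, int]]
    totals: tuple[int, int]

    @property
    def trainable(self) -> int:
        return self.totals[0]

    @property
    def non_trainable(self) -> int:
        return self.totals[1]

    def layer_total(self, name: str) -> int:
        """Trainable + non-trainable of one layer (the convention used by
        framework model summaries, which print batchnorm rows as 4*C)."""
        t, n = self.per_layer[name]
        return t + n


def _scaled(base: int, wm: float, report: list[str], name: str) -> int:
    raw = base * wm
    scaled = int(round(raw))
    if abs(raw - scaled) > 1e-9:
        report.append(f"{name}: {raw:g} rounded to {scaled}")
    return max(scaled, 1)


def build_architecture(
    num_classes: int = 4,
    input_size: tuple[int, int, int] = (512, 512, 3),
    dropout_rate: float = 0.5,
    width_multiplier: float = 1.0,
) -> ArchitectureGraph:
    """Construct the default layer graph.

    ``width_multiplier`` scales every convolution filter count and dense
    width (1 reproduces the reference architecture); non-integer scaled
    counts are rounded with a warning.
    """
    h, w, c = input_size
    if h % 16 != 0 or w % 16 != 0:
        raise DimensionError(
            f"input spatial size {h}x{w} must be divisible by 16 "
            "(four wavelet levels and four stride-2 convolutions)"
        )
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    if width_multiplier <= 0:
        raise ValueError("width_multiplier must be positive")

    rounding: list[str] = []

    def f(base):  # scaled filter/unit count
        return _scaled(base, width_multiplier, rounding, f"width {base}")

    layers: list[LayerSpec] = [LayerSpec("input", "input", {}, ())]
    for lvl in range(1, N_WAVELET_LEVELS + 1):
        name = "wavelet" if lvl == 1 else f"wavelet[{lvl - 1}]"
        layers.append(LayerSpec(name, "wavelet", {"level": lvl}, ("input",)))

    def conv(name, filters, inp, stride=1):
        layers.append(
            LayerSpec(
                name,
                "conv",
                {"filters": filters, "kernel": 3, "stride": stride, "padding": "same"},
                (inp,),
            )
        )

    def bn(name, inp):
        layers.append(LayerSpec(name, "batchnorm", {}, (inp,)))

    def relu(name, inp):
        layers.append(LayerSpec(name, "relu", {}, (inp,)))

    def cbr(conv_name, filters, inp, stride=1, bn_name=None, relu_name=None):
        """conv -> batchnorm -> relu block with the table's naming scheme."""
        suffix = conv_name.split("conv_", 1)[1]
        conv(conv_name, filters, inp, stride)
        bn_name = bn_name or f"norm_{suffix}"
        relu_name = relu_name or f"relu_{suffix}"
        bn(bn_name, conv_name)
        relu(relu_name, bn_name)
        return relu_name

    # Spatial trunk, stage 1, fed by the level-1 wavelet stack.
    cbr("conv_1", f(64), "wavelet")
    cbr("conv_1_2", f(64), "relu_1", stride=2)
    # Spectral branch a: level-2 wavelet tap.
    cbr("conv_a", f(128), "wavelet[1]")
    layers.append(LayerSpec("concate_1", "concat", {}, ("relu_1_2", "relu_a")))

    cbr("conv_2", f(128), "concate_1")
    cbr("conv_2_2", f(128), "relu_2", stride=2)
    # Spectral branch b: level-3 wavelet tap, deepened once.
    cbr("conv_b", f(64), "wavelet[2]")
    cbr("conv_b_2", f(128), "relu_b")
    layers.append(LayerSpec("concate_2", "concat", {}, ("relu_2_2", "relu_b_2")))

    cbr("conv_3", f(256), "concate_2")
    cbr("conv_3_2", f(256), "relu_3", stride=2)
    # Spectral branch c: level-4 wavelet tap, deepened twice.
    cbr("conv_c", f(256), "wavelet[3]")
    cbr("conv_c_2", f(256), "relu_c")
    cbr("conv_c_3", f(256), "relu_c_2")
    layers.append(LayerSpec("concate_3", "concat", {}, ("relu_3_2", "relu_c_3")))

    cbr("conv_4", f(256), "concate_3")
    cbr("conv_4_2", f(256), "relu_4", stride=2)
    cbr("conv_5_1", f(128), "relu_4_2")

    layers.append(
        LayerSpec(
            "pool_5_1", "avgpool", {"window": 2, "stride": 1, "padding": "same"}, ("relu_5_1",)
        )
    )
    layers.append(LayerSpec("flat_5_1", "flatten", {}, ("pool_5_1",)))

    def dense_block(idx, units, inp):
        layers.append(LayerSpec(f"fc_{idx}", "dense", {"units": units}, (inp,)))
        bn(f"norm_{idx}", f"fc_{idx}")
        relu(f"relu_{idx}", f"norm_{idx}")
        layers.append(LayerSpec(f"drop_{idx}", "dropout", {"rate": dropout_rate}, (f"relu_{idx}",)))
        return f"drop_{idx}"

    head = dense_block(5, f(2048), "flat_5_1")
    head = dense_block(6, f(2048), head)
    layers.append(LayerSpec("fc_7", "dense", {"units": num_classes}, (head,)))

    if rounding:
        warnings.warn(
            "width_multiplier produced non-integer channel counts; rounded: "
            + "; ".join(rounding),
            stacklevel=2,
        )
    return ArchitectureGraph(tuple(layers), num_classes=num_classes, input_size=(h, w, c))


def _same_pad(size: int, window: int, stride: int) -> tuple[int, int, int]:
    """Output size and (begin, end) padding for 'same' windows (extra at end)."""
    out = math.ceil(size / stride)
    total = max((out - 1) * stride + window - size, 0)
    return out, total // 2, total - total // 2


def _window_out(size: int, window: int, stride: int, padding: str) -> int:
    if padding == "same":
        return _same_pad(size, window, stride)[0]
    if size < window:
        raise DimensionError(f"window {window} larger than extent {size}")
    return (size - window) // stride + 1


def forward_shapes(graph: ArchitectureGraph) -> dict[str, tuple[int, ...]]:
    """Symbolic shape propagation over the layer graph (no batch axis)."""
    shapes: dict[str, tuple[int, ...]] = {}
    for layer in graph.layers:
        ins = [shapes[n] for n in layer.inputs]
        if layer.kind == "input":
            shape: tuple[int, ...] = graph.input_size
        elif layer.kind == "wavelet":
            h, w, c = ins[0]
            lvl = layer.hyper["level"]
            shape = (h >> lvl, w >> lvl, 4 * c)
        elif layer.kind == "conv":
            h, w, _ = ins[0]
            s = layer.hyper["stride"]
            k = layer.hyper["kernel"]
            shape = (
                _window_out(h, k, s, layer.hyper["padding"]),
                _window_out(w, k, s, layer.hyper["padding"]),
                layer.hyper["filters"],
            )
        elif layer.kind in ("batchnorm", "relu", "dropout"):
            shape = ins[0]
        elif layer.kind == "avgpool":
            h, w, c = ins[0]
            win, s, pad = layer.hyper["window"], layer.hyper["stride"], layer.hyper["padding"]
            shape = (_window_out(h, win, s, pad), _window_out(w, win, s, pad), c)
        elif layer.kind == "concat":
            spatial = {inp: shp[:2] for inp, shp in zip(layer.inputs, ins)}
            first = ins[0][:2]
            for inp, sp in spatial.items():
                if sp != first:
                    raise ShapeError(
                        f"concat {layer.name!r}: spatial mismatch between "
                        f"{layer.inputs[0]!r} {first} and {inp!r} {sp}"
                    )
            shape = first + (sum(shp[2] for shp in ins),)
        elif layer.kind == "flatten":
            shape = (int(np.prod(ins[0])),)
        elif layer.kind == "dense":
            shape = (layer.hyper["units"],)
        else:  # pragma: no cover - guarded by ArchitectureGraph validation
            raise AuditError(f"unknown layer kind {layer.kind!r}")
        shapes[layer.name] = shape
    return shapes


def audit_parameters(graph: ArchitectureGraph) -> ParameterAudit:
    """Closed-form per-layer parameter counts.

    conv: (k*k*C_in + 1) * C_out; dense: (N_in + 1) * N_out; batchnorm:
    2*C trainable (scale, shift) + 2*C non-trainable (moving mean, var);
    every other kind is parameter-free.
    """
    shapes = forward_shapes(graph)
    per_layer: dict[str, tuple[int, int]] = {}
    for layer in graph.layers:
        if layer.kind == "conv":
            c_in = shapes[layer.inputs[0]][2]
            k = layer.hyper["kernel"]
            t = (k * k * c_in + 1) * layer.hyper["filters"]
            per_layer[layer.name] = (t, 0)
        elif layer.kind == "dense":
            n_in = shapes[layer.inputs[0]][0]
            per_layer[layer.name] = ((n_in + 1) * layer.hyper["units"], 0)
        elif layer.kind == "batchnorm":
            c = shapes[layer.inputs[0]][-1]
            per_layer[layer.name] = (2 * c, 2 * c)
        elif layer.kind in LAYER_KINDS:
            per_layer[layer.name] = (0, 0)
        else:
            raise AuditError(f"unknown layer kind {layer.kind!r}")
    totals = (
        sum(t for t, _ in per_layer.values()),
        sum(n for _, n in per_layer.values()),
    )
    return ParameterAudit(per_layer=per_layer, totals=totals)


def audit_to_frame(graph: ArchitectureGraph):
    """Audit as a DataFrame mirroring a model-summary table."""
    import pandas as pd

    shapes = forward_shapes(graph)
    audit = audit_parameters(graph)
    rows = [
        {
            "layer": l.name,
            "kind": l.kind,
            "output_shape": str(shapes[l.name]),
            "parameters": audit.layer_total(l.name),
            "connected_to": ",".join(l.inputs),
        }
        for l in graph.layers
    ]
    return pd.DataFrame(rows)


def avg_pool(feature_map, window: int, stride: int, padding: str = "valid") -> np.ndarray:
    """Average pooling over an HxW[xC] grid.

    With ``same`` padding the mean is taken over the cells that fall inside
    the input (padding cells are excluded from the count).
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    arr = np.asarray(feature_map, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    h, w, c = arr.shape
    out, counts = _pool_sum(arr[None], window, stride, padding)
    result = out[0] / counts[..., None]
    return result[:, :, 0] if squeeze else result


def _pool_sum(x: np.ndarray, window: int, stride: int, padding: str):
    """Windowed sums of a (N,H,W,C) array plus per-position valid-cell counts."""
    n, h, w, c = x.shape
    if padding == "same":
        oh, pt, pb = _same_pad(h, window, stride)
        ow, pl, pr = _same_pad(w, window, stride)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        valid = np.pad(np.ones((h, w)), ((pt, pb), (pl, pr)))
    else:
        if h < window or w < window:
            raise DimensionError(
                f"window {window} larger than input extent {(h, w)} under valid padding"
            )
        oh = (h - window) // stride + 1
        ow = (w - window) // stride + 1
        xp, valid = x, np.ones((h, w))
    out = np.zeros((n, oh, ow, c), dtype=x.dtype)
    counts = np.zeros((oh, ow))
    for di in range(window):
        for dj in range(window):
            out += xp[:, di : di + oh * stride : stride, dj : dj + ow * stride : stride, :]
            counts += valid[di : di + oh * stride : stride, dj : dj + ow * stride : stride]
    return out, counts
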