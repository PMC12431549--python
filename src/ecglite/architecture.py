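"""Declarative 1D-CNN architecture specs with analytic accounting.

Two reference networks are defined, both taking 1000-sample single-lead
windows:

* ``mitbih_multiclass`` — 5-way beat classifier (N/L/R/A/V).  Four
  same-padded conv layers (filters 16/32/64/128, kernels 11/13/15/17), each
  followed by a max-pool of size 2 — the first with stride 1, the rest with
  stride 2 — giving the length chain 1000 -> 999 -> 499 -> 249 -> 124 and a
  15,872-element flatten; head: dropout, dense 35 (ReLU), dense 5, softmax.
* ``simband_binary`` — Normal-vs-Arrhythmia classifier with the same conv
  stack but pool size 3, stride 2 throughout (1000 -> 499 -> 249 -> 124 ->
  61; flatten 7,808); head: dropout, dense 128 (ReLU), dense 2, softmax.

Shape propagation, trainable-parameter counts and FLOP estimates are
computed analytically from the spec; the training backend realizes the same
spec, and the two are cross-checked in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_KINDS = ("conv1d", "maxpool1d", "flatten", "dropout", "dense", "softmax")
REFERENCE_NAMES = ("mitbih_multiclass", "simband_binary")


@dataclass(frozen=True)
class LayerDescriptor:
    """One layer of a sequential 1D CNN.

    Only the fields relevant to ``kind`` are consulted: conv1d uses
    (filters, kernel_size, padding, activation); maxpool1d uses
    (pool_size, stride); dropout uses rate; dense uses (units, activation).
    """

    kind: str
    filters: int = 0
    kernel_size: int = 0
    padding: str = "same"
    activation: str = "relu"
    pool_size: int = 0
    stride: int = 0
    rate: float = 0.0
    units: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv1d":
            if self.filters <= 0 or self.kernel_size <= 0:
                raise ValueError("conv1d needs positive filters and kernel_size")
            if self.padding not in ("same", "valid"):
                raise ValueError(f"unknown padding {self.padding!r}")
            if self.activation not in ("relu", "none"):
                raise ValueError(f"unknown activation {self.activation!r}")
        elif self.kind == "maxpool1d":
            if self.pool_size <= 0 or self.stride <= 0:
                raise ValueError("maxpool1d needs positive pool_size and stride")
        elif self.kind == "dropout":
            if not 0 <= self.rate < 1:
                raise ValueError("dropout rate must be in [0, 1)")
        elif self.kind == "dense":
            if self.units <= 0:
                raise ValueError("dense needs positive units")
            if self.activation not in ("relu", "none"):
                raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer list plus input geometry and class count."""

    name: str
    input_len: int
    input_channels: int
    layers: tuple[LayerDescriptor, ...]
    n_classes: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.input_len <= 0 or self.input_channels <= 0:
            raise ValueError("input geometry must be positive")
        flattens = [ld for ld in self.layers if ld.kind == "flatten"]
        if len(flattens) > 1:
            raise ValueError("at most one flatten layer allowed")
        denses = [ld for ld in self.layers if ld.kind == "dense"]
        if denses and denses[-1].units != self.n_classes:
            raise ValueError("last dense layer must have n_classes units")
        if self.layers and self.layers[-1].kind == "softmax" and not denses:
            raise ValueError("softmax requires a preceding dense layer")


@dataclass(frozen=True)
class ShapeTrace:
    """Per-layer output geometry: (layer index, length, channels).

    For layers after the flatten, length is the vector width and channels 1.
    """

    steps: tuple[tuple[int, int, int], ...]
    flatten_size: int
    kinds: tuple[str, ...] = ()

    @property
    def pool_lengths(self) -> tuple[int, ...]:
        return tuple(
            length for (i, length, _), kind in zip(self.steps, self.kinds)
            if kind == "maxpool1d"
        )


def _conv_block(kernels, filters, pool_size, pool_strides) -> list[LayerDescriptor]:
    layers = []
    for k, f, s in zip(kernels, filters, pool_strides):
        layers.append(LayerDescriptor(kind="conv1d", filters=f, kernel_size=k,
                                      padding="same", activation="relu"))
        layers.append(LayerDescriptor(kind="maxpool1d", pool_size=pool_size, stride=s))
    return layers


def reference_spec(name: str, dropout_rate: float = 0.5) -> ModelSpec:
    """Build one of the two reference architectures by name."""
    if name == "mitbih_multiclass":
        layers = _conv_block(kernels=(11, 13, 15, 17), filters=(16, 32, 64, 128),
                             pool_size=2, pool_strides=(1, 2, 2, 2))
        layers += [
            LayerDescriptor(kind="flatten"),
            LayerDescriptor(kind="dropout", rate=dropout_rate),
            LayerDescriptor(kind="dense", units=35, activation="relu"),
            LayerDescriptor(kind="dense", units=5, activation="none"),
            LayerDescriptor(kind="softmax"),
        ]
        return ModelSpec(name=name, input_len=1000, input_channels=1,
                         layers=tuple(layers), n_classes=5)
    if name == "simband_binary":
        layers = _conv_block(kernels=(11, 13, 15, 17), filters=(16, 32, 64, 128),
                             pool_size=3, pool_strides=(2, 2, 2, 2))
        layers += [
            LayerDescriptor(kind="flatten"),
            LayerDescriptor(kind="dropout", rate=dropout_rate),
            LayerDescriptor(kind="dense", units=128, activation="relu"),
            LayerDescriptor(kind="dense", units=2, activation="none"),
            LayerDescriptor(kind="softmax"),
        ]
        return ModelSpec(name=name, input_len=1000, input_channels=1,
                         layers=tuple(layers), n_classes=2)
    raise ValueError(f"unknown reference spec {name!r}; valid names: {REFERENCE_NAMES}")


def propagate_shapes(spec: ModelSpec) -> ShapeTrace:
    """Propagate (length, channels) analytically through the layer list.

    Same-padded conv preserves length; valid max-pool gives
    floor((L - pool) / stride) + 1; flatten collapses to length x channels.
    """
    length, channels = spec.input_len, spec.input_channels
    flat: int | None = None
    steps = []
    kinds = []
    for i, ld in enumerate(spec.layers):
        if ld.kind == "conv1d":
            if ld.padding == "valid":
                length = length - ld.kernel_size + 1
            channels = ld.filters
        elif ld.kind == "maxpool1d":
            length = (length - ld.pool_size) // ld.stride + 1
        elif ld.kind == "flatten":
            flat = length * channels
            length, channels = flat, 1
        elif ld.kind == "dense":
            length, channels = ld.units, 1
        # dropout and softmax preserve shape
        if length <= 0:
            raise ValueError(f"layer {i} ({ld.kind}) produces non-positive length")
        steps.append((i, length, channels))
        kinds.append(ld.kind)
    if flat is None:
        flat = length * channels
    return ShapeTrace(steps=tuple(steps), flatten_size=flat, kinds=tuple(kinds))


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter total (weights plus biases).

    conv1d: kernel x in_channels x filters + filters;
    dense: in x units + units; all other layers contribute 0.
    """
    length, channels = spec.input_len, spec.input_channels
    total = 0
    for ld in spec.layers:
        if ld.kind == "conv1d":
            total += ld.kernel_size * channels * ld.filters + ld.filters
            if ld.padding == "valid":
                length = length - ld.kernel_size + 1
            channels = ld.filters
        elif ld.kind == "maxpool1d":
            length = (length - ld.pool_size) // ld.stride + 1
        elif ld.kind == "flatten":
            length, channels = length * channels, 1
        elif ld.kind == "dense":
            total += length * ld.units + ld.units
            length = ld.units
    return total


def estimate_flops(spec: ModelSpec) -> float:
    """FLOP estimate under the 2 x MAC convention.

    conv1d MACs = out_len x kernel x in_channels x filters; dense MACs =
    in x units.  Biases, pooling and activations are ignored.  Other FLOP
    counters (fused-MAC, bias-inclusive, profiler-based) give different
    totals; this module reports only this documented convention.
    """
    length, channels = spec.input_len, spec.input_channels
    macs = 0
    for ld in spec.layers:
        if ld.kind == "conv1d":
            out_len = length if ld.padding == "same" else length - ld.kernel_size + 1
            macs += out_len * ld.kernel_size * channels * ld.filters
            length, channels = out_len, ld.filters
        elif ld.kind == "maxpool1d":
            length = (length - ld.pool_size) // ld.stride + 1
        elif ld.kind == "flatten":
            length, channels = length * channels, 1
        elif ld.kind == "dense":
            macs += length * ld.units
            length = ld.units
    return float(2 * macs)


def ablation_spec(base: ModelSpec, variant: str) -> ModelSpec:
    """Derive an ablated architecture from a reference spec.

    ``three_conv`` drops the last conv+pool pair; ``kernel_plus_two`` adds 2
    to every conv kernel size.  Everything else is unchanged.
    """
    if variant == "three_conv":
        conv_idx = [i for i, ld in enumerate(base.layers) if ld.kind == "conv1d"]
        if len(conv_idx) < 2:
            raise ValueError("need at least two conv layers to drop one")
        last = conv_idx[-1]
        keep = [ld for i, ld in enumerate(base.layers) if i not in (last, last + 1)]
        if base.layers[last + 1].kind != "maxpool1d":
            raise ValueError("expected maxpool immediately after the last conv")
        return replace(base, name=f"{base.name}_three_conv", layers=tuple(keep))
    if variant == "kernel_plus_two":
        layers = tuple(
            replace(ld, kernel_size=ld.kernel_size + 2) if ld.kind == "conv1d" else ld
            for ld in base.layers
        )
        return replace(base, name=f"{base.name}_kernel_plus_two", layers=layers)
    raise ValueError(f"unknown variant {variant!r}; valid: three_conv, kernel_plus_two")


def spec_to_dict(spec: ModelSpec) -> dict:
    from dataclasses import asdict
    return {
        "name": spec.name,
        "input_len": spec.input_len,
        "input_channels": spec.input_channels,
        "n_classes": spec.n_classes,
        "layers": [asdict(ld) for ld in spec.layers],
    }


def spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        name=d["name"],
        input_len=d["input_len"],
        input_channels=d["input_channels"],
        n_classes=d["n_classes"],
        layers=tuple(LayerDescriptor(**ld) for ld in d["layers"]),
    )


def describe(spec: ModelSpec) -> str:
    """Human-readable shape trace, parameter count and FLOP estimate."""
    trace = propagate_shapes(spec)
    lines = [f"Model: {spec.name}  (input {spec.input_len} x {spec.input_channels})"]
    lines.append(f"{'#':>3} {'layer':<10} {'output':>16}")
    for (i, length, channels), kind in zip(trace.steps, trace.kinds):
        shape = (f"({length}, {channels})" if kind in ("conv1d", "maxpool1d")
                 else f"({length},)")
        lines.append(f"{i:>3} {kind:<10} {shape:>16}")
    lines.append(f"flatten size: {trace.flatten_size:,}")
    lines.append(f"trainable parameters: {count_parameters(spec):,}")
    lines.append(f"FLOPs (2 x MAC convention): {estimate_flops(spec):,.0f}")
    return "\n".join(lines)
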