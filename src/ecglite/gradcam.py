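"""1D Grad-CAM: localize the input regions driving a classification.

For a chosen conv layer with activations A_k (temporal length L, K
channels), the channel weights are the temporal means of the class-score
gradient, w_k = mean_t dy_c/dA_k(t); the raw map ReLU(sum_k w_k A_k) is
linearly interpolated back to the input length and normalized by its
maximum.  The class score is the pre-softmax logit, as in standard
Grad-CAM; the target layer defaults to the last conv layer, where the
receptive fields are widest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend import Model


@dataclass(frozen=True)
class SaliencyMap:
    """Non-negative, max-normalized saliency over the input window."""

    values: np.ndarray  # (input_len,), in [0, 1]
    target_class: str
    source_layer: int

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.values == 0.0))


def gradcam_map(model: Model, window: np.ndarray, class_index: int,
                layer: int | None = None) -> SaliencyMap:
    """Compute the Grad-CAM saliency map for one window and class.

    ``layer`` is an index into the model's layer list and must name a conv
    layer; by default the last conv layer is used.  An all-negative weighted
    sum yields the identically-zero map (the ReLU kills it), flagged via
    :attr:`SaliencyMap.is_zero`.
    """
    conv_layers = model.conv_layer_indices()
    if not conv_layers:
        raise ValueError("model has no conv layers")
    if layer is None:
        layer = conv_layers[-1]
    if layer not in conv_layers:
        raise ValueError(f"layer {layer} is not a conv layer (conv layers: {conv_layers})")

    acts, grads = model.activations_and_gradients(window, class_index, layer)
    weights = grads.mean(axis=0)  # (K,)
    raw = np.maximum(acts @ weights, 0.0)  # (L,)

    n_out = model.spec.input_len
    x_src = np.linspace(0.0, 1.0, num=len(raw))
    x_dst = np.linspace(0.0, 1.0, num=n_out)
    upsampled = np.interp(x_dst, x_src, raw)

    peak = upsampled.max()
    if peak > 0:
        upsampled = upsampled / peak
    class_name = (model.spec.name or "class") + f"[{class_index}]"
    return SaliencyMap(values=upsampled, target_class=class_name, source_layer=layer)
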