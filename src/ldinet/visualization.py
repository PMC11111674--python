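"""GradCAM attribution over the fused token grid.

For a chosen label, the gradient of that label's logit is taken with respect
to the fused tokens (the last spatial representation before the label-query
decoder).  Channel weights are the spatial mean of the gradient, the map is
the ReLU of the weighted activation sum reshaped to the token grid, and the
result is max-normalized to [0, 1].  Bilinear upsampling to the image size
produces the overlay; red marks high attention, blue low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .multilabel_decoder import LDINet
from .training import eval_transform, normalize_pixels

__all__ = ["Heatmap", "gradcam", "render_overlay", "lesion_focus"]


@dataclass
class Heatmap:
    grid_values: np.ndarray   # h×w in [0, 1]
    overlay_values: np.ndarray  # H×W in [0, 1], bilinear-upsampled
    label_name: str
    label_index: int


def gradcam(model: LDINet, image: np.ndarray, label_index: int,
            label_name: str | None = None) -> Heatmap:
    """GradCAM heatmap for one raw [0,1] H×W×3 image and one label index."""
    n_labels = model.config.n_labels
    if not 0 <= label_index < n_labels:
        raise IndexError(f"label index {label_index} out of range [0, {n_labels})")
    size = model.config.image_size
    prepped = normalize_pixels(eval_transform(image, size))[None]
    logits, _, inter = model.forward(prepped, training=False)
    fused = inter["fused"]
    seed_grad = np.zeros(logits.shape)
    seed_grad[0, label_index] = 1.0
    logits.backward(seed_grad)
    acts = fused.tokens.data[0]          # L×D
    grads = fused.tokens.grad[0]         # L×D
    weights = grads.mean(axis=0)         # D — spatial mean per channel
    cam = np.maximum(acts @ weights, 0.0)
    h, w = fused.grid
    cam = cam.reshape(h, w)
    if cam.max() > 0:
        cam = cam / cam.max()
    up = Image.fromarray((cam * 255.0).astype(np.float32), mode="F").resize(
        (image.shape[1], image.shape[0]), Image.BILINEAR)
    overlay = np.clip(np.asarray(up, dtype=np.float64) / 255.0, 0.0, 1.0)
    return Heatmap(cam, overlay, label_name or f"label_{label_index}", label_index)


def render_overlay(heatmap: Heatmap, image: np.ndarray, out_path) -> None:
    """Alpha-blend a red-high/blue-low colormap onto the image; save as PNG."""
    cmap = colormaps["jet"]
    colored = cmap(heatmap.overlay_values)[..., :3]
    blended = 0.5 * np.clip(image, 0.0, 1.0) + 0.5 * colored
    arr = np.round(blended * 255.0).astype(np.uint8)
    Image.fromarray(arr).save(out_path)


def lesion_focus(heatmap: Heatmap, lesion_mask: np.ndarray) -> float:
    """Fraction of total map mass falling on lesion pixels (mask at image res)."""
    mask = np.asarray(lesion_mask, dtype=bool)
    total = heatmap.overlay_values.sum()
    if total == 0:
        return 0.0
    return float(heatmap.overlay_values[mask].sum() / total)
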