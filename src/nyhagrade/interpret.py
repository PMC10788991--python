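"""1-D Grad-CAM relevance maps for the convolutional-recurrent classifiers.

The class score is the pre-softmax logit of the target class (the
standard grad-CAM choice; it avoids softmax saturation and makes the map
independent of the other classes' logits).  Channel importance weights
are the time-averaged gradients of that score with respect to the last
conv stage's activations; the map is the ReLU of the weighted channel
sum, linearly interpolated back to input resolution and normalized so its
maximum is 1 (an all-zero map is returned when nothing activates
positively).

By default the attended tensor is the SE-rescaled output of the last conv
stage (what the downstream network actually consumes); set
``use_se_output=False`` to attend to the raw post-ReLU conv activations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Network

__all__ = ["CamMap", "grad_cam", "overlay_plot"]


@dataclass
class CamMap:
    """Relevance per input sample, in [0, 1]; max 1 unless nothing activates."""

    relevance: np.ndarray
    target_class: int
    layer: str

    def __post_init__(self) -> None:
        self.relevance = np.asarray(self.relevance, dtype=float)
        if self.relevance.min() < -1e-9 or self.relevance.max() > 1.0 + 1e-9:
            raise ValueError("relevance values must lie in [0, 1]")


def _resolve_network(model) -> Network:
    if isinstance(model, Network):
        return model
    network = getattr(model, "network_", None)
    if network is None:
        raise ValueError(
            "model must be a fitted classifier (with .network_) or a Network"
        )
    return network


def grad_cam(
    model,
    segment: np.ndarray,
    target_class: int,
    use_se_output: bool = True,
) -> CamMap:
    """Grad-CAM relevance of one (normalized) segment for a target class.

    ``target_class`` indexes the model's output units (for a fitted
    :class:`~nyhagrade.model.NYHAClassifier`, a NYHA grade in
    ``model.classes_``).
    """
    network = _resolve_network(model)
    samples = np.asarray(
        segment.samples if hasattr(segment, "samples") else segment, dtype=np.float32
    )
    if samples.ndim != 1:
        raise ValueError("segment must be a 1-D sample vector")
    if len(samples) != network.input_length:
        raise ValueError(
            f"segment length {len(samples)} does not match model input "
            f"{network.input_length}"
        )
    classes = getattr(model, "classes_", None)
    if classes is not None:
        matches = np.flatnonzero(np.asarray(classes) == target_class)
        if matches.size == 0:
            raise ValueError(f"target class {target_class} not in {list(classes)}")
        unit = int(matches[0])
    else:
        unit = int(target_class)

    logits = network.forward(samples[None, :], train=False)
    if unit < 0 or unit >= logits.shape[1]:
        raise ValueError(f"target unit {unit} out of range for {logits.shape[1]} classes")
    dlogits = np.zeros_like(logits)
    dlogits[0, unit] = 1.0  # d(score)/d(logit): pre-softmax class score
    grads_at = network.backward(dlogits, stop_after_stage3=True)

    key = "stage3_out" if use_se_output else "conv3_relu"
    activations = network.activations[key][0]  # (C, T')
    gradient = grads_at[key][0]
    alpha = gradient.mean(axis=1)                       # channel weights
    cam_coarse = np.maximum((alpha[:, None] * activations).sum(axis=0), 0.0)

    t_coarse = len(cam_coarse)
    if t_coarse == 1:
        cam = np.full(len(samples), cam_coarse[0])
    else:
        src = np.linspace(0, len(samples) - 1, t_coarse)
        cam = np.interp(np.arange(len(samples)), src, cam_coarse)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return CamMap(relevance=cam, target_class=int(target_class), layer=key)


def overlay_plot(segment, cam: CamMap, out_path) -> Path:
    """Render the ECG trace over its relevance map (blue = low, red = high)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = np.asarray(
        segment.samples if hasattr(segment, "samples") else segment, dtype=float
    )
    if len(samples) != len(cam.relevance):
        raise ValueError(
            f"length mismatch: segment has {len(samples)} samples, "
            f"map has {len(cam.relevance)}"
        )
    fig, ax = plt.subplots(figsize=(10, 3))
    extent = (0, len(samples), samples.min() - 0.2, samples.max() + 0.2)
    im = ax.imshow(
        cam.relevance[None, :],
        aspect="auto",
        cmap="jet",
        vmin=0.0,
        vmax=1.0,
        extent=extent,
        alpha=0.6,
    )
    ax.plot(samples, color="black", linewidth=0.8)
    ax.set_xlabel("sample")
    ax.set_ylabel("amplitude")
    ax.set_title(f"Grad-CAM, target class {cam.target_class} ({cam.layer})")
    fig.colorbar(im, ax=ax, label="model attention")
    out_path = Path(out_path)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
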