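"""Receptive-field backprojection and confound saliency (shortcut scenario).

The receptive field of a class unit is reconstructed by propagating its
one-hot output vector backwards through the learned weight matrices: for
layers L..1 the vector is multiplied by ``W_l`` (summing over every route
that links the unit to each input pixel) and, between hidden layers,
negative entries are zeroed — a route-positivity reading of inverting the
rectified-linear activation.  A pure-linear variant (no zeroing) is
available behind ``rectify=False``; it is exactly linear in the starting
one-hot vector and serves as an analytic cross-check.

Biases play no role: routes are weight products only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ncbl.dnn_model import TrainedMLP

__all__ = [
    "ReceptiveFieldMap",
    "backproject",
    "reconstruct_receptive_field",
    "rf_repredict",
    "region_saliency",
    "save_map",
    "footprint_mask",
]


@dataclass(frozen=True)
class ReceptiveFieldMap:
    """Image-shaped pixel-contribution map for one class unit.

    ``intensity`` is min-max normalized to [0, 1]; the pre-normalization
    bounds are kept so the raw backprojection is recoverable.  ``degenerate``
    flags an all-equal map (e.g. from an untrained all-zero model), whose
    normalized intensity is defined as all zeros.
    """

    intensity: np.ndarray
    class_id: int
    pre_min: float
    pre_max: float
    degenerate: bool = False
    rectified: bool = True

    @property
    def raw(self) -> np.ndarray:
        """Backprojected intensities on their original scale."""
        return self.intensity * (self.pre_max - self.pre_min) + self.pre_min


def backproject(
    weights: Sequence[np.ndarray], class_id: int, rectify: bool = True
) -> np.ndarray:
    """Route-summed backprojection of a one-hot class vector to the input.

    ``weights[l]`` has shape ``(fan_in, fan_out)``; the chain
    ``v <- W_l @ v`` from the deepest layer to the input realizes the sum
    over all connecting routes exactly.  With ``rectify`` the vector is
    rectified after each hidden-layer backstep.
    """
    n_out = weights[-1].shape[1]
    if not 0 <= class_id < n_out:
        raise ValueError(f"class_id {class_id} out of range [0, {n_out})")
    v = np.zeros(n_out)
    v[class_id] = 1.0
    for l in range(len(weights) - 1, -1, -1):
        v = weights[l] @ v
        if rectify and l > 0:
            v = np.maximum(v, 0.0)
    return v


def reconstruct_receptive_field(
    model: TrainedMLP,
    class_id: int,
    image_shape: tuple[int, int, int],
    rectify: bool = True,
) -> ReceptiveFieldMap:
    """Backproject a class unit to pixel space and min-max normalize.

    Normalization is over the whole map (not per channel) and is
    order-preserving, so the argmax pixel is unchanged by it.
    """
    if int(np.prod(image_shape)) != model.spec.input_dim:
        raise ValueError(
            f"image_shape {image_shape} does not flatten to input_dim "
            f"{model.spec.input_dim}"
        )
    v = backproject(model.weights, class_id, rectify=rectify)
    v = v.reshape(image_shape)
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-300:
        return ReceptiveFieldMap(
            intensity=np.zeros(image_shape),
            class_id=class_id,
            pre_min=lo,
            pre_max=hi,
            degenerate=True,
            rectified=rectify,
        )
    return ReceptiveFieldMap(
        intensity=(v - lo) / (hi - lo),
        class_id=class_id,
        pre_min=lo,
        pre_max=hi,
        degenerate=False,
        rectified=rectify,
    )


def rf_repredict(
    model: TrainedMLP, maps: Sequence[ReceptiveFieldMap]
) -> tuple[np.ndarray, int]:
    """Feed each normalized map back through the model as if it were an image.

    Returns the argmax class per map and how many maps re-predict their own
    source class — the consistency check on the reconstruction.
    """
    x = np.stack([m.intensity.reshape(-1) for m in maps])
    preds = model.predict(x)
    correct = int(sum(p == m.class_id for p, m in zip(preds, maps)))
    return preds, correct


def footprint_mask(
    image_shape: tuple[int, int, int], rows: slice, cols: slice
) -> np.ndarray:
    """Boolean (H, W, C) mask for a rectangular pixel footprint."""
    mask = np.zeros(image_shape, dtype=bool)
    mask[rows, cols, :] = True
    return mask


def save_map(rf_map: ReceptiveFieldMap, path: str | Path) -> None:
    """Write the normalized map as an 8-bit PNG plus a lossless float sidecar.

    A map of shape (H, W, 3) is written as RGB, (H, W, 1) as grayscale; the
    ``.npz`` sidecar holds the exact float intensities and the
    pre-normalization bounds.
    """
    from PIL import Image

    path = Path(path)
    arr = np.clip(np.round(rf_map.intensity * 255), 0, 255).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    Image.fromarray(arr).save(path.with_suffix(".png"))
    np.savez(
        path.with_suffix(".npz"),
        intensity=rf_map.intensity,
        pre_min=rf_map.pre_min,
        pre_max=rf_map.pre_max,
        class_id=rf_map.class_id,
    )


def region_saliency(rf_map: ReceptiveFieldMap, region: np.ndarray) -> float:
    """Mean normalized intensity inside the region over the mean outside.

    Values above 1 mean the region is over-weighted in the unit's receptive
    field.  A region with zero outside intensity returns ``inf``.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape == rf_map.intensity.shape[:2]:
        region = np.repeat(region[:, :, None], rf_map.intensity.shape[2], axis=2)
    if region.shape != rf_map.intensity.shape:
        raise ValueError("region mask shape does not match the map")
    if not region.any():
        raise ValueError("region is empty")
    if region.all():
        raise ValueError("region covers the whole image")
    inside = float(rf_map.intensity[region].mean())
    outside = float(rf_map.intensity[~region].mean())
    if outside == 0.0:
        return float("inf") if inside > 0 else float("nan")
    return inside / outside
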