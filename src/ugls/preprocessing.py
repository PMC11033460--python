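"""Dataset preparation: intensity normalization, reference-patch extraction
and resizing."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.transform import resize as _sk_resize

from .imaging import BinaryMask, Image

__all__ = ["PatchSpec", "normalize_image", "equivalent_radius", "extract_patch", "resize"]


@dataclass(frozen=True)
class PatchSpec:
    """Square crop centered on a reference mask.

    The side length is three times the mask's equivalent-circle radius
    (sqrt(area/pi)); regions falling outside the image are zero-padded so the
    patch stays square.
    """

    center: tuple[float, float]
    side: int
    output_size: int = 256

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError("patch side must be >= 1")

    @classmethod
    def from_reference(cls, reference: BinaryMask | np.ndarray, output_size: int = 256):
        arr = reference.data if isinstance(reference, BinaryMask) else np.asarray(reference, bool)
        if not arr.any():
            raise ValueError("reference mask is empty")
        coords = np.argwhere(arr)
        center = tuple(coords.mean(axis=0))
        side = max(1, int(round(3.0 * equivalent_radius(arr))))
        return cls(center=center, side=side, output_size=output_size)


def equivalent_radius(mask: BinaryMask | np.ndarray) -> float:
    """Radius of the circle whose area matches the mask's pixel count."""
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    return float(np.sqrt(arr.sum() / np.pi))


def normalize_image(image: Image | np.ndarray) -> Image:
    """Per-channel standardization followed by an affine rescale to [0, 1].

    Invariant to per-channel shift and positive scaling of the input; a
    constant channel maps to all 0.5.
    """
    img = image if isinstance(image, Image) else Image(np.asarray(image))
    data = img.data
    squeeze = data.ndim == 2
    if squeeze:
        data = data[:, :, None]
    out = np.empty_like(data)
    for c in range(data.shape[2]):
        ch = data[:, :, c]
        sd = ch.std()
        if sd == 0 or ch.min() == ch.max():
            out[:, :, c] = 0.5
            continue
        z = (ch - ch.mean()) / sd
        lo, hi = z.min(), z.max()
        out[:, :, c] = (z - lo) / (hi - lo)
    if squeeze:
        out = out[:, :, 0]
    return Image(out)


def resize(data: Image | BinaryMask | np.ndarray, size: tuple[int, int] = (256, 256)):
    """Bilinear resize for images, nearest-neighbor for masks (masks stay
    strictly binary). Returns the same kind as the input."""
    if isinstance(data, BinaryMask):
        out = _sk_resize(
            data.data.astype(np.uint8), size, order=0, preserve_range=True,
            anti_aliasing=False,
        ).astype(bool)
        return data.with_data(out)
    if isinstance(data, Image):
        arr = data.data
        out_shape = size if arr.ndim == 2 else (*size, arr.shape[2])
        out = _sk_resize(arr, out_shape, order=1, preserve_range=True, anti_aliasing=False)
        return Image(np.clip(out, 0.0, 1.0))
    arr = np.asarray(data)
    if arr.dtype == bool:
        return _sk_resize(arr.astype(np.uint8), size, order=0, preserve_range=True,
                          anti_aliasing=False).astype(bool)
    return _sk_resize(arr, size, order=1, preserve_range=True, anti_aliasing=False)


def _crop_padded(arr: np.ndarray, top: int, left: int, side: int) -> np.ndarray:
    h, w = arr.shape[:2]
    out_shape = (side, side) + arr.shape[2:]
    out = np.zeros(out_shape, dtype=arr.dtype)
    y0, y1 = max(top, 0), min(top + side, h)
    x0, x1 = max(left, 0), min(left + side, w)
    if y0 < y1 and x0 < x1:
        out[y0 - top : y1 - top, x0 - left : x1 - left] = arr[y0:y1, x0:x1]
    return out


def extract_patch(
    image: Image | np.ndarray,
    masks: Mapping[str, BinaryMask | np.ndarray],
    reference_mask: BinaryMask | np.ndarray,
    output_size: int = 256,
) -> tuple[Image, dict[str, BinaryMask], PatchSpec]:
    """Crop the square patch defined by the reference mask and resize.

    All masks are cropped with the same geometry; the returned
    :class:`PatchSpec` records the crop so coordinates can be mapped back.
    """
    img = image if isinstance(image, Image) else Image(np.asarray(image))
    spec = PatchSpec.from_reference(reference_mask, output_size=output_size)
    cy, cx = spec.center
    top = int(round(cy - spec.side / 2.0))
    left = int(round(cx - spec.side / 2.0))
    patch = _crop_padded(img.data, top, left, spec.side)
    out_img = resize(Image(patch), (output_size, output_size))
    out_masks: dict[str, BinaryMask] = {}
    for name, m in masks.items():
        bm = m if isinstance(m, BinaryMask) else BinaryMask(np.asarray(m), object_id=name)
        cropped = _crop_padded(bm.data, top, left, spec.side)
        out_masks[name] = resize(bm.with_data(cropped), (output_size, output_size))
    return out_img, out_masks, spec
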