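"""Binary-mask morphology and boundary-uncertainty constructions.

The central objects of the two-stage strategy are derived from a single
coarse segmentation mask:

* the potential boundary region (PBR): an annular band
  ``dilate(P, SE_r) \\ erode(P, SE_r)`` around the coarse boundary,
* the boundary uncertainty map (BUM): the PBR smoothed with a truncated,
  normalized Gaussian kernel, peaking on the band's centerline,
* the background-excluded image (BEI): the elementwise product of the PBR
  with the input image.

All morphology uses a discrete circular structuring element (closed ball,
offsets with ``dy**2 + dx**2 <= r**2``); pixels outside the grid are treated
as background, so erosion shrinks objects at image borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage


__all__ = [
    "BinaryMask",
    "Image",
    "StructuringElement",
    "UncertaintyBundle",
    "EmptyCoarseMaskWarning",
    "dilate",
    "erode",
    "potential_boundary_region",
    "boundary_uncertainty_map",
    "background_excluded_image",
    "build_uncertainty_bundle",
    "gaussian_window_size",
]


class EmptyCoarseMaskWarning(UserWarning):
    """Raised (as a warning) when a coarse mask contains no foreground."""


@dataclass(frozen=True)
class StructuringElement:
    """Discrete disk of radius ``r``: all offsets with dy^2 + dx^2 <= r^2."""

    radius: int

    def __post_init__(self) -> None:
        if int(self.radius) != self.radius or self.radius < 0:
            raise ValueError(f"radius must be a non-negative integer, got {self.radius!r}")
        object.__setattr__(self, "radius", int(self.radius))

    @property
    def footprint(self) -> np.ndarray:
        """Boolean (2r+1, 2r+1) array with the disk centered."""
        return _disk_footprint(self.radius)

    @property
    def offsets(self) -> frozenset[tuple[int, int]]:
        r = self.radius
        fp = self.footprint
        return frozenset(
            (dy - r, dx - r) for dy, dx in np.argwhere(fp)
        )


@lru_cache(maxsize=64)
def _disk_footprint(radius: int) -> np.ndarray:
    r = radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    fp = (yy * yy + xx * xx) <= r * r
    fp.setflags(write=False)
    return fp


@dataclass
class BinaryMask:
    """A single object's 2-D boolean mask.

    ``provenance`` tags where the mask came from ("truth" for manual
    annotations, "prediction" for binarized network output); the training
    pipeline uses it to audit that ground truth never leaks into bundle
    construction.
    """

    data: np.ndarray
    object_id: str = ""
    provenance: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(f"mask values must be in {{0,1}}, found {uniq[:10]}")
            arr = arr.astype(bool)
        self.data = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def is_empty(self) -> bool:
        return not self.data.any()

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(data, object_id=self.object_id, provenance=self.provenance)


@dataclass
class Image:
    """2-D (H, W) or 3-D (H, W, C) image with intensities in [0, 1]."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim not in (2, 3):
            raise ValueError(f"image must be 2-D or 3-D, got shape {arr.shape}")
        if arr.ndim == 3 and arr.shape[2] not in (1, 3):
            raise ValueError(f"channel count must be 1 or 3, got {arr.shape[2]}")
        if not np.isfinite(arr).all():
            raise ValueError("image contains non-finite values")
        self.data = arr

    @property
    def channels(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class UncertaintyBundle:
    """PBR + BUM + BEI derived from one coarse mask and one image."""

    pbr: BinaryMask
    bum: np.ndarray
    bei: Image

    def __post_init__(self) -> None:
        s = self.pbr.shape
        if self.bum.shape != s or self.bei.spatial_shape != s:
            raise ValueError("pbr, bum and bei must share the spatial shape")


def _mask_array(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.data
    arr = np.asarray(mask)
    return arr.astype(bool) if arr.dtype != bool else arr


def _wrap_like(mask: BinaryMask | np.ndarray, data: np.ndarray):
    if isinstance(mask, BinaryMask):
        return mask.with_data(data)
    return data


def dilate(mask: BinaryMask | np.ndarray, se: StructuringElement):
    """Minkowski dilation; out-of-grid pixels are background."""
    arr = _mask_array(mask)
    if se.radius == 0:
        return _wrap_like(mask, arr.copy())
    out = ndimage.binary_dilation(arr, structure=se.footprint, border_value=0)
    return _wrap_like(mask, out)


def erode(mask: BinaryMask | np.ndarray, se: StructuringElement):
    """Morphological erosion; out-of-grid pixels are background, so objects
    touching the image border shrink there."""
    arr = _mask_array(mask)
    if se.radius == 0:
        return _wrap_like(mask, arr.copy())
    out = ndimage.binary_erosion(arr, structure=se.footprint, border_value=0)
    return _wrap_like(mask, out)


def potential_boundary_region(coarse: BinaryMask | np.ndarray, r_m: int):
    """Annular band ``dilate(P, SE) \\ erode(P, SE)`` around the coarse boundary.

    Implemented as ``dilation AND NOT erosion`` (erosion is always a subset of
    dilation, so this equals the arithmetic difference). An empty coarse mask
    yields an empty band and emits :class:`EmptyCoarseMaskWarning`.
    """
    if r_m < 1:
        raise ValueError(f"r_m must be >= 1, got {r_m}")
    arr = _mask_array(coarse)
    if not arr.any():
        warnings.warn(
            "coarse mask is empty; PBR is empty", EmptyCoarseMaskWarning, stacklevel=2
        )
        return _wrap_like(coarse, np.zeros_like(arr))
    se = StructuringElement(r_m)
    band = dilate(arr, se) & ~erode(arr, se)
    return _wrap_like(coarse, band)


def gaussian_window_size(r_g: int) -> int:
    """The r x r smoothing window, bumped to the next odd size when r is even
    so the kernel has a center pixel."""
    return r_g if r_g % 2 == 1 else r_g + 1


def boundary_uncertainty_map(pbr: BinaryMask | np.ndarray, r_g: int) -> np.ndarray:
    """Smooth the {0,1} PBR with a normalized Gaussian of sigma ``r_g``
    truncated to an ``r_g x r_g`` window (odd-adjusted), reflect padding.

    The result lives in [0, 1] and peaks on the band centerline; it is not
    re-normalized after smoothing.
    """
    if r_g < 1:
        raise ValueError(f"r_g must be >= 1, got {r_g}")
    arr = _mask_array(pbr).astype(np.float64)
    half = (gaussian_window_size(r_g) - 1) // 2
    if half == 0:
        return arr
    return ndimage.gaussian_filter(arr, sigma=float(r_g), mode="reflect", radius=half)


def background_excluded_image(pbr: BinaryMask | np.ndarray, image: Image | np.ndarray) -> Image:
    """Elementwise product PBR x I: zero outside the band, unchanged inside."""
    band = _mask_array(pbr)
    img = image if isinstance(image, Image) else Image(np.asarray(image))
    if img.spatial_shape != band.shape:
        raise ValueError(
            f"shape mismatch: pbr {band.shape} vs image {img.spatial_shape}"
        )
    weight = band.astype(np.float64)
    if img.data.ndim == 3:
        weight = weight[:, :, None]
    return Image(img.data * weight)


def build_uncertainty_bundle(
    coarse: BinaryMask | np.ndarray,
    image: Image | np.ndarray,
    r_m: int,
    r_g: int | None = None,
    *,
    empty_coarse: str = "empty",
) -> UncertaintyBundle:
    """Derive PBR, BUM and BEI from one coarse mask.

    ``r_g`` defaults to ``r_m`` (shared radii work best for both the
    morphology and the smoothing). ``empty_coarse`` selects the fallback when
    the coarse mask has no foreground: ``"empty"`` keeps all-zero outputs,
    ``"full"`` substitutes an all-ones PBR so a downstream network still
    receives trainable input (the whole image is then maximally uncertain);
    both emit :class:`EmptyCoarseMaskWarning`.
    """
    if empty_coarse not in ("empty", "full"):
        raise ValueError(f"empty_coarse must be 'empty' or 'full', got {empty_coarse!r}")
    if r_g is None:
        r_g = r_m
    arr = _mask_array(coarse)
    if not arr.any() and empty_coarse == "full":
        warnings.warn(
            "coarse mask is empty; substituting an all-ones PBR",
            EmptyCoarseMaskWarning,
            stacklevel=2,
        )
        pbr_arr = np.ones_like(arr)
        pbr = _wrap_like(coarse, pbr_arr)
    else:
        pbr = potential_boundary_region(coarse, r_m)
    bum = boundary_uncertainty_map(pbr, r_g)
    bei = background_excluded_image(pbr, image)
    if not isinstance(pbr, BinaryMask):
        pbr = BinaryMask(pbr)
    return UncertaintyBundle(pbr=pbr, bum=bum, bei=bei)
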