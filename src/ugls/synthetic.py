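"""Phantom generator for desk-scale experiments.

Two phantom families mirror the geometry the two-stage strategy targets:

* ``fundus``: a bright ellipse (disc) containing a smaller, low-contrast
  ellipse (cup) on a textured background — the cup boundary is deliberately
  hard to see,
* ``lungs``: two disjoint, mirrored dark lobes on a brighter thorax-like
  field.

A mask perturber produces plausible "coarse predictions" without training a
network, so the uncertainty constructions and the fine stage can be
exercised in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, Image, StructuringElement, dilate, erode

__all__ = [
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "perturb_mask",
    "generate_dataset",
    "SyntheticDataset",
]

FUNDUS_OBJECTS = ("disc", "cup")
LUNG_OBJECTS = ("left_lung", "right_lung")


@dataclass(frozen=True)
class PhantomSpec:
    kind: str = "lungs"
    size: int = 64
    noise_sd: float = 0.03
    # fundus geometry (fractions of image size / of disc axes)
    disc_axis_range: tuple[float, float] = (0.22, 0.3)
    cup_frac_range: tuple[float, float] = (0.4, 0.7)
    cup_contrast: float = 0.08
    # lungs geometry
    lobe_axis_range: tuple[float, float] = (0.16, 0.22)
    position_jitter: float = 0.06
    eccentricity_range: tuple[float, float] = (1.2, 1.7)

    def __post_init__(self) -> None:
        if self.kind not in ("fundus", "lungs"):
            raise ValueError(f"kind must be 'fundus' or 'lungs', got {self.kind!r}")
        if self.size < 8:
            raise ValueError("size must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.cup_frac_range
        if not (0 < lo <= hi < 1):
            raise ValueError("cup_frac_range must satisfy 0 < lo <= hi < 1")

    @property
    def objects(self) -> tuple[str, ...]:
        return FUNDUS_OBJECTS if self.kind == "fundus" else LUNG_OBJECTS


@dataclass
class Phantom:
    image: Image
    masks: dict[str, BinaryMask]


def _ellipse_mask(size, cy, cx, ay, ax, theta) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size].astype(np.float64)
    y = yy - cy
    x = xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def _textured_background(rng, size, level, amplitude) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    texture = ndimage.gaussian_filter(noise, sigma=size / 16.0, mode="reflect")
    scale = texture.std()
    if scale > 0:
        texture = texture / scale
    return level + amplitude * texture


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """One phantom image plus its ground-truth masks, deterministic per seed."""
    rng = np.random.default_rng(seed)
    n = spec.size
    if spec.kind == "fundus":
        img, masks = _fundus(spec, rng)
    else:
        img, masks = _lungs(spec, rng)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    out_masks = {
        name: BinaryMask(m, object_id=name, provenance="truth") for name, m in masks.items()
    }
    for name, m in out_masks.items():
        if m.is_empty():
            raise ValueError(f"phantom geometry produced an empty {name!r} mask")
    return Phantom(image=Image(img), masks=out_masks)


def _fundus(spec: PhantomSpec, rng) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    n = spec.size
    jit = spec.position_jitter * n
    cy = n / 2 + rng.uniform(-jit, jit)
    cx = n / 2 + rng.uniform(-jit, jit)
    a_lo, a_hi = spec.disc_axis_range
    ay = n * rng.uniform(a_lo, a_hi)
    ax = ay * rng.uniform(0.85, 1.15)
    theta = rng.uniform(-np.pi, np.pi)
    disc = _ellipse_mask(n, cy, cx, ay, ax, theta)

    frac = rng.uniform(*spec.cup_frac_range)
    # cup center shifted slightly inside the disc
    off = 0.15 * min(ay, ax)
    ccy = cy + rng.uniform(-off, off)
    ccx = cx + rng.uniform(-off, off)
    cup = _ellipse_mask(n, ccy, ccx, ay * frac, ax * frac, theta)
    cup &= disc  # nesting invariant
    if not cup.any() or cup.sum() == disc.sum():
        raise ValueError("fundus geometry cannot satisfy cup-inside-disc invariant")

    img = _textured_background(rng, n, level=0.35, amplitude=0.04)
    disc_level = 0.72
    img[disc] = disc_level
    img[cup] = disc_level + spec.cup_contrast
    return img, {"disc": disc, "cup": cup}


def _lungs(spec: PhantomSpec, rng) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    n = spec.size
    jit = spec.position_jitter * n
    a_lo, a_hi = spec.lobe_axis_range
    ecc = rng.uniform(*spec.eccentricity_range)
    ax_half = n * rng.uniform(a_lo, a_hi)
    ay_half = ax_half * ecc
    cy = n * 0.5 + rng.uniform(-jit, jit)
    gap = n * rng.uniform(0.02, 0.05)
    tilt = rng.uniform(-0.15, 0.15)
    left_cx = n * 0.5 - gap / 2 - ax_half + rng.uniform(-jit / 2, jit / 2)
    right_cx = n * 0.5 + gap / 2 + ax_half + rng.uniform(-jit / 2, jit / 2)
    left = _ellipse_mask(n, cy, left_cx, ay_half, ax_half, tilt)
    right = _ellipse_mask(n, cy, right_cx, ay_half, ax_half, -tilt)
    if (left & right).any():
        # enforce disjointness by splitting on the midline between centers
        mid = (left_cx + right_cx) / 2.0
        cols = np.arange(n)
        left &= cols[None, :] < mid
        right &= cols[None, :] >= mid
    img = _textured_background(rng, n, level=0.62, amplitude=0.05)
    img[left] = 0.28
    img[right] = 0.28
    return img, {"left_lung": left, "right_lung": right}


def perturb_mask(mask: BinaryMask | np.ndarray, magnitude: int, seed: int = 0):
    """Displace the mask boundary by up to ``magnitude`` pixels.

    Random angular sectors around the mask centroid are independently
    dilated or eroded with a disk of radius <= magnitude, emulating the
    boundary errors of a coarse prediction. Expected Dice against the input
    decreases with magnitude; the output boundary stays within
    ``magnitude`` px of the input boundary. Retries with a halved magnitude
    (up to 5 times) if the perturbation empties the mask.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not arr.any():
        raise ValueError("cannot perturb an empty mask")
    if magnitude == 0:
        out = arr.copy()
        return mask.with_data(out) if isinstance(mask, BinaryMask) else out

    rng = np.random.default_rng(seed)
    mag = int(magnitude)
    for _attempt in range(5):
        out = _sector_perturb(arr, mag, rng)
        if out.any():
            if isinstance(mask, BinaryMask):
                return BinaryMask(out, object_id=mask.object_id, provenance="perturbed")
            return out
        mag = max(1, mag // 2)
    raise ValueError("perturbation emptied the mask after 5 attempts")


def _sector_perturb(arr: np.ndarray, magnitude: int, rng) -> np.ndarray:
    cy, cx = ndimage.center_of_mass(arr)
    yy, xx = np.mgrid[: arr.shape[0], : arr.shape[1]]
    angles = np.arctan2(yy - cy, xx - cx)
    n_sectors = int(rng.integers(3, 8))
    edges = np.sort(rng.uniform(-np.pi, np.pi, size=n_sectors))
    sector_idx = np.searchsorted(edges, angles, side="right") % n_sectors
    out = arr.copy()
    for s in range(n_sectors):
        r = int(rng.integers(0, magnitude + 1))
        if r == 0:
            continue
        se = StructuringElement(r)
        op = dilate if rng.random() < 0.5 else erode
        changed = op(arr, se)
        sel = sector_idx == s
        out[sel] = changed[sel]
    return out


@dataclass
class SyntheticDataset:
    """Phantoms plus a deterministic three-way split (thirds; any remainder
    joins the training split)."""

    spec: PhantomSpec
    ids: list[str]
    phantoms: dict[str, Phantom]
    splits: dict[str, str] = field(default_factory=dict)  # id -> train/val/test

    @property
    def objects(self) -> tuple[str, ...]:
        return self.spec.objects

    def ids_for(self, role: str) -> list[str]:
        return [i for i in self.ids if self.splits[i] == role]


def generate_dataset(n: int, spec: PhantomSpec, seed: int = 0) -> SyntheticDataset:
    """``n`` phantoms with per-item seeds spawned from a master seed, split
    into train/val/test thirds."""
    if n < 3:
        raise ValueError("need at least 3 phantoms for a three-way split")
    master = np.random.SeedSequence(seed)
    ids = [f"{spec.kind}_{i:04d}" for i in range(n)]
    phantoms = {}
    for i, pid in enumerate(ids):
        child = np.random.SeedSequence(entropy=master.entropy, spawn_key=(i,))
        item_seed = int(child.generate_state(1)[0])
        phantoms[pid] = generate_phantom(spec, seed=item_seed)
    third = n // 3
    splits = {}
    for i, pid in enumerate(ids):
        if i < third:
            splits[pid] = "train"
        elif i < 2 * third:
            splits[pid] = "val"
        elif i < 3 * third:
            splits[pid] = "test"
        else:
            splits[pid] = "train"  # remainder
    return SyntheticDataset(spec=spec, ids=ids, phantoms=phantoms, splits=splits)
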