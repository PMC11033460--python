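"""On-disk dataset layout and image/mask readers-writers.

Layout::

    root/
      images/<image_id>.png        16-bit grayscale or RGB, intensities [0,1]
      masks/<object_id>/<image_id>.png   0/255 binary PNG
      split.json                   {"<image_id>": "train"|"val"|"test", ...}

Masks are the canonical 0/255 PNG dialect; 16-bit TIFF masks are accepted on
read and normalized. Float maps (BUMs, BEIs) are written as 32-bit float
TIFF. All ids are sorted lexicographically so in-memory order never depends
on directory listing order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .imaging import BinaryMask, Image

__all__ = [
    "Sample",
    "DiskDataset",
    "DatasetError",
    "load_dataset",
    "save_dataset",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "write_float_map",
    "read_float_map",
]

ROLES = ("train", "val", "test")


class DatasetError(ValueError):
    """A dataset directory violates the layout contract."""


@dataclass
class Sample:
    image_id: str
    image: Image
    masks: dict[str, BinaryMask]


@dataclass
class DiskDataset:
    root: Path
    objects: tuple[str, ...]
    ids: list[str]
    samples: dict[str, Sample]
    splits: dict[str, str] = field(default_factory=dict)

    def ids_for(self, role: str) -> list[str]:
        return [i for i in self.ids if self.splits.get(i) == role]


# -- single-file readers/writers --------------------------------------------


def write_mask(path, mask: BinaryMask | np.ndarray) -> None:
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (arr.astype(np.uint8) * 255))


def read_mask(path, object_id: str = "", provenance: str | None = "truth") -> BinaryMask:
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise DatasetError(f"unreadable mask file: {path} ({exc})") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    top = np.iinfo(arr.dtype).max if arr.dtype.kind == "u" else arr.max()
    values = np.unique(arr)
    if not np.isin(values, (0, top)).all():
        raise DatasetError(
            f"mask {path} is not binary: found values {values[:10].tolist()} "
            f"(expected only 0 and {top})"
        )
    return BinaryMask(arr == top, object_id=object_id, provenance=provenance)


def write_image(path, image: Image | np.ndarray) -> None:
    img = image if isinstance(image, Image) else Image(np.asarray(image))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.round(np.clip(img.data, 0.0, 1.0) * 65535).astype(np.uint16)
    iio.imwrite(path, data)


def read_image(path) -> Image:
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise DatasetError(f"unreadable image file: {path} ({exc})") from exc
    if arr.dtype.kind == "u":
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    return Image(np.clip(arr, 0.0, 1.0))


def write_float_map(path, data: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))


def read_float_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float64)


# -- whole-dataset round trip ------------------------------------------------


def save_dataset(dataset, root) -> Path:
    """Write any dataset exposing ``objects``/``ids``/``splits`` and a
    ``phantoms`` or ``samples`` record mapping into the directory layout."""
    root = Path(root)
    records = getattr(dataset, "phantoms", None) or dataset.samples
    for pid in dataset.ids:
        rec = records[pid]
        write_image(root / "images" / f"{pid}.png", rec.image)
        for obj in dataset.objects:
            write_mask(root / "masks" / obj / f"{pid}.png", rec.masks[obj])
    (root / "split.json").write_text(
        json.dumps({pid: dataset.splits[pid] for pid in dataset.ids}, indent=0)
    )
    return root


def load_dataset(root) -> DiskDataset:
    root = Path(root)
    images_dir = root / "images"
    masks_dir = root / "masks"
    if not images_dir.is_dir():
        raise DatasetError(f"missing images directory: {images_dir}")
    if not masks_dir.is_dir():
        raise DatasetError(f"missing masks directory: {masks_dir}")
    objects = tuple(sorted(p.name for p in masks_dir.iterdir() if p.is_dir()))
    if not objects:
        raise DatasetError(f"no object mask directories under {masks_dir}")
    ids = sorted(p.stem for p in images_dir.iterdir() if p.is_file())
    if not ids:
        raise DatasetError(f"no images under {images_dir}")

    split_path = root / "split.json"
    if split_path.is_file():
        splits = json.loads(split_path.read_text())
        missing = [i for i in ids if i not in splits]
        if missing:
            raise DatasetError(f"{split_path} does not cover image(s): {missing[:5]}")
        bad = {i: r for i, r in splits.items() if r not in ROLES}
        if bad:
            raise DatasetError(f"{split_path} contains invalid roles: {bad}")
    else:
        splits = {}

    samples: dict[str, Sample] = {}
    suffix = {p.stem: p for p in images_dir.iterdir() if p.is_file()}
    for pid in ids:
        image = read_image(suffix[pid])
        masks: dict[str, BinaryMask] = {}
        for obj in objects:
            candidates = sorted((masks_dir / obj).glob(f"{pid}.*"))
            if not candidates:
                raise DatasetError(f"missing mask for image {pid!r}: {masks_dir / obj / pid}")
            mask = read_mask(candidates[0], object_id=obj)
            if mask.shape != image.spatial_shape:
                raise DatasetError(
                    f"shape mismatch for {candidates[0]}: mask {mask.shape} vs "
                    f"image {image.spatial_shape}"
                )
            masks[obj] = mask
        samples[pid] = Sample(image_id=pid, image=image, masks=masks)
    return DiskDataset(root=root, objects=objects, ids=ids, samples=samples, splits=splits)
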