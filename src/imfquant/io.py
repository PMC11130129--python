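"""Reading and writing of images, masks, tables and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import FormatError


def read_image(path: str | Path) -> np.ndarray:
    """Load an RGB image (PNG/TIFF); drops an alpha channel if present."""
    img = iio.imread(path)
    if img.ndim == 2:
        raise FormatError(f"{path}: expected an RGB image, got a single channel")
    if img.shape[2] == 4:
        img = img[:, :, :3]
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, image)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel 0/255 PNG as a boolean mask."""
    m = iio.imread(path)
    if m.ndim == 3:
        m = m[..., 0]
    return m > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def dump_yaml(path: str | Path, obj) -> None:
    if is_dataclass(obj):
        obj = asdict(obj)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, seed: int, files: list[Path],
                   extra: dict | None = None) -> None:
    """Record seed and content checksums so a run is reconstructible."""
    manifest = {
        "seed": seed,
        "files": {str(f.name): file_checksum(f) for f in sorted(files)},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
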