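"""Image/mask pair loading, dataset splitting and dihedral augmentation.

Dataset layout on disk: a root directory with ``images/`` and ``masks/``
subdirectories holding grayscale rasters (PGM, both ASCII and binary
dialects, or PNG) with matching basenames.  Images are scaled by their
bit-depth maximum into [0, 1]; masks are binarized by ``value > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image


class PairingError(ValueError):
    """Image and mask rasters cannot be paired (size mismatch)."""


class FormatError(ValueError):
    """Raster file unreadable or not grayscale."""


class ConfigurationError(ValueError):
    pass


class DomainError(ValueError):
    pass


@dataclass
class SamplePair:
    """One unit flowing through the pipeline: image, binary mask, identifier."""

    image: np.ndarray  # H x W float in [0, 1]
    mask: np.ndarray   # H x W uint8 in {0, 1}
    id: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise PairingError(
                f"{self.id}: image {self.image.shape} vs mask {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise DomainError(f"{self.id}: mask must be binary")


def _read_gray(path: str | Path) -> np.ndarray:
    """Read a grayscale raster, scaled by its bit-depth maximum into [0, 1]."""
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # unreadable / undecodable
        raise FormatError(f"cannot read raster {path}: {exc}") from exc
    if img.mode == "L":
        maxval = 255.0
    elif img.mode in ("I", "I;16", "I;16B"):
        maxval = 65535.0
    elif img.mode == "1":
        maxval = 1.0
    else:
        raise FormatError(f"{path}: expected a grayscale raster, got mode {img.mode!r}")
    arr = np.asarray(img, dtype=np.float64)
    return arr / maxval


def load_pair(image_path: str | Path, mask_path: str | Path) -> SamplePair:
    """Load an angiogram and its ground-truth mask as one :class:`SamplePair`.

    The mask is binarized by ``value > 0``; both rasters must decode as
    grayscale images of identical size.
    """
    image = _read_gray(image_path)
    mask_raw = _read_gray(mask_path)
    if image.shape != mask_raw.shape:
        raise PairingError(
            f"image {image.shape} vs mask {mask_raw.shape} "
            f"({image_path} / {mask_path})")
    mask = (mask_raw > 0).astype(np.uint8)
    return SamplePair(image=image, mask=mask, id=Path(image_path).stem)


def save_gray(path: str | Path, array: np.ndarray) -> None:
    """Write a [0,1] float or {0,1} binary array as an 8-bit grayscale raster."""
    arr = np.asarray(array, dtype=np.float64)
    if arr.max() <= 1.0:
        arr = arr * 255.0
    Image.fromarray(np.clip(np.round(arr), 0, 255).astype(np.uint8), mode="L").save(path)


def load_dataset(root: str | Path) -> list[SamplePair]:
    """Load every image/mask pair under ``root/images`` and ``root/masks``."""
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    pairs = []
    for img_path in sorted(img_dir.iterdir()):
        matches = sorted(mask_dir.glob(img_path.stem + ".*"))
        if not matches:
            raise PairingError(f"no mask for {img_path.name}")
        pairs.append(load_pair(img_path, matches[0]))
    if not pairs:
        raise DomainError(f"no image/mask pairs under {root}")
    return pairs


# --------------------------------------------------------------------- splits
@dataclass
class DatasetSplit:
    """Disjoint, jointly exhaustive train/val/test id lists."""

    train: list
    val: list
    test: list
    ratios: tuple = (0.6, 0.1, 0.3)
    seed: int = 0

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)

    def write_manifests(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("train", "val", "test"):
            (out_dir / f"{name}.txt").write_text(
                "\n".join(str(i) for i in getattr(self, name)) + "\n")

    @classmethod
    def read_manifests(cls, out_dir: str | Path) -> "DatasetSplit":
        out_dir = Path(out_dir)
        parts = {name: (out_dir / f"{name}.txt").read_text().split()
                 for name in ("train", "val", "test")}
        return cls(train=parts["train"], val=parts["val"], test=parts["test"])


def split_dataset(items: int | Sequence, ratios: tuple = (0.6, 0.1, 0.3),
                  seed: int = 0) -> DatasetSplit:
    """Randomly partition ids into train/val/test by the 60/10/30 rule.

    Train and validation sizes use floor rounding and the remainder goes to
    test — 134 items split as (80, 13, 41) and 616 as (369, 61, 186).
    ``items`` may be a count (splitting ``range(n)``) or a sequence of ids.
    """
    ids = list(range(items)) if isinstance(items, int) else list(items)
    n = len(ids)
    if n < 3:
        raise DomainError(f"need at least 3 items to split, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3 or min(ratios) < 0:
        raise ConfigurationError(f"ratios must be three non-negatives summing to 1: {ratios}")
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(train=shuffled[:n_train],
                        val=shuffled[n_train:n_train + n_val],
                        test=shuffled[n_train + n_val:],
                        ratios=tuple(ratios), seed=seed)


# --------------------------------------------------------------- augmentation
def _rot180(a: np.ndarray) -> np.ndarray:
    return np.rot90(a, 2)


# name -> transform, for square rasters: the two mirrors, the three
# right-angle rotations, the main-diagonal transpose, plus identity = 7.
SQUARE_TRANSFORMS: list[tuple[str, Callable[[np.ndarray], np.ndarray]]] = [
    ("id", lambda a: a),
    ("hm", np.fliplr),
    ("vm", np.flipud),
    ("r90", lambda a: np.rot90(a, 1)),
    ("r180", _rot180),
    ("r270", lambda a: np.rot90(a, 3)),
    ("tr", np.transpose),
]

# Non-square rasters cannot take 90/270/transpose without changing shape;
# those slots become 180-degree-composed mirror variants so every pair still
# yields exactly 7 outputs of the original shape.
RECT_TRANSFORMS: list[tuple[str, Callable[[np.ndarray], np.ndarray]]] = [
    ("id", lambda a: a),
    ("hm", np.fliplr),
    ("vm", np.flipud),
    ("r90", lambda a: _rot180(np.fliplr(a))),
    ("r180", _rot180),
    ("r270", lambda a: _rot180(np.flipud(a))),
    ("tr", lambda a: _rot180(_rot180(a))),
]


def augment(pairs: Sequence[SamplePair]) -> list[SamplePair]:
    """Expand each pair into its 7 mirror/rotation variants (x7 exactly).

    The identical isometry is applied to image and mask; ids gain the
    transform name as a suffix.  80 pairs become 560, 369 become 2583.
    """
    pairs = list(pairs)
    if not pairs:
        raise DomainError("cannot augment an empty dataset")
    out = []
    for pair in pairs:
        square = pair.image.shape[0] == pair.image.shape[1]
        transforms = SQUARE_TRANSFORMS if square else RECT_TRANSFORMS
        for name, f in transforms:
            out.append(SamplePair(image=np.ascontiguousarray(f(pair.image)),
                                  mask=np.ascontiguousarray(f(pair.mask)),
                                  id=f"{pair.id}_{name}"))
    return out
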