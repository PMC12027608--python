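"""Raster I/O, 60/10/30 splitting, and the x7 dihedral augmentation."""

import numpy as np
import pytest

from angioseg.data import (ConfigurationError, DomainError, FormatError,
                           PairingError, SamplePair, augment, load_pair,
                           save_gray, split_dataset)
from angioseg.metrics import confusion


# ----------------------------------------------------------------------- I/O
def test_pgm_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    raw = rng.integers(0, 256, size=(300, 300)).astype(np.uint8)
    mask = (rng.random((300, 300)) < 0.1).astype(np.uint8)
    save_gray(tmp_path / "img.pgm", raw)
    save_gray(tmp_path / "msk.pgm", mask)
    pair = load_pair(tmp_path / "img.pgm", tmp_path / "msk.pgm")
    assert np.array_equal(np.round(pair.image * 255).astype(np.uint8), raw)
    assert np.array_equal(pair.mask, mask)


def test_full_scale_image_normalizes_to_one(tmp_path):
    save_gray(tmp_path / "img.pgm", np.full((8, 8), 255, dtype=np.uint8))
    save_gray(tmp_path / "msk.pgm", np.zeros((8, 8), dtype=np.uint8))
    pair = load_pair(tmp_path / "img.pgm", tmp_path / "msk.pgm")
    assert np.all(pair.image == 1.0)


def test_mask_binarized_with_identical_support(tmp_path):
    mask255 = np.zeros((10, 10), dtype=np.uint8)
    mask255[2:5, 3:7] = 255
    save_gray(tmp_path / "img.pgm", np.full((10, 10), 128, dtype=np.uint8))
    save_gray(tmp_path / "msk.pgm", mask255)
    pair = load_pair(tmp_path / "img.pgm", tmp_path / "msk.pgm")
    assert set(np.unique(pair.mask)) <= {0, 1}
    assert np.array_equal(pair.mask == 1, mask255 == 255)


def test_ascii_pgm_dialect_readable(tmp_path):
    # plain (P2) dialect, written by hand
    text = "P2\n4 2\n255\n0 64 128 255\n255 128 64 0\n"
    (tmp_path / "a.pgm").write_text(text)
    (tmp_path / "m.pgm").write_text("P2\n4 2\n255\n0 0 255 255\n0 0 0 0\n")
    pair = load_pair(tmp_path / "a.pgm", tmp_path / "m.pgm")
    assert pair.image[0, 3] == 1.0 and pair.image[0, 0] == 0.0
    assert pair.mask.sum() == 2


def test_size_mismatch_and_color_rejected(tmp_path):
    save_gray(tmp_path / "img.pgm", np.zeros((8, 8), dtype=np.uint8))
    save_gray(tmp_path / "msk.pgm", np.zeros((9, 9), dtype=np.uint8))
    with pytest.raises(PairingError):
        load_pair(tmp_path / "img.pgm", tmp_path / "msk.pgm")
    from PIL import Image
    Image.new("RGB", (8, 8), (10, 20, 30)).save(tmp_path / "color.png")
    with pytest.raises(FormatError):
        load_pair(tmp_path / "color.png", tmp_path / "color.png")


# -------------------------------------------------------------------- splits
@pytest.mark.parametrize("n, sizes", [
    (134, (80, 13, 41)),
    (616, (369, 61, 186)),
    (10, (6, 1, 3)),
    (3, (1, 0, 2)),
])
def test_split_sizes_floor_rule(n, sizes):
    assert split_dataset(n, seed=0).sizes() == sizes


@pytest.mark.parametrize("n", [3, 7, 34, 134, 616, 1001])
def test_split_disjoint_exhaustive_and_seeded(n):
    a = split_dataset(n, seed=5)
    b = split_dataset(n, seed=5)
    c = split_dataset(n, seed=6)
    assert (a.train, a.val, a.test) == (b.train, b.val, b.test)
    assert c.sizes() == a.sizes()
    pool = a.train + a.val + a.test
    assert sorted(pool) == list(range(n)) and len(set(pool)) == n


def test_split_validation():
    with pytest.raises(DomainError):
        split_dataset(2)
    with pytest.raises(ConfigurationError):
        split_dataset(10, ratios=(0.5, 0.2, 0.2))


# -------------------------------------------------------------- augmentation
def _tiny_pair(h=4, w=4):
    img = np.linspace(0, 1, h * w).reshape(h, w)
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[0, 1] = 1  # asymmetric single vessel pixel
    return SamplePair(image=img, mask=mask, id="p")


@pytest.mark.parametrize("n_in, n_out", [(80, 560), (369, 2583), (1, 7)])
def test_augmentation_multiplies_by_seven(n_in, n_out):
    pairs = [_tiny_pair() for _ in range(n_in)]
    assert len(augment(pairs)) == n_out


def test_augmented_single_pixel_supports_match_coordinate_oracle():
    h = w = 4
    out = {p.id.split("_")[-1]: p for p in augment([_tiny_pair(h, w)])}
    r, c = 0, 1
    expected = {  # brute-force coordinate mapping of (r, c) on an HxW grid
        "id": (r, c),
        "hm": (r, w - 1 - c),
        "vm": (h - 1 - r, c),
        "r90": (w - 1 - c, r),
        "r180": (h - 1 - r, w - 1 - c),
        "r270": (c, h - 1 - r),
        "tr": (c, r),
    }
    assert set(out) == set(expected)
    for name, coord in expected.items():
        support = [tuple(ix) for ix in np.argwhere(out[name].mask == 1)]
        assert support == [coord], name


def test_augmentation_preserves_shape_and_pixel_counts_nonsquare():
    img = np.random.default_rng(0).random((6, 9))
    mask = (img < 0.2).astype(np.uint8)
    out = augment([SamplePair(image=img, mask=mask, id="r")])
    assert len(out) == 7
    for p in out:
        assert p.image.shape == (6, 9)
        assert p.mask.sum() == mask.sum()  # isometries preserve vessel count


def test_image_and_mask_co_transformed(rng):
    pred = (rng.random((8, 8)) < 0.3).astype(np.uint8)
    truth = (rng.random((8, 8)) < 0.3).astype(np.uint8)
    base = confusion(pred, truth)
    aug_p = augment([SamplePair(image=pred.astype(float), mask=pred, id="a")])
    aug_t = augment([SamplePair(image=truth.astype(float), mask=truth, id="a")])
    for ap, at in zip(aug_p, aug_t):
        assert confusion(ap.mask, at.mask) == base


def test_augment_rejects_empty():
    with pytest.raises(DomainError):
        augment([])
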