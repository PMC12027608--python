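"""Synthetic X-ray angiogram phantoms.

An original generator that emulates the qualitative look of contrast-enhanced
coronary X-ray frames: a dark, tree-structured vessel with tapering widths
and bifurcations on a brighter background, degraded along five axes —
low signal-to-noise zones, an interfering catheter-like curve (excluded from
the ground-truth mask), non-uniform illumination, additive Gaussian noise,
and junction/bifurcation geometry.  Every other module is testable against
these phantoms without external downloads.

Vessel centerlines are seeded random walks with probabilistic branching;
half-widths taper along each branch and shrink by ``width_decay`` per branch
generation.  The mask is the union of disks stamped along the centerlines.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import SamplePair, save_gray


class GenerationError(RuntimeError):
    """The phantom could not be generated within the bounded retry budget."""


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic angiogram/mask pair.

    ``vessel_contrast`` is the intensity gap between background and vessel
    core before degradation; ``illum_amplitude`` modulates a low-frequency
    multiplicative illumination field; ``frac_band`` is the admissible vessel
    pixel fraction (the class imbalance the metrics must handle).
    """

    size: tuple = (300, 300)
    n_primary_branches: int = 3
    branch_prob: float = 0.02
    max_branches: int = 16
    width_root: float = 4.0
    width_decay: float = 0.7
    vessel_contrast: float = 0.45
    noise_sigma: float = 0.05
    illum_amplitude: float = 0.15
    catheter: bool = True
    low_snr_zone: bool = True
    background: float = 0.80
    frac_band: tuple = (0.01, 0.15)
    max_generations: int = 3
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError(f"size must be at least 32x32, got {self.size}")
        if self.width_root < 1:
            raise ValueError("width_root must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def spec_for_size(size: tuple, seed: int = 0, **overrides) -> SynthSpec:
    """Defaults scaled to the raster size so the vessel fraction stays in
    band: branch widths shrink proportionally below the 300-pixel scale and
    small frames carry two instead of three primary branches."""
    scale = min(size) / 300.0
    params = dict(size=size, seed=seed,
                  width_root=max(1.5, 4.0 * scale),
                  n_primary_branches=3 if min(size) >= 150 else 2)
    params.update(overrides)
    return SynthSpec(**params)


def easy_spec(seed: int = 0, size: tuple = (64, 64)) -> SynthSpec:
    """A high-contrast, zero-noise phantom spec for quick learnability runs."""
    return SynthSpec(size=size, n_primary_branches=2, branch_prob=0.03,
                     width_root=2.0, vessel_contrast=0.6, noise_sigma=0.0,
                     illum_amplitude=0.0, catheter=False, low_snr_zone=False,
                     seed=seed)


@dataclass
class Branch:
    """One vessel segment: centerline points with per-point half-widths."""

    points: list  # of (row, col) floats
    radii: list   # of floats
    generation: int


def _grow_tree(rng: np.random.Generator, spec: SynthSpec) -> list[Branch]:
    """Random-walk centerline tree with seeded branching and width tapering."""
    h, w = spec.size
    scale = min(h, w)
    step = max(1.0, scale / 200.0)
    max_steps = int(1.4 * max(h, w) / step)
    branches: list[Branch] = []
    # primary roots start on a border heading inward
    stack = []
    for _ in range(spec.n_primary_branches):
        side = rng.integers(4)
        if side == 0:
            pos, heading = (0.0, rng.uniform(0.1, 0.9) * w), rng.uniform(0.25, 0.75) * np.pi
        elif side == 1:
            pos, heading = (h - 1.0, rng.uniform(0.1, 0.9) * w), -rng.uniform(0.25, 0.75) * np.pi
        elif side == 2:
            pos, heading = (rng.uniform(0.1, 0.9) * h, 0.0), rng.uniform(-0.25, 0.25) * np.pi
        else:
            pos, heading = (rng.uniform(0.1, 0.9) * h, w - 1.0), np.pi + rng.uniform(-0.25, 0.25) * np.pi
        stack.append((pos, heading, float(spec.width_root), 1, max_steps))
    spawned_child = False
    while stack:
        (r, c), heading, w0, gen, steps = stack.pop()
        pts, radii = [], []
        for s in range(steps):
            taper = 1.0 - 0.4 * s / max(1, steps)
            rad = max(0.7, w0 * taper)
            pts.append((r, c))
            radii.append(rad)
            heading += rng.normal(0.0, 0.12)
            r += step * np.sin(heading)
            c += step * np.cos(heading)
            if not (-2 <= r < h + 2 and -2 <= c < w + 2):
                break
            if (gen < spec.max_generations and s > 5
                    and len(branches) + len(stack) < spec.max_branches
                    and rng.random() < spec.branch_prob):
                sign = 1.0 if rng.random() < 0.5 else -1.0
                child_heading = heading + sign * rng.uniform(0.35, 0.9)
                stack.append(((r, c), child_heading, w0 * taper * spec.width_decay,
                              gen + 1, int(steps * 0.6)))
                spawned_child = True
        if pts:
            branches.append(Branch(points=pts, radii=radii, generation=gen))
    # guarantee at least one bifurcation when branching is enabled
    if spec.branch_prob > 0 and not spawned_child and branches:
        parent = branches[0]
        if len(parent.points) >= 20:
            mid = len(parent.points) // 2
            (r, c) = parent.points[mid]
            rad = parent.radii[mid]
            heading = rng.uniform(0, 2 * np.pi)
            pts, radii = [], []
            steps = len(parent.points) // 2
            for s in range(steps):
                pts.append((r, c))
                radii.append(max(0.7, rad * spec.width_decay * (1 - 0.4 * s / steps)))
                heading += rng.normal(0.0, 0.12)
                r += step * np.sin(heading)
                c += step * np.cos(heading)
                if not (-2 <= r < h + 2 and -2 <= c < w + 2):
                    break
            if pts:
                branches.append(Branch(points=pts, radii=radii,
                                       generation=parent.generation + 1))
    return branches


def _stamp_disk(mask: np.ndarray, r: float, c: float, rad: float) -> None:
    h, w = mask.shape
    r0, r1 = max(0, int(np.floor(r - rad))), min(h, int(np.ceil(r + rad)) + 1)
    c0, c1 = max(0, int(np.floor(c - rad))), min(w, int(np.ceil(c + rad)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2


def rasterize(branches: list[Branch], size: tuple) -> np.ndarray:
    """Union of disks along every centerline; the binary ground-truth mask."""
    mask = np.zeros(size, dtype=bool)
    for br in branches:
        for (r, c), rad in zip(br.points, br.radii):
            _stamp_disk(mask, r, c, rad)
    return mask.astype(np.uint8)


_MAX_ATTEMPTS = 8


def _grow_valid_tree(rng: np.random.Generator, spec: SynthSpec):
    """Grow trees from the running seed stream until the rasterized vessel
    fraction falls inside ``spec.frac_band``; bounded retries."""
    lo, hi = spec.frac_band
    for _ in range(_MAX_ATTEMPTS):
        branches = _grow_tree(rng, spec)
        mask = rasterize(branches, spec.size)
        if branches and lo <= mask.mean() <= hi:
            return branches, mask
    raise GenerationError(
        f"no admissible vessel tree in {_MAX_ATTEMPTS} attempts "
        f"(band {spec.frac_band}, seed {spec.seed})")


def centerline_tree(spec: SynthSpec) -> list[Branch]:
    """The exact centerline tree that :func:`generate_pair` rasterizes."""
    branches, _ = _grow_valid_tree(np.random.default_rng(spec.seed), spec)
    return branches


def _catheter_curve(rng: np.random.Generator, size: tuple) -> np.ndarray:
    """A smooth quadratic distractor curve spanning the frame."""
    h, w = size
    p0 = np.array([rng.uniform(0, 0.2) * h, rng.uniform(0, w - 1)])
    p2 = np.array([rng.uniform(0.8, 1.0) * h, rng.uniform(0, w - 1)])
    p1 = np.array([rng.uniform(0.3, 0.7) * h, rng.uniform(0, w - 1)])
    t = np.linspace(0, 1, 4 * max(h, w))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    curve = np.zeros(size, dtype=bool)
    rad = max(1.2, min(h, w) / 180.0)
    for r, c in pts:
        _stamp_disk(curve, r, c, rad)
    return curve


def generate_pair(spec: SynthSpec) -> SamplePair:
    """One synthetic angiogram and its ground-truth vessel mask.

    Deterministic in ``spec.seed``: the same spec always returns bit-identical
    arrays.  The catheter distractor darkens the image but never enters the
    mask.  The image is clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    branches, mask = _grow_valid_tree(rng, spec)
    h, w = spec.size

    image = np.full(spec.size, spec.background, dtype=np.float64)
    if spec.illum_amplitude > 0:
        field = gaussian_filter(rng.standard_normal(spec.size), sigma=min(h, w) / 4.0)
        peak = np.abs(field).max()
        if peak > 0:
            image *= 1.0 + spec.illum_amplitude * field / peak

    soft = gaussian_filter(mask.astype(np.float64), sigma=0.8)
    if soft.max() > 0:
        soft /= soft.max()
    damp = np.ones(spec.size)
    if spec.low_snr_zone:
        zr = rng.uniform(0.35, 0.65) * h
        zc = rng.uniform(0.35, 0.65) * w
        zrad = rng.uniform(0.15, 0.30) * min(h, w)
        rr, cc = np.ogrid[:h, :w]
        zone = (rr - zr) ** 2 + (cc - zc) ** 2 <= zrad**2
        damp[zone] = 0.45
    image -= spec.vessel_contrast * damp * soft

    if spec.catheter:
        curve = _catheter_curve(rng, spec.size)
        csoft = gaussian_filter(curve.astype(np.float64), sigma=0.8)
        if csoft.max() > 0:
            csoft /= csoft.max()
        image -= 0.5 * spec.vessel_contrast * csoft

    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, spec.size)

    return SamplePair(image=np.clip(image, 0.0, 1.0), mask=mask,
                      id=f"synth_{spec.seed}")


def generate_dataset(spec: SynthSpec, n: int, out_dir: str | Path) -> list[dict]:
    """Write ``n`` pairs (per-pair seeds ``spec.seed + i``) in the standard
    dataset layout (``images/``, ``masks/``) plus a manifest CSV."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = []
    for i in range(n):
        pair_spec = replace(spec, seed=spec.seed + i)
        pair = generate_pair(pair_spec)
        pid = f"synth_{i:04d}"
        save_gray(out_dir / "images" / f"{pid}.pgm", pair.image)
        save_gray(out_dir / "masks" / f"{pid}.pgm", pair.mask)
        manifest.append({"id": pid, "seed": pair_spec.seed,
                         "vessel_fraction": float(pair.mask.mean())})
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "seed", "vessel_fraction"])
        writer.writeheader()
        writer.writerows(manifest)
    return manifest


def threshold_baseline(image: np.ndarray, t: float = 0.55) -> np.ndarray:
    """Fixed intensity-threshold segmenter: vessel where the image is darker
    than ``t``.  The reference point for difficulty ordering."""
    return (np.asarray(image) < t).astype(np.uint8)
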