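"""Synthetic fundus-angiogram phantoms with grouped "homologous image" structure.

The clinical setting this emulates: several angiographic frames per eye, all
showing the same anatomy (optic disc, macula, vessel arcades) but differing in
translation, rotation and illumination between frames. Images from the same eye
are *homologous*; frames from different eyes are not. The generator renders one
base phantom per simulated eye — bright fluorescing vessels branching out of a
bright disc over a darker fundus, a dark macular region, a smooth illumination
gradient and sensor noise — and derives group members as seeded geometric /
photometric perturbations of the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import Image, ImagePair, degrade

__all__ = ["PhantomParams", "GroupedDataset", "generate_phantom", "generate_grouped_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    """Rendering parameters for one fundus phantom.

    Intensity levels are on the normalized [0, 1] scale; geometry in pixels.
    """

    image_size: int = 128
    n_vessels: int = 5
    vessel_width_range: tuple[float, float] = (1.5, 4.0)
    disc_radius: float = 16.0
    background_gradient: float = 0.08
    noise_sigma: float = 0.01
    seed: int = 0
    background_level: float = 0.22
    disc_level: float = 0.85
    macula_level: float = 0.08
    vessel_level: float = 0.68

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.vessel_width_range[0] < 1:
            raise ValueError("vessel widths must be >= 1 pixel")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")


def _paint_disk(mask: np.ndarray, cy: float, cx: float, radius: float) -> None:
    size = mask.shape[0]
    r0 = max(int(cy - radius) - 1, 0)
    r1 = min(int(cy + radius) + 2, size)
    c0 = max(int(cx - radius) - 1, 0)
    c1 = min(int(cx + radius) + 2, size)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    """Dense samples of a quadratic Bezier curve (n, 2)."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _paint_vessel(mask, rng, start, direction, length, width, depth) -> None:
    """Recursively paint a branching vessel as stamped quadratic Bezier curves."""
    if depth > 2 or width < 0.8 or length < 4:
        return
    bend = rng.uniform(-0.7, 0.7)
    perp = np.array([-direction[1], direction[0]])
    p0 = np.asarray(start, dtype=float)
    p2 = p0 + direction * length
    p1 = p0 + direction * (length / 2) + perp * bend * length * 0.3
    pts = _bezier_points(p0, p1, p2, max(int(length * 2), 8))
    for y, x in pts:
        _paint_disk(mask, y, x, width / 2.0)
    # branch into two children with shrunken widths
    for sign in (-1.0, 1.0):
        angle = rng.uniform(0.25, 0.7) * sign
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        child_dir = rot @ direction
        child_dir /= np.linalg.norm(child_dir)
        _paint_vessel(
            mask,
            rng,
            p2,
            child_dir,
            length * rng.uniform(0.55, 0.8),
            width * rng.uniform(0.55, 0.75),
            depth + 1,
        )


def generate_phantom(params: PhantomParams, return_vessel_mask: bool = False):
    """Render one fundus phantom; deterministic for a fixed seed.

    Layers, painted in order with hard edges: illumination-graded background,
    bright optic disc, dark macula, bright branching vessel tree radiating from
    the disc, then additive Gaussian noise clipped to [0, 1]. Per-vessel
    randomness comes from spawned seed streams, so with a fixed seed the first
    ``k`` vessels are identical regardless of ``n_vessels`` — raising the
    vessel count only ever adds painted pixels.
    """
    p = params
    n = p.image_size
    root = np.random.SeedSequence(p.seed)
    layout_seq, noise_seq, *vessel_seqs = root.spawn(2 + max(p.n_vessels, 1))
    rng = np.random.default_rng(layout_seq)

    img = np.full((n, n), p.background_level)
    if p.background_gradient > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:n, 0:n] / (n - 1)
        ramp = np.cos(theta) * yy + np.sin(theta) * xx
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
        img += p.background_gradient * (ramp - 0.5)
    else:
        rng.uniform(0, 2 * np.pi)  # keep the stream aligned across configs

    # optic disc on the nasal side, macula near center
    disc_c = np.array([n * rng.uniform(0.4, 0.6), n * rng.uniform(0.18, 0.3)])
    disc_mask = np.zeros((n, n), dtype=bool)
    _paint_disk(disc_mask, disc_c[0], disc_c[1], p.disc_radius)
    img[disc_mask] = p.disc_level

    mac_c = np.array([n * rng.uniform(0.42, 0.58), n * rng.uniform(0.6, 0.75)])
    mac_mask = np.zeros((n, n), dtype=bool)
    _paint_disk(mac_mask, mac_c[0], mac_c[1], p.disc_radius * 0.8)
    img[mac_mask] = p.macula_level

    vessel_mask = np.zeros((n, n), dtype=bool)
    for i in range(p.n_vessels):
        vrng = np.random.default_rng(vessel_seqs[i])
        angle = vrng.uniform(0, 2 * np.pi)
        direction = np.array([np.sin(angle), np.cos(angle)])
        # arcades leave the disc rim and head away from it
        start = disc_c + direction * p.disc_radius * 0.9
        _paint_vessel(
            vessel_mask,
            vrng,
            start,
            direction,
            length=vrng.uniform(0.25, 0.45) * n,
            width=vrng.uniform(*p.vessel_width_range),
            depth=0,
        )
    img[vessel_mask] = p.vessel_level

    if p.noise_sigma > 0:
        img = img + np.random.default_rng(noise_seq).normal(0.0, p.noise_sigma, (n, n))
    out = Image(np.clip(img, 0.0, 1.0))
    if return_vessel_mask:
        return out, vessel_mask
    return out


@dataclass
class GroupedDataset:
    """Eye-grouped phantom images with a per-group train/test split.

    ``groups`` holds every rendered image; ``train_pairs`` / ``test_pairs``
    are their degraded HR/LR pairs. ``group_ids`` parallel the pair lists so a
    test image can be traced back to its eye.
    """

    groups: list[list[Image]]
    train_pairs: list[ImagePair]
    test_pairs: list[ImagePair]
    train_group_ids: list[int]
    test_group_ids: list[int]
    factor: int
    split_ratio: tuple[int, int]
    excluded_groups: list[int] = field(default_factory=list)


def _perturb(base: Image, rng, translation: float, rotation: float, illum: tuple[float, float]) -> Image:
    px = base.pixels
    angle = rng.uniform(-rotation, rotation)
    shift = rng.uniform(-translation, translation, size=2)
    scale = rng.uniform(*illum)
    out = ndimage.rotate(px, angle, reshape=False, order=3, mode="reflect")
    out = ndimage.shift(out, shift, order=3, mode="reflect")
    return Image(np.clip(out * scale, 0.0, 1.0))


def generate_grouped_dataset(
    n_groups: int = 10,
    per_group: int = 4,
    factor: int = 2,
    image_size: int = 128,
    translation: float = 5.0,
    rotation: float = 3.0,
    illumination: tuple[float, float] = (0.9, 1.1),
    split_ratio: tuple[int, int] = (23, 14),
    seed: int = 0,
    exclude_groups_from_train: list[int] | None = None,
    phantom_kwargs: dict | None = None,
) -> GroupedDataset:
    """Generate ``n_groups`` eyes x ``per_group`` homologous frames, split per group.

    Each group member is the group's base phantom under a random translation
    (<= ``translation`` px), rotation (<= ``rotation`` deg) and multiplicative
    illumination change, then degraded to an HR/LR pair at ``factor``. The
    per-group train share is ``round(per_group * a / (a + b))`` for
    ``split_ratio = (a, b)``; groups listed in ``exclude_groups_from_train``
    drop their train share and appear only through their test images.
    """
    if n_groups < 1 or per_group < 2:
        raise ValueError("need n_groups >= 1 and per_group >= 2")
    excluded = sorted(set(exclude_groups_from_train or []))
    if len(excluded) >= n_groups:
        raise ValueError("excluding every group leaves an empty training set")
    a, b = split_ratio
    n_train = int(round(per_group * a / (a + b)))
    n_train = min(max(n_train, 1), per_group - 1)

    root = np.random.SeedSequence(seed)
    group_seqs = root.spawn(n_groups)
    groups: list[list[Image]] = []
    train_pairs: list[ImagePair] = []
    test_pairs: list[ImagePair] = []
    train_ids: list[int] = []
    test_ids: list[int] = []
    pk = dict(phantom_kwargs or {})
    pk.setdefault("image_size", image_size)
    for g in range(n_groups):
        base_seq, perturb_seq = group_seqs[g].spawn(2)
        base = generate_phantom(
            PhantomParams(seed=int(base_seq.generate_state(1)[0] % (2**31)), **pk)
        )
        prng = np.random.default_rng(perturb_seq)
        members = [
            _perturb(base, prng, translation, rotation, illumination)
            for _ in range(per_group)
        ]
        groups.append(members)
        for i, member in enumerate(members):
            pair = degrade(member, factor)
            if i < n_train:
                if g not in excluded:
                    train_pairs.append(pair)
                    train_ids.append(g)
            else:
                test_pairs.append(pair)
                test_ids.append(g)
    return GroupedDataset(
        groups=groups,
        train_pairs=train_pairs,
        test_pairs=test_pairs,
        train_group_ids=train_ids,
        test_group_ids=test_ids,
        factor=factor,
        split_ratio=(a, b),
        excluded_groups=excluded,
    )
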