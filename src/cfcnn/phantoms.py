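"""Synthetic CT nodule phantoms with exact ground truth.

The generator builds the local intensity structure the segmentation method
actually consumes — a bright roughly-ellipsoidal nodule in a dark lung
field, optionally attached to a high-intensity chest-wall slab or a
cylindrical vessel — rather than anatomically realistic lungs. Five nodule
appearances are emulated:

* ``isolated``   — solid nodule surrounded by lung field;
* ``juxtapleural`` — nodule touching a wall slab of similar intensity;
* ``cavitary``   — nodule with an internal air cavity; the cavity voxels
  stay inside the ground-truth mask (a cavity belongs to its nodule);
* ``calcific``   — nodule with a very bright calcified core;
* ``ggo``        — ground-glass opacity: nodule/lung contrast scaled down.

Default intensity levels are HU-like: lung field -800, solid nodule -50,
chest wall 30, calcification 300, with additive Gaussian noise of 20 HU.
Everything is deterministic given the config (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, GeometryError
from .volumes import BoundingBox2D, CtVolume, NoduleMask, clip_box

KINDS = ("isolated", "juxtapleural", "cavitary", "calcific", "ggo")


@dataclass(frozen=True)
class PhantomConfig:
    nodule_kind: str = "isolated"
    radius_vox: float = 6.0
    center: tuple[int, int, int] = (16, 32, 32)
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_level: float = -800.0
    nodule_level: float = -50.0
    wall_level: float = 30.0
    calcific_level: float = 300.0
    contrast_scale: float = 0.25  # ggo only: fraction of full nodule/lung contrast
    cavity_radius_frac: float = 0.5
    noise_sd: float = 20.0
    vessel: bool = False
    vessel_radius_vox: float = 1.5
    shape: tuple[int, int, int] = (32, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nodule_kind not in KINDS:
            raise ConfigError(f"unknown nodule kind {self.nodule_kind!r}")
        if self.radius_vox <= 0:
            raise ConfigError("radius_vox must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 < self.cavity_radius_frac < 1:
            raise ConfigError("cavity_radius_frac must be in (0, 1)")
        if not 0 < self.contrast_scale <= 1:
            raise ConfigError("contrast_scale must be in (0, 1]")


@dataclass
class PhantomSample:
    volume: CtVolume
    mask: NoduleMask
    start_box: BoundingBox2D
    config: PhantomConfig


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Build one phantom volume, its ground-truth mask and a start box."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    cz, cy, cx = config.center
    semi = tuple(config.radius_vox * r for r in config.axis_ratios)
    for c, a, s in zip(config.center, semi, shape):
        if c - a < 0 or c + a > s - 1:
            raise GeometryError(
                f"nodule (center {config.center}, semi-axes {semi}) "
                f"does not fit inside volume {shape}"
            )

    vox = np.full(shape, config.lung_level, dtype=float)
    nodule_level = config.nodule_level
    if config.nodule_kind == "ggo":
        nodule_level = config.lung_level + config.contrast_scale * (
            config.nodule_level - config.lung_level
        )

    mask = _ellipsoid(shape, config.center, semi)

    if config.nodule_kind == "juxtapleural":
        # wall slab along the high-col side, shifted to touch the nodule
        wall_start = int(round(cx + semi[2]))
        wall_start = min(wall_start, shape[2] - 1)
        vox[:, :, wall_start:] = config.wall_level
        mask &= ~(np.arange(shape[2])[None, None, :] >= wall_start)
        if not mask.any():
            raise GeometryError("wall slab swallowed the whole nodule")

    vox[mask] = nodule_level

    if config.nodule_kind == "cavitary":
        cavity = _ellipsoid(
            shape, config.center, tuple(a * config.cavity_radius_frac for a in semi)
        )
        vox[cavity] = config.lung_level  # air pocket; mask keeps these voxels
    elif config.nodule_kind == "calcific":
        core = _ellipsoid(shape, config.center, tuple(a * 0.5 for a in semi))
        vox[core] = config.calcific_level

    if config.vessel:
        # a col-axis cylinder tangent to the nodule's upper edge
        gz, gy = np.ogrid[: shape[0], : shape[1]]
        vr = config.vessel_radius_vox
        d2 = ((gz - cz) / vr) ** 2 + ((gy - (cy - semi[1])) / vr) ** 2
        cyl = np.broadcast_to((d2 <= 1.0)[:, :, None], shape)
        vox[cyl & ~mask] = config.nodule_level

    if config.noise_sd > 0:
        vox = vox + rng.normal(0.0, config.noise_sd, size=shape)

    footprint = mask[cz]
    rows = np.flatnonzero(footprint.any(axis=1))
    cols = np.flatnonzero(footprint.any(axis=0))
    margin = 4
    box = clip_box(
        BoundingBox2D(
            slice_index=cz,
            row_start=int(rows[0]) - margin,
            row_stop=int(rows[-1]) + 1 + margin,
            col_start=int(cols[0]) - margin,
            col_stop=int(cols[-1]) + 1 + margin,
        ),
        shape,
    )
    volume = CtVolume(
        voxels=vox,
        spacing=config.spacing,
        volume_id=f"phantom-{config.nodule_kind}-{config.seed}",
    )
    return PhantomSample(
        volume=volume,
        mask=NoduleMask(mask.astype(np.uint8)),
        start_box=box,
        config=config,
    )


def generate_cohort(
    n: int,
    kind_mix: dict[str, float],
    base_config: PhantomConfig = PhantomConfig(),
    seed: int = 0,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with kinds, radii and centres jittered.

    Kinds are a seeded draw from ``kind_mix`` (proportions summing to 1);
    radii are jittered uniformly by +/-20% and centres by up to 3 voxels in
    plane, all from one seeded stream, so the same (n, mix, base, seed)
    always yields the same cohort.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if not kind_mix:
        raise ConfigError("kind_mix must be nonempty")
    kinds = sorted(kind_mix)
    probs = np.array([kind_mix[k] for k in kinds], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError("kind_mix proportions must be >= 0 and sum to 1")
    for k in kinds:
        if k not in KINDS:
            raise ConfigError(f"unknown nodule kind {k!r}")

    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(kinds), size=n, p=probs)
    samples = []
    for i, ki in enumerate(drawn):
        radius = base_config.radius_vox * rng.uniform(0.8, 1.2)
        jitter = rng.integers(-3, 4, size=2)
        center = (
            base_config.center[0],
            int(base_config.center[1] + jitter[0]),
            int(base_config.center[2] + jitter[1]),
        )
        cfg = replace(
            base_config,
            nodule_kind=kinds[ki],
            radius_vox=float(radius),
            center=center,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sample = generate_phantom(cfg)
        sample.volume.volume_id = f"phantom-{i:03d}-{kinds[ki]}"
        samples.append(sample)
    return samples
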