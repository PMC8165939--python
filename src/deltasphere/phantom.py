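"""Synthetic spheroid phantoms with ground truth.

Emulates the phenomenology of hiPSC spheroids in phase contrast: a
self-renewing ("round") spheroid grows as a disk; a differentiating
("branched") spheroid is identical until a branch-onset timepoint, after
which elliptical lobes bud outward along fixed random axes. Phase-contrast
appearance is approximated as a dark interior with a bright moving rim;
static artifacts (a bright background halo ring plus dust specks) and
per-frame Gaussian noise are overlaid. Artifacts are identical in every
frame, so they cancel exactly under frame-to-frame subtraction — the
property the segmentation method relies on.

All randomness derives from ``PhantomConfig.seed`` via independent spawned
streams (jitter, dust, lobe angles, noise), so a round and a branched
phantom that share a seed and core geometry are pixel-identical before the
branch onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .io_plate import FrameSeries, PlateLayout

Phenotype = Literal["round", "branched"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and noise parameters of one phantom well.

    Units: lengths in pixels, intensities in native (integer) gray levels,
    rates in pixels per timepoint. Timepoints are 1-based; the disk radius at
    timepoint ``t`` is ``initial_radius + (t - 1) * growth_rate``.
    """

    image_size: tuple[int, int] = (256, 256)
    n_timepoints: int = 96
    initial_radius: float = 12.0
    growth_rate: float = 0.5
    phenotype: Phenotype = "round"
    n_branches: int = 3
    branch_onset: int = 20
    branch_growth_rate: float = 0.6
    foreground_level: int = 80
    background_level: int = 180
    halo_amplitude: int = 40
    halo_radius: float | None = None  # None -> just outside the final extent
    dust_count: int = 30
    noise_sd: float = 2.0
    jitter_sd: float = 0.5
    bit_depth: int = 8
    seed: int = 0

    @property
    def dtype(self) -> np.dtype:
        if self.bit_depth == 8:
            return np.dtype(np.uint8)
        if self.bit_depth == 16:
            return np.dtype(np.uint16)
        raise ValueError(f"unsupported bit depth {self.bit_depth}")

    @property
    def intensity_max(self) -> int:
        return int(2**self.bit_depth - 1)

    @property
    def final_radius(self) -> float:
        return self.initial_radius + (self.n_timepoints - 1) * self.growth_rate

    @property
    def max_extent(self) -> float:
        """Largest distance from the well centre the object can reach."""
        extent = self.final_radius
        if self.phenotype == "branched":
            extent += max(0, self.n_timepoints - self.branch_onset) * self.branch_growth_rate
        return extent

    def resolved_halo_radius(self) -> float:
        # a fixed fraction of the frame, deliberately independent of the
        # phenotype's geometry: matched round/branched phantoms must share an
        # identical static background or the classes would be trivially
        # separable by their artifacts
        if self.halo_radius is not None:
            return float(self.halo_radius)
        return 0.45 * min(self.image_size)

    def validate(self) -> None:
        h, w = self.image_size
        half = min(h, w) / 2
        if self.initial_radius + self.n_timepoints * self.growth_rate >= half:
            raise ValueError(
                "spheroid would outgrow the frame: initial_radius + "
                "n_timepoints*growth_rate must stay below half the image size"
            )
        if self.phenotype == "branched" and self.max_extent >= half:
            raise ValueError("branch lobes would outgrow the frame")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.phenotype not in ("round", "branched"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.phenotype == "branched" and self.n_branches < 1:
            raise ValueError("branched phenotype needs n_branches >= 1")
        if self.max_extent + 4 >= self.resolved_halo_radius():
            raise ValueError(
                "static halo ring would be overrun by the growing object; "
                "enlarge the image, shrink the growth, or set halo_radius"
            )


@dataclass
class GroundTruth:
    """Per-timepoint truth accompanying a phantom series."""

    masks: np.ndarray  # (T, H, W) bool foreground
    areas: np.ndarray  # (T,) int pixel counts
    centers: np.ndarray  # (T, 2) float (row, col) disk centres
    phenotype: str
    artifact_mask: np.ndarray  # (H, W) bool, static halo + dust pixels

    def __post_init__(self) -> None:
        counted = self.masks.reshape(self.masks.shape[0], -1).sum(axis=1)
        if not np.array_equal(counted, self.areas):
            raise ValueError("recorded areas disagree with mask pixel counts")


def _foreground_mask(
    cfg: PhantomConfig,
    timepoint: int,
    center: np.ndarray,
    lobe_angles: np.ndarray,
    rr: np.ndarray,
    cc: np.ndarray,
) -> np.ndarray:
    """True foreground at a 1-based timepoint: disk plus any grown lobes."""
    radius = cfg.initial_radius + (timepoint - 1) * cfg.growth_rate
    dr = rr - center[0]
    dc = cc - center[1]
    mask = dr * dr + dc * dc <= radius * radius
    if cfg.phenotype == "branched":
        lobe_len = cfg.branch_growth_rate * max(0, timepoint - cfg.branch_onset)
        if lobe_len > 0:
            half = lobe_len / 2.0
            width = 2.0 + 0.2 * lobe_len
            for theta in lobe_angles:
                u = np.array([np.sin(theta), np.cos(theta)])
                lobe_center = center + (radius + half) * u
                lr = rr - lobe_center[0]
                lc = cc - lobe_center[1]
                along = lr * u[0] + lc * u[1]
                across = -lr * u[1] + lc * u[0]
                a = half + 1.0
                mask |= (along / a) ** 2 + (across / width) ** 2 <= 1.0
    return mask


def _static_artifacts(
    cfg: PhantomConfig,
    base_center: np.ndarray,
    rng_dust: np.random.Generator,
    rr: np.ndarray,
    cc: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the static background layer; returns (image, artifact mask)."""
    h, w = cfg.image_size
    img = np.full((h, w), float(cfg.background_level))
    artifact = np.zeros((h, w), dtype=bool)

    d = np.hypot(rr - base_center[0], cc - base_center[1])
    halo_r = cfg.resolved_halo_radius()
    ring = np.abs(d - halo_r) <= 1.5
    img[ring] = min(cfg.intensity_max, cfg.background_level + cfg.halo_amplitude)
    artifact |= ring

    # dust specks sit beyond the halo ring — outside any possible object
    # extent and, like the halo, at phenotype-independent positions
    min_d = halo_r + 3.0
    placed = 0
    attempts = 0
    bright = min(cfg.intensity_max, cfg.background_level + 60)
    dark = max(0, cfg.background_level - 60)
    while placed < cfg.dust_count and attempts < cfg.dust_count * 50:
        attempts += 1
        r0 = rng_dust.uniform(1, h - 2)
        c0 = rng_dust.uniform(1, w - 2)
        if np.hypot(r0 - base_center[0], c0 - base_center[1]) <= min_d:
            continue
        if abs(np.hypot(r0 - base_center[0], c0 - base_center[1]) - halo_r) <= 4:
            continue
        speck = np.hypot(rr - r0, cc - c0) <= rng_dust.uniform(0.8, 1.8)
        img[speck] = bright if placed % 2 == 0 else dark
        artifact |= speck
        placed += 1
    return img, artifact


def generate_series(config: PhantomConfig) -> tuple[FrameSeries, GroundTruth]:
    """Render one phantom well as a FrameSeries plus its GroundTruth.

    The rng streams are spawned in a fixed order from ``config.seed``
    regardless of phenotype, so matched round/branched configs consume
    identical random sequences and agree pixel-for-pixel before the
    branch onset.
    """
    config.validate()
    h, w = config.image_size
    ss = np.random.SeedSequence(config.seed)
    s_jitter, s_dust, s_lobes, s_noise = ss.spawn(4)
    rng_jitter = np.random.default_rng(s_jitter)
    rng_dust = np.random.default_rng(s_dust)
    rng_lobes = np.random.default_rng(s_lobes)
    rng_noise = np.random.default_rng(s_noise)

    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    base_center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])  # true raster centre
    # lobe axes are drawn for every phantom (even round ones) so the two
    # phenotypes consume the same random streams
    start = rng_lobes.uniform(0, 2 * np.pi)
    angles = (start + np.arange(max(config.n_branches, 1)) * 2 * np.pi / max(config.n_branches, 1)) % (
        2 * np.pi
    )
    jitter = (
        rng_jitter.normal(0.0, config.jitter_sd, size=(config.n_timepoints, 2))
        if config.jitter_sd > 0
        else np.zeros((config.n_timepoints, 2))
    )

    static, artifact = _static_artifacts(config, base_center, rng_dust, rr, cc)
    rim_value = float(min(config.intensity_max, config.background_level + config.halo_amplitude))

    frames = np.empty((config.n_timepoints, h, w), dtype=config.dtype)
    masks = np.empty((config.n_timepoints, h, w), dtype=bool)
    centers = np.empty((config.n_timepoints, 2))
    for i in range(config.n_timepoints):
        tp = i + 1
        center = base_center + jitter[i]
        centers[i] = center
        mask = _foreground_mask(config, tp, center, angles, rr, cc)
        masks[i] = mask

        img = static.copy()
        # bright phase rim travelling with the object edge
        rim = _foreground_mask(
            replace(config, initial_radius=config.initial_radius + 2.0), tp, center, angles, rr, cc
        ) & ~mask
        img[rim] = rim_value
        img[mask] = float(config.foreground_level)

        if config.noise_sd > 0:
            img = img + rng_noise.normal(0.0, config.noise_sd, size=(h, w))
        frames[i] = np.clip(np.rint(img), 0, config.intensity_max).astype(config.dtype)

    series = FrameSeries(
        well_id="PH1",
        frames=frames,
        condition=config.phenotype,
        interval=1.0,
        t0_index=1,
    )
    truth = GroundTruth(
        masks=masks,
        areas=masks.reshape(config.n_timepoints, -1).sum(axis=1),
        centers=centers,
        phenotype=config.phenotype,
        artifact_mask=artifact,
    )
    return series, truth


def _well_ids(n: int, columns: tuple[int, ...]) -> list[str]:
    """Row-major well ids over the given plate columns (rows A..H, then on)."""
    rows = "ABCDEFGH"
    ids = []
    for col in columns:
        for row in rows:
            ids.append(f"{row}{col:02d}")
    if n > len(ids):
        raise ValueError(f"cannot place {n} wells in columns {columns}")
    # fill column-blocks row-major the way a multichannel pipette would
    ordered = [f"{row}{col:02d}" for row in rows for col in columns]
    return ordered[:n]


def generate_plate(
    config_round: PhantomConfig,
    config_branched: PhantomConfig,
    n_wells_per_condition: int = 18,
    base_seed: int = 0,
) -> tuple[list[FrameSeries], PlateLayout, list[GroundTruth]]:
    """Simulate a two-condition plate: round wells in columns 1-3, branched
    in columns 10-12 (mirroring a left/right plate layout), each well with a
    distinct seed derived from ``base_seed``."""
    if n_wells_per_condition < 1:
        raise ValueError("need at least one well per condition")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(2 * n_wells_per_condition)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    round_wells = _well_ids(n_wells_per_condition, (1, 2, 3))
    branched_wells = _well_ids(n_wells_per_condition, (10, 11, 12))

    series_list: list[FrameSeries] = []
    truths: list[GroundTruth] = []
    conditions: dict[str, str] = {}
    for i, well in enumerate(round_wells):
        cfg = replace(config_round, phenotype="round", seed=seeds[i])
        s, t = generate_series(cfg)
        s.well_id = well
        s.condition = "round"
        conditions[well] = "round"
        series_list.append(s)
        truths.append(t)
    for i, well in enumerate(branched_wells):
        cfg = replace(config_branched, phenotype="branched", seed=seeds[n_wells_per_condition + i])
        s, t = generate_series(cfg)
        s.well_id = well
        s.condition = "branched"
        conditions[well] = "branched"
        series_list.append(s)
        truths.append(t)
    return series_list, PlateLayout(conditions), truths
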