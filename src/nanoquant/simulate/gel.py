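"""Synthetic EMSA gel lanes and competition-uptake series.

A lane is a vertical strip with two horizontal bands rendered as Gaussian
intensity profiles: a shifted (protein-bound) band running high and an
unshifted (free-DNA) band running low.  A bound fraction f in [0, 1] of the
lane's total signal sits in the shifted band; the rest in the free band,
over a uniform background.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..datatypes import GelImage, LaneBox
from ..manifest import GroundTruthManifest, _jsonify


@dataclass
class GelConfig:
    seed: int = 0
    lane_width_px: int = 30
    lane_height_px: int = 350
    bound_fraction: float = 0.3
    total_signal: float = 50_000.0
    band_center_bound: int = 80
    band_center_unbound: int = 270
    band_sigma_px: float = 12.0
    background: float = 5.0
    noise_sd: float = 0.0
    pad_px: int = 10
    saturation_level: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must be in [0, 1]")
        if self.total_signal < 0 or self.background < 0 or self.noise_sd < 0:
            raise ValueError("signal, background and noise must be non-negative")


def simulate_gel_lane(config: GelConfig) -> tuple[GelImage, LaneBox, GroundTruthManifest]:
    rng = np.random.default_rng(config.seed)
    h = config.lane_height_px + 2 * config.pad_px
    w = config.lane_width_px + 2 * config.pad_px
    img = np.full((h, w), config.background, dtype=float)
    rows = np.arange(config.lane_height_px)

    def band_profile(center: int) -> np.ndarray:
        p = np.exp(-0.5 * ((rows - center) / config.band_sigma_px) ** 2)
        return p / p.sum()

    lane = (
        config.bound_fraction * config.total_signal * band_profile(config.band_center_bound)
        + (1.0 - config.bound_fraction)
        * config.total_signal
        * band_profile(config.band_center_unbound)
    ) / config.lane_width_px
    img[
        config.pad_px : config.pad_px + config.lane_height_px,
        config.pad_px : config.pad_px + config.lane_width_px,
    ] += lane[:, None]
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
        img = np.clip(img, 0, None)
    if config.saturation_level is not None:
        img = np.minimum(img, config.saturation_level)

    bw = int(3 * config.band_sigma_px)
    lane_box = LaneBox(
        x=config.pad_px,
        y=config.pad_px,
        width_px=config.lane_width_px,
        height_px=config.lane_height_px,
        bound_rows=(max(0, config.band_center_bound - bw), config.band_center_bound + bw),
        unbound_rows=(
            max(0, config.band_center_unbound - bw),
            min(config.lane_height_px, config.band_center_unbound + bw),
        ),
    )
    manifest = GroundTruthManifest(
        generator="gel_lane",
        config=_jsonify(config),
        truth={
            "bound_fraction": config.bound_fraction,
            "percent_bound": 100.0 * config.bound_fraction,
            "total_signal": config.total_signal,
        },
    )
    return GelImage(values=img, saturation_level=config.saturation_level), lane_box, manifest


def simulate_competition_series(
    concentrations_nm: Sequence[float] = (50, 100, 200, 400, 800),
    uptake_fractions: Sequence[float] = (0.8, 0.6, 0.4, 0.25, 0.15),
    free_intensity_per_nm: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruthManifest]:
    """Free-band intensities for a competition titration.

    Returns (control_free, sample_free) band intensities per input DNA
    concentration; the manifest records the true uptake percentages
    ``100 * (control - sample) / control``.
    """
    conc = np.asarray(concentrations_nm, dtype=float)
    uptake = np.asarray(uptake_fractions, dtype=float)
    if conc.shape != uptake.shape:
        raise ValueError("concentrations and uptake fractions must align")
    if np.any((uptake < 0) | (uptake > 1)):
        raise ValueError("uptake fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    control = conc * free_intensity_per_nm
    sample = control * (1.0 - uptake)
    if noise_sd > 0:
        control = np.clip(control + rng.normal(0, noise_sd, conc.shape), 0, None)
        sample = np.clip(sample + rng.normal(0, noise_sd, conc.shape), 0, None)
    manifest = GroundTruthManifest(
        generator="competition_series",
        config={
            "concentrations_nm": conc,
            "uptake_fractions": uptake,
            "free_intensity_per_nm": free_intensity_per_nm,
            "noise_sd": noise_sd,
            "seed": seed,
        },
        truth={"uptake_percent": 100.0 * uptake},
    )
    return control, sample, manifest
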