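"""Synthetic AFM fields: worm-like-chain DNA plus protein blobs and clusters.

DNA is a discrete worm-like chain equilibrated in 2-D (tangent-angle
increments with variance ds/Lp, giving tangent correlation exp(-s/2Lp)),
rendered as a Gaussian-profile ridge of configurable height (default 1 nm,
safely inside the 0.1-2 nm segmentation band) and FWHM (default 6 nm).
Proteins are rendered as 2-D Gaussian caps whose analytic volume is
``2 pi sigma^2 h``; monomers/dimers land away from the DNA, "bound" dimers
sit on the DNA path, and clusters are larger caps.  Optional zero-mean
Gaussian roughness emulates instrument noise after background flattening.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ..datatypes import AFMImage
from ..manifest import GroundTruthManifest, _jsonify


@dataclass
class AFMConfig:
    seed: int = 0
    shape: tuple[int, int] = (500, 500)
    pixel_size_nm: float = 2.0
    dna_contour_nm: float = 1000.0
    n_dna: int = 1
    persistence_length_nm: float = 50.0
    straight: bool = False
    dna_height_nm: float = 1.0
    dna_fwhm_nm: float = 6.0
    n_monomers: int = 0
    n_dimers: int = 0
    n_bound_dimers: int = 0
    monomer_volume_nm3: float = 250.0
    dimer_volume_nm3: float = 500.0
    monomer_height_nm: float = 2.5
    dimer_height_nm: float = 4.0
    cluster_volumes_nm3: tuple = ()
    cluster_height_nm: float = 6.0
    roughness_nm: float = 0.05
    margin_nm: float = 60.0
    min_separation_nm: float = 60.0
    max_retries: int = 50

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_nm",
            "persistence_length_nm",
            "dna_height_nm",
            "dna_fwhm_nm",
            "monomer_height_nm",
            "dimer_height_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dna_contour_nm < 0 or self.roughness_nm < 0:
            raise ValueError("lengths and noise levels must be non-negative")
        if not 0.1 < self.dna_height_nm < 2.0:
            raise ValueError("dna_height_nm must sit inside the 0.1-2 nm band")


def _wlc_path(
    rng: np.random.Generator,
    contour_nm: float,
    lp_nm: float,
    shape_nm: tuple[float, float],
    margin_nm: float,
    straight: bool,
    max_retries: int,
) -> np.ndarray:
    """(n, 2) array of (y, x) positions in nm, ds = 1 nm steps."""
    ds = 1.0
    n = max(2, int(round(contour_nm / ds)) + 1)
    h, w = shape_nm
    if straight:
        # horizontal rod centred in the field
        x = np.linspace((w - contour_nm) / 2, (w + contour_nm) / 2, n)
        y = np.full(n, h / 2)
        if x[0] < margin_nm or x[-1] > w - margin_nm:
            raise ValueError("straight rod does not fit inside the field")
        return np.column_stack([y, x])
    sigma = np.sqrt(ds / lp_nm)
    for _ in range(max_retries):
        start = np.array(
            [rng.uniform(margin_nm, h - margin_nm), rng.uniform(margin_nm, w - margin_nm)]
        )
        theta = rng.uniform(0, 2 * np.pi) + np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, sigma, n - 1))]
        )
        steps = ds * np.column_stack([np.sin(theta), np.cos(theta)])
        path = start + np.concatenate([[[0.0, 0.0]], np.cumsum(steps[:-1], axis=0)])
        if (
            path[:, 0].min() >= margin_nm
            and path[:, 0].max() <= h - margin_nm
            and path[:, 1].min() >= margin_nm
            and path[:, 1].max() <= w - margin_nm
        ):
            return path
    raise RuntimeError("DNA path exited the field in every retry")


def _add_gaussian_cap(
    heights: np.ndarray, center_px: tuple[float, float], sigma_px: float, amp_nm: float
) -> None:
    rad = int(np.ceil(5 * sigma_px))
    r0 = int(round(center_px[0]))
    c0 = int(round(center_px[1]))
    y0, y1 = max(0, r0 - rad), min(heights.shape[0], r0 + rad + 1)
    x0, x1 = max(0, c0 - rad), min(heights.shape[1], c0 + rad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2
    cap = amp_nm * np.exp(-0.5 * d2 / sigma_px**2)
    # topography reads the top surface: a protein sitting on DNA presents
    # its own height, it does not stack additively on the ridge
    np.maximum(heights[y0:y1, x0:x1], cap, out=heights[y0:y1, x0:x1])


def simulate_afm_image(config: AFMConfig) -> tuple[AFMImage, GroundTruthManifest]:
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.shape
    px = config.pixel_size_nm
    shape_nm = (n_rows * px, n_cols * px)
    heights = np.zeros(config.shape)

    # --- DNA ridges ---
    paths = []
    for _ in range(config.n_dna if config.dna_contour_nm > 0 else 0):
        paths.append(
            _wlc_path(
                rng,
                config.dna_contour_nm,
                config.persistence_length_nm,
                shape_nm,
                config.margin_nm,
                config.straight,
                config.max_retries,
            )
        )
    sigma_r_px = config.dna_fwhm_nm / 2.3548 / px
    if paths:
        occupied = np.zeros(config.shape, dtype=bool)
        for path in paths:
            ij = np.round(path / px).astype(int)
            ij[:, 0] = np.clip(ij[:, 0], 0, n_rows - 1)
            ij[:, 1] = np.clip(ij[:, 1], 0, n_cols - 1)
            occupied[ij[:, 0], ij[:, 1]] = True
        dist_px = ndimage.distance_transform_edt(~occupied)
        ridge = config.dna_height_nm * np.exp(-0.5 * (dist_px / sigma_r_px) ** 2)
        heights = np.maximum(heights, ridge)

    # --- proteins ---
    objects: list[dict] = []

    def _free_spot() -> tuple[float, float]:
        for _ in range(200):
            p = (
                rng.uniform(config.margin_nm, shape_nm[0] - config.margin_nm),
                rng.uniform(config.margin_nm, shape_nm[1] - config.margin_nm),
            )
            if all(
                np.hypot(p[0] - o["y_nm"], p[1] - o["x_nm"]) > config.min_separation_nm
                for o in objects
            ) and (
                not paths
                or min(np.hypot(pp[:, 0] - p[0], pp[:, 1] - p[1]).min() for pp in paths)
                > config.min_separation_nm
            ):
                return p
        raise RuntimeError("could not place a free protein blob")

    def _on_dna_spot() -> tuple[float, float]:
        if not paths:
            raise ValueError("n_bound_dimers requires a DNA path")
        for _ in range(200):
            path = paths[rng.integers(len(paths))]
            p = tuple(path[rng.integers(len(path))])
            if all(
                np.hypot(p[0] - o["y_nm"], p[1] - o["x_nm"]) > config.min_separation_nm
                for o in objects
            ):
                return p
        raise RuntimeError("could not place a bound blob on the DNA")

    def _render(kind: str, pos: tuple[float, float], volume: float, height: float) -> None:
        sigma_nm = np.sqrt(volume / (2 * np.pi * height))
        _add_gaussian_cap(heights, (pos[0] / px, pos[1] / px), sigma_nm / px, height)
        objects.append(
            {
                "class": kind,
                "y_nm": pos[0],
                "x_nm": pos[1],
                "volume_nm3": volume,
                "height_nm": height,
                "sigma_nm": sigma_nm,
            }
        )

    for _ in range(config.n_monomers):
        _render("monomer", _free_spot(), config.monomer_volume_nm3, config.monomer_height_nm)
    for _ in range(config.n_dimers):
        _render("dimer", _free_spot(), config.dimer_volume_nm3, config.dimer_height_nm)
    for _ in range(config.n_bound_dimers):
        _render("bound_dimer", _on_dna_spot(), config.dimer_volume_nm3, config.dimer_height_nm)
    for v in config.cluster_volumes_nm3:
        pos = _on_dna_spot() if paths else _free_spot()
        _render("cluster", pos, float(v), config.cluster_height_nm)

    if config.roughness_nm > 0:
        heights = heights + rng.normal(0.0, config.roughness_nm, size=config.shape)

    img = AFMImage(heights=heights, pixel_size_nm=px)
    manifest = GroundTruthManifest(
        generator="afm_image",
        config=_jsonify(config),
        truth={
            "total_dna_contour_nm": config.dna_contour_nm * len(paths),
            "n_dna": len(paths),
            "objects": objects,
            "class_counts": {
                "monomer": config.n_monomers,
                "dimer": config.n_dimers,
                "bound_dimer": config.n_bound_dimers,
                "cluster": len(config.cluster_volumes_nm3),
            },
            "roughness_nm": config.roughness_nm,
            "dimer_volume_nm3": config.dimer_volume_nm3,
        },
    )
    return img, manifest


def sample_volume_mixture(
    n: int,
    dimer_weight: float,
    monomer_mean: float = 250.0,
    monomer_sd: float = 37.5,
    dimer_mean: float = 500.0,
    dimer_sd: float = 75.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthManifest]:
    """Draw grain volumes from a two-Gaussian monomer/dimer mixture.

    Class counts are exact for fixed ``n`` (``round(n * dimer_weight)``
    dimers), so the manifest proportions match the request rather than a
    binomial draw.
    """
    if not 0.0 <= dimer_weight <= 1.0:
        raise ValueError("dimer_weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_dimer = int(round(n * dimer_weight))
    n_mono = n - n_dimer
    vols = np.concatenate(
        [
            rng.normal(monomer_mean, monomer_sd, n_mono),
            rng.normal(dimer_mean, dimer_sd, n_dimer),
        ]
    )
    vols = np.abs(vols)  # volumes are physical; reflect rare negatives
    rng.shuffle(vols)
    manifest = GroundTruthManifest(
        generator="volume_mixture",
        config={
            "n": n,
            "dimer_weight": dimer_weight,
            "monomer_mean": monomer_mean,
            "monomer_sd": monomer_sd,
            "dimer_mean": dimer_mean,
            "dimer_sd": dimer_sd,
            "seed": seed,
        },
        truth={"n_monomer": n_mono, "n_dimer": n_dimer, "dimer_fraction": n_dimer / n},
    )
    return vols, manifest
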