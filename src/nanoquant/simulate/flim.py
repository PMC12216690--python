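"""Synthetic FLIM decay images at pulsed-laser repetition rates.

Per-pixel photon histograms are drawn from mono- or bi-exponential decays
folded into one modulation period T = 1/f (80 MHz default).  The folded
density for lifetime tau is ``exp(-t/tau) / (tau (1 - exp(-T/tau)))`` on
[0, T); bin contents are its exact integrals, so noise-free "expectation"
images have analytically known phasors.  A fluorescein-like reference field
(mono-exponential, 4.04 ns) is available for calibration tests.

The instrument response is ideal by default; an optional Gaussian IRF of
given width is applied by circular convolution.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ..datatypes import DecayImage
from ..manifest import GroundTruthManifest, _jsonify


def folded_decay_histogram(
    lifetimes_ns: Sequence[float],
    fractions: Sequence[float],
    n_bins: int,
    frequency_hz: float = 80e6,
    irf_sigma_ns: Optional[float] = None,
) -> np.ndarray:
    """Unit-sum expectation histogram (exact bin integrals of the folded decay).

    ``fractions`` are intensity (photon) fractions and must sum to 1.
    """
    lifetimes = np.asarray(lifetimes_ns, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    if lifetimes.shape != fractions.shape:
        raise ValueError("lifetimes and fractions must have the same length")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    period_ns = 1e9 / frequency_hz
    delta = period_ns / n_bins
    p = np.zeros(n_bins)
    for tau, w in zip(lifetimes, fractions):
        q = np.exp(-delta / tau)
        i = np.arange(n_bins)
        p += w * (q**i) * (1.0 - q) / (1.0 - q**n_bins)
    if irf_sigma_ns is not None and irf_sigma_ns > 0:
        t = (np.arange(n_bins) + 0.5) * delta
        # circular Gaussian IRF via FFT
        g = np.exp(-0.5 * ((np.minimum(t, period_ns - t)) / irf_sigma_ns) ** 2)
        g /= g.sum()
        p = np.real(np.fft.ifft(np.fft.fft(p) * np.fft.fft(g)))
        p = np.clip(p, 0, None)
        p /= p.sum()
    return p


@dataclass
class FLIMConfig:
    seed: int = 0
    shape: tuple[int, int] = (64, 64)
    n_bins: int = 256
    frequency_hz: float = 80e6
    lifetimes_ns: tuple = (4.04,)
    fractions: tuple = (1.0,)
    photons_per_pixel: float = 500.0
    noise: bool = True
    irf_sigma_ns: Optional[float] = None
    # optional second region (right half of the field) with its own decay
    region2_lifetimes_ns: Optional[tuple] = None
    region2_fractions: Optional[tuple] = None

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.lifetimes_ns):
            raise ValueError("lifetimes must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.region2_lifetimes_ns is not None:
            if self.region2_fractions is None or abs(sum(self.region2_fractions) - 1.0) > 1e-9:
                raise ValueError("region2 fractions must sum to 1")
            if any(t <= 0 for t in self.region2_lifetimes_ns):
                raise ValueError("region2 lifetimes must be positive")
        if self.photons_per_pixel <= 0 or self.n_bins < 2:
            raise ValueError("photons_per_pixel and n_bins must be positive")


def simulate_flim_image(config: FLIMConfig) -> tuple[DecayImage, GroundTruthManifest]:
    rng = np.random.default_rng(config.seed)
    period_ns = 1e9 / config.frequency_hz
    delta = period_ns / config.n_bins
    p1 = folded_decay_histogram(
        config.lifetimes_ns, config.fractions, config.n_bins, config.frequency_hz,
        config.irf_sigma_ns,
    )
    region_map = np.zeros(config.shape, dtype=int)
    ps = [p1]
    if config.region2_lifetimes_ns is not None:
        region_map[:, config.shape[1] // 2 :] = 1
        ps.append(
            folded_decay_histogram(
                config.region2_lifetimes_ns,
                config.region2_fractions,
                config.n_bins,
                config.frequency_hz,
                config.irf_sigma_ns,
            )
        )
    expectation = np.empty((config.n_bins,) + config.shape)
    for r, p in enumerate(ps):
        expectation[:, region_map == r] = (config.photons_per_pixel * p)[:, None]
    hist = rng.poisson(expectation).astype(float) if config.noise else expectation
    img = DecayImage(histograms=hist, bin_width_ns=delta, frequency_hz=config.frequency_hz)
    manifest = GroundTruthManifest(
        generator="flim_image",
        config=_jsonify(config),
        truth={
            "lifetimes_ns": list(config.lifetimes_ns),
            "fractions": list(config.fractions),
            "region2_lifetimes_ns": list(config.region2_lifetimes_ns)
            if config.region2_lifetimes_ns
            else None,
            "region2_fractions": list(config.region2_fractions)
            if config.region2_fractions
            else None,
            "region_map_split_col": config.shape[1] // 2
            if config.region2_lifetimes_ns
            else None,
            "photons_per_pixel": config.photons_per_pixel,
        },
    )
    return img, manifest


def simulate_reference_image(
    tau_ns: float = 4.04,
    shape: tuple[int, int] = (32, 32),
    n_bins: int = 256,
    frequency_hz: float = 80e6,
    photons_per_pixel: float = 2000.0,
    noise: bool = False,
    seed: int = 0,
) -> tuple[DecayImage, GroundTruthManifest]:
    """Mono-exponential calibration standard (fluorescein-like, 4.04 ns)."""
    cfg = FLIMConfig(
        seed=seed,
        shape=shape,
        n_bins=n_bins,
        frequency_hz=frequency_hz,
        lifetimes_ns=(tau_ns,),
        fractions=(1.0,),
        photons_per_pixel=photons_per_pixel,
        noise=noise,
    )
    img, manifest = simulate_flim_image(cfg)
    manifest.generator = "flim_reference"
    return img, manifest
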