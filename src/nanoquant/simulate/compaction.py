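"""Synthetic tethered-DNA compaction movies.

A doubly tethered, intercalator-stained DNA molecule is rendered as a
horizontal Gaussian-profile line.  After a lag time following protein
injection, a compact cluster anchored at one point along the DNA grows with
single-exponential kinetics: at time t past the onset a fraction
``1 - exp(-(t - onset)/tau)`` of the total DNA fluorescence sits in the
cluster.  Total expected intensity per frame is conserved (photobleaching is
an optional multiplier, off by default).

Two bookkeeping modes for where the cluster intensity comes from:

``"reel"`` (default)
    a contiguous stretch of DNA adjacent to the anchor is absorbed into the
    cluster; the remaining DNA keeps its full per-pixel intensity.  This is
    the physical picture for an intercalating stain (constant intensity per
    unit length, shrinking free length) and makes the inter-frame intensity
    fluctuation decay in proportion to the remaining free DNA.
``"dim"``
    intensity is removed uniformly from the whole uncompacted segment.

The uncompacted DNA additionally jitters transversely from frame to frame
(iid per column) so that the fluctuation-analysis pipeline has a
conformational-motion signal to measure; the cluster is static.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..datatypes import MovieStack
from ..manifest import GroundTruthManifest, _jsonify


@dataclass
class CompactionConfig:
    seed: int = 0
    n_frames: int = 120
    shape: tuple[int, int] = (48, 200)
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 1.0
    dna_length_bp: int = 48_500
    photons_per_bp_per_frame: float = 0.2
    t_lag_s: float = 30.0
    tau_s: float = 20.0
    injection_frame: int = 10
    anchor_col: Optional[int] = None  # None -> uniform random along the DNA
    dna_row: Optional[int] = None  # None -> image centre row
    dna_col_margin: int = 10
    ridge_sigma_px: float = 1.0
    cluster_sigma_px: float = 2.0
    jitter_sigma_px: float = 1.5
    mode: str = "reel"  # "reel" | "dim"
    noise: Optional[str] = "poisson"  # None | "poisson" | "poisson+gaussian"
    gaussian_sd: float = 0.0
    bleach_tau_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.t_lag_s < 0:
            raise ValueError("t_lag_s must be non-negative")
        for name in ("pixel_size_nm", "frame_interval_s", "photons_per_bp_per_frame"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("reel", "dim"):
            raise ValueError("mode must be 'reel' or 'dim'")
        if self.noise not in (None, "poisson", "poisson+gaussian"):
            raise ValueError("unknown noise model")
        if not (0 <= self.injection_frame < self.n_frames):
            raise ValueError("injection_frame outside the movie")


def _column_profiles(n_rows: int, centers: np.ndarray, sigma: float) -> np.ndarray:
    """(rows, cols) matrix of unit-sum vertical Gaussian profiles."""
    rows = np.arange(n_rows)[:, None]
    p = np.exp(-0.5 * ((rows - centers[None, :]) / sigma) ** 2)
    return p / p.sum(axis=0, keepdims=True)


def simulate_compaction_movie(
    config: CompactionConfig,
) -> tuple[MovieStack, GroundTruthManifest]:
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols_img = config.shape
    c0 = config.dna_col_margin
    c1 = n_cols_img - config.dna_col_margin - 1
    if c1 <= c0:
        raise ValueError("image too narrow for the DNA span")
    dna_cols = np.arange(c0, c1 + 1)
    n_cols = dna_cols.size
    row0 = config.dna_row if config.dna_row is not None else n_rows // 2

    anchor = (
        int(rng.integers(c0, c1 + 1))
        if config.anchor_col is None
        else int(config.anchor_col)
    )
    if not (c0 <= anchor <= c1):
        raise ValueError("anchor_col outside the DNA span")

    total_intensity = config.dna_length_bp * config.photons_per_bp_per_frame
    per_col = total_intensity / n_cols
    times = np.arange(config.n_frames) * config.frame_interval_s
    t_onset = config.injection_frame * config.frame_interval_s + config.t_lag_s
    frac = np.where(times > t_onset, 1.0 - np.exp(-(times - t_onset) / config.tau_s), 0.0)

    # columns ordered by distance from the anchor, farthest first: distal DNA
    # is reeled into the cluster first, so the cluster ROI (which also covers
    # the DNA running through it) gains exactly f * I_tot from the onset
    order = np.argsort(-np.abs(dna_cols - anchor), kind="stable")

    # cluster kernel (unit sum) on a local window
    ks = config.cluster_sigma_px
    rad = max(3, int(np.ceil(4 * ks)))
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    kernel = np.exp(-0.5 * (yy**2 + xx**2) / ks**2)
    kernel /= kernel.sum()
    kr0 = max(0, row0 - rad)
    kr1 = min(n_rows, row0 + rad + 1)
    kc0 = max(0, anchor - rad)
    kc1 = min(n_cols_img, anchor + rad + 1)
    kwin = kernel[kr0 - (row0 - rad) : kr1 - (row0 - rad), kc0 - (anchor - rad) : kc1 - (anchor - rad)]
    kwin = kwin / kwin.sum()

    frames = np.zeros((config.n_frames,) + config.shape, dtype=float)
    for i, f in enumerate(frac):
        col_int = np.full(n_cols, per_col)
        if config.mode == "dim":
            col_int *= 1.0 - f
        else:  # reel: consume whole columns nearest the anchor, one fractional
            consumed = f * total_intensity
            n_full = int(consumed // per_col)
            n_full = min(n_full, n_cols)
            col_int[order[:n_full]] = 0.0
            if n_full < n_cols:
                col_int[order[n_full]] -= consumed - n_full * per_col
        if config.jitter_sigma_px > 0:
            centers = row0 + rng.normal(0.0, config.jitter_sigma_px, size=n_cols)
        else:
            centers = np.full(n_cols, float(row0))
        profiles = _column_profiles(n_rows, centers, config.ridge_sigma_px)
        frame = np.zeros(config.shape)
        frame[:, dna_cols] = profiles * col_int[None, :]
        frame[kr0:kr1, kc0:kc1] += kwin * (f * total_intensity)
        if config.bleach_tau_s is not None:
            frame *= np.exp(-times[i] / config.bleach_tau_s)
        frames[i] = frame

    if config.noise is not None:
        frames = rng.poisson(frames).astype(float)
        if config.noise == "poisson+gaussian" and config.gaussian_sd > 0:
            frames += rng.normal(0.0, config.gaussian_sd, size=frames.shape)

    movie = MovieStack(
        frames=frames,
        pixel_size_nm=config.pixel_size_nm,
        frame_interval_s=config.frame_interval_s,
        injection_frame=config.injection_frame,
    )
    manifest = GroundTruthManifest(
        generator="compaction_movie",
        config=_jsonify(config),
        truth={
            "t_lag_s": config.t_lag_s,
            "tau_s": config.tau_s,
            "onset_time_s": t_onset,
            "anchor": [row0, anchor],
            "total_intensity_per_frame": total_intensity,
            "dna_span_cols": [c0, c1],
            "dna_row": row0,
            "mode": config.mode,
            "compacted_fraction": frac,
        },
    )
    return movie, manifest
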