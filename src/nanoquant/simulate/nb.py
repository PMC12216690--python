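"""Synthetic photon-counting stacks for Number & Brightness analysis.

Each pixel-frame count is compound Poisson: the number of emitters in the
focal volume fluctuates as N ~ Poisson(lambda), and each emitter contributes
Poisson(epsilon) detected counts in a frame.  The resulting per-pixel count
series has mean lambda*epsilon and variance lambda*epsilon*(1 + epsilon), so
the apparent brightness B = variance/mean equals epsilon + 1 — epsilon is
the molecular brightness in counts/emitter/frame and the extra 1 is the shot
noise of the photon-counting detector.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from ..datatypes import MovieStack
from ..manifest import GroundTruthManifest, _jsonify


@dataclass
class NBConfig:
    seed: int = 0
    shape: tuple[int, int] = (64, 64)
    n_frames: int = 500
    epsilon: Union[float, np.ndarray] = 0.15  # counts/emitter/frame, scalar or map
    mean_emitters: Union[float, np.ndarray] = 20.0  # lambda, scalar or map
    background_rate: float = 0.0  # fixed Poisson counts/pixel/frame (B contribution 1)
    pixel_size_nm: float = 41.0
    frame_interval_s: float = 1.108

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.epsilon) < 0):
            raise ValueError("epsilon must be >= 0")
        if np.any(np.asarray(self.mean_emitters) <= 0):
            raise ValueError("mean_emitters must be > 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for name, val in (("epsilon", self.epsilon), ("mean_emitters", self.mean_emitters)):
            arr = np.asarray(val)
            if arr.ndim not in (0, 2) or (arr.ndim == 2 and arr.shape != self.shape):
                raise ValueError(f"{name} must be scalar or a map of shape {self.shape}")


def two_region_epsilon(
    shape: tuple[int, int], eps_left: float, eps_right: float
) -> np.ndarray:
    """Convenience epsilon map: left half / right half of the field."""
    eps = np.full(shape, eps_left, dtype=float)
    eps[:, shape[1] // 2 :] = eps_right
    return eps


def simulate_nb_stack(config: NBConfig) -> tuple[MovieStack, GroundTruthManifest]:
    rng = np.random.default_rng(config.seed)
    eps = np.broadcast_to(np.asarray(config.epsilon, dtype=float), config.shape)
    lam = np.broadcast_to(np.asarray(config.mean_emitters, dtype=float), config.shape)
    size = (config.n_frames,) + config.shape
    n_emitters = rng.poisson(np.broadcast_to(lam, size))
    counts = rng.poisson(eps * n_emitters + config.background_rate).astype(float)
    movie = MovieStack(
        frames=counts,
        pixel_size_nm=config.pixel_size_nm,
        frame_interval_s=config.frame_interval_s,
    )
    manifest = GroundTruthManifest(
        generator="nb_stack",
        config=_jsonify(config),
        truth={
            "epsilon": np.asarray(config.epsilon),
            "mean_emitters": np.asarray(config.mean_emitters),
            "expected_brightness": 1.0 + np.asarray(config.epsilon),
        },
    )
    return movie, manifest
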