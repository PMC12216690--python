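"""Number & Brightness analysis of fluorescence-fluctuation frame scans.

For a photon-counting detector the apparent brightness of the molecules in
a pixel is B = variance/mean of that pixel's count series, and relates to
the molecular brightness epsilon (counts/emitter/frame) as B = epsilon + 1:
the additive 1 is the detector's shot-noise contribution.  An n-mer of a
calibrated monomer (epsilon_monomer) therefore appears at
B = n * epsilon_monomer + 1, which is the basis of the cursor classification
into monomer/dimer/oligomer pixel populations.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .datatypes import BrightnessCursors, BrightnessMap, MovieStack, SpeciesMap


def expected_brightness(n_units: int, epsilon_monomer: float) -> float:
    """Apparent brightness of an ``n_units``-mer: n * epsilon + 1."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if epsilon_monomer < 0:
        raise ValueError("epsilon_monomer must be >= 0")
    return n_units * epsilon_monomer + 1.0


def brightness_map(
    stack: MovieStack, detrend_window: Optional[int] = 10
) -> BrightnessMap:
    """Per-pixel apparent brightness B = variance/mean of the count series.

    When ``detrend_window`` is set, a boxcar moving average is subtracted
    from each pixel's series and the series re-centred on its global mean,
    removing slow drifts from cell movement or photobleaching.  Subtracting
    a length-w boxcar shrinks the variance of an uncorrelated series by
    (1 - 1/w); the detrended variance is divided by that factor so B stays
    unbiased for stationary series.  Pass ``None`` (or 0) to disable
    detrending.  Pixels with zero mean intensity are masked.
    """
    frames = stack.frames
    if detrend_window:
        if frames.shape[0] < 2 * detrend_window:
            raise ValueError("need at least 2 x detrend_window frames")
        ma = uniform_filter1d(frames, detrend_window, axis=0, mode="nearest")
        detrended = frames - ma + frames.mean(axis=0)
        var = detrended.var(axis=0, ddof=1) / (1.0 - 1.0 / detrend_window)
    else:
        if frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        var = frames.var(axis=0, ddof=1)
    mean = frames.mean(axis=0)
    mask = mean > 0
    B = np.full(mean.shape, np.nan)
    B[mask] = var[mask] / mean[mask]
    return BrightnessMap(
        B=B, mean_intensity=mean, mask=mask, detrend_window=detrend_window or None
    )


_CLASS_CODES = {"monomer": 1, "dimer": 2, "oligomer": 3}


def classify_and_fraction(
    bmap: BrightnessMap,
    cursors: Optional[BrightnessCursors] = None,
    intensity_floor: float = 0.0,
    median_passes: int = 1,
) -> SpeciesMap:
    """Assign pixels to brightness-cursor species and compute fractions.

    Pixels whose mean intensity is at or below ``intensity_floor`` are
    background; remaining pixels are assigned to the cursor interval
    containing their B (cursor intervals are validated disjoint at cursor
    construction), else left unclassified.  Fractions are computed over the
    classified pixels only.  Before classification the B map is smoothed
    with a 3x3 spatial median filter (``median_passes`` times, default
    once): the per-pixel variance/mean estimator carries sampling noise
    comparable to the cursor spacing, and local pooling sharpens the species
    separation without moving region means.
    """
    cursors = cursors or BrightnessCursors()
    B = bmap.B
    for _ in range(max(0, median_passes)):
        B = np.where(bmap.mask, median_filter(np.where(bmap.mask, B, 0.0), size=3), np.nan)
    labels = np.zeros(B.shape, dtype=np.uint8)  # background
    fg = bmap.mask & (bmap.mean_intensity > intensity_floor)
    labels[fg] = 4  # unclassified until a cursor claims the pixel
    for name, code in _CLASS_CODES.items():
        if name not in cursors.centers:
            continue
        lo, hi = cursors.interval(name)
        labels[fg & (B >= lo) & (B <= hi)] = code
    classified = np.isin(labels, list(_CLASS_CODES.values()))
    n_classified = int(classified.sum())
    if n_classified:
        fractions = {
            name: float((labels == code).sum() / n_classified)
            for name, code in _CLASS_CODES.items()
        }
        flags = ""
    else:
        fractions = {name: np.nan for name in _CLASS_CODES}
        flags = "no classified pixels"
    return SpeciesMap(
        labels=labels, fractions=fractions, n_classified=n_classified, flags=flags
    )
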