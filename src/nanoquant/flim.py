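"""Phasor-based FLIM-FRET analysis.

Each pixel's photon-arrival histogram maps to a phasor
``g + i s = sum_i c_i exp(i n omega t_i) / sum_i c_i`` at harmonic n of the
modulation frequency.  Mono-exponential decays lie on the universal
semicircle ``(g - 1/2)^2 + s^2 = 1/4``; mixtures are intensity-weighted
means of their components' phasors, so two-species pixels fall on the chord
between the pure phasors, and donor quenching by FRET traces the curve of
on-circle phasors of lifetime ``tau_D (1 - E)``.

A half-bin discretization correction (factor cos(omega * bin/2) on the raw
cosine/sine sums) is applied so that bin-integrated mono-exponential
expectation histograms land *exactly* on the circle for any bin count: with
N bins of width d, the raw bin-centre sum for a folded exponential is
1/(cos h - i beta sin h) with h = omega d / 2 and beta = (1+q)/(1-q),
q = exp(-d/tau); multiplying by cos h gives 1/(1 - i beta tan h), which is
on the circle with apparent modulation beta tan h -> omega tau as d -> 0.
The correction is a constant per harmonic, so phasor linearity is intact.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import (
    DecayImage,
    FretFractionMap,
    MaskRatioReport,
    PhasorCalibration,
    PhasorMap,
)

FLUORESCEIN_TAU_NS = 4.04


def lifetime_to_phasor(tau_ns: float, frequency_hz: float, harmonic: int = 1) -> tuple[float, float]:
    """Closed-form universal-circle phasor of a mono-exponential decay."""
    wt = 2 * np.pi * frequency_hz * 1e-9 * harmonic * tau_ns
    return 1.0 / (1.0 + wt**2), wt / (1.0 + wt**2)


def phasor_transform(
    decays: DecayImage, harmonic: int = 1, median_passes: int = 2
) -> PhasorMap:
    """Per-pixel phasor with half-bin correction and spatial median filtering.

    Zero-count pixels are masked rather than propagated as NaN.  A 3x3
    spatial median filter is applied ``median_passes`` times to g and s
    independently to increase phasor accuracy.
    """
    hist = decays.histograms
    n_bins = hist.shape[0]
    omega = 2 * np.pi * decays.frequency_hz * 1e-9 * harmonic  # rad/ns
    t = (np.arange(n_bins) + 0.5) * decays.bin_width_ns
    half_bin = np.cos(omega * decays.bin_width_ns / 2.0)
    counts = hist.sum(axis=0)
    mask = counts > 0
    safe = np.where(mask, counts, 1.0)
    g = np.tensordot(np.cos(omega * t), hist, axes=(0, 0)) / safe * half_bin
    s = np.tensordot(np.sin(omega * t), hist, axes=(0, 0)) / safe * half_bin
    g[~mask] = np.nan
    s[~mask] = np.nan
    for _ in range(median_passes):
        if mask.all():
            g = ndimage.median_filter(g, size=3)
            s = ndimage.median_filter(s, size=3)
        else:  # keep masked pixels out of the filter footprint
            g = np.where(mask, ndimage.median_filter(np.where(mask, g, 0.0), size=3), np.nan)
            s = np.where(mask, ndimage.median_filter(np.where(mask, s, 0.0), size=3), np.nan)
    return PhasorMap(
        g=g, s=s, counts=counts, harmonic=harmonic,
        frequency_hz=decays.frequency_hz, mask=mask,
    )


def calibrate_phasor(
    pmap: PhasorMap, reference: PhasorMap, tau_ref_ns: float = FLUORESCEIN_TAU_NS
) -> PhasorMap:
    """Rotate + scale so the reference lands on its universal-circle point.

    The complex factor mapping the reference's count-weighted mean phasor
    onto the closed-form phasor of ``tau_ref_ns`` is applied to every pixel
    of ``pmap``.  Calibrating an already-calibrated map against its own
    calibrated reference is the identity (idempotence).
    """
    w = np.where(reference.mask, reference.counts, 0.0).astype(float)
    if w.sum() == 0:
        raise ValueError("reference map has no counts")
    mg = float(np.nansum(reference.g * w) / w.sum())
    ms = float(np.nansum(reference.s * w) / w.sum())
    measured = mg + 1j * ms
    if abs(measured) < 1e-12:
        raise ValueError("reference mean phasor at the origin; cannot calibrate")
    g_true, s_true = lifetime_to_phasor(tau_ref_ns, pmap.frequency_hz, pmap.harmonic)
    factor = (g_true + 1j * s_true) / measured
    z = (pmap.g + 1j * pmap.s) * factor
    cal = PhasorCalibration(
        tau_ref_ns=tau_ref_ns,
        measured_g=mg,
        measured_s=ms,
        rotation_rad=float(np.angle(factor)),
        scale=float(np.abs(factor)),
    )
    return replace(pmap, g=z.real, s=z.imag, calibration=cal)


def fraction_two_species(
    pmap: PhasorMap, phasor_a: tuple[float, float], phasor_b: tuple[float, float]
) -> np.ndarray:
    """Per-pixel fraction of species a along the linear two-species trajectory.

    Orthogonal projection of each pixel phasor onto the segment a-b, clipped
    to [0, 1]; this equals the per-pixel least-squares mixture weight.
    """
    a = np.asarray(phasor_a, dtype=float)
    b = np.asarray(phasor_b, dtype=float)
    d = a - b
    denom = float(d @ d)
    if denom < 1e-24:
        raise ValueError("phasor_a and phasor_b coincide")
    frac = ((pmap.g - b[0]) * d[0] + (pmap.s - b[1]) * d[1]) / denom
    return np.clip(frac, 0.0, 1.0)


def quenched_donor_trajectory(
    donor_tau_ns: float,
    frequency_hz: float,
    harmonic: int = 1,
    efficiency_grid: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """FRET trajectory: on-circle phasors of lifetimes tau_D (1 - E)."""
    if efficiency_grid is None:
        efficiency_grid = np.linspace(0.0, 0.99, 100)
    E = np.asarray(efficiency_grid, dtype=float)
    if np.any((E < 0) | (E >= 1)):
        raise ValueError("efficiency grid must lie in [0, 1)")
    taus = donor_tau_ns * (1.0 - E)
    wt = 2 * np.pi * frequency_hz * 1e-9 * harmonic * taus
    return E, np.column_stack([1.0 / (1.0 + wt**2), wt / (1.0 + wt**2)])


def fret_fraction_map(
    pmap: PhasorMap,
    donor_unquenched: tuple[float, float],
    background: tuple[float, float],
    efficiency_grid: Optional[Sequence[float]] = None,
    fret_cutoff: float = 0.1,
    background_max_fraction: float = 0.9,
) -> FretFractionMap:
    """Assign per-pixel FRET efficiency after unmixing the background.

    The donor lifetime is recovered from the unquenched-donor phasor
    (tau = s / (omega g) for an on-circle phasor).  Every pixel is modelled
    as a linear combination of the global background phasor and a point on
    the quenched-donor trajectory; the trajectory point minimizing the
    residual distance gives the pixel's E, and the position along the
    background-to-trajectory chord gives the background fraction.  Pixels
    dominated by background (fraction above ``background_max_fraction``) or
    masked pixels are excluded from FRET statistics; the FRET-positive flag
    requires E at or above ``fret_cutoff``.
    """
    gd, sd = donor_unquenched
    omega = pmap.omega
    if gd <= 0 or sd <= 0:
        raise ValueError("donor lifetime unresolvable from donor_unquenched phasor")
    donor_tau = sd / (omega * gd)
    E_grid, traj = quenched_donor_trajectory(
        donor_tau, pmap.frequency_hz, pmap.harmonic, efficiency_grid
    )
    bg = np.asarray(background, dtype=float)

    pts = np.column_stack([pmap.g.ravel(), pmap.s.ravel()])  # (P, 2)
    finite = np.isfinite(pts).all(axis=1)
    pts_f = np.where(finite[:, None], pts, 0.0)
    u = traj - bg[None, :]  # (M, 2)
    uu = np.einsum("md,md->m", u, u)
    uu = np.where(uu < 1e-24, 1e-24, uu)
    rel = pts_f - bg[None, :]  # (P, 2)
    tproj = np.clip(np.einsum("pd,md->pm", rel, u) / uu[None, :], 0.0, 1.0)
    closest = bg[None, None, :] + tproj[:, :, None] * u[None, :, :]
    dist2 = np.sum((pts_f[:, None, :] - closest) ** 2, axis=2)
    best = np.argmin(dist2, axis=1)
    E_pix = E_grid[best]
    signal_frac = tproj[np.arange(len(pts_f)), best]
    f_bg = 1.0 - signal_frac

    shape = pmap.g.shape
    E_map = np.where(finite, E_pix, np.nan).reshape(shape)
    fbg_map = np.where(finite, f_bg, np.nan).reshape(shape)
    excluded = (~finite | (f_bg > background_max_fraction)).reshape(shape)
    positive = (~excluded) & (E_map >= fret_cutoff)
    return FretFractionMap(
        efficiency=E_map,
        background_fraction=fbg_map,
        fret_positive=positive,
        excluded=excluded,
        fret_cutoff=fret_cutoff,
        donor_tau_ns=float(donor_tau),
    )


def if_mask_ratio(
    fret_map: FretFractionMap,
    if_image: np.ndarray,
    top_percent: float = 5.0,
    median_passes: int = 1,
) -> MaskRatioReport:
    """FRET-positive fraction inside vs outside an IF high-intensity mask.

    The immunofluorescence image is smoothed with a 3x3 median filter
    (once, per the IF-mask recipe) and thresholded to retain the top
    ``top_percent`` intensity pixels; the report compares the FRET-positive
    pixel fraction inside that mask against the rest of the field.
    """
    if_image = np.asarray(if_image, dtype=float)
    if if_image.shape != fret_map.efficiency.shape:
        raise ValueError("IF image and FRET map must be co-registered (same shape)")
    if not 0 < top_percent < 100:
        raise ValueError("top_percent must be in (0, 100)")
    smoothed = if_image
    for _ in range(median_passes):
        smoothed = ndimage.median_filter(smoothed, size=3)
    thresh = np.percentile(smoothed, 100.0 - top_percent)
    mask = smoothed > thresh
    usable = ~fret_map.excluded
    inside = mask & usable
    outside = ~mask & usable
    if not inside.any():
        raise ValueError("empty mask after thresholding")
    if not outside.any():
        raise ValueError("mask covers the whole usable field")
    f_in = float(fret_map.fret_positive[inside].mean())
    f_out = float(fret_map.fret_positive[outside].mean())
    ratio = f_in / f_out if f_out > 0 else np.inf
    return MaskRatioReport(
        fraction_inside=f_in,
        fraction_outside=f_out,
        ratio=ratio,
        n_inside=int(inside.sum()),
        n_outside=int(outside.sum()),
        top_percent=top_percent,
    )
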