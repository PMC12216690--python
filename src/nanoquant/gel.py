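"""Densitometric EMSA quantification.

Percent bound per lane follows the lane-box recipe: a rectangle (default
30 x 350 px) covers the whole lane; the shifted (protein-bound) and
unshifted (free DNA) bands occupy row sub-regions inside it.  The median of
lane pixels outside both bands estimates the background, which is
subtracted per pixel (clamped at zero) before integrating each band;
percent bound = 100 * bound / (bound + unbound).  Competition uptake
compares the free-band intensity of a competed sample against the DNA-only
control at each input concentration.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import BandQuantification, GelImage, LaneBox


def percent_bound(
    img: GelImage,
    lane: LaneBox,
    lane_id: str = "",
    saturation_max_fraction: float = 0.01,
) -> BandQuantification:
    """Quantify bound/unbound band intensities and percent bound for a lane."""
    h, w = img.values.shape
    if not (0 <= lane.x and lane.x + lane.width_px <= w and 0 <= lane.y and lane.y + lane.height_px <= h):
        raise ValueError("lane box outside the image")
    box = img.values[lane.y : lane.y + lane.height_px, lane.x : lane.x + lane.width_px]

    rows = np.arange(lane.height_px)
    b0, b1 = lane.bound_rows
    u0, u1 = lane.unbound_rows
    in_bound = (rows >= b0) & (rows < b1)
    in_unbound = (rows >= u0) & (rows < u1)
    outside = ~(in_bound | in_unbound)
    background = float(np.median(box[outside])) if outside.any() else 0.0

    sub = np.clip(box - background, 0.0, None)
    bound = float(sub[in_bound].sum())
    unbound = float(sub[in_unbound].sum())
    total = bound + unbound

    saturated = False
    if img.saturation_level is not None:
        saturated = (box >= img.saturation_level).mean() > saturation_max_fraction

    if total <= 0:
        return BandQuantification(
            lane_id=lane_id, bound_intensity=0.0, unbound_intensity=0.0,
            percent_bound=np.nan, background=background,
            empty_lane=True, saturated=saturated,
        )
    return BandQuantification(
        lane_id=lane_id,
        bound_intensity=bound,
        unbound_intensity=unbound,
        percent_bound=100.0 * bound / total,
        background=background,
        empty_lane=False,
        saturated=saturated,
    )


def competition_uptake(
    sample_free_intensities: Sequence[float],
    control_free_intensities: Sequence[float],
    input_concentrations_nm: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Percent uptake of labelled competitor DNA per input concentration.

    ``uptake(c) = 100 * (control_free(c) - sample_free(c)) / control_free(c)``
    — the fractional loss of the free (bottom) band relative to the DNA-only
    control at the same input.  A zero control intensity is an error for
    that point (reported as NaN with a flag).
    """
    sample = np.asarray(sample_free_intensities, dtype=float)
    control = np.asarray(control_free_intensities, dtype=float)
    if sample.shape != control.shape:
        raise ValueError("sample and control series must have equal length")
    if input_concentrations_nm is None:
        conc = np.arange(len(sample), dtype=float)
    else:
        conc = np.asarray(input_concentrations_nm, dtype=float)
        if conc.shape != sample.shape:
            raise ValueError("concentration series must match the intensities")
    with np.errstate(divide="ignore", invalid="ignore"):
        uptake = 100.0 * (control - sample) / control
    flags = np.where(control == 0, "zero control intensity", "")
    uptake = np.where(control == 0, np.nan, uptake)
    return pd.DataFrame(
        {
            "input_nM": conc,
            "control_free": control,
            "sample_free": sample,
            "uptake_percent": uptake,
            "flags": flags,
        }
    )
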