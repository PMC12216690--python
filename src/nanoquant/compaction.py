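"""DNA-compaction kinetics from tethered-DNA movies.

Two complementary read-outs of the same process:

1. **Cluster-intensity analysis** — a cluster ROI defined on the final frame
   is reverse-tracked through earlier frames; the ROI sum, normalized to the
   whole-DNA intensity and scaled by the genome length (48.5 kbp for λ-DNA),
   gives cluster size in bp.  Lag time is the delay between injection and a
   sustained rise above the pre-compaction baseline, and the compaction time
   τ is the time constant of a single-exponential fit of the rise.
2. **Fluctuation analysis** — the adjacent-frame intensity variance over the
   DNA region (after background removal and per-frame sum equalization)
   decays as the molecule is immobilized into the cluster; a Savitzky-Golay
   smoothed, max-normalized variance trace is fitted with an exponential
   decay whose time constant estimates the same compaction time.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Optional, Union

import numpy as np
from scipy import ndimage, optimize, signal

from .datatypes import ClusterTrace, CompactionFit, FluctuationTrace, Kymograph, MovieStack

LAMBDA_DNA_BP = 48_500


# --------------------------------------------------------------------------
# kymograph
# --------------------------------------------------------------------------

def build_kymograph(
    movie: MovieStack, axis_line: np.ndarray, roi_width_px: int
) -> Kymograph:
    """Sum ``roi_width_px`` pixels perpendicular to the DNA axis per frame.

    ``axis_line`` is an (n, 2) polyline of (row, col) vertices along the
    extended DNA.  The axis is resampled at one-pixel arclength spacing; at
    each position the intensity of ``roi_width_px`` samples centred on the
    axis, along the local perpendicular, is summed (bilinear interpolation).
    Output is (space, time).
    """
    if roi_width_px < 1:
        raise ValueError("roi_width_px must be >= 1")
    axis = np.asarray(axis_line, dtype=float)
    if axis.ndim != 2 or axis.shape[1] != 2 or len(axis) < 2:
        raise ValueError("axis_line must be an (n, 2) polyline with n >= 2")
    n_rows, n_cols = movie.frames.shape[1:]
    for i, (r, c) in enumerate(axis):
        if not (0 <= r <= n_rows - 1 and 0 <= c <= n_cols - 1):
            raise ValueError(f"axis vertex {i} at ({r}, {c}) lies outside the image")

    # resample the polyline at ~1 px arclength spacing
    seg = np.diff(axis, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_pos = max(2, int(np.floor(arclen[-1])) + 1)
    s = np.linspace(0.0, arclen[-1], n_pos)
    pos = np.column_stack(
        [np.interp(s, arclen, axis[:, 0]), np.interp(s, arclen, axis[:, 1])]
    )
    tangent = np.gradient(pos, axis=0)
    tnorm = np.hypot(tangent[:, 0], tangent[:, 1])
    tnorm[tnorm == 0] = 1.0
    tangent /= tnorm[:, None]
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    offsets = np.arange(roi_width_px, dtype=float) - (roi_width_px - 1) / 2.0
    # sample coordinates: (n_pos, width, 2)
    coords = pos[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    rows = coords[..., 0].ravel()
    cols = coords[..., 1].ravel()
    values = np.empty((len(movie.frames), n_pos))
    for t, frame in enumerate(movie.frames):
        samples = ndimage.map_coordinates(frame, [rows, cols], order=1, mode="nearest")
        values[t] = samples.reshape(n_pos, roi_width_px).sum(axis=1)
    return Kymograph(
        values=values.T,
        roi_width_px=roi_width_px,
        pixel_size_nm=movie.pixel_size_nm,
        frame_interval_s=movie.frame_interval_s,
    )


# --------------------------------------------------------------------------
# cluster-intensity analysis
# --------------------------------------------------------------------------

def _circle_mask(shape: tuple[int, int], center: np.ndarray, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def extract_cluster_trace(
    movie: MovieStack,
    final_roi_center: tuple[float, float],
    final_roi_radius_px: float,
    search_radius_factor: float = 2.0,
    max_drift_px: float = 3.0,
    dna_mask: Optional[np.ndarray] = None,
) -> ClusterTrace:
    """Reverse-track the final-frame cluster ROI and sum it per frame.

    The ROI centre is re-estimated frame by frame (backwards from the final
    frame) as the intensity-weighted centroid within a search window of
    ``search_radius_factor`` times the ROI radius around the previous
    centre; drift beyond ``max_drift_px`` per frame marks the trace
    unreliable.  Background (per-frame median of pixels outside the DNA
    region, or outside the ROI if no DNA mask is given) is subtracted before
    summation; per-frame total DNA intensity is returned for normalization.
    """
    frames = movie.frames
    shape = frames.shape[1:]
    center = np.asarray(final_roi_center, dtype=float)
    radius = float(final_roi_radius_px)
    if radius <= 0:
        raise ValueError("final_roi_radius_px must be positive")
    search_r = search_radius_factor * radius

    centers = np.zeros((len(frames), 2))
    reliable = True
    notes = ""

    # sanity: the final ROI must contain signal above background
    final = frames[-1]
    final_mask = _circle_mask(shape, center, radius)
    bg_ref = np.median(final[~final_mask])
    mad = np.median(np.abs(final[~final_mask] - bg_ref)) + 1e-12
    if final[final_mask].max() < bg_ref + 5 * mad:
        reliable = False
        notes = "final ROI contains no clear intensity maximum"

    prev = center.copy()
    for t in range(len(frames) - 1, -1, -1):
        win = _circle_mask(shape, prev, search_r)
        w = frames[t] * win
        w = np.clip(w - np.median(frames[t][~win]) if (~win).any() else w, 0, None)
        total = w.sum()
        if total > 0:
            yy, xx = np.mgrid[: shape[0], : shape[1]]
            cand = np.array([(w * yy).sum() / total, (w * xx).sum() / total])
        else:
            cand = prev
        drift = np.hypot(*(cand - prev))
        if drift > max_drift_px:
            # ties/jumps resolved toward the previous centre
            cand = prev + (cand - prev) * (max_drift_px / drift)
            if drift > 2 * max_drift_px:
                reliable = False
                notes = notes or "centroid drift exceeded the per-frame limit"
        centers[t] = cand
        prev = cand

    intensities = np.empty(len(frames))
    totals = np.empty(len(frames))
    outside = (
        ~dna_mask.astype(bool)
        if dna_mask is not None
        else ~_circle_mask(shape, centers[-1], radius * 3)
    )
    for t, frame in enumerate(frames):
        bg = np.median(frame[outside]) if outside.any() else 0.0
        sub = np.clip(frame - bg, 0, None)
        # integer-pixel ROI placement: sub-pixel centroid wobble must not
        # flicker the discrete pixel membership of the ROI
        roi = _circle_mask(shape, np.round(centers[t]), radius)
        intensities[t] = sub[roi].sum()
        totals[t] = sub.sum()
    return ClusterTrace(
        times_s=movie.times_s,
        intensities=intensities,
        total_dna_intensity=totals,
        roi_centers=centers,
        roi_radius_px=radius,
        reliable=reliable,
        notes=notes,
    )


def cluster_size_bp(
    trace: ClusterTrace, genome_length_bp: int = LAMBDA_DNA_BP
) -> np.ndarray:
    """Cluster size in bp: ROI intensity / total DNA intensity × genome length."""
    totals = np.asarray(trace.total_dna_intensity, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("total DNA intensity must be positive in every frame")
    return np.asarray(trace.intensities) / totals * genome_length_bp


def detect_lag_time(
    trace: ClusterTrace,
    injection_time_s: float,
    k_sigma: float = 3.0,
    run_length: int = 5,
) -> Optional[float]:
    """Lag between injection and the onset of compaction, in seconds.

    Onset is the first frame whose cluster intensity exceeds the
    pre-injection mean + ``k_sigma`` standard deviations for ``run_length``
    consecutive frames.  Returns ``None`` when no compaction is detected
    (a distinguished result, not an error).
    """
    times = np.asarray(trace.times_s)
    y = np.asarray(trace.intensities, dtype=float)
    pre = y[times <= injection_time_s]
    if len(pre) < run_length:
        raise ValueError("need at least run_length pre-injection frames")
    mu, sd = pre.mean(), pre.std(ddof=0)
    thresh = mu + k_sigma * max(sd, 1e-12 * max(abs(mu), 1.0))
    above = y > thresh
    candidates = np.flatnonzero(above & (times >= injection_time_s))
    for i in candidates:
        if i + run_length <= len(y) and above[i : i + run_length].all():
            return float(times[i] - injection_time_s)
    return None


def _r_squared(y: np.ndarray, fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def fit_compaction_time(
    trace: ClusterTrace,
    onset_s: float,
    genome_length_bp: int = LAMBDA_DNA_BP,
    saturation_fraction: float = 0.95,
) -> CompactionFit:
    """Fit I(t) = baseline + A (1 - exp(-(t - onset)/tau)) over [onset, saturation].

    The fit window runs from the onset to the first frame whose intensity
    reaches ``saturation_fraction`` of the rise (pre-onset baseline to final
    plateau); frames beyond saturation carry no kinetic information and are
    dropped.  Set ``saturation_fraction=1`` to fit the whole trace.
    """
    times = np.asarray(trace.times_s)
    y = np.asarray(trace.intensities, dtype=float)
    sel = times >= onset_s
    if saturation_fraction < 1.0 and sel.sum() >= 10:
        base = y[~sel].mean() if (~sel).any() else y[sel][0]
        plateau = np.median(y[-5:])
        if plateau > base:
            level = base + saturation_fraction * (plateau - base)
            reached = np.flatnonzero(sel & (y >= level))
            if reached.size and reached[0] - np.flatnonzero(sel)[0] >= 10:
                sel = sel & (np.arange(len(y)) <= reached[0])
    t = times[sel] - onset_s
    yy = y[sel]
    if len(t) < 10:
        raise ValueError("need at least 10 post-onset samples")

    def model(t, tau, amp, base):
        return base + amp * (1.0 - np.exp(-t / tau))

    span = max(t[-1], 1e-9)
    p0 = (max(span / 3.0, 1e-6), max(yy[-1] - yy[0], 1e-6), yy[0])
    bounds = ([1e-9, 0.0, -np.inf], [100.0 * span, np.inf, np.inf])
    try:
        popt, _ = optimize.curve_fit(model, t, yy, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return CompactionFit(
            t_lag_s=None, tau_s=np.nan, amplitude=np.nan, baseline=np.nan,
            r_squared=np.nan, method="cluster", ok=False, message=f"fit failed: {exc}",
        )
    tau, amp, base = popt
    fitvals = model(t, *popt)
    r2 = _r_squared(yy, fitvals)
    ok = True
    message = ""
    if not np.isfinite(r2):
        ok, message = False, "constant trace: no variance to fit"
    elif tau <= 2e-9 or tau >= 99.0 * span:
        ok, message = False, "tau at fit bounds"
    final_total = float(np.asarray(trace.total_dna_intensity)[-1])
    size_bp = (base + amp) / final_total * genome_length_bp if final_total > 0 else None
    return CompactionFit(
        t_lag_s=None,
        tau_s=float(tau),
        amplitude=float(amp),
        baseline=float(base),
        r_squared=float(r2) if np.isfinite(r2) else np.nan,
        method="cluster",
        ok=ok,
        message=message,
        cluster_size_bp=size_bp,
    )


# --------------------------------------------------------------------------
# fluctuation analysis
# --------------------------------------------------------------------------

def preprocess_frames(frames: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Background-subtract, clamp and sum-equalize each frame within the ROI.

    Per frame: the mean of the sub-median ROI pixels is taken as background
    and subtracted, negatives are clamped to zero, and the frame is rescaled
    so its ROI sum equals the first frame's (the molecule's total stain does
    not change, so equal sums enforce a uniform DNA amount across frames).
    """
    out = np.zeros_like(frames, dtype=float)
    target = None
    for t, frame in enumerate(frames):
        vals = frame[roi]
        med = np.median(vals)
        sub_median = vals[vals < med]
        bg = sub_median.mean() if sub_median.size else 0.0
        f = np.clip(frame - bg, 0, None)
        f[~roi] = 0.0
        s = f[roi].sum()
        if target is None:
            target = s
        if s > 0 and target > 0:
            f *= target / s
        out[t] = f
    return out


def adjacent_frame_variance(
    frames: np.ndarray, roi: np.ndarray, variance_floor: Union[float, str, None] = 0.0
) -> np.ndarray:
    """Sum of squared adjacent-frame differences over the ROI, per frame pair.

    Pixels whose absolute inter-frame difference falls below the variance
    floor are treated as non-variant and zeroed: only the segments that
    actually changed between the two frames contribute.  ``variance_floor``
    may be a constant, or ``"shot"`` for the per-pixel expected shot-noise
    standard deviation ``sqrt(I_t + I_{t+1})``.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    diffs = np.diff(frames, axis=0)
    if variance_floor == "shot":
        floor = np.sqrt(np.clip(frames[:-1] + frames[1:], 0, None))
    else:
        floor = float(variance_floor or 0.0)
    d2 = np.where(np.abs(diffs) >= floor, diffs**2, 0.0)
    return d2[:, roi].sum(axis=1)


def compute_fluctuation_series(
    source: Union[MovieStack, Kymograph],
    dna_roi: np.ndarray,
    variance_floor: Union[float, str, None] = "shot",
) -> FluctuationTrace:
    """Adjacent-frame variance of the equalized DNA signal.

    Accepts a movie (frames, rows, cols with a 2-D ROI mask) or a kymograph
    (space, time with a 1-D spatial mask).  The variance value for the pair
    (t, t+1) is reported at time t+1.
    """
    if isinstance(source, Kymograph):
        frames = source.values.T[:, :, None]  # (time, space, 1)
        roi = np.asarray(dna_roi, dtype=bool).reshape(-1, 1)
        interval = source.frame_interval_s
    else:
        frames = source.frames
        roi = np.asarray(dna_roi, dtype=bool)
        interval = source.frame_interval_s
    if roi.shape != frames.shape[1:]:
        raise ValueError("dna_roi shape does not match the frames")
    if not roi.any():
        raise ValueError("dna_roi is empty")
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    processed = preprocess_frames(frames, roi)
    var = adjacent_frame_variance(processed, roi, variance_floor)
    times = (np.arange(len(var)) + 1) * interval
    return FluctuationTrace(times_s=times, variance=var)


def smooth_fluctuation(
    trace: FluctuationTrace, sg_window: int = 150, sg_order: int = 2
) -> FluctuationTrace:
    """Savitzky-Golay smooth and max-normalize the variance series."""
    n = len(trace.variance)
    if sg_window >= n:
        raise ValueError("Savitzky-Golay window must be shorter than the trace")
    if sg_window % 2 == 0:
        sg_window += 1
    sm = signal.savgol_filter(trace.variance, sg_window, sg_order)
    peak = sm.max()
    if peak > 0:
        sm = sm / peak
    return replace(trace, smoothed=sm, sg_window=sg_window, sg_order=sg_order)


def fit_fluctuation_decay(
    trace: FluctuationTrace, sg_window: int = 150, sg_order: int = 2
) -> CompactionFit:
    """Exponential-decay fit of the smoothed, normalized fluctuation trace.

    The fluctuation is flat (high) while the molecule is free, then decays
    once compaction starts.  The onset of the post-peak decrease and the
    decay are fitted jointly with the piecewise model
    ``f(t) = c + A exp(-max(t - onset, 0)/tau)``, which is robust to the
    shoulder rounding introduced by the Savitzky-Golay smoothing.
    """
    if trace.smoothed is None:
        trace = smooth_fluctuation(trace, sg_window, sg_order)
    sm = trace.smoothed
    times = np.asarray(trace.times_s)
    i_peak = int(np.argmax(sm))
    tail = sm[i_peak:]
    if len(sm) < 10 or len(tail) < 5 or tail[0] <= tail[-1] + 1e-12:
        return CompactionFit(
            t_lag_s=None, tau_s=np.nan, amplitude=np.nan, baseline=np.nan,
            r_squared=np.nan, method="fluctuation", ok=False,
            message="no post-peak decay in the fluctuation trace",
        )

    def model(t, onset, tau, amp, c):
        return c + amp * np.exp(-np.clip(t - onset, 0.0, None) / tau)

    span = max(times[-1] - times[0], 1e-9)
    grad = np.gradient(sm, times)
    t0_guess = float(times[int(np.argmin(grad))])
    p0 = (t0_guess, span / 5.0, sm.max() - sm.min(), sm.min())
    bounds = ([times[0], 1e-9, 0.0, -1.0], [times[-1], 100.0 * span, 2.0, 1.0])
    try:
        popt, _ = optimize.curve_fit(model, times, sm, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return CompactionFit(
            t_lag_s=None, tau_s=np.nan, amplitude=np.nan, baseline=np.nan,
            r_squared=np.nan, method="fluctuation", ok=False, message=f"fit failed: {exc}",
        )
    onset, tau, amp, c = popt
    r2 = _r_squared(sm, model(times, *popt))
    ok = np.isfinite(r2) and 2e-9 < tau < 99.0 * span and amp > 1e-6
    return CompactionFit(
        t_lag_s=float(onset),
        tau_s=float(tau),
        amplitude=float(amp),
        baseline=float(c),
        r_squared=float(r2) if np.isfinite(r2) else np.nan,
        method="fluctuation",
        ok=bool(ok),
        message="" if ok else "decay fit unreliable",
    )
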