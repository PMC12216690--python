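"""Shared in-memory containers for calibrated images and analysis results.

All arrays are plain :class:`numpy.ndarray`; physical calibration (nm/pixel,
s/frame, ns/bin) rides alongside as dataclass fields.  Conventions: image
arrays are row-major with origin top-left; time is always the leading axis;
frame indices are 0-based and time coordinates are seconds from movie start.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class MovieStack:
    """Calibrated image time series in detector counts.

    ``frames`` has shape (time, rows, cols).  ``injection_frame`` marks the
    frame at which the binding partner enters the flow channel; kinetic lag
    times are measured from that frame's timestamp.
    """

    frames: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    injection_frame: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        _require(self.frames.ndim == 3, "frames must be 3-D (time, rows, cols)")
        _require(self.frame_interval_s > 0, "frame_interval_s must be positive")
        _require(self.pixel_size_nm > 0, "pixel_size_nm must be positive")
        _require(
            0 <= self.injection_frame < self.frames.shape[0],
            "injection_frame outside movie",
        )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def injection_time_s(self) -> float:
        return self.injection_frame * self.frame_interval_s


@dataclass
class Kymograph:
    """Space-versus-time image: column = frame, row = arclength position."""

    values: np.ndarray  # (space, time)
    roi_width_px: int
    pixel_size_nm: float
    frame_interval_s: float


@dataclass
class ClusterTrace:
    """Background-subtracted cluster ROI intensity per frame."""

    times_s: np.ndarray
    intensities: np.ndarray
    total_dna_intensity: np.ndarray  # per-frame whole-DNA intensity
    roi_centers: np.ndarray  # (n_frames, 2) row/col per frame
    roi_radius_px: float
    reliable: bool = True
    notes: str = ""


@dataclass
class CompactionFit:
    """Single-exponential compaction fit result.

    For the cluster-intensity method the model is
    ``I(t) = baseline + A (1 - exp(-(t - onset)/tau))``; for the fluctuation
    method it is a decaying exponential of the normalized variance trace.
    """

    t_lag_s: Optional[float]
    tau_s: float
    amplitude: float
    baseline: float
    r_squared: float
    method: str = "cluster"  # "cluster" | "fluctuation"
    ok: bool = True
    message: str = ""
    cluster_size_bp: Optional[float] = None


@dataclass
class FluctuationTrace:
    """Adjacent-frame variance series from the intensity-fluctuation method."""

    times_s: np.ndarray
    variance: np.ndarray
    smoothed: Optional[np.ndarray] = None
    sg_window: Optional[int] = None
    sg_order: Optional[int] = None


@dataclass
class AFMImage:
    """AFM height map in nm with lateral calibration in nm/pixel."""

    heights: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        _require(self.heights.ndim == 2, "heights must be 2-D")
        _require(self.pixel_size_nm > 0, "pixel_size_nm must be positive")
        _require(np.all(np.isfinite(self.heights)), "heights must be finite")


@dataclass
class DNAMask:
    """Binary DNA-pixel map plus the segmentation provenance that produced it."""

    mask: np.ndarray
    z_low_nm: float
    z_high_nm: float
    smoothing_iterations: int = 0


@dataclass
class SkeletonSet:
    """One-pixel DNA skeleton paths with quasi-Euclidean lengths."""

    skeleton: np.ndarray  # bool image
    path_labels: np.ndarray  # int image, 0 = background
    path_lengths_nm: np.ndarray
    pixel_size_nm: float

    @property
    def total_length_nm(self) -> float:
        return float(np.sum(self.path_lengths_nm))


@dataclass
class GrainTable:
    """Per-grain morphometrics table plus its label image.

    ``table`` columns: grain_id, row, col, x_nm, y_nm, area_nm2, volume_nm3,
    max_height_nm, equiv_diameter_nm, class, on_border, flags.
    """

    table: pd.DataFrame
    labels: np.ndarray

    COLUMNS = [
        "grain_id",
        "row",
        "col",
        "x_nm",
        "y_nm",
        "area_nm2",
        "volume_nm3",
        "max_height_nm",
        "equiv_diameter_nm",
        "class",
        "on_border",
        "flags",
    ]

    @staticmethod
    def empty(shape: tuple[int, int]) -> "GrainTable":
        return GrainTable(
            table=pd.DataFrame(columns=GrainTable.COLUMNS),
            labels=np.zeros(shape, dtype=int),
        )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture of grain volumes (monomer first)."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    converged: bool
    log_likelihood: float
    unimodal_warning: bool = False


@dataclass
class ClusterReport:
    """Grains above the k-sigma dimer-volume threshold, with protein counts."""

    cluster_threshold_nm3: float
    cluster_ids: np.ndarray
    cluster_volumes_nm3: np.ndarray
    protein_counts: np.ndarray  # real-valued volume ratios
    protein_counts_rounded: np.ndarray
    n_individual_blobs: int = 0


@dataclass
class BrightnessMap:
    """Per-pixel apparent brightness B = variance/mean of the count series."""

    B: np.ndarray
    mean_intensity: np.ndarray
    mask: np.ndarray  # True where B is defined
    detrend_window: Optional[int]


@dataclass
class BrightnessCursors:
    """Brightness intervals used to classify pixels into oligomeric species."""

    centers: dict = field(
        default_factory=lambda: {"monomer": 1.15, "dimer": 1.30, "oligomer": 1.60}
    )
    half_widths: dict = field(
        default_factory=lambda: {"monomer": 0.075, "dimer": 0.075, "oligomer": 0.075}
    )

    def __post_init__(self) -> None:
        names = list(self.centers)
        vals = [self.centers[n] for n in names]
        _require(
            all(b > a for a, b in zip(vals, vals[1:])),
            "cursor centers must be strictly increasing",
        )
        for (na, nb) in zip(names, names[1:]):
            hi_a = self.centers[na] + self.half_widths[na]
            lo_b = self.centers[nb] - self.half_widths[nb]
            _require(hi_a <= lo_b, f"cursor intervals {na!r} and {nb!r} overlap")

    def interval(self, name: str) -> tuple[float, float]:
        c, h = self.centers[name], self.half_widths[name]
        return (c - h, c + h)


@dataclass
class SpeciesMap:
    """Per-pixel species classification and per-class pixel fractions."""

    labels: np.ndarray  # int codes per LEGEND
    fractions: dict  # over classified pixels only
    n_classified: int
    flags: str = ""

    LEGEND = {0: "background", 1: "monomer", 2: "dimer", 3: "oligomer", 4: "unclassified"}


@dataclass
class DecayImage:
    """Per-pixel photon-arrival histograms over one modulation period.

    ``histograms`` has shape (n_bins, rows, cols); ``bin_width_ns`` times the
    bin count equals the modulation period.
    """

    histograms: np.ndarray
    bin_width_ns: float
    frequency_hz: float = 80e6

    def __post_init__(self) -> None:
        self.histograms = np.asarray(self.histograms, dtype=float)
        _require(self.histograms.ndim == 3, "histograms must be (bins, rows, cols)")
        _require(np.all(self.histograms >= 0), "histogram entries must be >= 0")
        period_ns = 1e9 / self.frequency_hz
        _require(
            abs(self.histograms.shape[0] * self.bin_width_ns - period_ns) < 1e-6 * period_ns,
            "bins x bin width must equal the modulation period",
        )


@dataclass
class PhasorCalibration:
    """Complex rotation + scale mapping a measured reference onto the circle."""

    tau_ref_ns: float
    measured_g: float
    measured_s: float
    rotation_rad: float
    scale: float


@dataclass
class PhasorMap:
    """Per-pixel (g, s) phasor coordinates at one harmonic."""

    g: np.ndarray
    s: np.ndarray
    counts: np.ndarray
    harmonic: int
    frequency_hz: float
    mask: np.ndarray  # True where phasor defined
    calibration: Optional[PhasorCalibration] = None

    @property
    def omega(self) -> float:
        """Angular modulation frequency at this harmonic, rad/ns."""
        return 2.0 * np.pi * self.frequency_hz * 1e-9 * self.harmonic


@dataclass
class FretFractionMap:
    """Per-pixel FRET efficiency along the quenched-donor trajectory."""

    efficiency: np.ndarray
    background_fraction: np.ndarray
    fret_positive: np.ndarray  # bool
    excluded: np.ndarray  # bool: background-dominated or undefined pixels
    fret_cutoff: float
    donor_tau_ns: float


@dataclass
class MaskRatioReport:
    """FRET-positive fraction inside/outside an IF-guided intensity mask."""

    fraction_inside: float
    fraction_outside: float
    ratio: float
    n_inside: int
    n_outside: int
    top_percent: float


@dataclass
class GelImage:
    """Grayscale gel scan; ``saturation_level`` is the bit-depth maximum."""

    values: np.ndarray
    saturation_level: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _require(self.values.ndim == 2, "gel image must be 2-D")


@dataclass
class LaneBox:
    """Lane rectangle with row spans (relative to the box) for the two bands."""

    x: int
    y: int
    width_px: int = 30
    height_px: int = 350
    bound_rows: tuple[int, int] = (40, 120)  # shifted band (runs high)
    unbound_rows: tuple[int, int] = (230, 310)  # free DNA (runs low)

    def __post_init__(self) -> None:
        for name, (r0, r1) in (("bound_rows", self.bound_rows), ("unbound_rows", self.unbound_rows)):
            _require(0 <= r0 < r1 <= self.height_px, f"{name} outside the lane box")
        b0, b1 = self.bound_rows
        u0, u1 = self.unbound_rows
        _require(b1 <= u0 or u1 <= b0, "band sub-regions overlap")


@dataclass
class BandQuantification:
    lane_id: str
    bound_intensity: float
    unbound_intensity: float
    percent_bound: float
    background: float
    empty_lane: bool = False
    saturated: bool = False
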