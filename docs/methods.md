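# Methods

`nanoquant` quantifies five kinds of imaging data that arise when studying
protein-driven DNA compaction: tethered-DNA fluorescence movies, dry-AFM
height maps of protein–DNA fields, photon-counting fluctuation stacks
(Number & Brightness), frequency-domain FLIM decay images, and EMSA gel
scans.  Every pipeline has a matched synthetic-data generator that produces
inputs with the statistical structure the analysis assumes, together with a
ground-truth manifest, so each estimator can be validated by parameter
recovery without access to instrument data.

## Compaction kinetics

**Model.** A doubly tethered λ-DNA molecule (48,500 bp) stained with an
intercalating dye emits intensity proportional to local DNA amount.  After a
lag time `t_lag` following protein injection, a compact cluster anchored at
one point along the molecule grows so that a fraction
`f(t) = 1 − exp(−(t − t_onset)/τ)` of the total fluorescence resides in the
cluster; `τ` is the compaction time.  Total expected intensity per frame is
conserved (photobleaching is an optional exponential multiplier, off by
default).

**Generator.** Frames are 2-D renderings: the DNA is a horizontal
Gaussian-profile line (σ = 1 px), the cluster a 2-D Gaussian (σ = 1.5–2 px)
at the anchor.  Two bookkeeping modes decide where cluster intensity comes
from.  The default, `"reel"`, absorbs whole DNA columns starting from the
ends farthest from the anchor while the remaining columns keep full
per-column intensity — the physical picture for an intercalating stain
(constant brightness per unit length, shrinking free length).  `"dim"`
removes intensity uniformly from the whole uncompacted segment instead.
Reeling is the default because it makes the inter-frame intensity variance
decay in proportion to the *amount* of free DNA, `∝ (1 − f)`, so the
fluctuation read-out recovers the same `τ` as the cluster read-out; uniform
dimming decays the variance as `(1 − f)²` and halves the apparent time
constant.  The uncompacted DNA jitters transversely between frames
(iid per column, σ = 1.5 px by default): this frame-to-frame positional
noise stands in for the conformational motion of a free tethered polymer —
it is what the fluctuation analysis measures — without simulating polymer
dynamics.  Default conditions: 48×200 px at 100 nm/px, 1 s/frame, 0.2
photons/bp/frame (≈9,700 counts per frame over the molecule), injection at
frame 10, `t_lag` = 30 s, `τ` = 20 s, Poisson noise.

**Cluster-intensity analysis.** The cluster ROI is defined on the final
frame and reverse-tracked via the intensity-weighted centroid inside a
search window of twice the ROI radius; per-frame drift is clamped at 3 px
(ties resolved toward the previous centre) and excessive drift flags the
trace unreliable.  The ROI mask is placed on integer pixel centres so that
sub-pixel centroid wobble cannot flicker the discrete pixel membership.
Background is the per-frame median of pixels outside the DNA region.
Cluster size in bp is the ROI sum over the whole-image DNA sum times the
genome length (48.5 kbp for λ-DNA).  Lag time: onset is the first frame
exceeding the pre-injection mean + 3 SD for 5 consecutive frames (both
configurable; the criterion is an operational choice — sub-frame precision
is not claimed).  Compaction time: least squares of
`I(t) = baseline + A(1 − exp(−(t − onset)/τ))` from the onset to the frame
first reaching 95% of the rise; frames past saturation carry no kinetic
information and, in the reel bookkeeping, are additionally biased by the
late absorption of the DNA running through the ROI.  A fit with undefined
R² (constant trace) or `τ` at its bounds is flagged failed, not raised.

**Fluctuation analysis.** Per frame, the mean of sub-median ROI pixels is
subtracted (clamped at 0) and the ROI sum equalized to the first frame's;
the variance series is the sum of squared adjacent-frame differences over
the ROI, zeroing pixels whose |difference| is below a floor — by default
the per-pixel shot-noise SD `sqrt(I_t + I_{t+1})` — so only genuinely
variant segments contribute.  The series is Savitzky-Golay smoothed
(order 2; window 150 by convention, configurable — our scaled-down movies
use shorter windows) and max-normalized.  Because smoothing rounds the
plateau-to-decay shoulder, the onset of the post-peak decrease and the
decay are fitted jointly with `f(t) = c + A exp(−max(t − onset, 0)/τ)`
rather than located by a separate peak rule; on generator output the
fluctuation `τ` agrees with the cluster `τ` to within ~10%.

## AFM morphometrics

**Preprocessing.** Iterative Gaussian smoothing (σ = 2 nm, window 5 nm,
i.e. a truncated sampled-Gaussian kernel), repeated until the
connected-component count of the DNA height band stabilizes, bounded to
3–8 passes.  Plane/line flattening is assumed done upstream; a per-row
median subtraction is available as a fallback.

**Segmentation.** DNA candidates are pixels with height in (0.1, 2.0) nm.
Protein cores are pixels ≥ 2 nm; each core claims the in-band pixels within
12 nm of it (its skirt), so a blob bound on DNA removes only its own
footprint rather than the whole connected strand.  In-band regions without
a core are discriminated by size and shape: ≥ 10 nm equivalent diameter is
reassigned to the grain table unless the region is curvilinear (skeleton
length at least twice its inscribed-disk width), the signature of a DNA
strand — a plain equivalent-diameter rule would misclassify any long thin
molecule, whose area-equivalent diameter is large.  Grains under 20 nm²
are dropped as noise.

**Skeleton length.** Masks are thinned to 1-px skeletons; path length is
the total edge length of the 8-connected skeleton graph with axial steps
counting 1 pixel and diagonal steps √2 (quasi-Euclidean), skipping a
diagonal when its endpoints share an axial neighbour so corner triangles
are not double counted.  Thinning erodes roughly half the ridge width at
each free end, so rendered-rod lengths are accurate to ~1–2% rather than
one pixel; one-pixel paths measure exactly.

**Volumes and oligomeric states.** Grain volume is Σ heights × pixel area
over the footprint dilated by 10 nm (without crossing a neighbouring
grain), which captures the sub-threshold skirt of a peak; a rendered
Gaussian cap of volume `2π σ² h` is recovered within 2%.  Volume samples
are decomposed into monomer/dimer populations by a two-component Gaussian
mixture (EM, k-means initialization, 10 restarts with fixed sub-seeds;
components ordered by mean).  Degenerate or collapsed fits (a weight
< 0.02) carry a unimodality warning.  Clusters are grains above
`dimer_mean + 7 × dimer_sd` (one-sided normal tail ~1e-12, i.e. single
dimers are essentially never called clusters); cluster protein count is
grain volume / dimer volume, reported real-valued and rounded.  Binding
density = (individually bound blobs + Σ rounded cluster counts) / total
skeleton length, per 100 nm and per kbp (0.34 nm/bp).  Bound blobs — the
automated surrogate for manual picking — are above-band footprints of
10–25 nm equivalent diameter within 14 nm of the DNA mask; the upper bound
keeps clusters from being double counted as blobs.

**Generator.** DNA is a discrete worm-like chain equilibrated in 2-D
(tangent-angle increments of variance ds/Lp, Lp = 50 nm), rendered as a
1.0-nm-high ridge of 6 nm FWHM; proteins are Gaussian caps (monomer
250 nm³ at 2.5 nm height, dimer 500 nm³ at 4.0 nm) composited by height
maximum — topography reads the top surface, a protein on DNA does not add
its height to the ridge.  Background roughness is zero-mean Gaussian,
σ = 0.05 nm.  Volume-mixture samples use exact class counts for fixed n.

## Number & Brightness

For a photon-counting detector, apparent brightness is B = variance/mean of
a pixel's count series and relates to molecular brightness ε
(counts/emitter/frame) as **B = ε + 1**; an n-mer of a calibrated monomer
(ε = 0.15, B = 1.15) appears at B = 1 + 0.15 n, giving the dimer (1.30) and
oligomer (1.60) cursors.  The generator draws compound-Poisson counts:
emitters N ~ Poisson(λ = 20) per pixel-frame, counts ~ Poisson(εN), plus an
optional fixed-rate Poisson background whose own B is exactly 1.  Slow
drifts are removed by subtracting a boxcar moving average (default 10
frames) and re-centring on the series mean; because subtracting a length-w
boxcar shrinks the variance of an uncorrelated series by (1 − 1/w), the
detrended variance is divided by that factor so B stays unbiased for
stationary series.  Cursor classification uses disjoint intervals (half
width 0.075, half the monomer–dimer spacing); the B map is median filtered
(3×3, once) before classification because the per-pixel variance estimator
at 100–500 frames has sampling noise comparable to the cursor spacing —
local pooling sharpens species separation without moving region means.
Fractions are reported over classified pixels; unclassified pixels are
reported, never force-assigned.

## Phasor FLIM-FRET

Each pixel's photon-arrival histogram over one 80-MHz modulation period
maps to `g + i s = Σ cᵢ e^{i n ω tᵢ} / Σ cᵢ` at harmonic n = 1 (bin-centre
timestamps).  Mono-exponential decays lie on the universal semicircle
`(g − ½)² + s² = ¼`; mixtures are intensity-weighted means of component
phasors.  A **half-bin correction** multiplies the raw sums by
`cos(ωΔ/2)` (Δ = bin width): for a bin-integrated folded exponential the
raw bin-centre sum equals `1/(cos h − i β sin h)` with `h = ωΔ/2`,
`β = (1+q)/(1−q)`, `q = e^{−Δ/τ}`, and multiplying by `cos h` yields
`1/(1 − i β tan h)` — exactly on the circle for any bin count, with
apparent modulation `β tan h → ωτ` as Δ → 0.  The correction is one
constant per harmonic, so phasor linearity is untouched.  Zero-count pixels
are masked, not NaN-propagated; 3×3 spatial median filtering is applied
twice to FLIM maps (once in the IF-mask recipe), both configurable.

Calibration computes the complex rotation+scale taking the count-weighted
mean phasor of a mono-exponential standard (fluorescein at pH 9, 4.04 ns)
onto its closed-form circle point, and applies it to every pixel;
calibrating an already-calibrated map against its calibrated reference is
the identity.  Two-species fractions are orthogonal projections onto the
chord between the pure phasors (equal to the per-pixel least-squares
weight), clipped to [0, 1].  FRET analysis builds the quenched-donor
trajectory of circle phasors at lifetimes `τ_D(1 − E)` (E on a 100-point
grid over [0, 0.99]); each pixel is modelled as background + trajectory
point, assigned the E minimizing the residual to the background-to-
trajectory chord, with the chord position giving the background fraction.
Pixels above 90% background are excluded; FRET-positive means E ≥ 0.1 (the
cutoff is recorded in the output — cursor placements are instrument
conventions, not physical constants).  The IF-guided mask keeps the top 5%
intensity pixels of the median-smoothed immunofluorescence image; the
report compares FRET-positive fractions inside vs outside.

The FLIM generator samples Poisson photons from exact bin integrals of the
folded decay `e^{−t/τ}/(τ(1 − e^{−T/τ}))`; the instrument response is ideal
by default (the fluorescein reference absorbs real-world IRF effects), with
an optional circular-Gaussian IRF.

## Gel densitometry

A lane box (default 30 × 350 px) contains row sub-regions for the shifted
(bound) and unshifted (free) bands.  Background is the median of lane
pixels outside both bands, subtracted per pixel and clamped at zero;
percent bound = 100 × bound/(bound + unbound) — the only reading of the
bound-vs-total convention that stays in [0, 100] — making the measure
invariant under global rescaling.  Lanes with > 1% saturated pixels are
flagged.  Competition uptake at each input concentration is
`100 × (control_free − sample_free)/control_free`; a zero control is an
error for that point (NaN + flag).  The generator renders bands as
vertical Gaussian profiles carrying fractions f and 1 − f of the lane
signal over a uniform background.

## What the generators do and do not emulate

The generators reproduce the *statistical structure* each estimator relies
on: intensity bookkeeping and shot noise for compaction movies, height-band
geometry and additive roughness for AFM, compound-Poisson photon statistics
for N&B, folded exponential decays for FLIM, band-integral conservation for
gels.  They do not emulate polymer dynamics, optical PSFs, tip–sample
convolution, detector afterpulsing, IRF dispersion, or gel smearing — so
passing recovery tests demonstrates estimator correctness under the model's
assumptions, not robustness to every instrument artefact.

## Numerical choices and problem sizes

Fits use `scipy.optimize.curve_fit` with bounded parameters and
data-derived initial guesses; failed convergence, undefined R², or bound
hits produce flagged results rather than exceptions.  Degenerate inputs
(empty masks, zero totals, single frames) raise `ValueError` with specific
messages, except where a distinguished result is meaningful (no-compaction
lag = `None`, empty-lane flag).  Test and validation workloads use desk-
scale sizes chosen to keep every estimator in its asymptotic regime:
120–220-frame movies of 48×200 px, 500×500 px AFM fields at 2 nm/px,
64×64×500 N&B stacks, 256–4096-bin decay histograms, 10⁶-sample Monte
Carlo for the cluster-threshold tail, and 20-seed replicate ensembles.

## Known limitations

Reverse tracking assumes one dominant cluster; multi-cluster molecules need
per-cluster ROIs.  Skeleton length slightly underestimates rendered-ridge
lengths at free ends (thinning erosion) and the quasi-Euclidean metric
overestimates smooth curves by up to ~8% at 45° staircases.  The
two-Gaussian EM fit assumes exactly two volume populations.  The FRET
background unmixing uses a single global background phasor.  Lane boxes
are user-supplied; there is no automatic lane detection.
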