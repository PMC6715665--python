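# Methods

This note documents the models, conventions and numerical choices behind
`annulodyn`, and what the synthetic-data validation does and does not show.

## Crystal layout and chord definitions

Crystals 1–3 sit at the leaflet nadirs (NC, RC, LC), 4–6 at the
interleaflet triangles (LR, LN, RN), 7 at the LV apex and 8 high in the
ascending aorta. Because nadirs alternate with commissures around the ring,
the ring order is fixed to 1-6-2-4-3-5, and each of the three
cross-sectional diameters joins a nadir to the opposite commissure
(1–4 NC–LR, 2–5 RC–LN, 3–6 LC–RN). A sinus runs commissure-to-commissure
through its nadir, so its length is defined as the sum of the two ring
chords flanking the nadir; this makes NC + RC + LC = AAC an exact identity,
enforced per frame. The layout is a configurable object
(`CrystalLayout`) should a different labelling convention be needed; the
validator rejects ring orders that are not permutations of 1..6 and
diameter pairs that are not ring-opposite.

## Coordinate reconstruction and area

Each 8×8 distance matrix is embedded by classical multidimensional scaling:
double-centre the squared distances, eigendecompose, keep the top three
non-negative components. For exact Euclidean inputs the residual stress is
at machine precision (< 1e-9 mm, tested). Orientation is fixed by
convention only (annular centroid at origin, first ring crystal along +x,
apex at negative z) — all reported quantities are rigid-motion invariant.
Up to 20% of off-diagonal entries may be missing; they are completed with
graph shortest-path distances before embedding, which upper-bounds the
missing distances and is adequate for the near-convex annular
configuration. More missing data raises an error; an all-zero matrix
returns coincident points with a degenerate flag.

The annulus area is the shoelace area of the hexagon after orthogonal
projection onto the least-squares plane of the six annular points (plane
from the points' principal axes). For near-planar rings the projection
error is second order in the out-of-plane excursion. Circumference, sinus
lengths and diameters are read directly off the distance matrix and carry
no embedding error. Collinear points yield zero area with a warning.

## Beat segmentation and landmarks

dP/dt is computed as a central difference after Savitzky–Golay smoothing
(quadratic, default 7 ms window ≈ 11 samples at 1613 Hz); both steps are
exact on polynomials up to degree 2, so constant and ramp inputs give exact
derivatives, and the symmetric window does not displace extrema of
band-limited waveforms. R peaks are prominent local maxima (adaptive
prominence: half the excursion of the maximum above the median) separated
by at least `min_rr_s` (default 0.3 s). Per RR window: the dP/dt maximum is
the argmax; ES is the dP/dt minimum between consecutive dP/dt maxima; MS
and MD are arithmetic midpoints of their bracketing landmarks — the only
parameter-free reading of "the time point between". Beat windows run ED→ED;
since MD needs the following beat's dP/dt maximum, n R peaks yield n−2
complete beats (the default protocol therefore simulates 13 beats to
analyse 10). Beats violating the ordering
ED ≤ dP/dt-max < MS < ES < MD < next-ED are dropped and counted.

Per-beat Maximum/Minimum searches use the raw series over the full beat
window with no pre-filtering (a light low-pass is available but off by
default). The one exception is the transvalvular gradient, a max-statistic
of the difference of two noisy channels: LVP − AoP is passed through the
same light quadratic smoother before the per-beat maximum over
[dP/dt-max, ES] is taken, so the statistic reflects the waveform rather
than single-sample noise.

## Force processing

Each arm's raw bridge output maps to Newtons through a per-arm
least-squares line fitted to calibration pairs (≥ 2 distinct loads; a
non-positive slope aborts, signalling a polarity fault). Forces are zeroed
at mid-diastole per beat, with offsets linearly interpolated between MD
landmarks and held constant beyond the first and last; per-beat zeroing
removes slow drift and provably leaves Max−Min amplitudes unchanged
(tested, along with intercept invariance and linear scaling in the slope).
Cross-talk between arms is not modelled. The peak-phase label is the
inter-landmark interval containing the beat's force maximum, with a
"near-MS" band of ±5% of cycle length around MS.

## Statistics

Measurements enter as long-format rows (animal, segment, beat, value).
Summaries average beats within animal before taking mean and sample SD
(n−1) across animals. The repeated-measures model is

    value ~ segment + cycle + animal,   Var(ε) = σ²_segment

with all factors fixed (animal as block) and cycle categorical. It is
fitted by iterative FGLS: WLS given the current variances, then
per-segment residual-variance re-estimation with a group-prorated
degrees-of-freedom correction (SSR_g / (n_g − p·n_g/n)), iterated to a
relative tolerance of 1e-8 (max 50 iterations; non-convergence is flagged,
not fatal). Exactly-fitting groups get a tiny variance floor so weights
stay finite. The coefficient covariance is (XᵀWX)⁻¹ from the final
weighted fit. Pairwise segment contrasts use Wald z = Δ̂/SE(Δ̂) with
two-sided normal p-values and no multiplicity correction; α = 0.05.
Design choices left open by the problem: animal as fixed block rather than
a random intercept (avoids committing to an unstated covariance
structure), cycle categorical rather than a trend, and variance grouped by
segment only. A single-animal table is accepted by dropping the block
factor (noted in the result) so the per-dataset pipeline can compare arms
within one recording. Under a heteroscedastic null (7 animals × 10 beats,
SDs 0.5/0.6/2.1), the empirical type-I error of the pairwise z-tests is
≈ 0.057 over 2000 replicates (tested band 0.03–0.07); the small upward
bias is the usual normal-versus-t approximation at these group sizes.

## Synthetic generator

The generator is first-class, validated code; its defaults are the study
conditions wherever those are printed, and one-time physiological choices
elsewhere:

* HR 93 min⁻¹; LVP range (8, 93) mmHg; AoP range (55, 70) mmHg so the peak
  transvalvular gradient is 23 mmHg; annular radius 12.0834 + 0.7333 mm
  activation (hexagon perimeter spanning 72.5→76.9 mm when circular);
  arm amplitudes LN 1.20 / RN 1.61 / LR 2.87 N, LR peaking at MS and
  LN/RN midway between MS and ES; sampling 297 / 1613 Hz; 13 simulated
  beats for 10 analysed.
* Motion model: the six annular crystals lie on a planar ellipse; the mean
  radius follows a full-cycle raised cosine peaking at MS; the axis ratio
  interpolates from 1 at MD to `ellipticity_max` (default 1.3) at MS with
  the long axis along NC–LR — so the ring is oval in systole and round in
  diastole. Optional out-of-plane wobble (default 0.3 mm) exercises plane
  fitting without dominating the area. Per-ring-position phase lags are
  available (default 0).
* LVP is a raised-cosine systolic pulse over a 0.45-cycle systole, wrapped
  across the beat boundary so its foot (which precedes the R peak) stays
  continuous; this gives exactly one dP/dt maximum and one minimum per
  beat. The R spike (Gaussian, σ = 8 ms, 1.2 mV) precedes the dP/dt
  maximum by 40 ms — a standard electromechanical delay that keeps ED
  ahead of the systolic landmarks. AoP equals LVP minus a gradient pulse
  while the valve is open and decays exponentially (τ = 0.18 s) toward its
  floor in diastole.
* Forces are full-cycle raised cosines (amplitude = exact Max−Min per
  beat); strain channels invert the per-arm linear calibration, whose
  slope/intercept are configurable and whose pairs are emitted at five
  loads spanning 0–5 N. Strain noise is specified in force units
  (default SD 0.005 N, consistent with a calibrated bridge chain at
  Newton-scale loads) and divided by the slope before entering the raw
  channel.
* RR jitter is multiplicative Gaussian on the cycle length, clipped at
  ±3 SD (default 0.005 s). All noise comes from one seeded generator in a
  fixed draw order, so identical protocol + seed reproduces the streams
  byte for byte after serialization.

What the generator does *not* emulate: real sonomicrometry artefacts
(echo dropouts with level-dependent bias, trigger jitter), baseline wander
and mains interference on the analogue channels, arrhythmia, respiratory
modulation, transducer cross-talk, and any tissue mechanics. Passing
recovery tests therefore demonstrates that the pipeline is correct and
well-conditioned at realistic SNR, not that it is robust to every artefact
of in-vivo recordings.

## Numerical conventions and degenerate inputs

Text dialects store values at 6-decimal fixed precision; read(write(x))
is exact at that precision and the writer is byte-stable. Resampling and
landmark sampling use linear interpolation (exact on linear signals, no
overshoot). Missing-sample gaps of ≤ 5 sonomicrometry frames are linearly
interpolated; longer gaps flag the affected frames, which geometry
excludes and reports. Alignment requires ≥ 2 s of overlap and records the
estimated lag; without an LVP copy in the sonomicrometry stream the
declared time origins are trusted. The ovality threshold is a strict
inequality at 3 mm. Reported HR is rounded to the nearest integer;
Change cells in reports must equal Max − Min within 0.1 (the reporting
precision), one of the self-consistency checks `report_consistency`
applies together with the sinus-sum identity and landmark ordering.

## Problem sizes

Validation runs use 13 simulated beats (10 analysed) at the native
sampling rates — about 2,600 distance frames and 14,000 analogue samples
per dataset — and 2,000 replicates of the 7-animal × 10-beat × 3-segment
design for the null-calibration study of the Wald tests. These sizes give
Monte-Carlo standard errors comfortably inside the tested tolerance bands.

## Known limitations

* The area estimand is the plane-projected hexagon area; the vendor
  software behind the original measurements is a black box, so equivalence
  is declared, not assumed.
* The FGLS block design is an approximation to an unstated mixed model;
  with few animals its Wald tests are mildly anticonservative (see above).
* Landmark times inherit dP/dt noise (tens of ms jitter at default noise);
  quantities sampled at landmarks are near local extrema of smooth curves,
  so the induced error is second order, but sharper waveforms would need
  heavier smoothing.
* The shortest-path completion of missing distances is an upper bound, not
  an EDM completion; it is only used when a frame is otherwise unusable.
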