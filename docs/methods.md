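# Methods

This note documents the models, parameters, and numerical choices behind
`spheromet`, and what the synthetic validation does and does not show.

## Coordinate and unit conventions

Arrays are `[row, col]`; coordinates are pixel-centered with `x = column`,
`y = row`, origin at the top-left pixel center. All physical quantities are
µm (distances), µm² (areas), via the image's `pixel_size` (µm/pixel).
Intensities are arbitrary units on a loosely 16-bit-camera-like scale.
8-connectivity is used for all labeling, erosion, and dilation.

## Synthetic spheroid scenes

A scene renders three registered channels on an H×W grid (default 256×256
at 2 µm/px):

* **Spheroid geometry.** Border radius r(θ) = R·(1 + a·cos kθ) around a
  configurable center (default: image center). The lobe amplitude `a`
  (default 0) and lobe count `k` (default 3) give analytic control of
  rotational symmetry; `a = 0` yields a disk whose pixel sampling is
  exactly invariant under the dihedral symmetries of the grid.
* **DiL radial profile.** With u = ρ/r(θ): a plateau at the peak value
  (1000 a.u.) out to u = 0.05, a linear decay crossing exactly 60% of peak
  at u = `core_fraction` (default 0.6), then a half-cosine taper reaching
  zero *with zero slope* at the border. The C¹ approach to zero matters
  numerically: a hard intensity edge leaks ~10⁻³ of angular-moment energy
  into the 4-fold lattice harmonics of the symmetry score (square-grid
  quadrature error), while the tapered profile keeps that leakage near
  2×10⁻⁷, i.e. the symmetric-disk score is 1 to well under 10⁻⁶. The
  plateau guarantees that the 99.9th-percentile clip used by the
  compactness threshold equals the true peak. An alternative `uniform`
  profile fills the mask with the peak value (all-core limit).
* **Brightfield.** Background 1000 a.u.; inside the spheroid attenuated by
  600 + 100·profile. After max-based inversion this puts the spheroid
  ≥ 600 a.u. above background, leaving no intensity between background and
  spheroid on noiseless scenes — Otsu then reproduces the true mask
  exactly, and stays robust when noise shifts the inverted background.
* **Matrix cells and conglomerates.** Cells are DiL Gaussians (amplitude
  600, σ = 2 px) with a flat sytox disk (radius 4 px) at 8000 a.u. (dead)
  or 400 a.u. (live) — strictly either side of the 3×10³ dead cut-off, so
  labels are recoverable at zero noise. Conglomerates are DiL Gaussians
  (amplitude 3000, σ = 6 px) whose summed intensity (~6×10⁵) is above the
  2×10⁵ exclusion threshold by construction; cell sums (~1.1×10⁴) are far
  below it. Object centers are placed by an iterative projection onto the
  set of points at the requested distance from the border pixel set
  (p ← b + d·(p−b)/|p−b| with b the current nearest border pixel), with
  rejection of positions inside the mask, too near the image edge, or
  whose footprint would touch another object's. Recorded ground-truth
  distances are the exact brute-force minima from the true (sub-pixel)
  centers to the border pixel set. When no distance list is given,
  distances are drawn uniformly over the annulus that fits the image.
  Dead labels go to a seeded random subset of exactly
  round(dead_fraction·n) cells.
* **Noise.** Additive Gaussian, one unit-normal field per channel scaled
  by `noise_sd`, so a noise ladder on a fixed seed shares one realisation
  — this makes "segmentation quality degrades monotonically with noise"
  a testable statement rather than a statistical one. Values are not
  clipped at zero.

Defaults (30 matrix cells, 1/3 dead, 3 conglomerates) mirror the scale of
matrix-cell counts reported in spheroid outgrowth experiments (tens of
cells per spheroid).

## Segmentation

The composite is Σ w_c·channel_c with brightfield replaced by
max(brightfield) − brightfield before weighting (equal weights over all
channels if none are given; the scene pipeline uses brightfield + DiL —
adding sytox would let one bright dead cell dominate max-normalised
thresholds). Cut-off policies: absolute, fraction-of-max (default 0.2 in
`segment_spheroid`; scale-invariant), or Otsu (scale-invariant; the
pipeline default, because the max-based inversion shifts the background
level of noisy images). After thresholding: hole filling (spheroid
interiors can dip below threshold), largest 8-connected component (this
is what makes detection independent of surrounding cells), border = mask
pixels 8-adjacent to background, ordered by polar angle about the
centroid (well-defined for star-convex spheroids). An empty foreground
returns an explicit "no spheroid" (`None`), not an exception.

If a z-stack is supplied upstream, channels should be reduced by
maximum-intensity projection before merging; the generators emit single
planes.

## Morphometry

* **Symmetry.** Masked intensity is mapped onto the unit disk at the mask
  centroid; the radius is the enclosing-circle radius (default) or the
  equivalent-area radius. Moments Z_nm = Σ ρⁿ e^(−imφ)·I over mask pixels
  for 0 ≤ m ≤ n ≤ 8 (configurable), n−m even — the index lattice of a
  Zernike basis with monomial radial part. Score
  1 − Σ_{m>0}|Z_nm|/Σ_{all}|Z_nm|, clipped to [0,1]: bounded,
  scale-invariant, exactly invariant under 90° rotations, and maximal for
  rotational symmetry. The scalar aggregation (m>0 energy ratio) is a
  design choice; the moment magnitudes themselves are not exposed because
  no downstream readout needs them.
* **Threshold compactness.** s_border = spheroid area; s_body = area of
  mask pixels with intensity ≥ core_fraction (default 0.6) of the in-mask
  maximum, where the maximum is the 99.9th percentile of in-mask
  intensities to resist hot pixels. Both the conventional
  c = s_body²/s_border (µm²) and the dimensionless s_body/s_border are
  reported; treated-vs-control comparisons are insensitive to which is
  used. "s_border" is interpreted as the enclosed spheroid *area* (not
  border length); reporting both raw and normalised values keeps relative
  comparisons independent of that interpretation.
* **Profile.** Mean over border pixels of the Euclidean distance to the
  nearest core pixel (same core definition as compactness), in µm,
  computed with an exact Euclidean distance transform of the core
  complement; it agrees with a brute-force nearest-core search to float
  precision. An empty core yields NaN ("undefined profile") — reachable
  only for degenerate intensities, since the core threshold is relative
  to the in-mask maximum.

## Matrix-cell outgrowth

Detection thresholds the DiL channel outside a 1-pixel-dilated spheroid
mask (the guard ring keeps border-touching fragments out), on a copy
smoothed with a σ = 1 px Gaussian for noise robustness; sums, means and
centroids are measured on the raw channels over the detected component.
Components smaller than `min_area` (default 12 µm²) are dropped. The
default absolute detection cut-off (150 a.u.) is ~4.4 noise SD after
smoothing at the signal-to-noise-5 condition. Classification applies the
printed cut-offs with strict inequality ("higher than"): summed DiL
> 2×10⁵ ⇒ excluded conglomerate; then mean sytox > 3×10³ ⇒ dead.
Boundary-equal objects are retained/live; both cut-offs are configurable.
Distances are centroid-to-border by default (robust to segmentation
jitter); a nearest-object-pixel variant is available. A centroid inside
the mask reports distance 0 with an `inside_spheroid` flag. Summaries
partition detected = excluded + live + dead; viability % and the mean
distance are over live cells only, and are reported as missing (None)
when their denominators vanish — never as 0.

## Tracking

Detection: threshold (default: 5% of frame maximum, low enough to keep
faint blob tails and sub-pixel centroid accuracy), label, intensity-
weighted centroids, sorted by (x, y) for deterministic ids. Linking:
greedy mutual-nearest-neighbour between consecutive frames within
`max_step`; ties resolved by smaller distance then smaller id; unmatched
detections open new tracks; no gap closing (a missed detection terminates
the track — terminated tracks are counted, not hidden). On scenes whose
inter-cell spacing exceeds twice the per-frame step the linking is exact.
Accumulated distance uses raw centroids — smoothing would bias motility
downward. Cluster area is total foreground area above the cut-off, with
an optional ratio to a t = 0 reference (undefined if the reference is 0).

The time-lapse generator starts cells on a jittered grid whose pitch
guarantees the spacing for the whole sequence (straight mode: exact drift
bound; random-walk: 3× the rms net displacement of the Rayleigh walk) and
raises a configuration error when the requested cell count cannot fit.
Random-walk steps have uniform headings and Rayleigh(scale = step_length)
lengths, so the expected accumulated distance is
(n_frames−1)·scale·√(π/2) with genuine sampling variability — a
fixed-length walk would make the 3-SE comparison degenerate (SE → 0, with
sub-pixel detection jitter as the only error term).

## Cytometry

Event tables are CSV/DataFrames (one row per event; binary FCS parsing is
out of scope). Gates run sequentially: singlets by fsc_h/fsc_a within a
band (default 0.85–1.10), a configurable scatter rectangle (manual gates
cannot be recovered, so no automated clustering), DAPI⁻ by threshold
(default 1000 a.u.). MFI is the arithmetic mean (geometric available by
flag — practice varies). Correction subtracts the unstained MFI *matched
by treatment*; a mismatch raises, because subtracting the wrong condition's
autofluorescence is precisely the error the matched design prevents.
Negative corrected MFIs are reported as-is (clipping would bias fold
changes); fold change is undefined (None) for a non-positive control.
Floater counting deliberately skips the viability gate: fixed,
permeabilised cells are all DAPI⁺ and the absolute nucleated-event count
is the readout.

The generator's marker values are expected·LogNormal(−σ²/2, σ) with
σ = 0.25, so event means equal expectations; expected = baseline (default
0) + shift (treated only) + stain (stained only). Doublet and DAPI⁺
labels are exact-count seeded subsets (round(fraction·n)), making
count-based readouts exact by construction while fractions among gated
subsets remain binomial.

## What the synthetic validation shows — and what it does not

Passing the suite demonstrates that the *computational* pipeline is
correct: the distance computations equal brute-force oracles to 10⁻⁶ µm,
counts/labels/distances are recovered exactly in the noiseless limit and
degrade gracefully (≤5% count error at SNR 5), the morphometry metrics
take their analytic values on constructed shapes, and the correction
arithmetic is shift-invariant. The generators do not emulate optics
(point-spread functions, vignetting, z-sectioning), cell morphology
heterogeneity, touching/overlapping cells, spectral bleed-through, or
non-Gaussian camera noise — so these results bound algorithmic error, not
biological measurement error on real images. Multi-spheroid scenes,
machine-learned segmentation, mitosis-aware lineage tracking, and
multi-parameter spectral autofluorescence unmixing are out of scope; the
scalar matched subtraction is the correction implemented.

## Problem sizes used in the validation

20 scenes of 256×256 px for the oracle and recovery suites; 200 cells ×
13 frames on 1536×1536 px frames for tracking; 10⁴ events per cytometry
condition. These sizes put sampling error well below the tolerances being
checked while keeping the full suite around a quarter of a minute.
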