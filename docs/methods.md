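# Methods

`sxpre` preprocesses serial (femtosecond) crystallography detector frames:
it decides per frame whether enough Bragg peaks are present (a *hit*),
builds pixel masks, accumulates powder patterns from the accepted peaks,
and calibrates the detector geometry from powder rings. This note records
the models implemented, the defaults and why, what the synthetic data
emulate, and the numerical choices that are not forced by the mathematics.

## SNR hit finder

Per frame: the raw image is Gaussian-smoothed (`gauss_sigma`, default 1 px,
reflective boundaries), a central-difference gradient magnitude is taken,
and local maxima of the gradient above `min_gradient` (default 30 ADU/px),
mutually separated by `min_distance` (default 5 px) and restricted to
mask-valid pixels, become peak candidates. Because a symmetric peak's
gradient vanishes at its apex, each candidate is re-centred on the raw
image's local maximum within ±1 px before a 7×7 crop is cut; candidates
closer than 3 px to an edge are skipped rather than zero-padded, and
duplicates after re-centring are merged.

Signal and background pixels within the crop are chosen by one of three
schemes:

* **rings** — signal: distance ≤ r1 from the crop centre; background: the
  r2 ≤ d ≤ r3 annulus (defaults 1, 2, 3 px). Appropriate for compact peaks
  whose tails do not reach the annulus.
* **simple** — order statistics: the `n_signal` = 10 highest and
  `n_background` = 35 lowest intensities. Ties are broken by row-major
  position (stable sort), so results are deterministic on plateaus.
* **adaptive** (default) — the lowest 70% of crop pixels
  (`bg_fraction` = 0.70) form the background; pixels above
  mean(bg) + `n_sigma`·std(bg) (default n = 5) are signal. This is the
  recommended first-round scheme: it adapts to peaks of varying size with
  a single parameter.

The peak statistic is SNR = (⟨I_sig⟩ − ⟨I_bg⟩)/σ_bg with population
standard deviations throughout; it is invariant under any affine intensity
transform a·I + b (a > 0), so gain and offset changes do not move the
threshold. Peaks are kept when SNR ≥ `min_snr` (default 5) and the
signal-pixel count lies in [`min_signal_pixels`, `max_signal_pixels`]
(defaults 2 and 40) — the upper bound screens ice rings and detector
artifacts. Masked pixels are excluded from both regions; a peak whose
background degenerates (< 2 pixels or zero spread) is discarded. A frame
is a hit when ≥ `min_peaks_for_hit` peaks survive (default 20, typical
serial-crystallography practice).

## Poisson hit finder

The frame is converted to integer photon counts (divide by
`adu_per_photon`, round half away from zero, clip negatives from detector
noise at 0). Each pixel's background rate b is the mean photon count of
its radial ring around the beam centre (`ring_width` = 1 px; rings left
empty by the mask inherit the nearest populated ring's value). The
per-ring threshold is the smallest integer K with
P(X ≤ K) ≥ 1 − ε for X ~ Poisson(b), evaluated via the Poisson quantile
function and cross-checked in the tests against brute-force cumulative
summation; a pixel is signal only when its count **exceeds** K. ε
defaults to 1e-5, so on a peak-free frame at most a fraction ε of pixels
is flagged per ring. Connected components of the signal map
(`connectivity` 4 by default, 8 optional) whose size lies in
[`min_signal_pixels`, `max_signal_pixels`] become peaks at their
photon-weighted centroid. The background is estimated from the frame being
tested itself; there is no inter-frame running background. Peak-record
background statistics use the ring rate (mean b, std √b), with SNR
reported as (mean signal − b)/√b and +inf in the degenerate b = 0 case.

## Masks, reference images, powder patterns

Mean/sigma reference images use the population (÷N) standard deviation.
Threshold masks are two-sided windows [vmin, vmax] (one-sided with
infinite bounds); a σ = 0 pixel is dead and is excluded by any positive
vmin. Morphology acts on the *excluded* set with a full 3×3 structuring
element — dilation grows the bad region — and pixels beyond the detector
edge count as excluded, which keeps dilate-then-erode extensive. Mask
composition is a logical AND of validity. The eraser sets a Euclidean disc
(on pixel centres) to excluded or valid, clipped at the image edge.
Powder accumulation concatenates peak lists; the powder image keeps the
per-pixel *maximum* peak intensity across frames rather than the sum,
preserving sharp rings for calibration.

## Geometry calibration

The forward model is the exact cone–plane intersection. The lab frame has
the sample at the origin and the beam along +Z; the detector plane passes
through (0, 0, D) with unit normal n̂(θ_t, φ_t), and the in-plane pixel
axes are the minimal rotation of the lab X/Y axes carrying ẑ to n̂. A ray
at scattering angle 2θ and cone azimuth ψ meets the plane at
t = D·cosθ_t/(ŝ·n̂); positions are expressed in pixels relative to the
beam centre. The inverse (pixel → 2θ) is exact, and the tests require
round-trip agreement to 1e-9 rad.

Calibration runs in two steps:

1. **Closed-form seed.** Peak radii about the current beam-centre guess
   are clustered into rings with DBSCAN (1-D radii; eps = 10 px,
   min_samples = 4 — calibrant rings are well separated, which is why a
   small-unit-cell calibrant is used in the first place); noise points are
   dropped. Ring centres are the mean of member positions. Under a tilt
   the ring centres drift along a common line; a total-least-squares line
   through them (TLS, symmetric in x/y) gives the tilt azimuth — centres
   drift *away from* φ_t as 2θ grows, so φ_t is the direction opposite the
   inner→outer line direction. Signed centre offsets along that line are
   regressed against tan²(2θ_i). For centroid-based centres with
   near-uniform azimuthal coverage the first-order offset is
   ½·D·tanθ_t·tan²2θ (the mean of cos²ψ is ½ — half the true
   ellipse-centre offset, which the midpoint of the two extremes along the
   tilt direction attains), so the slope k gives
   θ_t = arctan(2k·pixel/D), and the beam centre is the innermost ring
   centre pulled back by δ₁ = D·tanθ_t·tan²(2θ₁)/(2·pixel). Rings whose
   centres coincide within 0.05 px are reported tilt-undetectable
   (θ_t = φ_t = 0). Any residual bias of these small-tilt approximations
   only perturbs the seed.
2. **Nelder–Mead refinement.** The residual
   R = Σ_i Σ_j (2θ_ij^calc − 2θ_i^model)² is minimized over (x_c, y_c, D,
   and the tilt expressed as the well-conditioned pair
   t_x = θ_t cosφ_t, t_y = θ_t sinφ_t); the wavelength can optionally be
   freed, but is fixed by default because λ and D are nearly degenerate
   for small-angle rings. Model angles come from Bragg's law,
   2θ_i = 2·arcsin(λ/2d_i), with rings matched to calibrant d spacings by
   rank order (innermost ring ↔ largest d; a count mismatch is a hard
   error, not a guess). The simplex runs at most 2000 evaluations with
   xatol 1e-9 / fatol 1e-15; if it somehow ends above the seed residual
   the seed is returned, so the refined residual never exceeds the step-1
   residual.

On the standard synthetic conditions (5 rings × 60 peaks, D = 100 mm,
0.1 mm pixels, 12 keV, θ_t = 0.02 rad, φ_t = 30°, initial guess 6–11 px
and 2% in D off the truth) the noiseless recovery is exact to ~1e-10 px
and the 0.2 px-jitter recovery is within ~0.05 px in the centre and
~0.005% in D (see `scripts/acceptance.py`).

## Batch execution

Jobs (compress, hits, peak2cxi) are split into batches of `batch_size`
frames (default 1) and dispatched dynamically to a serial or local
multiprocess engine; the engine layer is deliberately thin so cluster
schedulers can be added behind the same interface. Per-frame outputs
depend only on the frame and the parameters, and the master reassembles
them in frame order, so serial and parallel runs produce byte-identical
output files (HDF5 is written with `track_times=False` to keep files
bit-reproducible). A failed batch is retried once in the master before
the job is marked failed with the offending frame named. Projects use the
raw_lst/ (frame lists), cxi_comp/ (compressed stacks), cxi_hit/ (hit
files) layout; CXI files place the image stack at `entry_1/data_1/data`
and peak tables at `entry_1/result_1/*` (fixed-width, zero-padded rows),
compressed with gzip level 4 in one-frame chunks.

## Synthetic data: what it emulates, what it does not

`sxpre.synth` generates frames as `adu_per_photon` × Poisson(rate), where
the rate is a flat background b plus 2-D Gaussian peaks integrated over
pixel areas — both hit finders therefore see realistic count statistics.
Defaults model a typical single-panel setup: b = 3 photons/pixel, 20
ADU/photon, 256×256-pixel test frames, hit frames carrying 30 peaks of
150 photons (σ = 1.2 px) separated by ≥ 12 px, 10% hit fraction. Powder
peak sets are exact forward-model projections of calibrant rings at
uniform cone azimuths plus optional Gaussian jitter. All generators are
pure functions of their spec including the seed.

Not emulated: structure-factor physics, polarization and solid-angle
falloff, detector point-spread, gain dispersion, saturation, multi-panel
geometry, and correlated backgrounds (water rings, jet streaks). Passing
tests therefore demonstrate the statistical behaviour of the detectors
and estimators under Poisson noise, not robustness to every artifact of
real facility data; on real data the screening parameters exist precisely
to absorb what the generator leaves out. Test problem sizes (50-frame
datasets, 200-frame false-positive simulations, 300-peak powder sets)
were chosen so each statistical bound has comfortable power while the
whole suite stays quick.

## Known limitations

* Peak positions from the SNR finder are integer pixels (re-centred local
  maxima); sub-pixel interpolation is deliberately out of scope, so for
  broad peaks (σ ≳ 1 px) localization error can exceed 1 px even when the
  peak is found.
* The rings scheme assumes the peak fits inside r1; broad peaks leak into
  the background annulus and depress the SNR. Use simple/adaptive for
  wide or variable peak sizes.
* Calibration handles single-panel detectors (or multi-panel with known
  metrology) and non-overlapping calibrant rings; ring↔d matching is by
  rank order only.
* The Poisson finder needs an approximate beam centre for ring
  assignment; a grossly wrong centre biases the radial background.
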