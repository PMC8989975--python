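# Methods

This note documents the models, numerical choices, and limitations of
the package: the SVD clutter filter and Power Doppler formation, the
GLM activation mapper and ΔBV quantification, the nested mixed models,
the ULM tracking chain, and the synthetic-data generators that the test
suite exercises everything against.

## Coordinates and units

Depth `z` (mm, positive downward) and lateral position `x` (mm); arrays
are ordered `(z, x, t)`. The centre of pixel `(i, j)` is at
`((i+0.5)·dz, (j+0.5)·dx)`. Velocities are mm/s; a positive `vz` is
descending flow. Decibel parameters are amplitude ratios,
`20·log10(a₁/a₂)`.

## SVD clutter filter

A block of `n_t` frames is reshaped to the Casorati matrix
`M ∈ C^(n_z·n_x × n_t)`; the filter zeroes the `n_remove` largest
singular values (descending order; "first" = largest). It is computed
through the temporal Gram matrix `MᴴM` (an `n_t × n_t` eigenproblem),
which is exact and several times cheaper than a direct SVD for tall
imaging matrices. Complex data use conjugate-transpose reconstruction;
real data fall back to the ordinary transpose. Defaults follow the two
acquisition regimes: `n_remove = 60` for 200-frame functional blocks,
`n_remove = 10` for 400-frame ULM blocks. Blocks are contiguous and
non-overlapping; trailing frames that do not fill a block are dropped
with a warning. No apodization or noise-floor subtraction is applied,
and Power Doppler integrates (sums) the filtered energy without
normalizing by `n_t`.

Two properties deserve care:

* **Projection semantics.** The filter is the orthogonal projection onto
  the complement of the leading temporal subspace *of the block it was
  estimated from*. Re-estimating the subspace on already-filtered data
  removes the *next* `n_remove` components — for any truncation filter —
  so repeated filtering is only idempotent when the subspace is reused.
  `clutter_basis` exposes the estimated basis and
  `svd_filter_block(..., basis=...)` applies it; that operator satisfies
  `P∘P = P` to machine precision.
* **Blood loss is intrinsic.** Removing 60 of 200 temporal dimensions
  removes, at minimum, the corresponding fraction of any temporally
  broadband signal (≈30% of blood energy beyond the clutter itself).
  Clutter-rejection fidelity is therefore assessed against the
  clutter-free component *passed through the same filter*: the check is
  that 40 dB tissue is excised without distorting the result relative to
  the tissue-free case, not that truncation is lossless. On small grids
  the truncation is also mildly adaptive (it preferentially absorbs
  whatever excess variance exists, including stimulus-locked power); the
  effect shrinks as the pixel count grows past the block length, which
  is the operating regime of real probes, and the end-to-end recovery
  tests run at 48×48 and above for this reason.

## Hemodynamic response and GLM

The canonical HRF is four half-cosine segments: optional dip to `−c₁`
over `d₁`, rise to `+1` over `d₂`, fall to `−c₂` over `d₃`, recovery to
0 over `d₄`. Defaults `d = (0, 1, 2, 2) s`, `c₁ = 0`, `c₂ = 0.3` are
typical of fast rodent hemodynamics and are configuration-exposed; the
sampled kernel is rescaled so its maximum is exactly 1. `fit_hrf_params`
recovers these parameters from a measured ΔBV trace by bounded nonlinear
least squares (two starts); a fitted scale near zero flags the durations
as non-identifiable.

The stimulus regressor is the causal convolution of the binary paradigm
indicator (sampled at the paradigm's fine `dt`) with the kernel,
interpolated at Power Doppler frame centres and peak-normalized. The
design is regressor + intercept; no drift regressors or prewhitening are
applied (an optional linear-drift column is available). Per pixel, OLS
gives `t = β̂/SE`, one-sided p (activation = BV increase; two-sided by
flag), and `Z = Φ⁻¹(1−p)` clipped at ±8.2 (≈ p = 1e−16); zero-residual
pixels report the capped sentinel. Bonferroni correction uses every
pixel in the frame as the test count. The ROI is the 8-connected
component of the significant mask containing the maximal Z (raster-order
tie-break); mirroring about the midline rounds to the nearest pixel
column, which keeps the operation an involution and preserves pixel
count.

ΔBV uses the raw indicator-equals-zero rule for baseline frames, as the
block design defines it; post-stimulus HRF tails therefore sit inside
the baseline and slightly raise it. Consequently ΔBV_STIM estimates the
HRF-shaped expectation — the mean of `amplitude·r(t)` over stimulation
frames referenced to the tail-contaminated baseline — which for the
corneal design is ≈0.67 of the injected amplitude. Ground truth carries
this expectation so recovery is tested against the quantity the
estimator actually measures.

## Mixed models

Both published forms are intercept-only nested random-effect models.
The REML objective is evaluated in closed form from per-group sufficient
statistics (counts, means, within-group sums of squares) using the
Woodbury identity on the nested block structure, so one likelihood
evaluation costs O(#groups); optimization is Nelder–Mead over
log-variances with two starts (ANOVA moments; even split) and a 1e−11
function tolerance, with components snapped to the boundary when that
does not lower the restricted likelihood by more than 1e−9. The engine
is cross-checked in the tests against the balanced one-way closed form
and against an independent general-purpose REML implementation.

Degenerate hierarchies are detected, flagged and reduced rather than
silently dropped: one observation per rat collapses the one-level model
to an iid fit (σ²_rat reported 0, flagged); one acquisition per rat
collapses the two-level model to the one-level fit (σ²_acq reported 0,
flagged). The F test uses denominator df `n_obs − 1 − (levels of random
factors with positive estimated variance)`, floored at 1; a Satterthwaite
approximation (observed-information delta method) is available by flag.
The likelihood-ratio test for a variance component uses the plain χ²₁
reference, which is conservative for a boundary hypothesis; the
0.5·χ²₀ + 0.5·χ²₁ mixture is available by flag. The signed square root
`sign(x)·√|x|` is the default reading of the variance-stabilizing
transform; the literal reading (`+√(−x)` for negative values), which
destroys ordering, is available for comparison only.

## ULM chain

Detection: a pixel is a candidate iff it is strictly greater than every
neighbour in its window (default 7×7 at 100 µm pitch) and above the
intensity threshold; sub-pixel refinement is the intensity-weighted
centroid over the window (deterministic default) or a 3-point
log-parabola fit per axis, exact for a Gaussian PSF. Linking: optimal
assignment between consecutive frames on the birth/death-augmented cost
matrix — the objective is the summed link distances plus the gate for
every unlinked detection; pairs beyond `max_link_mm` are never linked.
There is no gap closing by default (`max_gap = 0`); `min_length`
defaults to 4 points; the gate default is 1.5× the expected maximal
displacement per frame. Velocities are per-segment displacements ×
framerate, attributed to the segment's starting super-resolved pixel in
the speed and signed-vz maps (line-rasterized attribution is not
implemented); the default reconstruction pitch is 6.5 µm. Vessel
diameter estimation from density profiles is deliberately not provided.
Identity preservation across genuinely crossing trajectories is a known
limitation of min-distance linking: when two bubbles pass within one
inter-frame step the swapped pairing has lower cost, as for any
motion-model-free tracker.

## Synthetic data

The generators reproduce the statistical structure the analyses assume,
not the acoustics: no wave propagation, speckle physics, or RF synthesis.

*Functional stacks.* Tissue is an exact-rank sum of smooth unit-norm
spatial patterns × orthonormal low-pass temporal modes (cutoff ~10 Hz,
amplitudes decaying ×10⁻⁰·⁵ per mode), scaled 40 dB (default) above
blood RMS — the usual in vivo regime of clutter dominating blood. Blood is
per-pixel independent complex speckle: a Doppler carrier (default 150 Hz,
axial flow) times a low-pass Gaussian envelope whose correlation time
(default 1 ms, ≈ half a frame at 500 Hz) models scatterer transit
through the PSF; the default is deliberately broadband so the blood
subspace is spectrally spread, as the SVD filter assumes of in vivo
Doppler. Blood power follows `baseline·(1 + amplitude·r(t))` inside the
activation mask, with `r` the peak-normalized HRF-convolved paradigm.
Noise is white complex Gaussian at `noise_db` (default −20 dB) relative
to blood RMS. Stacks are complex by default (IQ data); `complex64`
halves memory for long acquisitions. All randomness derives from one
seed; identical calls are bitwise identical.

*Bubble movies.* Bubbles enter as Poisson arrivals (default) or at
regular spacing ("regular": a dilute steady infusion in which bubbles
never overlap under the PSF — the condition for recovery experiments,
since two bubbles closer than the PSF merge into one maximum and defeat
any local-maxima detector). Each advances by `flow_speed/framerate`
along its vessel polyline with a fixed lateral offset within the vessel
radius, rendered as a Gaussian blob (default σ = 100 µm) with a Doppler
phase set by its axial velocity. Ground-truth per-frame positions and
velocities are exact.

*Power Doppler series.* `simulate_pd_series` bypasses the frame-level
physics: per-pixel `baseline·(1 + amplitude·r(t))·(1 + σ·ε)` with
multiplicative Gaussian noise (default σ = 0.1). It shares the GLM's
regressor construction, which makes the noise-free β̂ identity exact but
means GLM calibration on this substrate does not test the convolution
itself — the frame-level generator provides the independent route, and
both are exercised.

*Paradigm presets.* corneal: 6×10 s stimulations, 20 s gaps, 30 s rest
padding (total 220 s, 60 s stimulated); von Frey: 4×5 s, 55 s gaps, 60 s
padding (305 s); whisker: 6×20 s trains (4 Hz within the train; the
indicator marks the envelope), 20 s gaps, 30 s padding chosen here as no
padding is part of the cited design; capsaicin: 60 s baseline then one
180 s application with 60 s washout — a phasic paradigm unsuited to
block-design GLM, provided for ΔBV quantification only.

*What passing tests do and do not show.* The generators have no motion,
no spatially correlated noise, no aberration, no bubble disruption, and
tissue of exactly known rank; recovery results bound what the pipeline
can do under its own assumptions, not its in vivo performance.

## Problem sizes and determinism

Routine tests run at 8–64 pixel grids and 1–2 blocks. The calibration
and recovery studies use: a 64×64×200 block for filter fidelity; 100
null and one activation Power Doppler series of 64×64×550 frames for
GLM calibration; a 48×48 grid with a 250-block two-stimulus design for
the frame-level ΔBV chain (the pixel count must exceed the block length
for the truncation to be non-adaptive; memory stays ~2.5 GB in
complex64); an 800-frame three-vessel movie for ULM recovery; and
300–500 replicates of 20 rats × 5 stimulations for the mixed-model
studies. All stage seeds derive from one master seed via
`numpy.random.SeedSequence`.
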