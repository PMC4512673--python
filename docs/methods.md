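# Methods

## Signal model and units

The mono-exponential diffusion model is S(b) = S0·exp(−b·D) with b in
s/mm² and D carried throughout in units of 10⁻⁵ mm²/s (healthy liver
≈ 100, i.e. 1.0 × 10⁻³ mm²/s), so the exponent is b·D·10⁻⁵.  Magnitude
MR images carry Rician noise: the observed intensity is
|S + n₁ + i·n₂| with n₁, n₂ ~ N(0, σ²), which floors low-SNR signals at
≈ σ√(π/2) and biases the apparent decay (hence D) downward.

## Template matching

Matching compares gradient patches, not grey levels.  For a target patch
I and reference patch J with scale factors α, β (α² + β² = 1), the
matching χ² reduces via γ = α/β = √(B/A) to (γ²A + B − 2γC)/(σ²(1+γ²)),
where A = ΣI², B = ΣJ², C = ΣI·J are taken over both gradient components
inside the ROI.  B is fixed (the reference does not move) and σ is
constant during a search, so maximising C alone ranks shifts identically
— the implementation scores with C and exposes A, B, γ for diagnostics.
Gradients use the central-difference kernel [−1, 0, 1]/2 per axis
(minimal symmetric differential kernel; pinned by a direct-summation
oracle test), with edge replication at the image border and the ROI
eroded by the 1 px kernel radius so replicated values never enter a sum.
The search is exhaustive over integer shifts: ±3 px in-plane (49 cases)
and ±2 candidate slices, reflecting observed liver excursions of ≈ 1 cm
at 3 mm pixels.  Ties are broken by smallest Euclidean shift, then
row-major order.  The reference window stays fixed and the target is
sampled through shifted windows, so the recovered shift is the target's
motion relative to the reference.

Matching across b-values uses the single lowest-b reference.  A caveat
discovered on synthetic data and handled by ROI choice: free-fluid
structures (gallbladder-like, D ≳ 2 × 10⁻³ mm²/s) are brighter than
liver at b = 100 but darker at b = 900, so their edges reverse polarity
across b and contribute *negatively* to C at exact alignment — enough to
displace the z-argmax.  The matching ROI should therefore be liver
tissue plus the organ/air boundary (whose polarity is stable) and
exclude free fluid; the pipeline's phantom default does exactly this
(tissue dilated 1 px, minus D > 200 voxels with a 2 px guard band,
minus a 4 px image-border band so all shifted windows stay in bounds).
The ADC-statistics ROI is separate (eroded tissue) and keeps the fluid
blob, preserving its high-S0/high-D scatter cluster.

## Slice selection and compositing

For one b-value and direction: 4 repeats × 5 z-candidates → 20
hypotheses (best in-plane shift each); per repeat the best odd- and best
even-parity candidates are kept (8) and the top 4 of those survive; both
parities of one repeat may survive.  The 12 selected slices (4 × 3
directions) are translated in-plane by the negative of their recovered
shift — integer translation with edge replication, never interpolation —
and voxelwise averaged.  The z-offset is used only to *select* the
slice; there is no through-plane resampling.  Sub-pixel precision is
recovered statistically by selecting among slices that sample different
sub-pixel phases of the motion, which is the point of avoiding
interpolation smoothing.

An interleave consequence worth stating: a parity group whose true
z-offset is odd relative to the reference slice has no candidate slice
at its true anatomical plane (odd offsets land on the other parity's
slices).  Its best compromise slice is still selected — matching then
legitimately trades a one-plane offset against a small in-plane
adjustment.  Exactness contracts in the tests therefore apply to
parity-reachable selections (all of which recover their true 3D shift
noiselessly, and ≥ 90 % under SNR-10 Rician noise at the reference b).

## Constrained movement space

Respiration is cyclic, so the true shifts lie near a line in
(Δrow, Δcol, Δslice) space.  After aligning the reference b-value over
the full 7 × 7 × 5 = 245 lattice, a robust line is fitted to its 12
selected shifts and the other b-values search only lattice points whose
Chebyshev distance to the (box-clipped) orthogonal projection onto the
line is ≤ 1.  The line fit is deterministic: exhaustive leave-d-out
trimming (d ≤ 2, scored by median orthogonal residual over all points)
initialises the inlier set, then 3 Tukey-biweight (c = 4.685)
reweighted orthogonal regressions refine it within that set.  Plain
IRLS from the full-sample principal axis was rejected after it
provably locked onto outlier-tilted solutions at n = 12: one wild shift
at the end of the point cloud has high leverage, and because integer
rounding makes inlier scatter coarse (MAD ≈ 0.4 px) the outlier stays
inside the Tukey window.  Trimming is not undone by the reweighting for
the same reason.  All-identical shifts yield a flagged degenerate line
and the full lattice is kept (zero-motion data are re-aligned with all
shifts (0,0,0) — idempotence).

## ADC fitting and noise estimation

Per voxel, minimise Σₖ [I(bₖ) − f(bₖ, D, S0)]² with
f = √(S0²·e^(−2bₖD) + η·σ²); the likelihood's additive constant is
dropped.  η is the bias-correction weight (1 for unsmoothed magnitude
data; reduce if the data were spatially smoothed).  Starting values come
from an ordinary log-linear fit of log I vs b; refinement uses bounded
trust-region least squares (D ∈ [0, 1000] × 10⁻⁵ mm²/s, S0 ≥ 0,
tolerances 10⁻¹⁴) — a derivative-free simplex was tried first but does
not reliably reach the 10⁻⁹ relative exactness contract on noiseless
data.  All-zero voxels and non-positive fitted S0 are flagged
non-converged rather than clamped; negative inputs are clipped to zero
with a warning.

σ is estimated from the second-difference distribution: the kernel
(1, −2, 1) applied along x and y annihilates constant and linear
structure, leaving noise with variance 6σ² in smooth regions;
σ = 1.4826·MAD/√6 over the pooled in-region values (region eroded by
the stencil radius).  The estimator is exact on pure Gaussian fields to
within ~1 % at 128² samples and invariant to linear ramps; note it
estimates the noise of the slice it is given — an average of 12
acquisitions has ≈ σ/√12.  By default the lowest-b slice's estimate is
used for all b (single-σ convention), configurable per call.

Bias-correction behaviour, established by simulation oracle before the
tests were frozen: at SNR ≈ 5 on the strongest weighting, the η = 0 fit
underestimates D and η = 1 leaves a smaller absolute bias; at SNR ≲ 3
η = 1 over-corrects (the floor makes the objective one-sided and the
fit's nonlinearity skews D upward), so the correction should not be
relied on below SNR ~ 4.  The ordinary log-linear fit is *not* a useful
bias yardstick at moderate SNR: Jensen's inequality on the log nearly
cancels the floor bias to first order.

## Evaluation statistics

σ_D is the sample standard deviation (n−1) of ROI ADC values.  Assuming
acquisition noise, biology and motion add in quadrature, the signed
quadrature difference Δσ_D = sign(σ₁²−σ₂²)·√|σ₁²−σ₂²| (uncorrected
width first) measures equivalent motion noise removed; its printed
source rendering is ambiguous, and this form is fixed by reproducing
all 40 bundled width-reduction entries within 0.01 (including the four
negative ones).  Reproducibility is ΔD% = 200|D1−D2|/(D1+D2); its
accuracy is [400/(D1+D2)²]·√(D2²σ₁²/N1 + D1²σ₂²/N2), a grouping
verified symbolically (sympy) and by Monte-Carlo (0.48 vs 0.48) since
the printed radical is also ambiguous.  Method summaries use column
means (n) and within-population standard deviation (n−1); the bundled
summary rows recompute to within 0.01 from the bundled per-entry
tables.  Smoothness control between methods uses Gaussian blurring
(reflective borders; σ = 1 px default) of the sharper method's slices
before fitting.

## The phantom and what it does (not) show

The generator emulates a separately-stored-repeats protocol: 3 b-values
(100/500/900 s/mm²), 3 opaque gradient-direction labels, 4 repeats,
interleaved slice order (odd-index block then even-index block),
3 × 3 × 5 mm voxels.  Tissue is piecewise-constant tilted ellipsoids:
liver background (D = 100, S0 = 100), a low-D lesion (60, 85), an
oblique vessel (150, 60) and a bright free-fluid blob (250, 180).
Tilts (≤ 0.35 px/slice) make adjacent slices genuinely distinguishable
while keeping a one-plane offset below the 0.5 px integer-rounding
threshold, so parity-compromise selections do not corrupt in-plane
recovery.  Motion is a one-sided sinusoidal excursion from an
end-expiration baseline, shift(t) = A·(1+sin 2πt)/2·u, rounded to
integers and clipped (defaults u ∝ (2,1,1.5), A = 3.5 → ≤ 2.9 px
in-plane, ≤ 2 slices); one-sidedness keeps shifts *relative to any
reference acquisition* inside the search limits, which symmetric ±A
motion would violate.  Acquisition times advance deterministically by
0.37 cycles per acquisition with a 0.31-cycle lag for the even-slice
block (the coronal odd-even artefact); only noise and optional jitter
consume the seed, and one seed reproduces the series bit-for-bit.
Noise is two-channel (Rician, η = 1 regime).  Default grid 64 × 64 × 12
for speed; the full 256 × 224 × 40 geometry is a config away.

What passing phantom tests do not show about real data: no anisotropic
diffusion (direction labels are opaque, as the method averages
directions), no eddy-current/susceptibility distortion, no
through-plane dropout, no genuine sub-pixel motion by default
(optionally enabled via interpolated shifts), piecewise-constant tissue
rather than texture, and rigid bulk motion only — the phantom validates
the algorithmic contract, not clinical performance.

## Numerical choices and degenerate inputs

Flat patches (A = 0 or B = 0) score C = 0 with a degenerate flag; an
all-degenerate search falls to the tie-break rule ((0,0) wins).  Score
ties: smallest shift magnitude, then row-major; selection ties:
smallest |shift3d|, then repeat order.  The motion-line direction is
sign-normalised (largest-magnitude component positive).  A constraint
set that would exclude every in-plane shift at some z simply removes
that z-candidate.  Edge slice positions (closer than 2 slices to the
volume boundary) are rejected, mirroring the exclusion of edge slices
from analysis.  Problem sizes in tests: 64 × 64 × 12 phantom
(ROI ≈ 1.5 k voxels), 4000-draw fitting ensembles, 2 × 10⁵-draw
closed-form Monte-Carlo oracles; the full suite runs in under a minute
on one CPU, and a complete LRA pass on the default phantom takes
~0.2 s.

## Known limitations

Single-slice alignment (whole-volume operation would iterate over slice
positions); integer shifts only; no rotation or scale search; the
best-4-of-8 rule may take both parities from one repeat (the selection
is score-driven); σ is slice-global, not spatially varying; the
variance-floor correction is first-order, not a full Rician maximum
likelihood.
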