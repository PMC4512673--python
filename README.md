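# dwlra — local-rigid motion correction for liver DW-MRI

Respiratory motion is the dominant source of error when estimating the
apparent diffusion coefficient (ADC) in the liver from free-breathing
diffusion-weighted MRI.  When the repeat acquisitions of a multi-b-value
protocol are simply averaged (on the scanner or offline), motion blurs
the averages and widens the ROI's ADC histogram; deformable registration
fixes the alignment but smooths the data, destroying the voxel-level
detail needed for heterogeneity analysis.

`dwlra` implements a local-rigid alternative for users who analyse
regional ADC distributions: radiology/physics researchers working with
multi-b-value liver protocols that store repeats separately (typically 3
b-values x 3 diffusion gradient directions x 4 repeats, interleaved
slices).  It provides:

* **Local-rigid alignment (LRA).**  A reference slice is taken from the
  lowest b-value (best SNR).  For each b-value and gradient direction,
  every repeat contributes 5 candidate z-slices (central ± 2); each is
  matched to the reference over a 7 × 7 grid of integer in-plane shifts
  (49 cases) by exhaustive search — no interpolation, no local optima.
  The matching score is the gradient cross term

      C = Σ ∇I·∇J  over the ROI,   with  A = Σ|∇I|²,  B = Σ|∇J|²,

  which is the sufficient statistic of the scaled-patch χ² cost
  χ² = (γ²A + B − 2γC)/(σ²(1+γ²)), γ = √(B/A); gradient patches make it
  insensitive to intensity scaling across b-values.  Per repeat the best
  odd- and even-parity candidates are kept (interleaved acquisition puts
  the two parity groups at different respiratory phases), the best 4 of
  8 survive per direction, and the 12 selected slices are integer-
  translated onto the reference frame and averaged — one aligned slice
  per b-value.
* **Constrained movement space.**  Respiration is cyclic, so recovered
  3D shifts concentrate on a line.  A robust line fit (deterministic
  leave-d-out trimming + Tukey-reweighted orthogonal regression) to the
  reference b-value's 12 shifts restricts the 7 × 7 × 5 = 245-point
  search lattice to the line's Chebyshev-1 neighbourhood for the noisier
  b-values.
* **Rician-bias-corrected ADC fitting.**  Magnitude MR noise puts a
  floor under low-SNR signals; fitting I(b) against
  f(b) = √(S0²·e^(−2bD) + η·σ²) (η = 1 for unsmoothed data) removes the
  resulting downward bias in D.  σ is estimated from the image itself
  via the robust width of the second-difference distribution (÷√6).
* **Evaluation statistics.**  Histogram width σ_D, signed quadrature
  width difference Δσ_D (equivalent motion noise removed), between-scan
  reproducibility ΔD% = 200|D1−D2|/(D1+D2) and its error-propagated
  accuracy, plus S0-vs-ADC scatter export.
* **A synthetic phantom** with ground-truth D/S0 maps, interleave-aware
  cyclic respiratory motion along a 3D line, and Rician noise, emulating
  the separately-stored-repeats protocol for testing everything above.

## Worked example

Run the end-to-end pipeline on the default phantom (64 × 64 × 12 grid,
b = 100/500/900 s/mm², 3 directions × 4 repeats, respiratory shifts up
to ~3 px / 2 slices along a fixed 3D line, Rician σ = 5):

```
$ dwlra pipeline --seed 0 --out out/
        sigma_D  mean_D     N  noise_sigma_est  delta_sigma_vs_AVG
method
AVG       37.44  109.79  1544             1.63                0.00
LRA       36.48  108.76  1544             1.74                8.43
AVG-b     34.81  109.32  1544             0.18               13.79
LRA-b     32.37  108.01  1544             0.18               18.82
```

Reading the numbers: each row is one processing variant of the same
simulated scan (AVG: plain average of the 12 acquisitions per b-value;
LRA: local-rigid alignment; `-b`: 1 px Gaussian-blurred versions used to
control smoothness when comparing against inherently smoothing
methods).  `sigma_D` is the ADC-histogram width over the 1544-voxel ROI
in 10⁻⁵ mm²/s — alignment narrows it (36.48 vs 37.44), and
`delta_sigma_vs_AVG` expresses that narrowing as equivalent per-voxel
ADC noise removed (8.43 × 10⁻⁵ mm²/s).  `mean_D` is close to the
ground-truth mixture mean of the phantom's tissue (liver background
D = 100).  The same stages are available separately as `dwlra simulate`,
`dwlra align`, `dwlra fit` and `dwlra metrics`, and as library calls
(`dwlra.run_lra`, `dwlra.fit_adc_map`, …).

`dwlra report --out DIR` recomputes the bundled reference evaluation
tables (a five-volunteer, two-scan liver study distributed with the
package) from their per-scan widths and mean ADCs:

```
                   AVG  AVG-b    LRA  LRA-b   NRA    PA
mean_delta_D_pct  3.94   3.99   3.28   3.13  1.88  6.12
std_delta_D_pct   2.47   2.63   0.56   1.26  1.48  5.06
mean_delta_sigma   NaN  15.89  14.04  23.30  8.49   NaN
```

The mean reproducibility of the on-scanner averaged protocol (PA, 6.12%)
is roughly halved by alignment (LRA 3.28%), and LRA gives the most
consistent reproducibility across volunteers (std 0.56%).

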