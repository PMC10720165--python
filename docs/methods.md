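# Methods

## The kinetic model

Hyperpolarized magnetization is non-renewable: every excitation consumes a
`cos θ` fraction and T₁ relaxation destroys the rest within tens of seconds.
The model is a uni-directional three-site exchange in one physical
compartment,

    dM_P/dt = −(1/T1_P + k_PL + k_PB)·M_P + u(t)
    dM_L/dt = −M_L/T1_L + k_PL·M_P
    dM_B/dt = −M_B/T1_B + k_PB·M_P

with fixed relaxation times T1 = 30 / 25 / 20 s (pyruvate / lactate /
bicarbonate) and flip angles θ = 20° / 30° / 30°, one excitation per
metabolite per slice per frame. Back-conversion (k_LP), an alanine pool,
multi-compartment vascular models and T₁ fitting are deliberately out of
scope.

The discrete contract advances frame to frame: the measured signal is
`S_X(i) = M_X(i⁻)·sin θ_X`; the excitation leaves `M_X(i⁻)·cos θ_X`; between
frames the product pools relax and accumulate `k_PX·C_i`, where `C_i` is the
closed-form convolution of the pyruvate magnetization — interpolated
mono-exponentially between its frame endpoints (flat if either endpoint is
non-positive, so signed noise passes through unrectified) — against the
product's T₁ decay. For decay-driven pyruvate this recursion is *exact*
(machine precision against a 1 ms Runge–Kutta integration); when an external
input arrives mid-interval the interpolation is approximate, and the error
vanishes at least first-order as the frame interval shrinks.

**Inputless fitting** replaces the modeled pyruvate by the measurement:
`M_P(i⁻) = S_P(i)/sin θ_P` drives the same recursion, so no arterial input
function or amplitude scale is assumed. The fit minimizes the summed squared
lactate + bicarbonate residuals over (k_PL, k_PB) by Levenberg–Marquardt
from (0.01, 0.005) s⁻¹, unbounded — zero-mean noise may produce small
negative rates, which is statistically correct behavior. Initial product
magnetizations come from the first measured frame, as measured. With
uni-directional conversion the problem is linear in each rate, so the local
optimizer finds the global optimum; joint and per-metabolite fitting
coincide.

## Reconstruction

Spiral samples are gridded with a width-4.5 Kaiser–Bessel kernel on a
1.4×-oversampled grid (β from the standard minimal-aliasing formula),
inverse-FFT'd, deapodized, and cropped. Deapodization uses the DFT of the
*sampled* kernel rather than its continuous transform — exact for on-grid
samples and a closer match to the discrete convolution actually performed
(the continuous transform leaves ~0.7% ripple). Density compensation is the
analytic `|k|·d|k|/dt` rule for the modeled linear-radius spiral, normalized
to the sampled disk area; sample positions start at half a time-step so no
sample sits exactly at k = 0. Verified against brute-force conjugate-phase
DFT (<0.2% RMS) and against synthesis round trips (<0.1% real-channel error
for band-limited objects). Two facts matter when judging fidelity: a spiral
samples a *disk* in k-space, so the matrix corners lie outside the supported
circular FOV, and non-conjugate-symmetric sampling puts a percent-level
artifact into the *imaginary* channel, which the phasing step discards.

**Coil combination.** Sensitivities are estimated from the complex
per-channel pyruvate AUC (the highest-SNR ¹³C data available), normalized by
the root-sum-of-squares across channels, referenced to the strongest
channel's phase so the voxel-common (object) phase drops out, smoothed
in-plane with a 2-voxel-FWHM Gaussian, and combined by the Roemer
unit-noise-scaling formula `Σ conj(s_c)x_c / Σ|s_c|²`. Outside the
reliability mask (RSS above 5% of maximum by default) the maps fall back to
the raw unsmoothed ratios instead of zero: zeroing would null the combined
background entirely, making the background noise σ undefined and defeating
the zero-mean background checks that justify working with signed real data.
Literal masking remains available (`outside="zero"`).

**Phasing.** The real-channel energy `Σ_t Re(s_t e^{−iφ})²` is maximized in
closed form by `φ = ½·arg Σ_t s_t²`, estimated from the full series. The π
ambiguity is resolved by making the temporal sum of the real channel
nonnegative, *gated* on that sum being significant against the series' own
power (|Σ Re| ≥ 3·√(Σ|s|²/2)). An unconditional flip would rectify
noise-only voxels and bias the background positive by ≈ σ√(2n/π) per
series; the gate preserves the sign of any signal spanning a handful of
frames while leaving pure noise zero-mean. The price is that an isolated
single-frame signal in the left half-plane can keep the wrong sign — not a
regime the windowed AUC analysis operates in.

## Quantification

AUC maps are plain frame sums of the signed real dynamics over
metabolite-specific windows (pyruvate 1–25, lactate 1–30, bicarbonate 5–20,
1-based inclusive); no frame-interval weighting, consistent with the √n
noise normalization in AUC-SNR = |AUC|/(σ√n). σ is the spatial standard
deviation of the real image at a post-decay frame (default: last frame) over
the region outside the body mask. Rates and ratios are computed only where
pyruvate AUC-SNR ≥ 200; the threshold is a per-study override because the
original per-subject adjustment was manual. Ratios are signed quotients —
no magnitude rectification anywhere in the chain.

## The synthetic phantom

The phantom emulates the study conditions: 64×64×5 grid at 3×3×21 mm
simulation scale, 8 receive channels, 30 frames every 3.6 s,
6 mm-equivalent pyruvate vs 12 mm-equivalent lactate/bicarbonate in-plane
resolution (2×2 block averaging before noise), labels
{background, RV blood, LV blood, 16 AHA myocardial segments}. The bolus is
a gamma-variate (t₀ = 5 s, α = 2.5, β = 2 s) reaching the LV 2 s after the
RV and the myocardium 2 s later; blood converts pyruvate to lactate at
k_PL = 0.002 s⁻¹ (red-blood-cell LDH) and produces no bicarbonate;
myocardium defaults to k_PL = 0.02, k_PB = 0.01 s⁻¹ fasted — chosen from
the typical range of the hyperpolarized literature, since absolute
myocardial rates vary between studies. The fed state multiplies k_PB by 2
and k_PL by 1.3 nominally, scaled per subject by the individual
blood-glucose rise; the cohort sampler (fasted glucose ≈ 70 ± 8 mg/dL, rise
≈ 35 ± 8 mg/dL, 15% between-subject rate variability) includes one
non-responder with no glucose rise and unchanged rates. Coil sensitivities
are smooth low-order complex polynomials biased toward the anterior wall,
as a paddle array on the chest produces. Per-voxel phase offsets are
constant in time but *smooth in space* (≈4-voxel correlation, ≈1.2 rad
spread): physical B₀/receive phase varies smoothly, and a white per-voxel
phase would push half the object's spectral energy beyond any sampled
k-space disk. Noise is complex Gaussian, σ = 3×10⁻³ per component per
channel, placing the blood-pool pyruvate AUC-SNR in the thousands (well
above the 200 mask threshold), background near 1, and myocardial
bicarbonate in the hundreds.

What the phantom does **not** emulate — and what passing tests therefore do
not demonstrate about in-vivo data: cardiac/respiratory motion,
B₀ off-resonance blurring, perfusion changes between states (fed pyruvate
SNR *falls* slightly in the phantom because more pyruvate is converted,
whereas in vivo it can rise with perfusion), realistic between-subject
biology (the synthetic glucose correlations are far stronger than clinical
ones), spectral-spatial excitation profiles, and partial-volume anatomy
beyond the 2× resolution mismatch. That mismatch is deliberate and visible:
voxels whose 2×2 block straddles a region boundary mix timecourses, biasing
edge-voxel and whole-myocardium mean rates low by ~10–15%; ground-truth
recovery is therefore asserted on block-homogeneous voxels, where noiseless
voxelwise fits recover rates to ≈10⁻⁶ s⁻¹.

## PSF and effective resolution

The 22 ms single-shot spiral acquires outer k-space last, so transverse
decay apodizes high frequencies by `exp(−t(k)/T2*)`. The trajectory time
map is linear in radius (constant-velocity radial growth) and pluggable.
The PSF of the apodized disk is its order-0 Hankel transform, evaluated by
midpoint quadrature (4000 nodes) on a radial grid of 256 points per nominal
voxel; the FWHM comes from a cubic-spline root around the half-maximum
crossing. The broadening ratio is scale-invariant in k_max, so it depends
only on T_read/T2*: 1.014 (T2* = 119 ms), 1.042 (43 ms), 1.028 (64 ms),
i.e. effective resolutions of 6.09, 12.51 and 12.33 mm at the 6/12/12 mm
nominal resolutions.

## Numerical and test-scale choices

* Closed-form interval convolutions use `expm1` for small exponents; the
  mono-exponential interpolation rate falls back to flat when an endpoint
  is ≤ 0.
* The Fermi window defaults to radius 0.45 and width 0.05 of the padded
  Nyquist radius; with the window off, 2× upsampling preserves the original
  voxel values to ≤10⁻⁹.
* Degenerate inputs behave predictably: empty k-space → zero image with a
  warning; all-zero series → φ = 0; empty fit mask → all-NaN maps with a
  warning; zero-variance paired differences → t = 0, p = 1.
* Tests and the cohort significance analysis run on a reduced phantom
  (32×32, 3 slices spanning all AHA levels, 8 channels) with 10 seeded
  cohort replicates; the analysis drivers run the full 64×64×5 protocol.
  The reduced grid keeps ≥3 voxels across the myocardial wall and preserves
  every qualitative property of the full-scale phantom.
* The undefined-value marker in all maps is NaN, excluded from every
  statistic.

## Known limitations

* Pyruvate's own background AUC is slightly rectified because the
  combination weights are derived from the same pyruvate data
  (self-calibration); lactate and bicarbonate backgrounds — where the
  signed-data argument actually matters — are unbiased because their noise
  is independent of the pyruvate-derived maps.
* The conjugate-phase/gridding reconstruction is an adjoint, not an
  inverse; residual in-FOV error on band-limited objects is a few percent,
  dominated by density-compensation ripple.
* Whole-myocardium mean rates inherit the deliberate 2×-resolution partial
  volume bias described above; regional comparisons within a study are
  unaffected in rank.
* The per-study SNR-threshold adjustment of the original analysis is a
  manual override here; no artifact-minimization heuristic is implemented.
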