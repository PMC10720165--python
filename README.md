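# hpcardiac

Regional quantification of cardiac metabolism from dynamic hyperpolarized
[1-¹³C]-pyruvate MRI.

Hyperpolarized ¹³C-pyruvate MRI watches an injected pyruvate bolus being
metabolized in real time: lactate dehydrogenase (LDH) converts
[1-¹³C]-pyruvate to [1-¹³C]-lactate and pyruvate dehydrogenase (PDH) routes
it into the Krebs cycle, visible as ¹³C-bicarbonate. The apparent
first-order rates k_PL and k_PB (s⁻¹) are surrogate measures of LDH and PDH
flux, and in the healthy heart they shift with substrate availability — an
oral glucose load raises PDH flux, so myocardial bicarbonate production
rises from the fasted to the fed state.

This package implements the full quantification chain for such studies, for
researchers developing or validating cardiac ¹³C analysis pipelines:

* **`hpcardiac.recon`** — Kaiser-Bessel convolution gridding of single-shot
  spiral k-space (oversampling 1.4, kernel width 4.5), Roemer coil
  combination with sensitivities estimated from the pyruvate data itself,
  2× sinc upsampling with a Fermi anti-ringing window, and per-voxel
  constant-phase correction so all analysis runs on signed real images
  (magnitude images would bias the low-SNR bicarbonate measurements).
* **`hpcardiac.kinetics`** — a uni-directional three-site model with fixed
  T₁ (30/25/20 s for pyruvate/lactate/bicarbonate) and per-frame flip-angle
  losses (20°/30°/30°). Between frames each product pool obeys
  dM_X/dt = −M_X/T₁_X + k_PX·M_P(t); the *inputless* fit drives this
  recursion with the measured pyruvate signal, so no arterial input
  function is assumed, and the two rates are fit unbounded by least squares.
* **`hpcardiac.quantify`** — windowed AUC maps (pyruvate frames 1–25,
  lactate 1–30, bicarbonate 5–20), AUC-SNR = |AUC|/(σ√n), the pyruvate
  AUC-SNR ≥ 200 analysis mask, signed metabolite ratio maps, and coil-profile
  correction.
* **`hpcardiac.regional`** — AHA 16-segment division of the LV myocardium
  (6 basal / 6 mid / 4 apical sectors from the RV-insertion angle),
  per-segment summaries, paired Student's t-test and Pearson correlation.
* **`hpcardiac.psf`** — the point-spread function of the 22 ms spiral
  readout under metabolite-specific T2* decay and the resulting effective
  resolution.
* **`hpcardiac.phantom`** — a fully synthetic dynamic cardiac phantom
  (gamma-variate bolus transiting RV → LV → myocardium, blood-pool LDH
  lactate, region-varying myocardial rates, 8-channel coil shading, smooth
  per-voxel phase offsets, complex Gaussian noise) with complete ground
  truth, so every stage above is testable without any patient data.

The numbered drivers under `analysis/` run the study end to end on the
phantom: PSF resolution, cohort simulation, per-study quantification,
regional analysis, and fed/fasted statistics; tables land in `results/`.

## Worked example

```python
import numpy as np
from hpcardiac.kinetics import RelaxationTimes, FlipSchedule, \
    forward_model, fit_inputless
from hpcardiac.phantom import AIFModel

relax = RelaxationTimes()                      # T1 = 30 / 25 / 20 s
flips = FlipSchedule(times=3.6 * np.arange(30))  # 30 frames, 3-heartbeat gap
tc = forward_model(AIFModel(), k_pl=0.02, k_pb=0.01, relax=relax, flips=flips)

fit = fit_inputless(tc, relax, flips)
print(f"k_PL = {fit.k_pl:.4f} /s, k_PB = {fit.k_pb:.4f} /s")
```

prints

```
k_PL = 0.0200, k_PB = 0.0100 /s
```

— the inputless fit inverts the forward model exactly on noiseless data.
At a pyruvate-peak SNR of 50 the median recovered k_PB over 200 noise
replicates stays within 1% of truth (see
`tests/test_kinetics.py::TestFitInputless`).

Running the analysis chain:

```sh
python analysis/01_psf_resolution.py
python analysis/02_simulate_cohort.py
python analysis/03_quantify_cohort.py
python analysis/04_regional_pattern.py
python analysis/05_cohort_stats.py
```

`01` prints the effective-resolution table (relative FWHM 1.014 at
T2* = 119 ms / 6 mm pyruvate → 6.09 mm effective; 1.042 at 43 ms / 12 mm
lactate → 12.51 mm; 1.028 at 64 ms / 12 mm bicarbonate → 12.33 mm).
`03`/`05` quantify the simulated 5-subject paired cohort: fed-state k_PB
roughly doubles in responders (e.g. subject S4: 0.0094 → 0.0207 s⁻¹), the
built-in non-responder is flat (S5: 0.0082 → 0.0082 s⁻¹), and the paired
t-test on k_PB gives p ≈ 0.024 with a glucose correlation of r ≈ 0.93.

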