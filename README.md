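# mrsquant

Absolute metabolite quantification for short-echo-time single-voxel ¹H-MRS
at ultra-high field (7 T), with the small-cohort permutation statistics used
in neuroinflammatory lesion studies.

The package is aimed at spectroscopists comparing chronic white-matter
lesions against contralateral normal-appearing white matter (NAWM) in
conditions such as multiple sclerosis (MS) and AQP4Ab-positive NMOSD, where
lesional water-T2 differences confound naive quantification and cohort
sizes are far too small for asymptotic inference.

## What it computes

**Linear-combination spectral fitting.** A measured spectrum S(ν) is
modelled over the 0.5–4.2 ppm window as

    S(ν) = Σ_m A_m · B_m(ν − Δν; σ_g) + baseline(ν)

where the B_m are metabolite basis spectra rendered from line lists
(chemical shifts, proton counts, first-order J-multiplets) as Lorentzians,
Δν is a global frequency shift, σ_g a Gaussian broadening (Voigt lineshape
by convolution) and the baseline a cubic B-spline with 0.3 ppm knots.
Amplitudes are non-negative; the problem is separable, so amplitudes and
spline coefficients are solved by bound-constrained linear least squares
inside a two-parameter nonlinear search. Per-metabolite Cramér–Rao lower
bounds CRLB_i = σ·√[(JᵀJ)⁻¹]_ii (J the Jacobian of the full model,
including baseline and nonlinear parameters) are reported as percent of the
fitted amplitude, and metabolites are screened at CRLB < 20 %.

**Water-T2 / CSF estimation.** Unsuppressed-water integrals acquired at
echo times from 11 to 4000 ms are fitted with the constrained biexponential

    S(TE) = A_t·exp(−TE/T2_t) + A_c·exp(−TE/565)

(CSF T2 fixed at 565 ms; three free parameters) by variable projection:
non-negative amplitudes solved linearly at each candidate T2_t. The CSF
volume fraction is A_c/(A_t + A_c) at TE = 0.

**Absolute quantification.** Fitted amplitudes become mmol/L via the water
reference from the same voxel,

    conc = A_met · (55510 · f_w) / (A_t · exp(−TE/T2_t)),

with f_w = 0.70 the white-matter tissue water content. Referencing to the
tissue amplitude A_t (not total water) removes the CSF partial volume;
the exponential undoes tissue-water T2 decay at TE = 11 ms. Composite
measures tNAA = NAA+NAAG, tCr = Cr+PCr, tCho = GPC+PCho, Glx = Gln+Glu and
per-subject ratios (e.g. Ins:NAA) are derived afterwards.

**Exact permutation inference.** One-sample (sign-flip) and unpaired
two-sample permutation t-tests enumerate all 2ⁿ sign patterns or
C(n₁+n₂, n₁) label assignments (e.g. 2048 sign-flips at n = 11; 16 at
n = 4, where the smallest attainable p is 1/16 = 0.0625; 1365 permutations
for 11 vs 4). Families sharing a shuffling scheme are corrected with the
single-step max-statistic (Westfall–Young) method; Cohen's d satisfies
t = d√n and t = d√(n₁n₂/(n₁+n₂)) exactly.

**Synthetic cohorts.** `mrsquant.simulate` generates complete study-shaped
datasets — per-subject true concentrations, water-T2 values, CSF fractions,
spectra at configurable S/N and linewidth, multi-TE water series, and an
EDSS disability score constructed to correlate with NAWM Ins:NAA — so the
whole chain is testable end to end without patient data.

## Worked example

```python
import numpy as np
from mrsquant import (default_basis, make_water_series, fit_water_biexponential,
                      make_spectrum, QuantConstants, absolute_concentration)
from mrsquant.specfit import SpectralFitModel

basis = default_basis()
truth = {"Ins": 8.1, "NAA": 8.94, "NAAG": 2.09, "Cr": 4.5, "PCr": 4.0, "Glu": 7.5}

water = fit_water_biexponential(
    make_water_series(43.3, 0.05, noise_sd=5.0, seed=0, total_amplitude=1000.0))
print(water.summary())

k = QuantConstants()
scale = water.a_tissue * np.exp(-k.te_ms / 43.3) / (
    k.pure_water_conc_mmol_L * k.tissue_water_content)
spec = make_spectrum(truth, basis, target_snr=25.7, scale=scale, seed=0)
fit = SpectralFitModel(spec, basis).fit()
for m in ("Ins", "NAA", "NAAG"):
    conc = absolute_concentration(fit.amplitudes[m], water, k)
    print(f"{m:<6} {conc:6.2f} mmol/L   (CRLB {fit.crlb_pct[m]:.1f}%)")
```

prints

```
Biexponential water-T2 fit
==========================
points:        12
T2 tissue:         42.801 ms  (bounds 5.0-200.0)
T2 CSF:             565.0 ms  (fixed)
A tissue:           948.7
A CSF:               54.6
CSF fraction:      0.0544
RSS:                126.8
converged:     True

Ins      8.06 mmol/L   (CRLB 1.7%)
NAA      8.90 mmol/L   (CRLB 0.9%)
NAAG     2.03 mmol/L   (CRLB 3.2%)
```

The water fit recovers the simulated lesion-tissue T2 (43.3 ms) and CSF
fraction (5 %) from 1 %-noise integrals; quantification then returns the
configured lesion concentrations (Ins 8.1, NAA 8.94, NAAG 2.09 mmol/L)
within each metabolite's CRLB.

A shell pipeline is also available:

```
mrsquant simulate --seed 1 --out cohort        # synthetic 11 MS + 4 NMOSD cohort
mrsquant run cohort/manifest.tsv --seed 1 --out report
```

which writes demographics, quality (water-T2/FWHM/SNR by group × site),
concentration, statistics (three permutation batches with FWER) and
Ins:NAA-vs-EDSS correlation tables as TSV.

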