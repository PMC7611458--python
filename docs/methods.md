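# Methods

This note documents the models implemented in `mrsquant`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Basis set

Metabolite basis spectra are built from line lists, not density-matrix
simulation. Each spin group (chemical shift δ in ppm, proton count,
scalar couplings J in Hz with equivalent-partner counts) is expanded into a
first-order multiplet: n+1 lines separated by J/ν₀ ppm with binomial
intensities summing exactly to the proton count; multiple couplings split
sequentially. Lines are rendered as area-normalised Lorentzians on the
acquisition ppm grid, so the integral of each rendered spectrum is
proportional to total proton count and unit amplitude corresponds to
1 mmol/L.

This first-order treatment is a deliberate simplification: strongly coupled
spin systems (the myo-inositol ring, glutamate/glutamine multiplets) are
approximated as weakly coupled line lists at literature positions, and
J-evolution during the echo time is not modelled. The approximation is
acceptable here because the package's validation targets the fitting,
uncertainty and quantification machinery, not basis fidelity; for real 7 T
data a density-matrix-simulated basis should be substituted (the
`BasisSet` container accepts any rendered spectra on the shared grid).
Shifts and couplings ship as a versioned JSON file
(`mrsquant/data/basis_library.json`) — they are configuration, not
hard-coded truth.

Lineshape convention: the basis is rendered at a base Lorentzian width
(default 2 Hz); Gaussian broadening is applied at fit time, giving a Voigt
profile by convolution. Grids are stored ascending in ppm; the
right-to-left display convention is applied only in plots.

## Spectral fitting

The model over the 0.5–4.2 ppm window is
S(ν) = Σ A_m B_m(ν − Δν; σ_g) + spline(ν) with A_m ≥ 0, a global shift
|Δν| ≤ 0.05 ppm, Gaussian broadening 0 ≤ σ_g ≤ 15 Hz, and a cubic B-spline
baseline with 0.3 ppm knot spacing (LCModel-like stiffness; the baseline
model is our choice, as published studies rarely specify one). The
separable structure is exploited: for fixed (Δν, σ_g) the amplitudes and
spline coefficients are a bound-constrained linear least-squares problem
(solved with BVLS); the two nonlinear parameters are found by a coarse
grid scan followed by Nelder–Mead. A brute-force grid oracle over
(Δν, σ_g) is used in the tests to confirm the joint optimum.

Noise σ is estimated from the metabolite-free 9–10 ppm region after
removing a linear trend (at 7 T this region carries no metabolite signal).
CRLBs are computed from the Jacobian of the *full* model — amplitude
columns, spline columns, and finite-difference columns for Δν and σ_g —
as CRLB_i = σ·√[(JᵀJ)⁻¹]_ii; including the baseline and nonlinear
parameters makes the bounds conservative, mirroring LCModel's behaviour.
Percent bounds are infinite at zero amplitude, and a singular information
matrix marks CRLBs unavailable rather than crashing. Screening retains a
metabolite iff CRLB < 20 % — strictly less than, following the standard
inclusion wording. For noiseless input no noise estimate exists; the
pipeline then skips screening (with a log entry) instead of excluding
everything.

Quality metrics: linewidth is the FWHM of the fitted NAA 2.01 ppm acetyl
singlet (linear interpolation of the half-maximum crossings); S/N is the
maximum baseline-subtracted fitted signal divided by twice the RMS of the
noise region.

Phase correction is assumed done upstream (synthetic data are phased);
phasing, frequency-drift correction and measured macromolecule spectra are
out of scope.

## Water-T2 and CSF fraction

The multi-TE unsuppressed-water integrals are fitted with
S(TE) = A_t·e^(−TE/T2_t) + A_c·e^(−TE/565), T2 of CSF fixed at 565 ms,
three free parameters. Estimation is by variable projection: at each
candidate T2_t the amplitude subproblem is non-negative linear least
squares, leaving a 1-D profile over T2_t ∈ [5, 200] ms that is scanned
coarsely (8 log-spaced seeds) and refined by bounded scalar minimisation.
This is globally robust where a 3-parameter joint optimiser can stall; the
profiled optimum is verified in tests against an exhaustive 0.01 ms grid.
An optimum within tolerance of a T2 bound is flagged `at_boundary` and
reported `converged=False` — never silently returned as success. TR = 15 s
is treated as fully relaxed, so no T1 term appears.

## Absolute quantification

conc = A_met · (55510 mmol/L · f_w) / (A_t · exp(−TE/T2_t)), with

- 55510 mmol/L: proton-pair concentration of pure water;
- f_w = 0.70: white-matter tissue water content (literature value; the
  constant is configurable per tissue, including a lesion override, since
  lesional water content is elevated);
- A_t: tissue-water amplitude extrapolated to TE = 0 from the biexponential
  fit — referencing to A_t rather than A_t + A_c is precisely the CSF
  partial-volume correction;
- exp(−TE/T2_t): undoes tissue-water T2 decay at the metabolite TE
  (11 ms). With lesion vs NAWM T2 of 43.7 vs 39.9 ms this correction
  changes concentrations by ≈ 2.4 % (exp(11/43.7 − 11/39.9) = 0.9763) —
  the size of the bias that uncorrected analyses inherit.

Deliberate omissions, each a uniform scale factor across voxels: metabolite
T2 attenuation is not corrected (metabolite T2s are not measured in a
short-TE protocol) and T1 saturation at TR = 5 s is neglected. The formula
is an explicit reconstruction of water-referenced scaling; the absolute
scale is therefore only as good as f_w and these assumptions, while
*between-voxel comparisons* (the study design) are unaffected.

Composite measures (tNAA, tCr, tCho, Glx) are exact sums added per subject
and site; a missing component leaves the sum out rather than imputing.
Ratios (Ins:NAA) are computed per subject before averaging (mean of
ratios, not ratio of means).

## Permutation inference

Sign-flip (one-sample) and label-permutation (two-sample, pooled-variance
t) tests enumerate exhaustively when the count (2ⁿ or C(n₁+n₂, n₁)) is at
most 2²⁰, otherwise fall back to seeded Monte Carlo with the identity
shuffling always included. p-values count the identity, so exhaustive
p-values are exact multiples of 1/N and never below 1/N; at n = 4 the
smallest attainable one-tailed p is 1/16 = 0.0625. Tests verify
super-uniformity by full enumeration at n = 6 and empirical type-I control
over 1000 null simulations.

FWER correction within a batch is single-step max-statistic
(Westfall–Young): each result carries its per-shuffling statistic vector,
batches are validated to share one shuffling scheme (exhaustive
enumeration is canonically ordered, so shufflings align across tests), and
the corrected p of test m is the proportion of shufflings whose maximum
|t| across the family reaches |t_m|. Bonferroni is available as an
alternative flag. One-tailed tests run in both directions are combined as
min(1, 2·min(p)), which equals the two-tailed p for a symmetric enumerated
null.

Cohen's d uses the conventions d = mean/SD (one-sample) and pooled-SD
difference (two-sample), which satisfy t = d√n and t = d√(n₁n₂/(n₁+n₂))
identically — the tests assert these identities to 1e-12.

Pearson correlations report r, R², t = r√((n−2)/(1−r²)) and the two-tailed
t-distribution p; 2×2 demographic tables use Yates-corrected chi-square.

## Synthetic cohort generator

The generator emulates the study design's statistical structure: 11 MS and
4 NMOSD subjects, lesion and NAWM voxels per subject, group × site
concentration means/SDs for Ins, NAA and NAAG (plausible white-matter
values for the other 16 compounds), tissue-water T2 means of 43.3/44.7 ms
(lesion) vs 40.1/39.3 ms (NAWM), CSF fractions uniform on [0.02, 0.12],
linewidth 0.03 ppm and S/N targets 25.7 (lesion) / 28.3 (NAWM).

Concentrations are truncated normals (truncation at zero prevents negative
mmol/L); the within-subject lesion/NAWM correlation — a quantity real
cohorts have but published tables do not report — defaults to 0.3 and is
carried through a Gaussian copula so the truncated marginals are exact.
EDSS is a latent-variable construction: the NAWM Ins:NAA ratio is
standardised, mixed with noise at the target correlation (default
r = 0.55), mapped to a group-centred 0–10 scale and rounded to 0.5 steps —
the simplest mechanism that delivers a target correlation on an ordinal
scale. The realised large-sample correlation runs slightly above the
mixing coefficient (~0.60 at n = 1000) because the group difference in
both EDSS centre and Ins:NAA adds a between-group component; this is
retained as realistic.

Spectra are the noiseless sum of concentration-weighted basis spectra,
Gaussian-broadened to the target Voigt FWHM (Olivero–Longbothum
inversion), plus a smooth macromolecule-style background (three broad
Gaussian humps — a stand-in for the in-vivo MM baseline, not a measured
one) and white noise calibrated so the package's own S/N estimator lands
at the target. Water series follow the biexponential model exactly, with
Gaussian noise. A voxel-level scale factor links metabolite-signal units
to water-integral units so that absolute quantification round-trips; it is
derived from the voxel's true water amplitudes via the same constants the
quantifier uses.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: eddy currents, frequency drift, phase
errors, coil combination, measured macromolecule shapes, non-Gaussian
noise, basis imperfection (the fit uses the same basis that generated the
data), and partial-volume heterogeneity beyond a scalar CSF fraction.

## Numerical choices and problem sizes

- Default grid: 4096 points over 12 ppm (≈ 0.0029 ppm/point) centred on
  water at 4.65 ppm; the fit window then holds ~1260 points.
- Water-fit tolerance 1e-6 ms on T2; spectral nonlinear search: 3×4 coarse
  grid then Nelder–Mead (xatol 1e-4), ≤ 120 iterations.
- Tie-breaks: bound-touching water optima flagged not-converged;
  rank-deficient spectral designs are flagged and warned, never crashed;
  degenerate permutation inputs (all-zero differences, zero pooled
  variance) raise typed errors, which the pipeline converts to p = 1 rows
  (paired) or skipped comparisons (unpaired) with log entries.
- Simulation sizes in the test suite were chosen to keep the default run
  fast while leaving estimates stable: 200 replicates for water-fit bias,
  500 refits for CRLB-vs-Monte-Carlo calibration, 1000 null datasets for
  type-I control, full 2⁶ enumeration for super-uniformity, 50 seeds for
  noisy-recovery medians, and 1000-subject cohorts for generator
  correlation checks.

## Known limitations

- First-order basis: quantification accuracy on real strongly coupled
  systems will be worse than the synthetic round-trips suggest.
- The water-scaling constants (f_w, no metabolite-T2/T1 terms) set the
  absolute scale by assumption; cross-study absolute comparisons need the
  same conventions.
- CRLBs are lower bounds under the assumed model; baseline mis-modelling
  biases both amplitudes and their reported uncertainty.
- The max-statistic FWER correction assumes the family shares one
  shuffling scheme; tests across different designs cannot be batched and
  must fall back to Bonferroni.
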