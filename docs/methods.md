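# Methods

This note documents the models, estimators and numerical choices behind
`fdgquant`, and what the synthetic-data tests do and do not demonstrate.

## Quantification

**Patlak analysis.** For an irreversibly trapped tracer the tissue
concentration obeys Ct(T) = Ki·∫₀ᵀCp dt + V·Cp(T) once the free compartment
has equilibrated, so y = Ct/Cp against x = ∫Cp/Cp is linear with slope Ki.
We evaluate both coordinates at frame midpoints; Cp at a midpoint is
linearly interpolated between blood samples, and ∫₀ᵀCp is the exact
integral of that piecewise-linear curve (with a leading segment rising from
(0, 0) when the first sample is later than injection). Points with
Cp below 10⁻⁶ of the peak plasma activity are dropped before fitting.
The fit is ordinary least squares over points with frame midpoint ≥ t*
(default 30 min), intercept free, no blood-volume correction, and requires
at least 3 points and non-degenerate x. With the default 21-frame schedule
exactly the three 600 s frames qualify. Midpoints rather than
decay-weighted frame times are used because the frames are long relative to
the kinetics and the curves are decay-corrected; the residual bias this
causes is part of the recovery error quantified below.

**CMRglu.** CMRglu = Ki·Gly/LC·(100/ρ) with the lumped constant LC = 0.34,
tissue density ρ = 1 g/mL, and Gly taken from the arterial sample by
default (venous can be selected; arterial and venous glycemia are nearly
interchangeable in this setting and the generator links them with slope
0.972). Glycemia in mmol/L equals µmol/mL, giving µmol·min⁻¹·(100 g)⁻¹.

**SUV family.** Plateau SUV is the duration-weighted mean over frames whose
midpoints lie in [30, 60] min (a frame ending exactly at 30 min is
excluded); duration weighting makes the estimate independent of how the
plateau is subdivided into frames. SUV×Gly multiplies by the same glycemia
used for CMRglu. SUVR divides by the reference region's plateau SUV; a
reference region's ratio to itself is omitted from outputs.

**Plasma exposure.** Trapezoidal AUC of the SUV-normalized input function
from 0 to 60 min, on the sampled schedule (no extrapolation).

## Repeatability statistics

With N subjects scanned twice, the decomposition uses all 2N values:

* grand mean m and SD s (df = 2N−1);
* intra-subject variance σ²ᵢ = Var(test−retest)/2 with df = N−1 — the
  residual mean square of the subject×session two-way layout, verified in
  the tests against a statsmodels ANOVA oracle;
* inter-subject variance σ²ᵦ = s² − σ²ᵢ, clipped at 0 when sampling
  fluctuation drives it negative (the pre-clip value is kept as
  `var_inter_raw` because it is the unbiased carrier — the clipped CV is
  biased upward in small samples, so parameter-recovery checks compare
  variance-scale means);
* CVs are 100·σ/m; explained-variance shares are computed on the variance
  scale after clipping, so they always sum to 100;
* the 95% CI is m ± t₀.₉₇₅,₂N−₁·s with the lower bound clipped at 0. This
  is a population-dispersion interval (t quantile times the SD, not the
  standard error): it describes where individual values are expected to
  lie, which is what the robustness check needs, and it uniquely reproduces
  the reference study's printed bounds (e.g. 20.6 + 2.201·10.1 = 42.8,
  whereas 1.96·SD does not);
* sample size n = max(1, ⌈(t·s/(precision·mean))²⌉) with t = 1.96 and
  precision 0.20 by default; rounding up is our choice.

Spearman correlations use average ranks with an exact permutation p-value
for n ≤ 8 (full n! enumeration) and the t approximation above that. The
paired Wilcoxon test drops zero differences, mid-ranks ties, and enumerates
all 2ᴺ sign assignments for N ≤ 12 (two-sided p = mass at or beyond the
observed statistic in either tail), falling back to the normal
approximation beyond. The robustness check reports, per parameter, the
fraction of an independent group's (subject × region) values inside the
test–retest CIs.

No multiplicity correction is applied anywhere.

## Synthetic study generator

The generator emulates a standardized test–retest protocol in anesthetized
macaques: 6 subjects × 2 sessions (plus independent single-session groups
for robustness), 10 brain regions, a 60 min dynamic acquisition rebinned as
4×15, 4×30, 2×60, 5×120, 3×300 and 3×600 s frames, and arterial sampling
every 15 s to 2 min then at 2.5, 3, 5, 10, 20, 40 and 60 min. The printed
rebinning protocol of the reference acquisition lists 9×600 s frames
(120 min total) against a 60 min scan; the default schedule keeps the
printed durations and truncates at 3600 s (21 frames), and is fully
configurable.

**Input function.** Cp(t) is zero before an appearance delay (0.25 min),
then a gamma-variate bolus (shape 3, rate 6.25 min⁻¹) plus a
two-exponential tail (fractions 0.08 and 0.15 of the bolus peak, rates 0.01
and 0.7 min⁻¹) with a smooth onset. The curve is scaled so the
SUV-normalized 0–60 min AUC equals a target plasma exposure
(94.1 SUV·min), jittered per session by a unit-mean lognormal factor with
CV 14.5%. The shape constants were calibrated once so the continuous curve
peaks at 0.73 min and so the Patlak transient decays fast enough for the
recovery contract below; a distribution-phase rate comparable to k₂+k₃
(e.g. 0.25 min⁻¹) would leave a slowly fading transient that biases the
30–60 min Patlak slope by about −5%.

**Kinetics.** Each region follows the irreversible two-tissue model
dC₁/dt = K₁Cp − (k₂+k₃)C₁, dC₂/dt = k₃C₁, solved on a dense uniform grid
(step ≤ 0.01 min — an enforced accuracy contract) by trapezoid-corrected
FFT convolution; Ct = (1−v_B)(C₁+C₂) + v_B·Cp with v_B = 0 by default
(whether the reference analysis included a blood-volume term is unknown).
K₁ = 0.10 mL·min⁻¹·mL⁻¹ and k₂ = 0.13 min⁻¹ are fixed; k₃ is set per
region from a reference influx-rate map (Ki 0.0119–0.0199 min⁻¹, pons
lowest, caudate/putamen/frontal highest) chosen so CMRglu means span
roughly 15–27 µmol/min/100 g at glycemia 4.5 mmol/L.

**Variance structure.** True influx rates are
Ki(i,s,r) = map[r]·exp(bᵢ)·exp(e_is) with bᵢ ~ N(0, σ²ᵢₙₜₑᵣ) (default
σ = 0.05, applied by scaling K₁ per subject) and e_is ~ N(0, σ²ᵢₙₜᵣₐ)
(default σ = 0.18, applied as a *global* multiplicative factor on the
measured scan — matching the observation that test–retest differences are
global rather than regional, and making reference-region ratios cancel
them). Two further measurement-level components are needed to reproduce
realistic variability ranges: a per-region session residual
exp(u_isr), u ~ N(0, 0.06²), standing for residual segmentation/
repositioning differences (without it SUVR would carry only frame noise,
an unrealistically low ~3% AbsVar), and multiplicative Gaussian frame
noise with CV 0.05 on the longest frame, scaled by 1/√duration.
Glycemia keeps a 4.5 ± 0.7 mmol/L marginal split by an intraclass
correlation of 0.75 into a stable subject level plus session fluctuation;
venous glycemia is 0.972·arterial plus N(0, 0.25) residual. Doses
(169.2 ± 9.0 MBq) and weights (5.8 ± 1.1 kg) are truncated normals.
A single seeded generator drives all draws in a fixed, documented order,
so studies are bit-reproducible from `rng_seed`.

With these defaults the emulated protocol lands where the reference study
reports its ranges: region-averaged group AbsVar ≈ 35% for CMRglu
(reported range 25–43%), ≈ 11% for SUVR (7–14%), ≈ 27–28% for SUV and
SUV×Gly, and an independent-group CI membership around 0.95.

**What the generator does not emulate.** No image domain (voxels, PSF,
attenuation, scatter, reconstruction), no anesthesia or physiology
dynamics, no glycemia→kinetics coupling (measured glycemia enters CMRglu
as pure noise rather than as the competitive substrate effect it corrects
for in vivo), no blood-sample counting noise, and no inter-regional
correlation beyond the shared global effects. Passing tests therefore
demonstrate the correctness and calibration of the estimators on
TAC-level data with a plausible variance structure — not image-processing
fidelity on real scans.

## Numerical choices and degenerate inputs

* Dense grid: [0, 60] min, step 0.01 min; coarser grids are rejected.
  Convolution is trapezoid-corrected (O(dt²)); the trapped compartment uses
  cumulative trapezoid integration; tiny negative round-off is clipped.
* Frame binning integrates the piecewise-linear dense curve exactly and is
  affine in the curve; a schedule outside the curve's span is an error.
* Noiseless end-to-end Patlak recovery error is below 1.5% of the true Ki
  in every default region (dominated by the sampled-AIF trapezoidal AUC
  and the Patlak transient), inside the 2% contract asserted by the tests.
* Patlak R² is reported per fit; under default frame noise single 3-point
  fits can scatter (R² occasionally < 0.9) while the Ki estimate stays
  unbiased — this mirrors the fragility of late-window Patlak with few
  frames.
* Exact tests enumerate (n! permutations for Spearman at n ≤ 8, 2ᴺ sign
  assignments for Wilcoxon at N ≤ 12); ties are mid-ranked; a constant
  vector (Spearman) or all-zero differences (Wilcoxon) is an error, as is
  a non-positive pair mean for AbsVar and n < 2 for any CI.
* CSVs are written with 12 significant digits and round-trip at 1e-9;
  pipeline outputs contain no timestamps, so a rerun with the same config
  and seed is byte-identical.

## Problem sizes used by the test suite and acceptance script

Stochastic checks use 200 replicate studies (6 subjects × 2 sessions × 10
regions) in the test suite and 100 (400 for the variance-component
recovery, whose 5% between-subject component is small relative to its
Monte-Carlo error) in the acceptance script; calibration checks use 20
studies (240 scans). These sizes put the Monte-Carlo standard errors well
inside the asserted tolerances while keeping runs to about a minute.

## Known limitations

* The Mermet-style intra-subject estimator assumes exactly two sessions;
  designs with more sessions are not supported by `decompose`.
* The clipped inter-subject CV is biased upward when the true component is
  small; use `var_inter_raw` for unbiased aggregation across studies.
* The 3-point default Patlak window gives noisy per-scan Ki under frame
  noise; this is a property of the emulated protocol, not of the fit.
* The printed sample sizes and cross-parameter correlation matrix of the
  reference study depend on unpublished per-animal data and unstated
  pooled inputs; the formulas are implemented and property-tested, but
  those absolute numbers are not reconstructed.
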