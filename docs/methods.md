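# Methods

## Spectral model and preprocessing

Spectra are dimensionless absorbance on a shared, strictly ascending
wavenumber grid; the default acquisition grid is 400–4000 cm⁻¹ at 4 cm⁻¹
steps (901 points). All modeling uses the 800–1800 cm⁻¹ fingerprint
window (251 points, closed interval on both ends), where the lipid,
protein and carbohydrate marker bands live.

**AsLS baseline.** For each spectrum y the baseline z minimizes
Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σᵢ(Δ²z)ᵢ², with asymmetric weights wᵢ = p above the
baseline and 1−p below (Eilers–Boelens formulation with a second-order
difference penalty — the λ = 20 000 magnitude is meaningful for second
differences on a ~4 cm⁻¹ grid). Defaults: λ = 20 000, p = 0.001,
≤ 50 reweightings, starting from w ≡ 1. Iteration stops at an exact fixed
point of the discrete weight assignment (typical within ~10 iterations) or
when the baseline changes by < 1e-6 relative. The linear system
(W + λDᵀD)z = Wy is solved with a sparse Cholesky-style factorization
(`scipy.sparse`); the test suite checks it elementwise (≤ 1e-8) against an
independent dense-matrix solve. Corrected spectra are *not* floored at
zero: clipping would bias the subsequent area normalization.

**Area normalization.** Each corrected spectrum is scaled so its
trapezoidal integral over the retained grid equals 1. The trapezoid (not a
plain sum) is well defined on non-uniform grids; on uniform grids the two
differ by a constant factor that normalization absorbs. Normalization
cancels multiplicative scatter (gain) exactly in the noise-free limit.
AsLS is applied per spectrum, not to the matrix jointly.

## PLS regression

Single-response NIPALS on mean-centered X and y — no unit-variance
scaling, since area-normalized absorbances share one scale. Per component:
w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X is deflated
by t pᵀ; y is not deflated (redundant for one response). The factorization
collapses to b = W(PᵀW)⁻¹q with intercept ȳ − x̄ᵀb; predictions via the
factorization and via (b, b₀) agree to 1e-10, and with all components PLS
reproduces ordinary least squares. If the deflated matrix stops covarying
with the response (rank exhaustion), extraction stops early and the model
keeps the factors found — leave-one-out selection then sees a flat RMSECV
tail and, with ties broken to the smallest k, still picks the parsimonious
order.

**Component selection.** Leave-one-out cross-validation over k = 1…k_max
(default k_max = min(10, n_cal − 2)). NIPALS factors are nested, so one
factorization at k_max per left-out sample yields the whole RMSECV curve;
the tests verify exact agreement (≤ 1e-10) with naive per-(i, k) refits.
chosen_k is the argmin, first index on ties.

**Calibration/validation split.** round(frac·n) calibration samples
(default frac = 0.75; for n = 101 this is 76/25), stratified over
quartiles of y by largest-remainder allocation, with the overall minimum
and maximum y forced into calibration so validation never extrapolates.
The split is a pure function of (y, frac, seed).

**Metrics.** RMSEP = √(Σ(ŷ−y)²/n_val); RE = RMSEP / mean(y_val);
R² = squared Pearson correlation of observed vs predicted, floored at 0
for zero-variance predictions. The squared-correlation convention keeps a
failed model's R² at a small positive value rather than the negative
numbers 1 − SS_res/SS_tot produces; both conventions were considered and
the correlation form is used throughout.

## PCA

SVD of the centered spectra matrix; explained-variance ratios are
singular values squared over their total. Sign indeterminacy is fixed by
making the largest-magnitude element of each loading vector positive, so
results are reproducible across linear-algebra backends. Group summaries
in the (PC1, PC2) plane report centroids and 90 % normal-theory confidence
ellipses (score covariance scaled by the χ²(2) 0.90 quantile ≈ 4.605);
groups with fewer than 3 samples get a centroid only, and pairs of
non-intersecting ellipses are flagged.

## Univariate peaks

Peak height is the maximum absorbance within ± 8 cm⁻¹ (two grid steps) of
the nominal center — 1740 cm⁻¹ for the ester carbonyl, 1650 cm⁻¹ for
Amide I. The windowed maximum absorbs the 1740-vs-1750 (and 1650-vs-1660)
ambiguity of literature band positions. The 1740/1650 ratio cancels
multiplicative effects (scatter gain, ash dilution, imperfect
normalization) shared by both bands; it helps exactly when those shifts
exceed the independent variation of protein, which is the condition the
corresponding test constructs. Calibration is ordinary least squares with
squared-Pearson r².

## Group statistics

Student's pooled-variance two-sample t (df = n₁+n₂−2, two-tailed p) — the
pooled form, not Welch, matching the integer degrees of freedom
conventional for small balanced culture comparisons — and classical
one-way ANOVA (F with df (k−1, N−k)). Degenerate conventions: identical
data give t = 0 / F = 0 with p = 1; zero within-group variance with
unequal means gives p = 0; both-degenerate t-test inputs raise. Culture
durations are binned into weeks as floor(days/7). No multiple-testing
correction is applied.

## FAME quantification

RRF_i = (A_i/m_i)/(A_IS/m_IS) against the C15:0 internal standard
(default 10 µg per sample); with multi-level calibration data the RRF is
the least-squares slope through the origin of A_i/A_IS vs m_i/m_IS — an
intercept would contradict the ratio definition. Sample masses follow
m_i = (A_i/A_IS)·m_IS/RRF_i and totals are (Σm_i µg)/(biomass·1000)·100
%DW with a 20 mg default biomass. Results are FAME-equivalent masses: no
FAME→free-fatty-acid molecular-weight correction is applied (users can
post-correct), and any internal-standard stoichiometry (one
tripentadecanoin yielding three C15:0 methyl esters) is absorbed into the
RRF normalization. Peak integration and identification are out of scope;
inputs are integrated area tables.

## Synthetic-data generator

Each sample is a Beer–Lambert-style linear mixture on the acquisition
grid:

    A(ν) = gain · (1 − ash/100) · Σ_k (conc_k/100) · B_k(ν)
           + baseline(ν) + ε(ν)

with Gaussian/Lorentzian component bands (fatty acid: 1740 strong plus
1470/1160/990 minor; protein: 1650 > 1540 plus 1310; carbohydrate:
1030/1080/1150 broad; one broad low background band), a random quadratic
baseline, log-normal multiplicative gain and iid additive noise.

Regimes (compositions in %DW, uniform over the stated ranges):

| parameter | monoculture | polyculture |
|---|---|---|
| fatty acid | U(1.32, 22.46) | U(0.76, 4.21) |
| protein | U(15, 35) | U(16, 30) |
| ash | U(2, 8) | U(10, 30) |
| n (default) | 44 | 57 |

Carbohydrate is remainder-coupled, carb = max(70 − fa − protein, 5),
introducing the negative fatty-acid/carbohydrate correlation expected of
storage-compound partitioning; "other" fills the balance to 100 − ash.
Noise defaults: gain_sd = 0.1 (log-normal σ), noise_sd = 0.002 absorbance
per point, baseline offset/slope/curvature sds 0.005 / 5e-6 / 2e-9 (in
absorbance, per cm⁻¹ and per cm⁻², i.e. excursions below ~0.01
absorbance — small relative to the signal, as a KBr-background-subtracted
measurement should be).

Two deliberate scale choices: all four components share the same
*integrated* absorptivity (~14 absorbance·cm⁻¹ per unit mass fraction),
so total spectral intensity tracks organic content and ash dilution
rather than the organic mix — polyculture spectra are then dimmer than
monoculture spectra on average, as high-ash pond biomass is. And the
absolute band scale (0.30 peak absorbance per unit fraction at 1740) sets
the detector-noise floor at roughly 0.5 %DW of fatty-acid equivalent,
the error magnitude typical of this kind of calibration; mixed-sample
peak absorbances land around 0.02–0.2.

What the generator does **not** model: Kubelka–Munk diffuse-reflectance
nonlinearity, atmospheric CO₂/H₂O artifacts, instrument line-shape
effects, band-position jitter between samples, and reference-method error
(the truth table is exact). Passing tests therefore demonstrate that the
pipeline recovers a known linear mixing structure under realistic noise,
scatter and dilution — not that it handles every pathology of real
diffuse-reflectance measurements.

All randomness flows from one explicit seed through a single
`numpy.random.Generator`; there is no global random state.

## Problem sizes and tolerances

The default study-shaped dataset is n = 101 (44 + 57) on a 901-point
grid, modeled on 251 fingerprint points; the headline evaluation repeats
the full pipeline for ten consecutive seeds (a few seconds per run on one
CPU). Oracle equivalences are asserted at 1e-8 (AsLS dense solve,
PLS-vs-OLS) and 1e-10 (LOO-CV refits, F = t²); null-calibration of the
tests uses 10 000 simulated replicates with rejection rates required
inside [0.04, 0.06] at α = 0.05.

## Known limitations

- The polyculture-only pipeline degrades markedly relative to the
  combined model (narrow calibration range), but under the default
  generator conditions its validation R² does not reliably fall below
  0.5: the noise level that would force that would simultaneously push
  the combined model's relative error above its own acceptance bound.
  The two regime behaviors are in tension at these settings, and the
  qualitative ordering (polyculture ≪ combined) is the property asserted
  robustly.
- RE is defined as RMSEP over the mean *observed validation* value;
  other denominators (calibration mean, range) exist in the literature
  and are not configurable.
- PLS is single-response; no uncertainty intervals, variable selection
  or kernel variants.
- Vendor file formats (OPUS/SPC/JCAMP-DX) are not parsed; interchange is
  plain CSV.
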