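# driftfa

Chemometrics for estimating **total fatty acid content of microalgal
biomass** from diffuse reflectance infrared Fourier transform (DRIFTS)
spectra.

Screening algal strains and timing the harvest of production ponds both
require frequent fatty-acid measurements. The reference method —
chloroform/methanol extraction, transmethylation and GC-FID of the fatty
acid methyl esters (FAMEs) — is slow and solvent-hungry. Infrared spectra
of dried biomass contain the same information in the fingerprint region
(800–1800 cm⁻¹), where the lipid ester carbonyl stretch near 1740 cm⁻¹ is
the principal fatty-acid marker band next to the protein Amide I/II bands
(≈1650/1540 cm⁻¹) and carbohydrate C–O–C stretches (950–1200 cm⁻¹).
`driftfa` implements the full calibration workflow that links the two:

- **Preprocessing** — cut to the fingerprint region, asymmetric least
  squares (AsLS) baseline correction (Whittaker-type second-difference
  penalty, λ = 20 000, p = 0.001), normalization to unit spectral area.
- **PLS regression** — single-response NIPALS partial least squares on
  mean-centered spectra; the component count is chosen by leave-one-out
  cross-validation; validation quality is reported as RMSEP,
  RE = RMSEP / ȳ_val, and R² (squared Pearson correlation).
- **PCA** — SVD scores/loadings/explained variance with 90 % confidence
  ellipses per sample group.
- **Univariate comparator** — 1740 cm⁻¹ peak height and the 1740/1650
  peak ratio with ordinary least-squares calibration.
- **Group statistics** — pooled two-sample *t*-test and one-way ANOVA of
  fatty-acid content across culture conditions.
- **FAME quantification** — relative response factors against a C15:0
  internal standard and conversion of GC-FID peak areas to %DW.
- **Synthetic data** — a seeded generator of DRIFTS-like spectra with
  known fatty-acid ground truth, emulating a wide-range *monoculture*
  regime (1.32–22.46 %DW fatty acids, low ash) and a narrow-range
  *polyculture* regime (0.76–4.21 %DW, high protein, 10–30 %DW ash).

The core model: a calibration set of preprocessed spectra **X** (n × p
absorbance values) and reference values **y** (%DW from GC-FID) yields the
NIPALS factorization X = T Pᵀ + E, with weights **W**, scores T = X W(PᵀW)⁻¹
and response loadings **q**, collapsed to b = W(PᵀW)⁻¹q so that
ŷ = X b + b₀. The RMSECV curve over k = 1…10 latent variables picks the
model order.

## Worked example

```python
from driftfa import evaluate_synthetic

report = evaluate_synthetic(seed=1, subset="combined")
for key in ("n_cal", "n_val", "chosen_k", "rmsep", "re", "r2"):
    print(key, report[key])
```

prints

```
n_cal 76
n_val 25
chosen_k 4
rmsep 0.40867...
re 0.06171...
r2 0.99557...
```

A combined dataset of 101 synthetic samples (44 monoculture + 57
polyculture) was split 76/25, leave-one-out cross-validation selected 4
latent variables, and the held-out predictions have a root-mean-square
error of 0.41 %DW — about 6 % of the mean validation value (RE) — with
R² ≈ 0.996. Restricting the same pipeline to the narrow polyculture range
(`subset="polyculture"`) degrades prediction markedly (R² ≈ 0.66, RE ≈ 0.27
at the same seed): a calibration spanning a wide fatty-acid range is what
makes the model reliable.

The same workflow is scriptable from a shell:

```
driftfa simulate --n-mono 44 --n-poly 57 --seed 1 --out spectra.csv --ref fa.csv
driftfa preprocess --in spectra.csv --out processed.csv --lo 800 --hi 1800
driftfa fit --spectra processed.csv --ref fa.csv --seed 1 --model model.json
driftfa evaluate --model model.json --spectra processed.csv --ref fa.csv --metrics m.json
```

plus `pca`, `peaks`, `groupstats`, `famequant` and `run --config run.yaml`
for a fully logged end-to-end run.

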