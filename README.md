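# cbctomics

Quantitative interchangeability of radiomic features between planning CT
(pCT) and cone-beam CT (CBCT) rests on two ingredients: consistent automatic
tumor segmentation on both modalities, and per-feature agreement statistics
across a paired cohort.  `cbctomics` implements that full analysis as a
tested, seedable Python pipeline for researchers studying CBCT-based
radiomics (e.g. for monitoring rectal-cancer response during
chemoradiotherapy), exercised end-to-end on synthetic paired phantoms
because clinical pCT/CBCT pairs are rarely shareable.

The pipeline:

1. **Synthetic paired cohorts** — lobulated tumor phantoms in noisy
   soft-tissue backgrounds at 5 mm slice spacing, plus CBCT-like
   counterparts of the same anatomy (3 mm native slices resampled back to
   5 mm, extra noise, reduced contrast, cupping shading).
2. **Preprocessing** — HU windowing to (−200, 300), foreground cropping,
   linear resampling to a fixed grid, and slice-wise contrast-limited
   adaptive histogram equalization (CLAHE).
3. **Segmentation** — a 3D residual U-Net (numpy/numba implementation,
   no GPU required) trained with the Tversky loss

   `T(α,β) = Σpg / (Σpg + α·Σp(1−g) + β·Σ(1−p)g)`,  loss = 1 − T,

   with α = 0.3, β = 0.7 weighting false negatives harder (α = β = 0.5 is
   soft Dice); Adam, learning rate 1e-4, batch size 2 (batch 1 in the
   scaled CPU profile).
4. **Scoring** — Dice similarity coefficient (DSC), 95th-percentile
   Hausdorff distance (HD95, mm) and average symmetric surface distance
   (ASSD, mm), verified against brute-force oracles.
5. **Radiomics** — a from-scratch 1037-feature engine: 14 shape, 19
   first-order, 172 texture (GLCM/GLRLM/GLSZM/GLDM/NGTDM over original,
   intensity-transform and gradient images), 728 wavelet (8 sub-bands) and
   104 Laplacian-of-Gaussian features.
6. **Concordance** — per-feature Pearson R across the paired cohort; a
   feature is interchangeable between modalities when R > 0.9, with three
   literature prognostic features (original first-order Energy, original
   and wavelet-HLH GLRLM gray-level non-uniformity) flagged.

See `docs/methods.md` for the models, parameters and design choices.

## Worked example

```python
from cbctomics.config import scaled_profile
from cbctomics.pipeline import run_segmentation_study, run_concordance_study
from cbctomics.synthetic import generate_cohort_arrays
from cbctomics.radiomics import firstorder_only_manifest

cfg = scaled_profile(seed=42, n=60)          # 48^3 phantoms, 15 epochs
cases = generate_cohort_arrays(cfg.cohort_size, cfg.phantom)

net, history, table, summary = run_segmentation_study(cfg, "PCT", cases)
print(summary)                                # held-out DSC / HD95 / ASSD

report = run_concordance_study(cfg, cases, firstorder_only_manifest())
print(report.table.head(3)[["feature", "r", "selected"]])
```

Output from this exact script (seed 42):

```
           dsc      hd95      assd
mean  0.808346  6.046373  1.326824
std   0.111974  9.137494  1.651369
                           feature         r  selected
0       original_firstorder_Energy  0.996481      True
1  original_firstorder_TotalEnergy  0.996481      True
2         original_firstorder_Mean  0.993383      True
```

The summary rows are the mean and standard deviation over the 18 held-out
phantoms: mean DSC 0.81 says the scaled network recovers the tumors well
on this synthetic task after only 15 epochs, and the HD95/ASSD rows give
the residual boundary error in millimetres (≈6 mm HD95 at 5 mm slice
spacing is about one slice of disagreement).  In the concordance table,
`r` is the Pearson correlation of that feature between the pCT and CBCT
version of each case; rows with `selected=True` pass the strict R > 0.9
interchangeability rule — 7 of the 19 first-order features survive the
default CBCT degradation.

A command-line interface mirrors the library (`cbctomics simulate /
preprocess / train / segment / evaluate / extract / correlate / run-all`),
each subcommand taking `--config` (YAML) and `--seed`.

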