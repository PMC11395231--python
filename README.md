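# hybridscope

Enumeration and phenotyping of **circulating neoplastic–immune hybrid cells
(CHCs)** from multichannel immunofluorescence of peripheral-blood mononuclear
cells (PBMCs), for researchers developing liquid-biopsy biomarkers of
treatment response in solid tumors.

CHCs are peripheral-blood cells co-expressing an epithelial/tumor marker
(pan-cytokeratin, CK) and the pan-leukocyte marker CD45 — CK⁺/CD45⁺ — and are
detected at far higher frequency than conventional circulating tumor cells
(CTCs, CK⁺/CD45⁻). Their count per 50,000 PBMCs tracks treatment response:
it falls to zero after effective therapy and rebounds with resistance or
progression.

Because no raw patient imaging data are publicly deposited for this assay,
the package ships a first-class synthetic-data module that emulates the
assay's statistical structure (stained fields with an unstained-control
region, two-phenotype cell crops, longitudinal count trajectories), so every
stage is testable end to end.

## What the pipeline computes

1. **simgen** — synthetic fields (CK/CD45/DAPI channels + ground truth),
   labeled 64×64×3 cell crops (treatment-responsive: CD45-high/CK-low;
   treatment-resistant: CK-high/CD45-low, optionally punctate CK), and
   cohorts: patient baselines in 7.6–15.5 CHCs/50k PBMCs, decline to zero
   after treatment start, regime-specific rebounds of 2.0–49.6, healthy
   subjects at 0–1.67, zero CTCs throughout.
2. **segment** — DAPI-seeded nuclei (Gaussian smoothing → Otsu → distance
   transform → watershed) expanded to whole cells on the CK/CD45 projection;
   pluggable so a deep segmenter can be substituted.
3. **gate** — per-channel positivity thresholds at the 99.5th percentile of
   *unstained control-cell* mean intensities from the same slide; strict
   gating CK⁺/CD45⁺→CHC, CK⁺/CD45⁻→CTC, CK⁻/CD45⁺→leukocyte; counts
   normalized as `raw × 50000 / total_pbmcs`.
4. **cohort** — baseline patient-vs-healthy comparison with a
   **Mann–Whitney U test whose exact small-sample branch is implemented
   here** (full null distribution of the mid-rank sum via dynamic
   programming, used whenever n₁·n₂ ≤ 400); per-patient course
   classification (nadir / end-of-trial / post-trial status, interval
   increase); responsive/resistant phase labels for every detection.
5. **latent** — crop padding and per-sample median normalization, a
   **β-annealed convolutional VAE** (encoder filters 32/64/128/256/512,
   latent dimension 64, mirrored decoder; β ramped 0.001 → 2.0 in steps of
   0.001 per batch), posterior-mean embeddings, UMAP projection, and a
   phenotype-separation report (silhouette in the 64-d latent space plus
   CK/CD45 direction checks).

The training loss is the standard β-VAE objective
`L = ‖x − x̂‖² + β·KL(q(z|x) ‖ N(0, I))`, optimized with Adam
(batch 16, learning rate 5·10⁻⁴, early stopping, ≤100 epochs). The network
is implemented in numpy with explicit backpropagation (verified against
numerical gradients in the test suite), so the package has no deep-learning
framework dependency and trains desk-scale fixtures on one CPU in minutes.

## Worked example

```bash
hybridscope demo --out demo/ --seed 7
```

runs the whole pipeline on synthetic data. From a run with seed 7:

* `stats.json` — baseline comparison of 5 simulated patients (median
  baseline 12.0 CHCs/50k, range 9–14) against 15 healthy subjects (all
  ≤1.67): exact Mann–Whitney `U = 75`, `p = 0.000129`. With complete
  separation of 5 vs 15 this is the smallest achievable two-sided exact
  p-value, 2/C(20,5) = 2/15504.
* `course_summary.csv` — one row per patient, e.g.

  | subject | nadir | end of trial | post-trial | interval increase |
  |---------|-------|--------------|------------|-------------------|
  | P01 | undetectable | undetectable | increased | 39.0 |
  | P02 | undetectable | increased | not_available | 3.0 |
  | P03 | undetectable | undetectable | not_available | — |

  Every simulated patient reaches an undetectable nadir; rebounds appear
  only under the resistance/progression regimes, and the interval increase
  is the first positive count after the zero nadir.
* `phenotype_report.json` — after training the β-VAE on 200 two-phenotype
  crops (15 epochs), the phase labels separate in latent space with
  silhouette **0.409**, and the feature table reproduces the expected
  marker directions: mean normalized CK 2.49 in resistant vs 0.51 in
  responsive crops, mean normalized CD45 2.27 in responsive vs 0.40 in
  resistant.
* `embeddings.csv` — 64-d posterior means plus 2-d UMAP coordinates per
  crop; `manifest.json` records the seed so a rerun is byte-identical.

Stage-by-stage commands (`hybridscope simulate field|crops|cohort`,
`segment`, `gate`, `cohort`, `latent train|report`, `validate`) operate on
the documented TIFF/CSV/JSON dialects so stages can be rerun independently;
see `--help` on each.

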