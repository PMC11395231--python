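# Methods

This note documents the models, defaults and numerical choices behind
hybridscope, and what its synthetic benchmarks do and do not demonstrate.

## Assay model

The pipeline assumes slide-based immunofluorescence of PBMCs with three
channels in fixed order (CK, CD45, DAPI) and an annotated unstained-control
region on the same slide. Cell identity is defined purely by marker
co-expression relative to control-derived thresholds:

| call | CK | CD45 |
|------|----|------|
| CHC (hybrid) | + | + |
| CTC (tumor)  | + | − |
| leukocyte    | − | + |
| negative     | − | − |

Counts are reported per 50,000 PBMCs (`raw × 50000 / total_pbmcs`), where
"total PBMCs" is the number of segmented non-control cells in the sample.
Full precision is kept internally; 2-decimal rounding happens only at file
boundaries. "Undetectable" means a raw count of exactly 0 — counts are
integers scaled by a positive constant, so no epsilon is needed.

## Segmentation

Nuclei: Gaussian smoothing (`smoothing_sigma`, default 1.5 px) → Otsu
threshold → hole filling → removal of components below `min_area`
(default 20 px, debris cutoff) → Euclidean distance transform → peak seeds
(minimum separation 5 px) → watershed. Ties in watershed flooding resolve
by marker enumeration order, which is deterministic.

Whole cells: nucleus labels are expanded up to `max_expand_px` (default
8 px) into pixels above the membrane background on the pixelwise max of CK
and CD45. When the field carries a control region, the background level is
the 99.9th percentile of control-region membrane pixels; otherwise Otsu on
the projection. The control-referenced level matters: a global Otsu cut is
dominated by the brightest cells and strips dim cells back to their
nucleus, which both loses cytoplasm signal and — because gating compares
per-cell *means* — leaves small noisy masks whose channel means collide
with the control threshold. Coordinates are 0-based (row, col); bounding
boxes half-open; border-touching cells are kept and flagged. The segmenter
is a deliberately simple stand-in behind a narrow interface
(field → label image), so a learned segmenter can be plugged in without
touching the rest of the pipeline.

## Gating

Thresholds are per-channel percentiles (default 99.5) of the control
cells' mean intensities, computed by linear interpolation of the empirical
CDF (`interpolated_inverted_cdf`), so an arithmetic sequence 1..100 at
99.5 gives exactly 99.5. Positivity is strict (`mean > threshold`);
boundary ties are negative. A minimum of 30 control cells is enforced, but
the default synthetic fields plant 100: at a 99.5th-percentile rule, a
small control sample makes the threshold a noisy sample maximum rather
than a stable quantile, and false-positive hybrid calls on leukocytes
become seed lottery. With ~100 controls (nucleus-only masks) and analysis
masks systematically larger (cytoplasm included), the threshold sits
several noise standard errors above any negative cell's channel mean.
Whether intensities should be background-subtracted is left as
configuration; the default is no subtraction.

## Longitudinal analysis

Baseline is the last sample at or before treatment start (healthy
subjects: first sample). Course classification per patient: nadir is
undetectable iff any on-trial post-treatment sample is zero; end-of-trial
status reflects the last on-trial sample; post-trial status is evaluated
on samples after trial end (`not_available` when none). The interval
increase is the first positive count after the first zero, and its sample
time is the rebound time. Phase labels follow the definitions: positive
samples from treatment onset until the first zero are *responsive*,
positive samples after any zero are *resistant*, zero and strictly
pre-treatment samples carry no phase.

The Mann–Whitney U test is implemented in-package so the exact branch is
testable. For n₁·n₂ ≤ 400 the full permutation null of the rank sum (ties
handled by mid-ranks) is computed by subset-sum dynamic programming over
doubled mid-ranks — algebraically identical to enumerating all
C(n₁+n₂, n₁) group assignments, but polynomial-time, so the exact branch
covers the whole small-sample regime rather than only toy sizes. The
two-sided p is twice the smaller tail mass (tail masses include the
observed value), capped at 1. Above the cutoff, a normal approximation
with tie and continuity corrections is used, and the result records which
method produced it.

## Representation learning

Crops are 64×64×3 windows centered on cell centroids, zero-padded at field
borders, each channel divided by the sample's median per-cell mean
intensity on that channel (divisor floored at 10⁻⁶). This cancels
multiplicative illumination/staining differences between samples exactly,
which the tests verify by construction.

The autoencoder: five stride-2 3×3 convolutions with 32/64/128/256/512
filters (spatial 64→2), dense heads for the 64-d posterior mean and
log-variance, and a mirrored decoder of five stride-2 transposed
convolutions; ReLU activations, linear output. Loss is per-sample summed
squared error plus β times the KL divergence to a standard normal,
averaged over the batch. β follows a per-batch linear ramp: 0.001 at batch
0, +0.001 per batch, clamped at 2.0 thereafter (batch 0 uses the start
value). Optimization is Adam at 5·10⁻⁴ with batch size 16, a 10%
validation split, early stopping (patience 10, min-delta 0) restoring the
best-validation weights, and at most 100 epochs. All randomness —
initialization, shuffling, posterior sampling — derives from the config
seed, making runs bit-reproducible. The layers are implemented in numpy
with explicit backpropagation; the test suite pins them to central-
difference gradients in float64.

Inputs are standardized to unit variance inside `train_vae` (the divisor
is stored on the model and reapplied at encoding). Without this, the
summed reconstruction term on large-dynamic-range normalized crops dwarfs
the KL term, the β ramp never prunes nuisance dimensions, and the latent
geometry of a run depends strongly on initialization; with it, the two
loss terms are commensurate and class separation is stable across seeds.

Embeddings are posterior means. Separation is quantified by the silhouette
score of the phase labels in the full 64-d latent space — not in UMAP
coordinates, which are kept for visualization only (defaults: 15
neighbors, min_dist 0.1, seed 42) — alongside per-class means of
normalized CK/CD45/DAPI and area, with explicit direction flags
(CK higher in resistant, CD45 higher in responsive). Identical embeddings
are reported as degenerate rather than raising.

## Synthetic data: what it emulates, and what it does not

Fields render cells as isotropic Gaussian disks: nucleus on DAPI
(σ = radius/2), cytoplasm on marker channels at 1.6× the nuclear radius;
punctate CK is rendered as 3–6 small Gaussians (σ 2.5 px, ≥9 px apart)
inside the cytoplasm instead of a diffuse disk. Noise is additive
zero-clipped Gaussian (default σ 4 intensity units); positive-marker
amplitudes must exceed 5·noise_sd (enforced at config time), which
guarantees gating is exercised rather than fought. Placement is rejection
sampling with non-overlapping footprints (100 retries per cell, then a
placement error), so ground-truth counts are exact. The unstained-control
strip is sized to hold the requested control population and never exceeds
half the field.

Cohorts: patient baselines are integer raw counts whose normalization
lands in 7.6–15.5 per 50k; counts reach exactly zero within two
post-treatment samples (directly or via one intermediate value); the four
regimes then diverge — sustained response and long-term stability stay at
zero (the latter with post-trial samples), on-trial resistance rebounds at
the last on-trial sample, post-trial progression rebounds during
surveillance — with rebound magnitudes normalized into 2.0–49.6. Healthy
subjects are zero with probability 0.8, otherwise a single detected cell
at a sampling depth chosen so the normalized count falls in (0, 1.67]
(depth capped at 250k cells, since the sampling depth behind the published
healthy range is not knowable); tumor-cell counts are zero everywhere.
Sampling cadence is 28 days on trial and 56 days post-trial, with 6–7
on-trial samples — the cadence is a convenience, not a claim.

Not emulated: optical realism (PSF, vignetting, autofluorescence, spectral
bleed-through), cell doublets and overlaps, staining batch effects beyond
a global multiplicative factor, CA 19-9 kinetics, and real morphological
heterogeneity beyond size/brightness jitter and the punctate pattern.
Passing the synthetic benchmarks therefore demonstrates the *logic* of the
pipeline — threshold calibration, enumeration, trajectory classification,
representation learning — under the assay's assumed statistical structure,
not robustness to real-world imaging artifacts.

## Benchmark problem sizes

Test and acceptance fixtures are desk-scale by design: 448×448 px fields
with 30 leukocytes, 3 hybrid and 1 tumor cell (50–100 seeds per suite);
200 patients for regime recovery; 200+200 crops and ≤30 epochs for the
phenotype-separation run, using the full-size architecture. The
two-phenotype separation fixture uses diffuse rendering for both classes;
the punctate pattern is validated separately by connected-component
counts, because a punctate admixture intentionally makes the resistant
class bimodal and the silhouette would then measure multimodality rather
than the class contrast.

## Known limitations

* The watershed stand-in undersegments touching cells; the generator
  avoids overlaps, so benchmark recovery rates do not measure clumped
  specimens.
* Gating assumes the control region shares the field's noise
  characteristics; per-slide illumination gradients would break the single
  global threshold.
* The exact-test cutoff (n₁·n₂ ≤ 400) keeps study-scale comparisons exact;
  far larger cohorts fall back to the normal approximation.
* The β-VAE is trained per crop set; no transfer across marker panels or
  staining protocols is attempted.
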