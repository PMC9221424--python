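# Methods

This document describes the models and algorithms implemented in `liqbio`,
the parameter defaults and their rationale, and the known limitations of the
synthetic generator.

## 1. Channel-type ontology

Each event receives four positivity booleans — DAPI, CK, Vim, CD45/CD31 —
by comparing its median channel intensities against per-channel thresholds
(strict `>`; a value exactly at the threshold is negative). The 16
combinations map onto:

* **8 cellular (DAPI+) classes**: `epi.CTC` (DAPI|CK), `mes.CTC`
  (DAPI|CK|Vim), `CK|CD45/CD31`, `CK|Vim|CD45/CD31`, `Vim only`,
  `Vim|CD45/CD31`, `CD45/CD31 only`, `DAPI only`;
* **4 anucleated LEV (DAPI−, CK+) classes**: `LEV CK only`, `LEV CK|Vim`,
  `LEV CK|CD45/CD31`, `LEV CK|Vim|CD45/CD31`;
* everything DAPI− and CK− is `NOT_RARE`.

That yields exactly 12 rare categories. The common white blood cell
(DAPI+CD45/CD31+) shares a signature with the `CD45/CD31 only` rare class;
the enumeration layer therefore treats that category's count as
WBC-dominated and uses it as the denominator for blood-volume normalization
rather than reporting it as rare on its own. LEVs additionally carry a
proximity annotation — `cell_proximal` when the vesicle centroid lies
within 10 µm of a nucleated-cell centroid, else `free_floating` — and a
per-frame debris filter: a frame carrying more than 3 LEVs is treated as a
debris field and its LEVs are either dropped (`drop` mode, default) or
truncated to the cap (`cap` mode).

## 2. Synthetic generator

### 2.1 Intensities

Per-channel intensities are log-normal. Negative populations use
`mu = 4.0`, positive populations `mu = 6.7`, both with `sigma = 0.35` on
the log scale. The classification cutoff is the geometric midpoint
`exp((4.0 + 6.7)/2) ≈ 210.6`, which sits ≈ 3.9 population standard
deviations from each mode, so the populations are separable but not
degenerate: misclassification by intensity alone is possible in principle
(≈ 5 × 10⁻⁵ per channel) but never dominates.

### 2.2 Event tables and cohorts

`generate_event_table` draws category labels from a multinomial over the
mixture proportions, then draws the 8 features from per-category
distributions (cell radius ≈ 8 µm, nucleus ≈ 5 µm for cells; LEV radius
≈ 3 µm with nuclear area 0). `generate_cohort` draws per-sample,
per-category counts from a negative binomial (dispersion 1.5) around
cohort rate scales — tumor cellular events ≈ 170/mL vs donor ≈ 34/mL, and
tumor LEVs ≈ 8.3/mL vs donor ≈ 3.3/mL — times a blood volume derived from
a log-normal WBC count (median 6.65 × 10⁶/mL). Clinical covariates with a
planted monotone association to a chosen analyte are generated through a
Gaussian copula: the covariate's latent normal is correlated with the
analyte's latent at `rho_latent = 2 sin(pi * rho_s / 6)`, the standard
conversion making the *Spearman* correlation of the observed values equal
the target. Continuous, ordinal and binary covariate kinds are supported;
ordinal/binary values are produced by quantile-binning the latent.

### 2.3 Frame rendering

`generate_frames` renders each frame at 256 × 256 px, 1 µm/px by default:
a log-normal speckle background per channel, soft-edged disks for nuclei
and marker-positive cytoplasm, thin high-eccentricity bars as planted
artifacts, and optional debris frames carrying > 3 LEVs. Placement
enforces minimum separations so the planted truth is recoverable:

* cells keep ≥ (r_i + r_j + 4 px) between centers;
* every LEV keeps a clearance of (marker radius + LEV radius + 6 px) from
  **every** cell's marker disk, so a vesicle never fuses with a cytoplasm
  component, including that of a non-host neighbor;
* cell-proximal LEVs are placed in the annulus between the host cell
  boundary and 1.5 px inside the 10 µm proximity radius; free-floating
  LEVs stay > 4 px outside it — margins chosen so sub-pixel centroid error
  cannot flip the proximity annotation.

The truth table records per event: frame, class, kind, centroid,
proximity flag and debris-frame flag.

## 3. Detection

* **Nuclei** — the DAPI raster is log-transformed (`log1p`) and Otsu
  thresholding is applied in the log domain, which separates dim nuclei
  from a multiplicative (log-normal) background far more reliably than
  linear-domain Otsu. Connected components smaller than 10 µm² are
  discarded (a 3-σ-small nucleus is ≈ 20 µm², so the floor rejects specks
  without touching real nuclei).
* **Cell masks** — each nucleus is dilated by a 2.5 µm halo to capture
  cytoplasmic signal; median intensities for nucleated events are measured
  over the nucleus mask (the region guaranteed to carry the event's own
  signal rather than a neighbor's cytoplasm).
* **Anucleated candidates** — the CK raster is Gaussian-smoothed (σ = 1 px)
  and thresholded at background mean + 3 SD (background = everything
  outside the dilated nuclei). The binary is eroded by 1 px before
  labeling, which severs faint single-pixel bridges between nearby
  objects. A component is assigned to a cellular event — and therefore not
  an LEV candidate — only if its eroded interior overlaps a nucleus; a
  1-px boundary graze does not disqualify a vesicle. LEV intensity medians
  are taken over the twice-eroded core to avoid soft-edge dilution.
* **Artifact screen** — candidates with solidity < 0.7 or eccentricity
  > 0.95 are rejected. The eccentricity bound removes bar/crescent imaging
  artifacts; the solidity floor is set at 0.7 because the discrete
  solidity of a genuine ~3 px-radius eroded disk fluctuates down to
  ≈ 0.75.

All defaults are calibrated against the generator's rendering physics
(disk geometry, soft-edge width, background statistics), not against any
individual random draw; a 40-seed sweep at 8 frames × 60 cells recovers and
correctly classifies every planted event on every seed.

## 4. Enumeration

Blood volume analyzed = WBCs detected / clinical WBCs per mL; events/mL =
count / volume. Reported percentages use decimal half-up rounding (so
50.85 → 50.9, matching hand arithmetic rather than banker's rounding).
`proximity_split` reports the free-floating vs cell-proximal percentage of
LEVs; `cohort_summary` reports per-category median/min/max/mean rates and
prevalence (% of samples with ≥ 1 event).

## 5. Statistics

* **Rank-sum (Mann–Whitney)** — for m + n ≤ 20 without ties, the exact
  null distribution of U is built by the standard counting recurrence and
  the two-sided p-value is equal-tail: `P(U ≤ min(u, mn−u)) +
  P(U ≥ max(u, mn−u))`, clamped to 1 (the tails overlap when u = mn/2).
  With ties or larger samples, a tie-corrected normal approximation with
  continuity correction is used. The test suite verifies the exact branch
  against full enumeration of all group assignments for every m + n ≤ 10
  and the asymptotic branch against an independent implementation.
* **Spearman** — midranks, then Pearson on ranks. For n ≤ 9 without a
  degenerate (constant) margin the p-value is an exact permutation tail
  over all n! orderings; otherwise the t-approximation. Verified against a
  pure-Python permutation oracle at n ≤ 6, including ties.
* **Reporting rules** — significance at p ≤ 0.05; clinical correlations
  computed on a subgroup of fewer than 4 patients are suppressed;
  Benjamini–Hochberg correction is available but off by default (each
  test is reported marginally, matching the descriptive framing of the
  cohort comparison).
* **Ward clustering** — `scipy` Ward linkage on the standardized feature
  matrix; the merge history is verified against a brute-force greedy
  minimum-ΔSSE (ΔSSE = |A||B|/(|A|+|B|) · ‖c_A − c_B‖²) agglomerator for
  n ≤ 8.

## 6. Morphometrics

The feature matrix is events × 8 (cell area/eccentricity, nuclear
area/eccentricity, four median intensities), z-scored per column; constant
columns are dropped and recorded. LEVs are excluded from clustering
(nuclear features are degenerate for them). The 2-D embedding uses t-SNE
with perplexity clamped below (n − 1)/3; density profiles use a Gaussian
KDE per class and feature, with peak counts from local-maximum detection.

## 7. Scope and limitations

* The WBC/`CD45/CD31 only` signature degeneracy is inherent to a 4-channel
  assay; disambiguation would need morphology or additional markers.
* Planted artifact bars are the only artifact model; real scans show a
  broader artifact morphology spectrum.
* Intensity medians for cells are measured on the nucleus mask. For
  markers that are strictly cytoplasmic in reality this is a modeling
  simplification the generator mirrors (marker disks cover the nucleus).
* The generator plants at most one proximal LEV per host and does not
  model overlapping cells, out-of-focus planes, or illumination gradients.
* Problem sizes for exact statistics (enumeration at m + n ≤ 10 in tests,
  exact U for m + n ≤ 20 in the implementation, n! permutation at n ≤ 9)
  were chosen to keep the full suite under a few minutes while covering
  every branch of the exact/asymptotic switch.
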