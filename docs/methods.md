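# Methods

This note documents the models and procedures implemented in `sioi`, the
defaults and their rationale, what the synthetic generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Coordinate and data model

All coordinates are micrometres in image convention (origin top-left, y
increasing downward); distances are Euclidean, so results are invariant to
the y-direction convention. A patient contributes two serial sections: the
lymphocyte slide (CD3 on FITC, CD8 on Cy5, PCK on a third channel) and the
macrophage slide (CD68 on FITC, CD163 on Cy5, PCK). Cells enter as centroids
with per-compartment (nucleus/cytoplasm/membrane) channel intensities, or
with phenotype flags already assigned, so the pipeline can be entered at any
stage. Every tunable is a named field of `PipelineConfig` and is echoed into
the run report; no threshold is hard-coded in stage code.

## Cell phenotyping

A channel is called positive when a compartment intensity strictly exceeds
its threshold. Defaults (dimensionless dye intensities, identical for all
samples): lymphocyte slide nucleus FITC 0.15 / Cy5 0.132; macrophage slide
nucleus FITC 0.200 / Cy5 0.132; cytoplasm FITC 0.5 / Cy5 0.075; membrane
FITC 0.5 / Cy5 0.075. The *combination rule* across compartments is not a
published quantity; the default calls a channel positive when **any**
compartment exceeds its threshold, with "nucleus required" and
"cytoplasm AND membrane" selectable. Colocalized classes (CD3+CD8+,
CD68+CD163+) require both channels; CD68+ and CD163+ reporting totals both
include the colocalized class, while CD68+CD163− excludes it. Values exactly
at a threshold are negative — a deterministic tie rule on a probability-zero
boundary. Whole-slide PCK intensity dichotomizes tumors at 2.16 × 10⁻²
(strictly above = high). Pixel-level tumor/stroma classifiers are out of
scope: tumor geometry is an input polygon, or the union of 20-μm discs
around PCK+ centroids as a coordinate-level surrogate.

## Regions

From the tumor polygon and the invasive-front polyline: IM is the symmetric
two-sided buffer of the front at 500 μm, optionally clipped to a supplied
tissue extent (whether the outer band should be clipped to tissue or to the
scanned area is not specified upstream, so the clipping extent is an
argument); CT is tumor minus IM; IMCT their union; TBROI is
tumor ∩ buffer(front, 1000 μm), which realizes "1000 μm inward" without an
oriented polyline. Boundary points count as inside; areas are reported in
mm² to 6 decimals so density denominators are stable. area(IM ∩ tumor) +
area(CT) equals the tumor area to within 1e-6 relative.

## Tumor buds

Buds are detected by single-linkage clustering of **all** tumor-cell
centroids at a link distance of 15 μm (≈ one nucleus diameter plus margin;
the defining inter-nucleus distance is not published, so the parameter is
exposed and this default is a documented surrogate). Clustering over all
tumor cells means cells contiguous with the tumor mass join large
components; a connected component is a bud iff it has ≤ 4 cells **and** its
centroid lies in the TBROI. Pair distances exactly at the link distance are
linked. Detection is validated against a union-find oracle over the full
pairwise distance matrix and against planted clusters.

## Coregistration

Serial 3-μm sections are modelled as related by a similarity transform
(s·R + t). The landmark route is the closed-form least-squares
(orthogonal-Procrustes-with-scale) solution; the landmark-free route is ICP
on centroids (nearest-neighbor matching alternated with re-estimation),
whose matched-pair rmse never increases between iterations. `rmse_um` is the
root-mean-square **point distance** after mapping (so with isotropic
per-coordinate noise σ on n pairs the expected residual is
σ·√2·√(1 − 4/(2n))). ICP from a grossly wrong initialization can converge to
a wrong optimum; the residual is reported so this is visible. Deformable
registration is out of scope; results assume the similarity model.

## Feature catalog

Per patient: 6 phenotype classes × 3 regions densities (18), bud count (1),
CD68+/CD163+ ratios in 3 regions (3), 3 macrophage classes × 3 targets
(buds, CD3+, CD8+) × 2 radii (50, 100 μm) proximity means (18), and CD3+,
CD8+, CD3+CD8+ within 50 μm of buds (3) — 43 features. This is the closed
set implied by the published description; its realized length is logged
rather than forced to any particular count. Distance comparisons are
inclusive (≤ r). Proximity features are **means per target** (matching "the
average number of lymphocytes within 50 μm"), not slide totals. Conventions
for degenerate cases: zero area → density missing (never 0); zero targets →
proximity mean missing; CD68/CD163 ratio with zero CD163 density → +inf
(binarizes as ratio-high), both zero → missing. A patient with zero buds has
no bud-proximity measurement; the **zero-bud policy** (default `favorable`)
grants the favorable index flag because absent budding is the prognostically
good state — `missing` (exclude the patient) and `zero` are selectable. This
default is a package decision, prominently logged, not a published rule.

## Selection chain

Features are z-scored before the LASSO (penalty fairness); cutpoints are
computed on raw scales so cutoffs stay interpretable (cells/mm², counts,
ratios). Non-finite entries are made finite for the multivariate steps
(+inf capped at the column's finite maximum, missing imputed with the
column median, constants dropped), and every such repair is logged in the
selection trace.

1. **LASSO Cox** — `scikit-survival` coordinate-descent path (ℓ₁ ratio 1);
   λ chosen at minimum 10-fold cross-validated partial-likelihood deviance
   (Verweij–van Houwelingen: dev = −2·[pl(β; all) − pl(β; train)], Breslow
   ties inside the CV loop), with the one-standard-error rule selectable.
   Nonzero-coefficient features survive.
2. **Random forest Gini ranking** — a classification forest (500 trees) on
   the binary disease-specific-death label; censoring is not modelled at
   this step (the label's horizon is configurable, default full follow-up).
   Importance is the classic mean decrease Gini — the sum over trees of the
   bootstrap-weighted Gini impurity decrease at splits on the feature,
   divided by the number of trees — computed from tree internals rather
   than sklearn's normalized importances. Out-of-bag error is reported.
3. **Gini filter** at strictly > 3, then **correlation pruning**: greedy in
   descending Gini, a feature survives iff |Spearman r| < 0.8 with every
   already-kept feature (the published account states the rule but not the
   threshold; 0.8 is this package's default).
4. **Cutpoints** — maximally selected rank statistic: candidate cutoffs are
   midpoints of consecutive sorted unique values with both groups ≥ 10% of
   the cohort; the standardized two-group log-rank statistic is maximized;
   ties resolve to the smallest cutoff. The favorable side is the group
   with fewer deaths than expected (the higher Kaplan–Meier curve).
   Binarization uses strict inequalities; equality with a cutoff is
   unfavorable.
5. **Iterative refinement** — remove the component with the largest
   single-feature Cox p; if the combined index's criterion (default: Wald p
   of the ordinal favorable-count index; likelihood-ratio χ² selectable)
   worsens, undo and stop. Deterministic; the full removal sequence is
   recorded in the selection trace.

Cox models use Efron tie handling throughout (lifelines). Monotone
likelihood / separation is flagged on the fit rather than failing silently.
Forward-stepwise Cox enters predictors by likelihood-ratio p < 0.05 and
records the entry order.

## Synthetic cohorts

The spatial generator emulates: a rectangular tissue (default 2 × 2 mm, a
desk-scale stand-in for whole-slide extents) with a straight or sinusoidal
invasive front; immune cells as homogeneous Poisson or Thomas cluster
processes over the whole tissue (defaults: CD3-only 250, CD8-only 120,
CD3+CD8+ 120, CD68-only 90, CD163-only 160, CD68+CD163+ 70 cells/mm²,
lognormal between-patient heterogeneity with CV 0.5); the tumor mass as
dense Thomas "glands" (30 cells/parent, σ 20 μm, 400 cells/mm² overall) so
the mass forms components far larger than a bud; planted 1–4-cell buds
(Poisson rate 12/patient) inside the TBROI, kept ≥ 40 μm from mass cells so
detection is well-posed; optional extra lymphocytes in 50-μm discs around
buds (default 2 CD3+CD8+ per bud) planting the bud-proximity signal; a known
similarity transform (2°, (30, −20) μm) between slides; and intensities
drawn a margin above/below the classification thresholds with truncated
Gaussian noise, so noiseless intensities classify back to the planted
phenotypes exactly.

Survival is exponential with hazard h₀·exp(βᵀz), z the cohort-standardized
true feature vector (β is a log hazard ratio per s.d.), h₀ = 0.0012
events/month over a 141.6-month administrative horizon with 10% independent
uniform censoring — event frequencies on the order of a stage II colorectal
cohort. Default planted structure: CD3+ density in IMCT and bud-proximal
CD3+CD8+ lymphocytes protective (β = −0.7/s.d.), CD68+/CD163+ ratio in the
core hazardous (β = +0.7/s.d.). Constant baseline hazard means
proportionality holds exactly and closed-form checks are available. A
feature-level generator (`simulate_feature_cohort`) draws the feature table
directly from lognormal marginals at realistic scales (CD3 IMCT median ≈ 390
cells/mm², bud-proximal count ≈ 4, core ratio ≈ 1.1) for studies that stress
the statistical chain rather than geometry.

Not emulated: pixel images and segmentation error, autofluorescence,
intensity batch effects, correlated clinicopathological covariates,
non-proportional hazards, and tissue-scale heterogeneity beyond the planted
processes. Passing tests therefore demonstrate correctness of the
computational pipeline under the stated point-process and
proportional-hazards assumptions — not robustness to staining or
segmentation artifacts in real slides.

## Problem sizes used in tests and reproduction

The test suite uses the sizes its statistical claims need (e.g. 50
replicates at n = 300 for selection-chain and end-to-end recovery, 200
replicates at n = 1000 for Cox CI coverage) and smaller cohorts (12–20
patients) for end-to-end smoke and determinism checks; the reproduction
script simulates 113 training and 117 validation patients, matching typical
stage II cohort sizes.

## Known limitations

- Mean decrease Gini magnitudes scale with cohort size, so the fixed
  Gini > 3 filter keeps more features at n = 300 than at n ≈ 113 and can
  keep none at smoke scale (n ≈ 20); the threshold is configurable.
- The refinement criterion is in-sample: cutpoints maximize a selected
  statistic, so uninformative features that survive earlier stages can
  acquire overfit in-sample association and be retained, growing the index
  beyond three components and shrinking the all-favorable tier. With many
  candidate features this dilutes the 3-tier separation; a held-out or
  penalized criterion would be the natural extension.
- The bud detector's link distance is a surrogate for an unpublished
  merging rule; bud counts are comparable within a cohort processed with
  one setting, not across settings.
- The zero-bud policy and the compartment combination rule are documented
  package decisions where the published account is silent; both are
  configurable and logged.
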