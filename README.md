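# sioi — spatial immune profiling and the Spatial Immuno-Oncology Index

`sioi` is a Python library for spatial immune profiling of the tumor
microenvironment in multiplex-immunofluorescence slides, and for building the
**Spatial Immuno-Oncology Index (SIOI)** — a combinatorial prognostic
category for disease-specific survival in colorectal cancer.

It is written for computational pathologists and biostatisticians who have
per-cell exports from a slide scanner (centroids plus compartment dye
intensities on two coregistered serial sections — a CD3/CD8/PCK lymphocyte
slide and a CD68/CD163/PCK macrophage slide), tumor geometry (tumor polygon
and invasive-front polyline), and a cohort survival table.

## What it computes

**Spatial profiling.** Cells are phenotyped by fixed intensity thresholds
(e.g. nuclear FITC > 0.15 for CD3, nuclear Cy5 > 0.132 for CD8, nuclear FITC
> 0.200 for CD68); regions are built from the invasive front — the invasive
margin IM (±500 μm band), tumor core CT, their union IMCT, and the
tumor-budding region TBROI (1000 μm inward); tumor buds are connected
clusters of ≤ 4 tumor cells with centroid in the TBROI; the macrophage slide
is mapped into the lymphocyte frame by a least-squares similarity transform
(Procrustes on landmarks, optional ICP). The feature catalog per patient:
densities (cells/mm²) of CD3+, CD8+, CD3+CD8+, CD68+, CD163+, CD68+CD163−
in IM/CT/IMCT, the bud count, CD68+/CD163+ density ratios, and mean counts
of each macrophage class within 0–50 and 0–100 μm of buds, CD3+ and CD8+
cells, plus mean lymphocytes within 50 μm of buds — 43 features.

**Index construction.** On a training cohort, features are screened by a
LASSO-penalized Cox model (partial likelihood with an ℓ₁ penalty,
`λ` chosen by 10-fold cross-validated deviance), ranked by random-forest
mean decrease Gini on the death label (n = 500 trees), filtered at
Gini > 3, pruned so only the highest-Gini member of any highly correlated
pair survives, dichotomized at maximally selected log-rank cutpoints

&nbsp;&nbsp;&nbsp;&nbsp;`cut* = argmax_c |(O₁(c) − E₁(c)) / √V(c)|`

and iteratively refined by removing the least significant component until
removal worsens the index's Cox p-value. Patients with all components
favorable are "+/+/+" (low risk), exactly two "+/+/−", one or none
"+/−/− or −/−/−". Evaluation is by univariate/forward-stepwise Cox
(Efron ties) and Kaplan–Meier with log-rank tests, with optional censoring
horizons.

Because the clinical cohorts behind the published index are not publicly
deposited, the package ships a synthetic cohort generator (`sioi.synthetic`)
that plants known geometry, point patterns, buds, a known inter-slide
transform, and proportional-hazards survival with chosen log-hazard ratios —
every stage is testable against planted truth.

## Worked example

```bash
python examples/05_build_sioi.py
```

```
final components and cutoffs:
  CD3+ in IMCT                       above  324.462
  CD68+/CD163+ in CT                 below    1.664
  CD3+CD8+ within 0-50-um of TB      above    3.615
3-tier Cox HR per risk step: 3.58 (p=7e-20), log-rank p=3.3e-23
validation (cutoffs transferred unmodified): HR 2.61 (p=1.5e-13)
```

The chain recovered exactly the three planted prognostic features (CD3+
density in IMCT and bud-proximal CD3+CD8+ lymphocytes protective above their
cutoffs, the CD68+/CD163+ core ratio hazardous above its cutoff) from a
300-patient synthetic cohort with nuisance features. The hazard ratio of
3.58 per risk tier means each step from "+/+/+" toward "+/−/−" multiplies
the disease-specific death hazard by ~3.6; transferring the learned cutoffs
unmodified to an independent cohort keeps the index strongly prognostic.
The other examples (`examples/01…04`) walk through phenotyping, region/bud
geometry, slide coregistration and the feature table individually.

A thin CLI mirrors the stages for shell use:

```bash
sioi simulate --n-patients 20 --seed 5 --out cohort/
sioi run-all cohort/ --seed 11 --config my_config.yaml --out results/
```

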