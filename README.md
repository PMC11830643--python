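# valvemorph

Morphometric and macroevolutionary analysis of bivalve shell valves:
mesh-based shell volumetrics, substratum-use functional-group
classification, disparity rarefaction, and phylogenetically corrected
linear models with permutation ANOVA.

## The scientific problem

Two clades of heterodont bivalves differ in one key trait: the speciose
family **Veneridae** possesses siphons (fused mantle tubes that allow deep
infaunal life), while the three families of the **Archiheterodonta**
(Astartidae, Carditidae, Crassatellidae) lack them and must live at the
sediment–water interface. Comparing shell form across these clades asks
whether a single trait reshapes the morphological and ecological diversity
of a lineage. Three variables summarise each shell valve:

- **pSV** (proportional shell volume) — shell-material volume over
  shell-material plus internal volume, `pSV = TSV / (TSV + TIV)`, a proxy
  for investment in shell thickness and weight. Volumes are measured on
  watertight triangle meshes as the sum of signed tetrahedra,
  `V = (1/6) Σ v0 · (v1 × v2)`, and single-valve values are doubled for
  these equivalve taxa.
- **SL** (shell length, mm) — bounding-box extent along the
  anterior–posterior axis.
- **XS** (cross-sectional aspect ratio) — doubled valve half-width over
  shell height; 1 means as wide as tall.

Around these measurements the package provides:

- **Functional groups** — a burial-depth rule set assigns each specimen to
  one of six substratum-use categories (infaunal asiphonate,
  shallow/deep infaunal siphonate, borer, nestler, epifaunal): explicit
  habit annotations win; siphonate species under 50 mm are assumed shallow;
  otherwise the estimated siphon length (pallial-sinus depth fraction × SL)
  decides, with > 30 mm counting as deep.
- **Disparity rarefaction** — per family, the variance and cumulative
  range of a variable are subsampled without replacement at sizes from 5 to
  the full sample (1000 replicates; median and 2.5/97.5-percentile
  envelope), yielding the sample size at which two families' disparities
  become distinguishable and the size at which the range curve flattens.
- **Phylogenetic comparative statistics** — Brownian-motion covariance
  `C_ij = depth of MRCA(i, j)` from a time-calibrated tree; phylogenetic
  signal via Blomberg's K (expectation 1 under Brownian motion) and Pagel's
  λ (ML, likelihood-ratio test); GLS linear models with sequential type-I
  sums of squares and residual-randomization permutation ANOVA (RRPP):
  per term, reduced-model residuals are permuted to build the null
  distribution of F, with effect size Z measured on log F and
  `p ≥ 1/(n_perm + 1)`.
- **Synthetic data** — parametric valves (nested hemi-ellipsoids with
  analytic volumes), birth–death trees, Brownian traits, and a full
  four-family cohort emulating the study system, so the entire pipeline
  runs with no external downloads.

## Worked example

Measure a parametric valve with known ground truth:

```python
import valvemorph as vm
from valvemorph.synthdata import ShellParams, make_valve

params = ShellParams(a=20.0, b=12.0, c=9.0, thickness=2.0)  # mm
shell, interior = make_valve(params)
metrics = vm.compute_metrics(shell, interior)
print(f"analytic pSV: {params.analytic_pSV:.4f}")
print(f"measured pSV: {metrics.pSV:.4f}")
print(f"SL = {metrics.SL:.1f} mm, height = {metrics.height:.1f} mm, "
      f"width = {metrics.width:.1f} mm, XS = {metrics.XS:.3f}")
```

```
analytic pSV: 0.4167
measured pSV: 0.4167
SL = 40.0 mm, height = 24.0 mm, width = 18.0 mm, XS = 0.750
```

The measured pSV equals the analytic value `(abc − a′b′c′)/abc` because the
mesh volumetrics are exact for this geometry; SL is the full
anterior–posterior extent (2a), width the doubled valve half-width (2c).

Run the whole pipeline on a synthetic cohort from the command line:

```bash
valvemorph run --out-dir demo
```

This simulates a 250-species, four-family cohort with its phylogeny,
classifies every specimen (all six substratum groups are realised),
computes the Pearson correlation matrix of pSV/logSL/XS, rarefies variance
and range per family, and fits three phylogenetic RRPP ANOVAs. The output
directory holds `classified.csv`, `correlations.csv`, `curves.csv`,
`anova_*.csv`, `tree.nwk` and a `manifest.json` stamped with the config
hash and all seeds; rerunning with the same config reproduces every file
byte for byte. For example, the correlation matrix printed from
`correlations.csv`:

```
         pSV  logSL     XS
pSV    1.000 -0.178 -0.085
logSL -0.178  1.000 -0.193
XS    -0.085 -0.193  1.000
```

shows the weak trait correlations the cohort is designed to have, and the
last rows of the venerid pSV variance curve in `curves.csv`

```
    group variable   metric   n  median      lo      hi
Veneridae      pSV variance 125 0.00561 0.00534 0.00564
Veneridae      pSV variance 126 0.00559 0.00559 0.00559
```

pin the envelope to the full-sample variance at n = N, as rarefaction
without replacement must.

Other subcommands: `measure` (one valve from STL/OBJ/PLY meshes),
`classify`, `correlate`, `rarefy`, `pgls`, `simulate`; see
`valvemorph <cmd> --help`.

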