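# phantomgs

Additive vs. epistatic genomic prediction across marker densities, and the
*phantom epistasis* that connects them.

Genomic selection models predict phenotypes of genotyped accessions from a
genomic relationship matrix (GRM). Epistatic variants of these models —
built from interaction terms between markers — often out-predict the
additive standard on low-density marker panels, which is tempting to read
as evidence of functional gene interaction. `phantomgs` implements the
counter-argument end to end: when markers are in incomplete linkage
disequilibrium (LD) with unobserved additive causal loci, interaction terms
on the markers soak up purely *additive* causal variance, so the epistatic
advantage is an artifact of marker density that vanishes as panels densify.

The package is aimed at quantitative geneticists and breeders who want to
reproduce, probe, or extend this analysis on simulated or real inbred-line
panels (e.g. Arabidopsis or rice diversity collections).

## What it implements

For minor-allele indicators m_ik ∈ {0, 1} over fully homozygous lines:

* **Three GRMs**, each scaled to trace n —
  additive `G_ij ∝ Σ_k (m_ik − m̄_k)(m_jk − m̄_k)`,
  pairwise-epistatic `H_ij ∝ (Σ_k m_ik m_jk)²`, and Gaussian-kernel
  `K_ij ∝ exp(−‖m_i − m_j‖²/2h)` with h half (or a quarter of) the median
  squared Euclidean distance between genotype profiles — plus the explicit
  feature maps of their equivalent ridge regressions.
* **A variance-order decomposition**: Monte Carlo sampling of regression
  terms whose variance is split recursively into additive, pairwise, and
  higher-order shares (additive variance takes precedence, lower orders
  before higher).
* **Single-kernel mixed models** `y = Xβ + u + e`, `u ~ N(0, σ²ᵤ·GRM)`,
  fitted by exact spectral REML, with five fixed-effect sets for population
  structure (mean only, 1 or 5 principal components, 3 or 9 genomic
  clusters) and held-out BLUP prediction.
* **Replicated cross-validation** (10×10 by default) with predictive
  ability per test fold and 99% block-bootstrap confidence intervals for
  the epistatic-minus-additive contrasts rK − rG and rH − rG.
* **A founder-mosaic simulator** of inbred genotypes with distance-decaying
  LD, a rare-skewed allele-frequency spectrum and population substructure,
  plus purely additive traits (heritability 0.6) whose causal loci sit
  midway between panel markers — the construction that maximizes incomplete
  LD and makes phantom epistasis visible.

Genotypes are read from VCF (biallelic SNPs, homozygous calls) or a TSV
matrix; all outputs are TSV tables. See `docs/methods.md` for the models,
parameter defaults and their rationale.

## Worked example

Simulate a panel, decompose each kernel's implied genetic variance by
interaction order, and print a variance-components table:

```python
import numpy as np
from phantomgs import (MosaicConfig, simulate_genotypes, filter_maf,
                       thin_uniform, select_bandwidth, decompose_grm)

g = simulate_genotypes(MosaicConfig(n_lines=200, p_sites=8000,
                                    chrom_length_bp=4_000_000, seed=42))
gf = filter_maf(g, 0.01)                  # drop MAF < 1%: keeps 5075 of 8000
panel = thin_uniform(gf, 1000)            # ~10^3 uniformly spaced markers
h = select_bandwidth(panel)               # half median squared distance: 140.0

for kind, hh in [("G", None), ("H", None), ("K", h),
                 ("K", select_bandwidth(panel, 0.25))]:
    dec = decompose_grm(panel, kind, h=hh, n_samples=2000, seed=0)
    print(kind, np.round(dec.percents[:4], 1))
```

```
G [100.   0.   0.   0.]
H [50.3 49.7  0.   0. ]
K [62.8 30.2  6.5  0.5]
K [39.9 41.1 16.8  2. ]
```

Each row is the percent of that kernel's genetic variance at interaction
orders 1–4 (additive, pairwise, third-, fourth-order). The additive GRM is
100% additive by construction; H splits between additive and pairwise; the
Gaussian kernel concentrates at low orders at the default bandwidth, and
shifts toward higher orders when the bandwidth is halved (last row).

The headline experiment — does the epistatic accuracy gap shrink with
density on purely additive traits? — runs from a YAML config:

```bash
phantomgs cv --config examples/experiment.yaml --out run/
phantomgs report --run-dir run/
```

With the default simulator (500 lines, densities 10²/10³/10⁴, mean trait
accuracy pooled over five replicate traits), the contrast table shows the
signature pattern: `rK-rG` falls from +0.011 at 100 markers through +0.002
at 1,000 to −0.004 at 10,000, and `rH-rG` from +0.023 through +0.001 to
−0.010 — positive epistatic gaps at low density that vanish or reverse at
high density, although every causal effect is additive.

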