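# Methods

`phantomgs` studies how the predictive advantage of epistatic genomic models
over additive ones depends on marker density, and demonstrates — on purely
additive simulated traits — that this advantage can be entirely *apparent*
("phantom" epistasis): a consequence of incomplete linkage disequilibrium
(LD) between markers and unobserved additive causal loci, not of functional
gene interaction.

## Model

Phenotypes of n inbred accessions follow the single-kernel mixed model

    y = X beta + u + e,    u ~ N(0, sigma2_u K),    e ~ N(0, sigma2_e I),

where `K` is one of three genomic relationship matrices (GRMs) built from
minor-allele indicators m_ik in {0, 1} (inbred lines carry no heterozygotes):

* **G** (additive): G_ij ∝ Σ_k (m_ik − m̄_k)(m_jk − m̄_k);
* **H** (pairwise epistatic): H_ij ∝ (Σ_k m_ik m_jk)², the Hadamard square
  of the uncentered cross product;
* **K(h)** (Gaussian kernel): K_ij ∝ exp(−‖m_i − m_j‖² / 2h).

All GRMs are scaled to trace n, which fixes their proportionality constants.
Each GRM is the Gram matrix of an explicit ridge regression: centered
markers for G (interaction order 1), ordered pairwise products m_k m_l for H
(orders 1–2 after re-attribution, see below), and for K the exact Taylor
feature map

    phi_J(m) = exp(−‖m‖²/2h) (h^d d!)^(−1/2) Π_q m_{J_q}

over ordered d-tuples J, whose inner products reconstruct the kernel to
machine precision (a property the test suite checks by brute-force tuple
enumeration at p = 4, d ≤ 6).

### Bandwidth

`select_bandwidth` returns h = multiplier × median *squared* Euclidean
distance between genotype rows (multiplier 0.5 for the working kernel,
0.25 for the sharper variant). On the squared-distance scale the typical
kernel exponent is −d²/median(d²) ≈ −1 — the standard median heuristic — so
the kernel is informative at every panel density and its Taylor mass sits at
low interaction orders, with contributions above order four negligible for
the 0.5-multiplier kernel. A bandwidth on the plain distance scale would
drive the typical exponent to −median(d) (tens to hundreds for realistic
panels), collapsing K to near-identity and pushing the variance
decomposition to arbitrarily high orders; we therefore use the squared
scale.

## Variance-order decomposition

The contribution of a regression term X_J of degree d is split across
interaction orders by a recursion that gives additive variance precedence
over epistatic variance and lower orders precedence over higher ones: for
n = d, …, 1 the current term is regressed (ordinary least squares; fitted
values are unique even on the rank-deficient monomial designs that binary
markers force) on all monomials of the involved markers of total degree
≤ n − 1; the residual variance (population divisor n) is booked as the
order-n contribution and the fitted value replaces the term. On binary
markers m² = m, so monomials are deduplicated to products over distinct
subsets.

Whole-kernel decompositions average these contributions over uniformly
sampled tuples — single indices for G, ordered pairs (diagonal included) for
H, ordered d-tuples with repetition for d = 1…6 for K — with per-length
means weighted by p^d, the count of ordered d-tuples, matching the expansion
measure of the feature map. 10^4 samples per length give estimates stable to
well under half a percentage point per order on ~10^3-marker panels. For G
the result is analytic: a centered marker regressed on a constant is left
intact, so the additive share is exactly 100% regardless of the genotypes —
this is the package's sharpest internal consistency check.

## REML and held-out prediction

With a single random effect the restricted likelihood is profiled exactly on
the variance ratio λ = sigma2_u/sigma2_e after one eigendecomposition of the
GRM: for fixed λ the GLS coefficients, residual variance and restricted
log-likelihood are closed-form in the eigenbasis. A bounded scalar search
over ln λ ∈ [−10, 10] (tolerance 1e−8, endpoints checked) locates the
optimum. The reported log-likelihood includes all constants of the
restricted likelihood (Harville's form, with the +½log|XᵀX| term), and the
tests verify it against a dense-matrix evaluation of the same formula.

Held-out accessions are predicted by the conditional-expectation rule
u_test = K[test,train](K[train,train] + δI)^(−1)(y_train − X_train β) with
δ = sigma2_e/sigma2_u, variance components re-estimated within every
training fold. This coincides with solving Henderson's mixed-model
equations with the test phenotypes masked, which the tests verify on a
full-rank 30-accession Gaussian-kernel fixture to 1e−8 relative error.

Fixed-effect sets: a global mean (mu); the first one or five principal
components of the full-marker additive GRM (PC1, PC5); and k-means
clusterings of the 10 leading PCs into 3 or 9 groups (CL3, CL9; 25 restarts,
fixed seed), entered as one-hot columns with the first cluster absorbed into
the intercept. PCs are computed from the full marker set, not per panel,
since they model population structure.

## Synthetic data

The genotype generator is a founder-mosaic model chosen over a coalescent
simulator because it exposes the three features the argument needs as direct
knobs:

* **Founder haplotypes** are latent Gaussian AR(1) chains thresholded at
  per-site quantiles. The AR coefficient at the mean inter-site gap is
  `founder_allele_corr` (default 0.99) and decays geometrically with
  physical distance, giving a population LD decay scale of roughly 30 kb.
  Site minor-allele probabilities are 0.5·Beta(`sfs_shape`, 1) (default
  0.35), a rare-skewed site-frequency spectrum like that of re-sequencing
  panels; with a common-allele spectrum the Gaussian kernel's variance would
  sit at unrealistically high interaction orders.
* **Lines** are mosaics of founder segments with Poisson breakpoints at
  `switch_rate` per bp (default 3e−6, mean segment ≈ 333 kb, ≈ 30 segments
  per line on the default 10 Mb chromosome). Few, long segments give the
  heterogeneous, family-like kinship of structured selfing collections;
  with many short segments kinship homogenizes and no model differences
  remain to detect.
* **Structure** comes from `n_subpops` (default 3) disjoint founder pools
  (default 30 founders).

Defaults (500 lines, 3×10^4 sites on 10^7 bp) define the study conditions.
With them, adjacent-marker |r| rises from ≈ 0.1 (90th quantile ≈ 0.25) on a
100-marker panel to ≈ 0.9 on a 10^4-marker panel — the density–LD gradient
on which the phantom-epistasis mechanism rests.

What the simulator does *not* emulate: multiple chromosomes, crossover
interference, mutation/selection history, genotyping error, and any
non-additive trait architecture (the point of the exercise is a purely
additive truth). Passing tests therefore demonstrate the statistical
mechanism — apparent epistasis from incomplete LD — not a calibrated
reproduction of any particular species' data.

**Traits.** Causal loci are the polymorphic sites (of the full, pre-filter
site set — the stand-in for sequence data) nearest the physical midpoint of
every pair of consecutive markers of a 1,000-marker anchor panel, ties going
to the lower position: 999 loci on one chromosome, each maximally distant in
LD terms from the genotyped markers. Effects are iid standard normal, the
genetic value is the sum of causal contributions, and the noise variance is
set from the realized sample variance of the genetic values so the expected
realized heritability equals the 0.6 target (calibrating on realized rather
than expected variance keeps the expectation exact for every draw of
effects). Replicate traits redraw effects and noise on the same loci.
Causal positions are removed from the filtered matrix before any panel is
thinned, so no analysis panel contains a causal locus.

## Evaluation

Panels of requested densities are thinned uniformly over physical position
(per-chromosome allotment proportional to physical span, nearest-marker
snapping, ties to the lower position) after removing markers with minor
allele frequency below 1%. Accuracy is the Pearson correlation between
predictions and observed phenotypes per held-out test set of a replicated
k-fold cross-validation (every accession tested exactly once per replicate;
fold sizes differ by at most one). Epistatic-minus-additive contrasts
(rK − rG, rH − rG) are summarized by the mean over fold-level paired
differences with a 99% percentile bootstrap interval that resamples whole
test sets as blocks (default 10^4 draws), plus the share of folds,
replicates and traits where the epistatic model wins (ties count as losses).
Per-fold correlations are averaged rather than pooling predictions, because
the block bootstrap operates on fold-level statistics. A constant observed
or predicted vector in a fold yields NaN with a warning and the fold is
excluded from the contrast.

## Problem sizes and reproducibility

The shipped experiment configuration runs 500 lines at densities
10²/10³/10⁴ with five replicate traits and 5×5 cross-validation — large
enough for the density pattern of the epistatic gap to be resolved, small
enough to run on a laptop in minutes. At this downscale the H − G gap
(≈ +0.02 at density 10²) is of the same order as its Monte Carlo error, so
individual seeds can blur it; the shipped seed resolves the full pattern.
All randomness flows from one master seed through named substreams
(simulation, traits, CV plan, bootstrap, clustering), so every stage is
independently reproducible and re-running a configuration reproduces its
output tables byte-for-byte.

## Known limitations

* Single chromosome per simulated genome (the analysis code itself handles
  multi-chromosome panels read from VCF or TSV).
* The order decomposition, like its relatives, ignores genome-wide
  higher-order LD among panel markers; its percentages describe the kernel's
  equivalent regression, not the causal architecture.
* Only single-kernel models are fitted; two-kernel models (G + H jointly)
  and multi-kernel bandwidth mixtures are out of scope.
* No missing-genotype handling: heterozygous or missing calls are rejected,
  never imputed.
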