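"""Simulate inbred genotypes with distance-decaying LD and purely additive traits.

The genotype generator is a founder-mosaic model: a small pool of founder
haplotypes is drawn as a correlated allele chain along the chromosome (so
that LD decays with physical distance), and each line is a mosaic of founder
segments with Poisson-distributed breakpoints.  Assigning lines to disjoint
founder pools induces population substructure.  Founder alleles come from a
latent Gaussian AR(1) process thresholded at site-specific quantiles, so the
site-frequency spectrum is skewed towards rare minor alleles as in
re-sequencing panels.  This reproduces the features the analysis needs —
homozygous biallelic genotypes, LD that decays in physical distance, a
rare-skewed allele-frequency spectrum, and structured relatedness — with a
handful of interpretable knobs and no external simulator.

The trait generator places additive causal loci at existing polymorphisms
nearest the physical midpoint between consecutive markers of an anchor
panel, so that every causal locus is in incomplete LD with the genotyped
markers; the phenotype is the sum of causal contributions plus independent
Gaussian noise calibrated to a target heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geno_io import MarkerMatrix, MarkerPanel, _chrom_blocks, orient_minor

__all__ = [
    "MosaicConfig",
    "SimulatedTrait",
    "simulate_genotypes",
    "place_causal_midpoints",
    "simulate_additive_trait",
    "write_trait",
]


@dataclass
class MosaicConfig:
    """Knobs of the founder-mosaic genotype simulator.

    Parameters
    ----------
    n_lines : number of inbred lines (rows).
    n_founders : number of founder haplotypes; small pools mean high
        background relatedness.
    p_sites : number of biallelic sites along the chromosome.
    chrom_length_bp : physical chromosome length in base pairs.
    switch_rate : expected founder switches per bp along a line; its inverse
        is the mean mosaic segment length.
    founder_allele_corr : latent AR(1) correlation between founder alleles
        at adjacent sites separated by the mean inter-site gap;
        along-chromosome correlation decays geometrically with distance.
    n_subpops : founder pools / subpopulations inducing structure.
    sfs_shape : shape a of the Beta(a, 1) site-frequency spectrum; per-site
        minor-allele probabilities are 0.5 x Beta(a, 1), so values < 1 skew
        the spectrum towards rare variants (1 = uniform over [0, 0.5]).
    seed : RNG seed; the generator is deterministic under it.
    """

    n_lines: int = 500
    n_founders: int = 30
    p_sites: int = 30_000
    chrom_length_bp: int = 10_000_000
    switch_rate: float = 3e-6
    founder_allele_corr: float = 0.99
    n_subpops: int = 3
    sfs_shape: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be > 0")
        if not 0 <= self.founder_allele_corr < 1:
            raise ValueError("founder_allele_corr must be in [0, 1)")
        if self.n_subpops < 1 or self.n_subpops > self.n_founders:
            raise ValueError("n_subpops must be in [1, n_founders]")
        if self.p_sites < 2 or self.p_sites > self.chrom_length_bp:
            raise ValueError("p_sites must be in [2, chrom_length_bp]")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.sfs_shape <= 0:
            raise ValueError("sfs_shape must be > 0")


@dataclass
class SimulatedTrait:
    """A purely additive trait with its hidden causal architecture."""

    phenotypes: np.ndarray
    accession_ids: np.ndarray
    causal_idx: np.ndarray      # column indices into the source MarkerMatrix
    causal_chrom: np.ndarray
    causal_pos: np.ndarray
    causal_geno: np.ndarray     # n x q minor-allele indicators at causal loci
    effects: np.ndarray
    genetic_values: np.ndarray
    h2_target: float
    realized_h2: float


def simulate_genotypes(cfg: MosaicConfig) -> MarkerMatrix:
    """Draw an inbred genotype matrix from the founder-mosaic model."""
    rng = np.random.default_rng(cfg.seed)
    L, p, nf = cfg.chrom_length_bp, cfg.p_sites, cfg.n_founders

    pos = np.sort(rng.choice(L, size=p, replace=False)) + 1  # 1-based, unique

    # Founder haplotypes: a latent Gaussian AR(1) chain per founder,
    # thresholded at site-specific quantiles.  The AR coefficient decays
    # geometrically in the physical gap (scale = mean inter-site gap), so
    # allele correlation decays with distance; the thresholds draw the
    # per-site allele probability from a rare-skewed Beta spectrum.
    from scipy.stats import norm

    mean_gap = L / p
    a = cfg.founder_allele_corr ** (np.diff(pos) / mean_gap)
    noise_sd = np.sqrt(1.0 - a**2)
    z = np.empty((nf, p))
    z[:, 0] = rng.standard_normal(nf)
    eps = rng.standard_normal((nf, p - 1))
    for k in range(1, p):
        z[:, k] = a[k - 1] * z[:, k - 1] + noise_sd[k - 1] * eps[:, k - 1]
    site_freq = 0.5 * rng.beta(cfg.sfs_shape, 1.0, size=p)
    F = (z < norm.ppf(site_freq)).astype(np.int8)

    pools = np.array_split(np.arange(nf), cfg.n_subpops)
    values = np.empty((cfg.n_lines, p), dtype=np.int8)
    site = np.arange(p)
    for i in range(cfg.n_lines):
        pool = pools[i % cfg.n_subpops]
        n_breaks = rng.poisson(cfg.switch_rate * L)
        breaks = np.sort(rng.integers(1, L + 1, size=n_breaks))
        seg_founder = rng.choice(pool, size=n_breaks + 1)
        values[i] = F[seg_founder[np.searchsorted(breaks, pos)], site]

    ids = np.array(
        [f"S{i % cfg.n_subpops}_L{i:04d}" for i in range(cfg.n_lines)], dtype=object
    )
    chrom = np.full(p, "1")
    return MarkerMatrix(orient_minor(values), ids, chrom, pos)


def place_causal_midpoints(g: MarkerMatrix, panel: MarkerPanel) -> np.ndarray:
    """Column indices in ``g`` of the polymorphic site nearest each inter-marker midpoint.

    For every within-chromosome pair of consecutive panel markers, the
    polymorphic site of ``g`` strictly between them that lies closest to the
    physical midpoint is selected (ties towards the lower position).  On a
    single chromosome a panel of size m yields m - 1 causal positions.
    """
    if panel.source is not g:
        own = set(zip(map(str, g.chrom), g.pos.tolist()))
        if not all((str(c), int(p)) in own for c, p in zip(panel.chrom, panel.pos)):
            raise ValueError("panel markers must be drawn from the genotype matrix")
    causal: list[int] = []
    empty_gaps: list[str] = []
    g_blocks = {label: (s, e) for label, s, e in _chrom_blocks(g.chrom)}
    for label, s, e in _chrom_blocks(panel.chrom):
        if e - s < 2:
            continue
        gs, ge = g_blocks[label]
        poly = np.flatnonzero(g.maf[gs:ge] > 0) + gs
        cand_pos = g.pos[poly]
        ppos = panel.pos[s:e]
        for a, b in zip(ppos[:-1], ppos[1:]):
            lo = np.searchsorted(cand_pos, a, side="right")
            hi = np.searchsorted(cand_pos, b, side="left")
            if lo >= hi:
                empty_gaps.append(f"{label}:{a}-{b}")
                continue
            mid = (a + b) / 2.0
            seg = cand_pos[lo:hi]
            k = int(np.argmin(np.abs(seg - mid)))  # first minimum = lower position
            causal.append(int(poly[lo + k]))
    if empty_gaps:
        raise ValueError(
            "no polymorphic site inside inter-marker gap(s): " + ", ".join(empty_gaps[:10])
        )
    return np.asarray(causal, dtype=np.intp)


def simulate_additive_trait(
    g: MarkerMatrix, causal_idx: np.ndarray, h2: float, seed: int
) -> SimulatedTrait:
    """Draw iid Gaussian effects at the causal loci and a noise-calibrated phenotype.

    The noise variance is set from the realized sample variance of the genetic
    values so that var(g) / (var(g) + var(e)) equals ``h2`` in expectation.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    causal_idx = np.asarray(causal_idx, dtype=np.intp)
    if causal_idx.size == 0:
        raise ValueError("need at least one causal locus")
    if causal_idx.min() < 0 or causal_idx.max() >= g.n_markers:
        raise ValueError("causal indices out of range")
    rng = np.random.default_rng(seed)
    C = g.values[:, causal_idx].astype(float)
    effects = rng.standard_normal(causal_idx.size)
    gvals = C @ effects
    var_g = float(gvals.var())
    if var_g <= 0:
        raise ValueError("genetic variance is zero (all causal loci monomorphic)")
    sigma2_e = var_g * (1.0 - h2) / h2
    phen = gvals + rng.normal(0.0, np.sqrt(sigma2_e), size=g.n_accessions)
    return SimulatedTrait(
        phenotypes=phen,
        accession_ids=g.accession_ids,
        causal_idx=causal_idx,
        causal_chrom=g.chrom[causal_idx],
        causal_pos=g.pos[causal_idx],
        causal_geno=g.values[:, causal_idx].copy(),
        effects=effects,
        genetic_values=gvals,
        h2_target=h2,
        realized_h2=var_g / float(phen.var()),
    )


def write_trait(trait: SimulatedTrait, path, sidecar_path=None) -> None:
    """Write phenotypes as TSV (accession, phenotype); optionally the causal sidecar."""
    import pandas as pd

    pd.DataFrame(
        {"accession": trait.accession_ids, "phenotype": trait.phenotypes}
    ).to_csv(path, sep="\t", index=False)
    if sidecar_path is not None:
        pd.DataFrame(
            {
                "chrom": trait.causal_chrom,
                "pos": trait.causal_pos,
                "effect": trait.effects,
            }
        ).to_csv(sidecar_path, sep="\t", index=False)
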