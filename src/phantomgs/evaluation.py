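"""Replicated cross-validation, predictive ability, and bootstrap contrasts.

Predictive ability is the Pearson correlation between predictions and
observed phenotypes over each held-out test set; a model configuration's
accuracy is the mean over all fold-level test sets.  Epistatic-minus-additive
contrasts (rK - rG, rH - rG) are summarized with percentile bootstrap
confidence intervals obtained by resampling whole test sets as blocks,
paired across models, plus the share of folds / replicates / traits where
the epistatic model wins.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import grm as grm_mod
from .geno_io import MarkerMatrix, adjacent_ld, filter_maf, thin_uniform
from .mixed_model import _eigh_psd, make_fixed_effects, predict_heldout
from .synthetic_data import (
    MosaicConfig,
    place_causal_midpoints,
    simulate_additive_trait,
    simulate_genotypes,
)

__all__ = [
    "CVPlan",
    "ContrastCI",
    "ExperimentResult",
    "make_cv_plan",
    "predictive_ability",
    "bootstrap_contrast",
    "run_experiment",
]

logger = logging.getLogger("phantomgs")

EPISTATIC_CONTRASTS = (("K", "G"), ("H", "G"))


@dataclass
class CVPlan:
    """Fold assignments for an n_replicates x n_folds cross-validation."""

    n_folds: int
    n_replicates: int
    assignments: np.ndarray  # (n_replicates, n) fold id per accession
    seed: int

    @property
    def n_accessions(self) -> int:
        return self.assignments.shape[1]


def make_cv_plan(n_accessions: int, n_folds: int = 10, n_replicates: int = 10,
                 seed: int = 0) -> CVPlan:
    """Independent balanced random partitions per replicate, deterministic under seed."""
    if n_folds > n_accessions:
        raise ValueError("n_folds cannot exceed the number of accessions")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.empty((n_replicates, n_accessions), dtype=np.int64)
    for rep in range(n_replicates):
        perm = rng.permutation(n_accessions)
        assignments[rep, perm] = np.arange(n_accessions) % n_folds
    return CVPlan(n_folds, n_replicates, assignments, seed)


def predictive_ability(observed, predicted) -> float:
    """Pearson correlation over one test set; NaN (with a warning) if degenerate."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 3:
        raise ValueError("need at least 3 pairs for a predictive ability")
    if observed.std() == 0 or predicted.std() == 0:
        warnings.warn("constant vector in test set; predictive ability undefined")
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1])


@dataclass
class ContrastCI:
    """Block-bootstrap summary of a paired accuracy contrast."""

    contrast: str
    mean_diff: float
    ci_low: float
    ci_high: float
    level: float
    pct_folds: float
    pct_replicates: float | None = None
    pct_traits: float | None = None


def bootstrap_contrast(
    table_a: pd.Series,
    table_b: pd.Series,
    level: float = 0.99,
    n_boot: int = 10_000,
    seed: int = 0,
    contrast: str = "",
) -> ContrastCI:
    """Percentile bootstrap CI for the mean paired fold-level difference a - b.

    The two tables must share an identical index (same CV plan); fold-level
    test sets are the resampling blocks.  Alongside the CI, reports the share
    of folds, of replicates, and of traits where a exceeds b (ties counted as
    not-greater); the latter two require 'replicate' / 'trait' index levels.
    """
    if not table_a.index.equals(table_b.index):
        raise ValueError("contrast tables are not paired (indexes differ)")
    both = pd.DataFrame({"a": table_a, "b": table_b}).dropna()
    d = (both["a"] - both["b"]).to_numpy()
    if d.size == 0:
        raise ValueError("no paired fold-level values to contrast")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    means = d[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    ci_low, ci_high = np.quantile(means, [alpha, 1.0 - alpha])
    pct_folds = 100.0 * float((both["a"] > both["b"]).mean())

    def _pct_grouped(levels):
        if not set(levels) <= set(both.index.names):
            return None
        m = both.groupby(level=list(levels), sort=False).mean()
        return 100.0 * float((m["a"] > m["b"]).mean())

    names = [n for n in both.index.names if n is not None]
    pct_reps = _pct_grouped([n for n in ("trait", "replicate") if n in names]) \
        if "replicate" in names else None
    pct_traits = _pct_grouped(["trait"]) if "trait" in names else None
    return ContrastCI(
        contrast=contrast,
        mean_diff=float(d.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        level=level,
        pct_folds=pct_folds,
        pct_replicates=pct_reps,
        pct_traits=pct_traits,
    )


@dataclass
class ExperimentResult:
    """Outputs of a full factorial density x kernel x fixed-effect sweep."""

    accuracy: pd.DataFrame            # fold-level predictive abilities
    contrasts: pd.DataFrame           # bootstrap contrast summaries
    ld_profiles: dict                 # density -> LDProfile
    bandwidths: dict                  # density -> h used by K
    realized_h2: list[float]
    n_causal: int
    failures: list = field(default_factory=list)

    def accuracy_series(self, density, kind, fx) -> pd.Series:
        sub = self.accuracy.query(
            "density == @density and kind == @kind and fx == @fx"
        )
        return sub.set_index(["trait", "replicate", "fold"])["r"].sort_index()


def _stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Named substream seeds derived deterministically from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def prepare_study(genotypes: MarkerMatrix, cfg, trait_seed: int):
    """MAF-filter, anchor the causal loci, simulate traits, and mask causal columns.

    Causal candidates come from the full pre-filter polymorphic site set (the
    stand-in for sequence data); the analysis matrix is the MAF-filtered
    panel with every causal position removed, so no analysis panel can
    contain a causal locus.
    """
    g_f = filter_maf(genotypes, cfg.maf_threshold)
    logger.info("MAF filter kept %d of %d markers", g_f.n_markers, genotypes.n_markers)
    anchor = thin_uniform(g_f, cfg.causal_anchor_density)
    causal = place_causal_midpoints(genotypes, anchor)
    traits = [
        simulate_additive_trait(genotypes, causal, cfg.h2, seed=trait_seed + t)
        for t in range(cfg.n_traits)
    ]
    causal_keys = set(
        zip(map(str, genotypes.chrom[causal]), genotypes.pos[causal].tolist())
    )
    keep = [
        j for j in range(g_f.n_markers)
        if (str(g_f.chrom[j]), int(g_f.pos[j])) not in causal_keys
    ]
    analysis = g_f.subset(np.asarray(keep, dtype=np.intp))
    return g_f, analysis, causal, traits


def run_experiment(cfg, genotypes: MarkerMatrix | None = None) -> ExperimentResult:
    """Simulate (or take) genotypes, build panels/GRMs, run replicated CV, contrast.

    ``cfg`` is an :class:`phantomgs.config.ExperimentConfig`.  Any failing
    factorial cell is recorded in ``failures`` and the sweep continues.
    """
    (s_sim, s_trait, s_cv, s_boot, s_fx, *_ ) = _stage_seeds(cfg.master_seed)

    if genotypes is None:
        mosaic = MosaicConfig(**cfg.simulator, seed=s_sim)
        logger.info("simulating %d lines x %d sites", mosaic.n_lines, mosaic.p_sites)
        genotypes = simulate_genotypes(mosaic)
    g_f, analysis, causal, traits = prepare_study(genotypes, cfg, s_trait)
    n = analysis.n_accessions

    grm_full = grm_mod.build_G(analysis)
    fx_map = {
        label: make_fixed_effects(analysis, label, seed=s_fx, grm=grm_full)
        for label in cfg.fixed_effects
    }
    plan = make_cv_plan(n, cfg.cv_folds, cfg.cv_replicates, seed=s_cv)

    rows, failures = [], []
    ld_profiles, bandwidths = {}, {}
    for density in cfg.densities:
        panel = thin_uniform(analysis, density)
        ld_profiles[density] = adjacent_ld(panel)
        kernels = {}
        for kind in cfg.kinds:
            if kind == "K":
                h = grm_mod.select_bandwidth(panel)
                bandwidths[density] = h
                kernels[kind] = grm_mod.build_K(panel, h)
            elif kind == "G":
                kernels[kind] = grm_mod.build_G(panel)
            else:
                kernels[kind] = grm_mod.build_H(panel)
        for kind, kern in kernels.items():
            t0 = time.perf_counter()
            for rep in range(plan.n_replicates):
                for fold in range(plan.n_folds):
                    test = plan.assignments[rep] == fold
                    train = ~test
                    tr_idx = np.flatnonzero(train)
                    te_idx = np.flatnonzero(test)
                    eig = _eigh_psd(kern.values[np.ix_(tr_idx, tr_idx)])
                    for fx_label, fx in fx_map.items():
                        for t, trait in enumerate(traits):
                            try:
                                pred, _ = predict_heldout(
                                    trait.phenotypes, fx, kern, tr_idx, te_idx, eig=eig
                                )
                                r = predictive_ability(trait.phenotypes[te_idx], pred)
                            except Exception as exc:  # record and continue the sweep
                                failures.append(
                                    dict(density=density, kind=kind, fx=fx_label,
                                         trait=t, replicate=rep, fold=fold,
                                         error=repr(exc))
                                )
                                continue
                            rows.append(
                                dict(trait=t, density=density, kind=kind, fx=fx_label,
                                     replicate=rep, fold=fold, n_test=te_idx.size, r=r)
                            )
            logger.info(
                "density %d kind %s: %d fits in %.1fs",
                density, kind,
                plan.n_replicates * plan.n_folds * len(fx_map) * len(traits),
                time.perf_counter() - t0,
            )

    accuracy = pd.DataFrame(rows)
    result = ExperimentResult(
        accuracy=accuracy,
        contrasts=pd.DataFrame(),
        ld_profiles=ld_profiles,
        bandwidths=bandwidths,
        realized_h2=[t.realized_h2 for t in traits],
        n_causal=int(causal.size),
        failures=failures,
    )
    crows = []
    for density in cfg.densities:
        for fx_label in cfg.fixed_effects:
            for epi, add in EPISTATIC_CONTRASTS:
                if epi not in cfg.kinds or add not in cfg.kinds:
                    continue
                ci = bootstrap_contrast(
                    result.accuracy_series(density, epi, fx_label),
                    result.accuracy_series(density, add, fx_label),
                    level=0.99,
                    n_boot=cfg.n_boot,
                    seed=s_boot,
                    contrast=f"r{epi}-r{add}",
                )
                crows.append(
                    dict(density=density, fx=fx_label, contrast=ci.contrast,
                         mean_diff=ci.mean_diff, ci_low=ci.ci_low, ci_high=ci.ci_high,
                         pct_folds=ci.pct_folds, pct_replicates=ci.pct_replicates,
                         pct_traits=ci.pct_traits)
                )
    result.contrasts = pd.DataFrame(crows)
    return result
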