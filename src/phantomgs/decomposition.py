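"""Partition each kernel's implied genetic variance into interaction orders.

A regression term of degree d (a monomial in d marker indicators, possibly
with the Gaussian-feature prefactor) is decomposed recursively: the term is
regressed on all monomials of the involved markers of total degree <= d-1,
the residual variance is booked as the order-d contribution, and the fitted
value takes the term's place for the next round.  Additive variance is thus
given precedence over epistatic variance, and lower orders over higher ones.

Whole-kernel decompositions are Monte Carlo averages of these per-term
contributions over uniformly sampled marker tuples: single indices for G,
ordered pairs for H, and ordered d-tuples with repetition for lengths
1..max_order for K, the per-length averages weighted by p^d (the count of
ordered d-tuples).  For G the result is analytic — 100% additive — because a
centered marker regressed on a constant is left intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import linalg

from .grm import _panel_values, regression_term

__all__ = [
    "OrderDecomposition",
    "poly_design",
    "contribution_varcomp",
    "decompose_grm",
    "write_decompositions",
]


@dataclass
class OrderDecomposition:
    """Percent of kernel-implied genetic variance per interaction order.

    ``percents[o-1]`` is the share of order o (1 = additive, 2 = additive x
    additive, ...); entries are non-negative and sum to 100.
    """

    kind: str
    percents: np.ndarray
    n_samples: int
    max_order: int
    bandwidth: float | None = None
    bandwidth_multiplier: float | None = None

    @property
    def tail(self) -> float:
        """Combined share of orders above four."""
        return float(self.percents[4:].sum())


def _is_binary(M: np.ndarray) -> bool:
    return bool(np.isin(M, (0.0, 1.0)).all())


def poly_design(M_J: np.ndarray, degree: int) -> np.ndarray:
    """All monomials of total degree <= degree of the columns of ``M_J``.

    Includes the constant column.  On binary markers m^2 = m, so monomials
    collapse onto products over distinct columns; duplicate columns are
    deduplicated.
    """
    M_J = np.atleast_2d(np.asarray(M_J, dtype=float))
    if M_J.ndim != 2:
        raise ValueError("marker submatrix must be 2-D")
    n, d = M_J.shape
    if degree < 0:
        raise ValueError("degree must be >= 0")
    cols = [np.ones(n)]
    if degree > 0 and d > 0:
        if _is_binary(M_J):
            # m^a = m for binary markers: a degree-<=deg monomial is a product
            # over <= deg distinct columns.
            uniq = np.unique(M_J, axis=1)
            u = uniq.shape[1]
            for size in range(1, min(degree, u) + 1):
                for sub in combinations(range(u), size):
                    cols.append(np.prod(uniq[:, sub], axis=1))
        else:
            for size in range(1, degree + 1):
                for sub in combinations_with_replacement(range(d), size):
                    cols.append(np.prod(M_J[:, sub], axis=1))
    Z = np.column_stack(cols)
    # Exact duplicate products (e.g. identical markers) add nothing.
    _, keep = np.unique(Z.T, axis=0, return_index=True)
    return Z[:, np.sort(keep)]


def contribution_varcomp(
    markers, J, kind: str, h: float | None = None
) -> np.ndarray:
    """Per-order variance contributions of one regression term (orders 1..d).

    Rank-deficient monomial designs (forced by binary-marker collinearity)
    are handled by least squares; fitted values are unique regardless of the
    solver's choice of coefficients.  A zero-variance term contributes zero
    at every order.
    """
    M, _ = _panel_values(markers)
    term = regression_term(M, J, kind, h)
    J = term.J
    d = len(J)
    result = np.zeros(d)
    x = term.values.astype(float)
    if x.var() == 0:
        return result
    M_J = M[:, list(J)]
    X_n = x
    for order in range(d, 0, -1):
        Z = poly_design(M_J, order - 1)
        coef, *_ = linalg.lstsq(Z, X_n, lapack_driver="gelsy")
        fitted = Z @ coef
        result[order - 1] = np.var(X_n - fitted)  # population-style, divisor n
        X_n = fitted
    return result


def decompose_grm(
    geno,
    kind: str,
    h: float | None = None,
    n_samples: int = 10_000,
    max_order: int = 6,
    seed: int = 0,
    bandwidth_multiplier: float | None = None,
) -> OrderDecomposition:
    """Monte Carlo decomposition of one kernel's genetic variance by order.

    Tuples are sampled uniformly (with repetition for K, over ordered
    tuples); for K the per-length mean contributions are weighted by p^d
    before normalizing the output to percentages.  Deterministic under
    ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    M, _ = _panel_values(geno)
    p = M.shape[1]
    rng = np.random.default_rng(seed)
    totals = np.zeros(max_order)
    if kind == "G":
        for k in rng.integers(0, p, size=n_samples):
            totals[:1] += contribution_varcomp(M, (int(k),), "G")
    elif kind == "H":
        for k, l in rng.integers(0, p, size=(n_samples, 2)):
            totals[:2] += contribution_varcomp(M, (int(k), int(l)), "H")
    elif kind == "K":
        if h is None:
            raise ValueError("kind K requires a bandwidth h")
        for d in range(1, max_order + 1):
            per_len = np.zeros(d)
            for J in rng.integers(0, p, size=(n_samples, d)):
                per_len += contribution_varcomp(M, tuple(int(j) for j in J), "K", h)
            totals[:d] += (per_len / n_samples) * float(p) ** d
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if totals.sum() <= 0:
        raise ValueError("all sampled terms have zero variance")
    return OrderDecomposition(
        kind=kind,
        percents=100.0 * totals / totals.sum(),
        n_samples=n_samples,
        max_order=max_order,
        bandwidth=h,
        bandwidth_multiplier=bandwidth_multiplier,
    )


def write_decompositions(decomps: list[OrderDecomposition], path) -> None:
    """TSV with one row per kernel: additive through fourth-order shares plus tail."""
    rows = []
    for dec in decomps:
        pct = np.concatenate([dec.percents, np.zeros(4)])
        rows.append(
            {
                "kind": dec.kind,
                "bandwidth": "" if dec.bandwidth is None else f"{dec.bandwidth:.6g}",
                "pct_A": round(float(pct[0]), 1),
                "pct_AA": round(float(pct[1]), 1),
                "pct_AAA": round(float(pct[2]), 1),
                "pct_A4": round(float(pct[3]), 1),
                "tail_pct": round(dec.tail, 2),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
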