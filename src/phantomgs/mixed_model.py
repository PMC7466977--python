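"""Single-kernel mixed models: REML fitting, fixed-effect sets, held-out BLUPs.

The model is y = X beta + u + e with u ~ N(0, sigma2_u K) for one of the
relationship matrices and e ~ N(0, sigma2_e I).  With a single random effect
the restricted likelihood can be profiled exactly on the variance ratio
lambda = sigma2_u / sigma2_e after one eigendecomposition of K: for each
lambda the GLS coefficients, the residual variance and the restricted
log-likelihood are closed-form, and a bounded scalar search over
log(lambda) in [-10, 10] locates the optimum.

Held-out accessions are predicted by the conditional-expectation rule

    u_test = K[test, train] (K[train, train] + delta I)^{-1} (y_train - X_train beta)

with delta = sigma2_e / sigma2_u, which coincides with solving the joint
mixed-model equations with the test phenotypes masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .geno_io import MarkerMatrix
from .grm import GRM, PSD_TOL, build_G

__all__ = [
    "FixedEffects",
    "LMMFit",
    "FIXED_EFFECT_LABELS",
    "make_fixed_effects",
    "fit_reml",
    "predict_heldout",
]

FIXED_EFFECT_LABELS = ("mu", "PC1", "PC5", "CL3", "CL9")
_LOG_RATIO_BOUNDS = (-10.0, 10.0)


@dataclass
class FixedEffects:
    """A labelled fixed-effect design matrix; the first column is the intercept."""

    label: str
    X: np.ndarray

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.allclose(self.X[:, 0], self.X[0, 0]) or self.X[0, 0] == 0:
            raise ValueError("first design column must be a nonzero constant")

    @property
    def q(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FixedEffects":
        sub = FixedEffects.__new__(FixedEffects)
        sub.label = self.label
        sub.X = self.X[idx]
        return sub


@dataclass
class LMMFit:
    """REML estimates and BLUPs for one kernel."""

    beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    blups: np.ndarray
    reml_loglik: float
    grm_kind: str
    fx_label: str = ""

    @property
    def log_ratio(self) -> float:
        if self.sigma2_u == 0:
            return -np.inf
        return math.log(self.sigma2_u / self.sigma2_e)


def _pc_scores(grm_values: np.ndarray, k: int) -> np.ndarray:
    """Leading principal-component scores (eigenvectors scaled by sqrt eigenvalue)."""
    w, U = np.linalg.eigh(grm_values)
    order = np.argsort(w)[::-1][:k]
    return U[:, order] * np.sqrt(np.clip(w[order], 0, None))


def make_fixed_effects(
    g: MarkerMatrix,
    label: str,
    seed: int = 0,
    grm: GRM | None = None,
    n_cluster_pcs: int = 10,
) -> FixedEffects:
    """Build one of the five fixed-effect sets (mu / PC1 / PC5 / CL3 / CL9).

    Principal components come from the additive GRM of the full marker set
    (they model population structure, so they are not panel-specific);
    clusters from k-means on the 10 leading PCs with 25 restarts under a
    fixed seed.  Cluster memberships enter as one-hot columns with the first
    cluster absorbed into the intercept, giving q = 1, 2, 6, 3, 9 columns
    for mu, PC1, PC5, CL3, CL9.
    """
    if label not in FIXED_EFFECT_LABELS:
        raise ValueError(f"unknown fixed-effect label {label!r}; expected one of {FIXED_EFFECT_LABELS}")
    n = g.n_accessions
    ones = np.ones((n, 1))
    if label == "mu":
        return FixedEffects(label, ones)
    A = (grm if grm is not None else build_G(g)).values
    if label in ("PC1", "PC5"):
        k = 1 if label == "PC1" else 5
        X = np.hstack([ones, _pc_scores(A, k)])
    else:
        from sklearn.cluster import KMeans

        k = 3 if label == "CL3" else 9
        if k > n:
            raise ValueError(f"cannot form {k} clusters from {n} accessions")
        scores = _pc_scores(A, min(n_cluster_pcs, n))
        labels = KMeans(n_clusters=k, n_init=25, random_state=seed).fit_predict(scores)
        onehot = np.eye(k)[labels]
        X = np.hstack([ones, onehot[:, 1:]])  # intercept absorbs the first cluster
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"fixed-effect design {label} is rank deficient")
    return FixedEffects(label, X)


def _eigh_psd(K: np.ndarray, tol: float = PSD_TOL) -> tuple[np.ndarray, np.ndarray]:
    w, U = np.linalg.eigh(K)
    if w.min() < -tol * K.shape[0]:
        raise ValueError(f"GRM is not PSD (min eigenvalue {w.min():.3e})")
    return np.clip(w, 0.0, None), U


def _profile_at(ln_lam, yt, Xt, w, ldet_xtx, n, q):
    """GLS quantities and restricted log-likelihood at one log variance ratio."""
    lam = math.exp(ln_lam)
    d = lam * w + 1.0
    Xd = Xt / d[:, None]
    A = Xt.T @ Xd
    beta = np.linalg.solve(A, Xd.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ (r / d))
    s2e = rss / (n - q)
    sign, ldet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("singular fixed-effect design in REML profiling")
    loglik = -0.5 * (
        (n - q) * (math.log(2 * math.pi) + math.log(s2e) + 1.0)
        + float(np.log(d).sum())
        + ldet_a
        - ldet_xtx
    )
    return lam, d, beta, r, s2e, loglik


def _reml_spectral(y, X, w, U, tol: float = 1e-8):
    """Profile REML over the variance ratio in the kernel eigenbasis."""
    n, q = X.shape
    if n != y.size:
        raise ValueError("phenotype length must match design rows")
    if n <= q:
        raise ValueError("more fixed effects than observations")
    sign, ldet_xtx = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise ValueError("singular fixed-effect design")
    yt = U.T @ y
    Xt = U.T @ X

    def neg(ln_lam):
        return -_profile_at(ln_lam, yt, Xt, w, ldet_xtx, n, q)[-1]

    res = minimize_scalar(
        neg, bounds=_LOG_RATIO_BOUNDS, method="bounded", options={"xatol": tol}
    )
    # The bounded search can park short of a boundary optimum; compare ends.
    best = min(
        [res.x, _LOG_RATIO_BOUNDS[0], _LOG_RATIO_BOUNDS[1]], key=neg
    )
    lam, d, beta, r, s2e, loglik = _profile_at(best, yt, Xt, w, ldet_xtx, n, q)
    blups = U @ (lam * w / d * r)
    return {
        "lam": lam,
        "beta": beta,
        "sigma2_e": s2e,
        "sigma2_u": lam * s2e,
        "blups": blups,
        "loglik": loglik,
        "resid_rot": r,
        "d": d,
    }


def fit_reml(y, fx: FixedEffects, grm: GRM) -> LMMFit:
    """REML fit of the single-kernel mixed model by spectral ratio profiling."""
    y = np.asarray(y, dtype=float)
    if y.size != grm.n or fx.X.shape[0] != grm.n:
        raise ValueError("phenotypes, design and GRM dimensions must agree")
    w, U = _eigh_psd(grm.values)
    out = _reml_spectral(y, fx.X, w, U)
    return LMMFit(
        beta=out["beta"],
        sigma2_u=out["sigma2_u"],
        sigma2_e=out["sigma2_e"],
        blups=out["blups"],
        reml_loglik=out["loglik"],
        grm_kind=grm.kind,
        fx_label=fx.label,
    )


def predict_heldout(
    y,
    fx: FixedEffects,
    grm: GRM,
    train_idx,
    test_idx,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, LMMFit]:
    """Predict test accessions from a fit on the training block of the GRM.

    Variance components and GLS coefficients are re-estimated on the
    training subset; test genetic values follow the conditional-expectation
    rule.  ``eig`` optionally supplies a precomputed eigendecomposition of
    the training block (reused across traits in cross-validation sweeps).
    """
    y = np.asarray(y, dtype=float)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if train_idx.dtype == bool:
        train_idx = np.flatnonzero(train_idx)
    if test_idx.dtype == bool:
        test_idx = np.flatnonzero(test_idx)
    if test_idx.size == 0:
        raise ValueError("test set is empty")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test sets must be disjoint")
    K = grm.values
    Ktt = K[np.ix_(train_idx, train_idx)]
    if eig is None:
        eig = _eigh_psd(Ktt)
    w, U = eig
    X_tr = fx.X[train_idx]
    out = _reml_spectral(y[train_idx], X_tr, w, U)
    fit = LMMFit(
        beta=out["beta"],
        sigma2_u=out["sigma2_u"],
        sigma2_e=out["sigma2_e"],
        blups=out["blups"],
        reml_loglik=out["loglik"],
        grm_kind=grm.kind,
        fx_label=fx.label,
    )
    X_te = fx.X[test_idx]
    pred = X_te @ out["beta"]
    lam = out["lam"]
    if lam > 0:
        # (K_tt + delta I)^{-1} r via the eigenbasis, delta = 1/lambda
        v = U @ (out["resid_rot"] / (w + 1.0 / lam))
        pred = pred + K[np.ix_(test_idx, train_idx)] @ v
    return pred, fit
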