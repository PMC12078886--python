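"""Whole-genome regression models for genomic prediction.

Two scikit-learn-style estimators carry the statistical machinery:

``RidgeBLUP``
    Ridge-regression BLUP (rrBLUP).  All markers share one effect variance;
    the variance components are estimated by REML using the spectral
    decomposition of the marker cross-product kinship, so fitting is
    efficient when markers vastly outnumber accessions.  Marker effects are
    the ridge solution at lambda = sigma2_e / sigma2_u on centered dosages,
    and predictions are identical to GBLUP with the cross-product kinship.

``BayesianAlphabet``
    The five Bayesian whole-genome regressions (BRR, BayesA, BayesB, BayesC,
    Bayesian LASSO) fit by a single-site Gibbs sampler (default 6000 sweeps,
    1000 burn-in).  They differ only in the prior on marker effects —
    common-variance Gaussian, per-marker scaled-t, spike-and-slab variants,
    and double-exponential — which is what lets them adapt to oligogenic
    architectures where rrBLUP's equal-variance assumption is off.

Both accept columns of the marker matrix as fixed-effect covariates (GWAS
peak SNPs used as cofactors); by default such columns are excluded from the
random marker set to avoid double counting.

GenotypeMatrix-level wrappers (``fit_rrblup``, ``fit_bayesian``,
``predict``) reconcile SNP panels by id and carry accession bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._gibbs import MODEL_CODES, gibbs_sample, split_rhat
from .io_formats import GenotypeMatrix

__all__ = [
    "RidgeBLUP",
    "BayesianAlphabet",
    "ModelSpec",
    "FixedCofactorSet",
    "MarkerModelFit",
    "fit_rrblup",
    "fit_bayesian",
    "predict",
    "gblup_predict",
]

MODEL_NAMES = ("rrblup", "bayes_a", "bayes_b", "bayes_c", "bayes_lasso", "brr")


def _split_design(X, fixed_idx, keep_in_random):
    """Partition marker columns into fixed covariates and the random set."""
    m = X.shape[1]
    if fixed_idx is None or len(fixed_idx) == 0:
        return np.empty((X.shape[0], 0)), np.arange(m), np.array([], dtype=int)
    fixed_idx = np.asarray(fixed_idx, dtype=int)
    if keep_in_random:
        rand_idx = np.arange(m)
    else:
        rand_idx = np.setdiff1d(np.arange(m), fixed_idx)
    return X[:, fixed_idx].astype(float), rand_idx, fixed_idx


def _check_fixed_rank(W, fixed_idx):
    if W.shape[1] == 0:
        return
    full = np.column_stack([np.ones(W.shape[0]), W])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        raise ValueError(
            "collinear fixed-effect cofactors (design is singular); "
            f"offending columns among marker indices {list(map(int, fixed_idx))}"
        )


class RidgeBLUP(RegressorMixin, BaseEstimator):
    """Ridge-regression BLUP with REML variance components.

    Parameters
    ----------
    ridge_lambda : float or None
        If given, skip REML and solve the ridge system at this fixed
        lambda = sigma2_e / sigma2_u.  If None (default), estimate both
        variance components by REML.
    fixed_idx : sequence of int or None
        Marker columns to treat as fixed-effect covariates.
    keep_in_random : bool
        Whether fixed-cofactor columns also stay in the random marker set
        (default False: excluded, to avoid double counting).

    Attributes
    ----------
    marker_effects_ : ndarray of shape (n_markers,)
        Ridge/BLUP solution for every input column (zero for columns moved
        to the fixed design when ``keep_in_random`` is False).
    intercept_ : float
    fixed_effects_ : ndarray, coefficients of the fixed cofactor columns.
    sigma2_u_, sigma2_e_, lambda_ : REML variance components and their ratio.
    centers_ : training column means used to center dosages.
    """

    def __init__(self, ridge_lambda=None, fixed_idx=None, keep_in_random=False):
        self.ridge_lambda = ridge_lambda
        self.fixed_idx = fixed_idx
        self.keep_in_random = keep_in_random

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        n, m_all = X.shape
        self.n_features_in_ = m_all
        F, rand_idx, fixed_idx = _split_design(X, self.fixed_idx, self.keep_in_random)
        _check_fixed_rank(F, fixed_idx)
        W = np.column_stack([np.ones(n), F])
        p = W.shape[1]

        Xr = X[:, rand_idx]
        centers = Xr.mean(axis=0)
        Xc = Xr - centers

        if np.var(y) == 0.0:
            # degenerate but well-defined: nothing to predict beyond the mean
            warnings.warn("constant phenotype: all marker effects set to 0",
                          stacklevel=2)
            self._finalize(rand_idx, fixed_idx, np.zeros(len(rand_idx)),
                           np.zeros(F.shape[1]), float(y[0]), centers,
                           0.0, 0.0, np.inf, Xc, np.zeros(n))
            return self

        K = Xc @ Xc.T
        if self.ridge_lambda is not None:
            lam = float(self.ridge_lambda)
            if lam <= 0:
                raise ValueError("ridge_lambda must be positive")
            beta, u, ghat = self._solve_at_lambda(K, Xc, W, y, lam)
            s2u, s2e = np.nan, np.nan
        else:
            lam, s2u, s2e = self._reml(K, W, y)
            beta, u, ghat = self._solve_at_lambda(K, Xc, W, y, lam)
        self._finalize(rand_idx, fixed_idx, u, beta[1:], float(beta[0]),
                       centers, s2u, s2e, lam, Xc, ghat)
        return self

    @staticmethod
    def _reml(K, W, y):
        """Profiled REML over delta = sigma2_e / sigma2_u (spectral form)."""
        n, p = W.shape
        WtW_inv = np.linalg.inv(W.T @ W)
        S = np.eye(n) - W @ WtW_inv @ W.T
        d, U = np.linalg.eigh(S @ K @ S)
        # keep the n-p informative directions (largest eigenvalues)
        order = np.argsort(d)[::-1][: n - p]
        d = np.clip(d[order], 0.0, None)
        eta = U[:, order].T @ y

        def neg_ll(log_delta):
            delta = np.exp(log_delta)
            denom = d + delta
            q = np.sum(eta**2 / denom)
            if q <= 0:
                return np.inf
            return np.sum(np.log(denom)) + (n - p) * np.log(q)

        grid = np.linspace(np.log(1e-6), np.log(1e6), 61)
        vals = [neg_ll(g) for g in grid]
        i = int(np.argmin(vals))
        res = minimize_scalar(
            neg_ll,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded", options={"xatol": 1e-10},
        )
        delta = float(np.exp(res.x))
        s2u = float(np.sum(eta**2 / (d + delta)) / (n - p))
        s2e = delta * s2u
        return delta, s2u, s2e

    @staticmethod
    def _solve_at_lambda(K, Xc, W, y, lam):
        n = K.shape[0]
        H = K + lam * np.eye(n)
        Hinv_W = np.linalg.solve(H, W)
        Hinv_y = np.linalg.solve(H, y)
        beta = np.linalg.solve(W.T @ Hinv_W, W.T @ Hinv_y)
        alpha = np.linalg.solve(H, y - W @ beta)
        u = Xc.T @ alpha
        ghat = K @ alpha
        return beta, u, ghat

    def _finalize(self, rand_idx, fixed_idx, u, fixed_effects, intercept,
                  centers, s2u, s2e, lam, Xc, ghat):
        self.rand_idx_ = rand_idx
        self.fixed_idx_ = fixed_idx
        self.marker_effects_ = np.zeros(self.n_features_in_)
        self.marker_effects_[rand_idx] = u
        self.random_effects_ = u
        self.fixed_effects_ = np.asarray(fixed_effects, dtype=float)
        self.intercept_ = intercept
        self.centers_ = np.zeros(self.n_features_in_)
        self.centers_[rand_idx] = centers
        self.sigma2_u_ = s2u
        self.sigma2_e_ = s2e
        self.lambda_ = lam
        self.fitted_genetic_values_ = ghat

    def predict(self, X):
        check_is_fitted(self, "marker_effects_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        out = np.full(X.shape[0], self.intercept_)
        if len(self.fixed_idx_):
            out += X[:, self.fixed_idx_] @ self.fixed_effects_
        Xc = X[:, self.rand_idx_] - self.centers_[self.rand_idx_]
        out += Xc @ self.random_effects_
        return out


class BayesianAlphabet(RegressorMixin, BaseEstimator):
    """Bayesian whole-genome regression via single-site Gibbs sampling.

    Parameters
    ----------
    model : {"brr", "bayes_a", "bayes_b", "bayes_c", "bayes_lasso"}
    n_iter, burn_in : int
        Total Gibbs sweeps and the number discarded (defaults 6000 / 1000).
    pi : float in (0, 1)
        Prior probability that a marker effect is exactly zero
        (BayesB/BayesC only).  Default 0.5.
    update_pi : bool
        Sample pi with a flat beta hyperprior instead of keeping it fixed.
    df_marker, df_e : float
        Degrees of freedom of the scaled-inv-chi2 hyperpriors.
    r2 : float
        Prior fraction of phenotypic variance attributed to markers; sets
        the hyperprior scales (default 0.5).
    seed : int
        Seeds the chain; a fixed seed reproduces posterior means exactly.
    fixed_idx, keep_in_random : as in :class:`RidgeBLUP`.

    Attributes
    ----------
    marker_effects_ : posterior-mean effects for every input column.
    inclusion_prob_ : posterior inclusion probability (BayesB/C; 1 elsewhere).
    sigma2_e_, marker_variance_ : posterior means.
    rhat_sigma2_e_ : split-chain potential scale reduction of sigma2_e.
    converged_ : bool, True when rhat < 1.1 (warning otherwise, not an error).
    """

    def __init__(self, model="brr", n_iter=6000, burn_in=1000, pi=0.5,
                 update_pi=False, df_marker=5.0, df_e=5.0, r2=0.5, seed=0,
                 fixed_idx=None, keep_in_random=False):
        self.model = model
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.pi = pi
        self.update_pi = update_pi
        self.df_marker = df_marker
        self.df_e = df_e
        self.r2 = r2
        self.seed = seed
        self.fixed_idx = fixed_idx
        self.keep_in_random = keep_in_random

    def fit(self, X, y):
        if self.model not in MODEL_CODES:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {sorted(MODEL_CODES)}"
            )
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("need 0 < burn_in < n_iter")
        if self.model in ("bayes_b", "bayes_c") and not (0.0 < self.pi < 1.0):
            raise ValueError("pi must lie strictly in (0, 1)")
        X, y = check_X_y(X, y, dtype=float)
        n, m_all = X.shape
        self.n_features_in_ = m_all
        F, rand_idx, fixed_idx = _split_design(X, self.fixed_idx, self.keep_in_random)
        _check_fixed_rank(F, fixed_idx)
        W = np.column_stack([np.ones(n), F - (F.mean(axis=0) if F.size else 0.0)])
        Xr = X[:, rand_idx]
        centers = Xr.mean(axis=0)
        Xc = np.ascontiguousarray(Xr - centers)

        var_y = float(np.var(y))
        if var_y == 0:
            raise ValueError("constant phenotype: nothing to fit")
        msx = float(np.sum(Xc.var(axis=0)))
        if msx == 0:
            raise ValueError("all markers are monomorphic")
        frac_in = 1.0
        if self.model in ("bayes_b", "bayes_c"):
            frac_in = max(1.0 - self.pi, 1e-3)
        mode_u = self.r2 * var_y / (msx * frac_in)
        S_u = mode_u * (self.df_marker + 2.0) / self.df_marker
        mode_e = (1.0 - self.r2) * var_y
        S_e = mode_e * (self.df_e + 2.0) / self.df_e
        # Bayesian LASSO regularization: gamma prior on lambda^2 centered so
        # the prior marker variance matches the r2 budget
        var_b = self.r2 * var_y / msx
        lambda2_init = 2.0 * mode_e / var_b
        bl_shape = 1.1
        bl_rate = bl_shape / lambda2_init

        u, b, s2e_chain, incl, s2u_mean, pi_chain = gibbs_sample(
            Xc, np.ascontiguousarray(y, dtype=float),
            np.ascontiguousarray(W),
            MODEL_CODES[self.model], int(self.n_iter), int(self.burn_in),
            float(self.df_marker), float(S_u), float(self.df_e), float(S_e),
            float(self.pi), bool(self.update_pi), bl_shape, bl_rate,
            int(self.seed) % (2**31 - 1),
        )

        self.rand_idx_ = rand_idx
        self.fixed_idx_ = fixed_idx
        self.marker_effects_ = np.zeros(m_all)
        self.marker_effects_[rand_idx] = u
        self.random_effects_ = u
        # fixed covariates were centered in W, so b[0] is the intercept at
        # the training means; predict() re-centers accordingly
        self.intercept_ = float(b[0])
        self.fixed_effects_ = np.asarray(b[1:], dtype=float)
        self.fixed_centers_ = F.mean(axis=0) if F.size else np.zeros(0)
        self.centers_ = np.zeros(m_all)
        self.centers_[rand_idx] = centers
        self.inclusion_prob_ = np.ones(m_all)
        self.inclusion_prob_[rand_idx] = incl
        post = s2e_chain[self.burn_in:]
        self.sigma2_e_ = float(post.mean())
        self.sigma2_e_chain_ = s2e_chain
        self.marker_variance_ = float(s2u_mean)
        self.pi_mean_ = float(pi_chain[self.burn_in:].mean())
        self.rhat_sigma2_e_ = split_rhat(post)
        self.converged_ = bool(np.isnan(self.rhat_sigma2_e_) or
                               self.rhat_sigma2_e_ < 1.1)
        if not self.converged_:
            warnings.warn(
                f"{self.model}: sigma2_e split-chain Rhat = "
                f"{self.rhat_sigma2_e_:.3f} > 1.1; chain may not have converged",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        check_is_fitted(self, "marker_effects_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        out = np.full(X.shape[0], self.intercept_)
        if len(self.fixed_idx_):
            out += (X[:, self.fixed_idx_] - self.fixed_centers_) @ self.fixed_effects_
        Xc = X[:, self.rand_idx_] - self.centers_[self.rand_idx_]
        out += Xc @ self.random_effects_
        return out


def gblup_predict(X_train, y, X_new, ridge_lambda, W_train=None, W_new=None):
    """GBLUP predictions through the cross-product kinship XX'.

    Independent route to the same predictions as :class:`RidgeBLUP` at the
    same lambda: genetic values are kriged from the training kinship
    without ever forming marker effects.
    """
    X_train = np.asarray(X_train, float)
    X_new = np.asarray(X_new, float)
    centers = X_train.mean(axis=0)
    Xc = X_train - centers
    Xn = X_new - centers
    n = Xc.shape[0]
    W = np.ones((n, 1)) if W_train is None else W_train
    Wn = np.ones((Xn.shape[0], 1)) if W_new is None else W_new
    H = Xc @ Xc.T + ridge_lambda * np.eye(n)
    Hinv_W = np.linalg.solve(H, W)
    beta = np.linalg.solve(W.T @ Hinv_W, W.T @ np.linalg.solve(H, y))
    alpha = np.linalg.solve(H, y - W @ beta)
    return (Wn @ beta) + Xn @ (Xc.T @ alpha)


# ---------------------------------------------------------------------------
# GenotypeMatrix-level surface


@dataclass
class FixedCofactorSet:
    """SNPs used as fixed-effect covariates (GWAS peaks)."""

    snp_ids: Sequence[str]
    mode: str = "exclude_from_random"   # or "keep_in_random"

    def indices(self, g: GenotypeMatrix) -> np.ndarray:
        pos = pd.Index(g.snps["snp_id"])
        idx = pos.get_indexer(list(self.snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(self.snp_ids, idx) if i < 0]
            raise KeyError(f"cofactor SNPs absent from panel: {missing}")
        return idx


@dataclass
class ModelSpec:
    """Declarative model choice used by the cross-validation engine."""

    model_name: str = "rrblup"
    n_iter: int = 6000
    burn_in: int = 1000
    pi: float = 0.5
    r2: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.model_name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.model_name!r}; choose from {MODEL_NAMES}"
            )
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")

    def build(self, seed=None, fixed_idx=None, keep_in_random=False):
        if self.model_name == "rrblup":
            return RidgeBLUP(fixed_idx=fixed_idx, keep_in_random=keep_in_random)
        return BayesianAlphabet(
            model=self.model_name, n_iter=self.n_iter, burn_in=self.burn_in,
            pi=self.pi, r2=self.r2,
            seed=self.seed if seed is None else seed,
            fixed_idx=fixed_idx, keep_in_random=keep_in_random,
        )


@dataclass
class MarkerModelFit:
    """A fitted model bound to its SNP panel (ids + order)."""

    estimator: object
    snp_ids: list
    trait_id: Optional[str] = None

    @property
    def marker_effects(self) -> pd.Series:
        return pd.Series(self.estimator.marker_effects_, index=self.snp_ids)


def _as_series(y) -> pd.Series:
    if hasattr(y, "values") and hasattr(y, "h2"):   # AdjustedPhenotype
        return y.values
    if isinstance(y, pd.Series):
        return y
    raise TypeError("y must be a pandas Series or an AdjustedPhenotype")


def _align_xy(g: GenotypeMatrix, y: pd.Series):
    common = [a for a in g.accession_ids if a in y.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 accessions with genotype and phenotype")
    gm = g.subset_accessions(common)
    return gm.dosage, y.loc[common].to_numpy(float), common


def fit_rrblup(g: GenotypeMatrix, y, cofactors: Optional[FixedCofactorSet] = None,
               trait_id=None) -> MarkerModelFit:
    """Fit rrBLUP on accessions present in both the panel and ``y``.

    ``y`` is a pandas Series indexed by accession (e.g. the adjusted BLUPs).
    """
    X, yv, _ = _align_xy(g, _as_series(y))
    fixed_idx, keep = None, False
    if cofactors is not None:
        fixed_idx = cofactors.indices(g)
        keep = cofactors.mode == "keep_in_random"
    est = RidgeBLUP(fixed_idx=fixed_idx, keep_in_random=keep).fit(X, yv)
    return MarkerModelFit(est, g.snp_ids, trait_id)


def fit_bayesian(g: GenotypeMatrix, y, spec: ModelSpec,
                 cofactors: Optional[FixedCofactorSet] = None,
                 trait_id=None) -> MarkerModelFit:
    X, yv, _ = _align_xy(g, _as_series(y))
    fixed_idx, keep = None, False
    if cofactors is not None:
        fixed_idx = cofactors.indices(g)
        keep = cofactors.mode == "keep_in_random"
    est = spec.build(fixed_idx=fixed_idx, keep_in_random=keep).fit(X, yv)
    return MarkerModelFit(est, g.snp_ids, trait_id)


def predict(fit: MarkerModelFit, g_new: GenotypeMatrix) -> pd.Series:
    """Predict genetic merit for new accessions, reconciling SNPs by id."""
    aligned = g_new.subset_snp_ids(fit.snp_ids)
    values = fit.estimator.predict(aligned.dosage)
    return pd.Series(values, index=aligned.accession_ids, name="predicted")
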