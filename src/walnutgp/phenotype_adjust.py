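"""Per-accession genotypic BLUPs adjusting for year, and broad-sense H².

Traits observed over two (or more) years are adjusted with the mixed model

    P_ik = mu + Y_i + g_k + e_ik

where ``Y_i`` is the fixed effect of year *i* (sum-to-zero coding, so ``mu``
is the grand mean) and ``g_k ~ N(0, sigma2_G)`` is the random genotypic
effect.  Variance components are estimated by REML with the likelihood
profiled over the ratio ``gamma = sigma2_G / sigma2_eps`` — the model has a
single random factor, so no general mixed-model machinery is needed.
Negative variance estimates are clamped at the REML boundary (gamma = 0) and
flagged.  Broad-sense heritability uses the genotype-mean variance identity

    H2 = sigma2_G / (sigma2_G + sigma2_eps / n_y).

Traits observed in a single year cannot separate genotype from residual;
they pass through unadjusted with no H².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io_formats import PhenotypeTable

__all__ = [
    "BlupModel",
    "AdjustedPhenotype",
    "SingleYearError",
    "fit_year_genotype_mixed_model",
    "broad_sense_h2",
    "passthrough_single_year",
    "adjust_trait",
    "adjust_all",
]


class SingleYearError(ValueError):
    """Raised when the mixed model is asked for a trait with one year of data."""


@dataclass
class BlupModel:
    trait_id: str
    mu: float
    year_effects: dict            # year -> fixed deviation from mu
    g: pd.Series                  # accession -> genotypic BLUP (deviation)
    sigma2_G: float
    sigma2_eps: float
    n_y: int
    boundary_clamped: bool = False

    def adjusted_values(self) -> pd.Series:
        """BLUP-adjusted phenotype per accession: mu + g_k (trait units)."""
        return self.mu + self.g


@dataclass
class AdjustedPhenotype:
    trait_id: str
    values: pd.Series             # accession_id -> adjusted value
    h2: Optional[float] = None    # present iff >= 2 years of data
    model: Optional[BlupModel] = None


def _design(records: pd.DataFrame):
    """Fixed design (intercept + sum-coded years) and genotype incidence."""
    years = np.sort(records["year"].unique())
    accs = pd.Index(records["accession_id"].unique())
    n = len(records)
    X = np.ones((n, len(years)))
    for i, yr in enumerate(years[:-1]):
        X[:, i + 1] = np.where(
            records["year"] == yr, 1.0,
            np.where(records["year"] == years[-1], -1.0, 0.0),
        )
    Z = np.zeros((n, len(accs)))
    Z[np.arange(n), accs.get_indexer(records["accession_id"])] = 1.0
    return X, Z, years, accs


def fit_year_genotype_mixed_model(p: PhenotypeTable, trait_id) -> BlupModel:
    """REML fit of the year + genotype model for one trait.

    Requires at least two years of data.  Handles unbalanced records (an
    accession missing in one year) through the same profiled-REML fit; for
    balanced two-year data the solution coincides with the closed-form
    one-way ANOVA estimators.
    """
    rec = p.for_trait(trait_id)
    if rec.empty:
        raise ValueError(f"no records for trait {trait_id!r}")
    n_years = rec["year"].nunique()
    if n_years < 2:
        raise SingleYearError(
            f"trait {trait_id!r} has a single year of data; "
            "use passthrough_single_year"
        )
    X, Z, years, accs = _design(rec)
    y = rec["value"].to_numpy(float)
    n, p_fix = X.shape

    K = Z @ Z.T
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    Xt, yt = U.T @ X, U.T @ y

    def neg_reml(log_gamma):
        gamma = np.exp(log_gamma)
        w = 1.0 / (1.0 + gamma * d)
        XtWX = Xt.T @ (w[:, None] * Xt)
        XtWy = Xt.T @ (w * yt)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        sign, logdet_XWX = np.linalg.slogdet(XtWX)
        if sign <= 0 or rss <= 0:
            return np.inf
        # REML deviance up to a constant, sigma2_eps profiled out
        return (
            -np.sum(np.log(w))
            + logdet_XWX
            + (n - p_fix) * np.log(rss)
        )

    grid = np.linspace(np.log(1e-8), np.log(1e8), 65)
    vals = np.array([neg_reml(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    gamma = float(np.exp(res.x))

    clamped = False
    if gamma < 1e-7 and neg_reml(np.log(1e-12)) <= res.fun + 1e-9:
        gamma, clamped = 0.0, True
        warnings.warn(
            f"trait {trait_id!r}: REML genotype variance at the zero boundary",
            stacklevel=2,
        )

    w = 1.0 / (1.0 + gamma * d)
    XtWX = Xt.T @ (w[:, None] * Xt)
    beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    sigma2_eps = float(r @ (w * r)) / (n - p_fix)
    sigma2_G = gamma * sigma2_eps

    # BLUPs: g_hat = gamma * Z' V0^{-1} (y - X beta), V0 = I + gamma*K
    v0_inv_r = U @ (w * r)
    g_hat = gamma * (Z.T @ v0_inv_r)

    mu = float(beta[0])
    year_eff = {}
    for i_y, yr in enumerate(years[:-1]):
        year_eff[int(yr)] = float(beta[i_y + 1])
    year_eff[int(years[-1])] = float(-np.sum(beta[1:]))

    return BlupModel(
        trait_id=trait_id,
        mu=mu,
        year_effects=year_eff,
        g=pd.Series(g_hat, index=accs, name="blup"),
        sigma2_G=sigma2_G,
        sigma2_eps=sigma2_eps,
        n_y=int(n_years),
        boundary_clamped=clamped,
    )


def broad_sense_h2(m: BlupModel) -> float:
    """H2 = sigma2_G / (sigma2_G + sigma2_eps / n_y); NaN when undefined."""
    if m.n_y < 2:
        raise ValueError("H2 is defined only for models fit on >= 2 years")
    denom = m.sigma2_G + m.sigma2_eps / m.n_y
    if denom == 0:
        warnings.warn("both variance components are zero; H2 undefined",
                      stacklevel=2)
        return float("nan")
    return float(m.sigma2_G / denom)


def passthrough_single_year(p: PhenotypeTable, trait_id) -> AdjustedPhenotype:
    """Single-year traits are used raw: adjusted value = observed value."""
    rec = p.for_trait(trait_id)
    if rec.empty:
        warnings.warn(f"trait {trait_id!r} has no records", stacklevel=2)
        return AdjustedPhenotype(trait_id, pd.Series(dtype=float), None, None)
    if rec["year"].nunique() != 1:
        raise ValueError(
            f"trait {trait_id!r} has multiple years; use the mixed model"
        )
    vals = rec.set_index("accession_id")["value"].astype(float)
    vals.name = "blup"
    return AdjustedPhenotype(trait_id, vals, None, None)


def adjust_trait(p: PhenotypeTable, trait_id) -> AdjustedPhenotype:
    """Dispatch: mixed-model BLUPs for multi-year traits, passthrough else."""
    if p.n_years(trait_id) >= 2:
        m = fit_year_genotype_mixed_model(p, trait_id)
        return AdjustedPhenotype(
            trait_id, m.adjusted_values(), broad_sense_h2(m), m
        )
    return passthrough_single_year(p, trait_id)


def adjust_all(p: PhenotypeTable) -> dict:
    return {t: adjust_trait(p, t) for t in p.trait_ids}
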