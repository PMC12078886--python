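"""Optimized training-set selection on the genomic relationship matrix.

The additive GRM follows VanRaden: G = WW' / (2 * sum p_j (1 - p_j)) with W
the dosage matrix column-centered by twice the panel allele frequency.

Three design criteria are implemented for a candidate split of the panel
into a training set (phenotyped) and a validation set (to be predicted):

CDmean
    Mean coefficient of determination of the validation genetic-value
    predictions, CD_i = 1 - PEV_i / (sigma2_g * G_ii); maximized.
PEVmean
    Mean prediction error variance PEV_i of the validation predictions,
    obtained from the inverse coefficient matrix of the mixed-model
    equations restricted to training records; minimized.
MeanRel
    Mean genomic relationship G_ij between training and validation
    members; maximized (pick the training set most related to the
    candidates it must predict).

MeanRel is optimized by a deterministic greedy forward selection — repeated
runs return the identical design.  CDmean/PEVmean use a seeded genetic
algorithm (tournament selection, uniform crossover with size repair,
exchange mutation, elitism) whose initial population includes the best of a
set of random designs, so the final design never scores below that
baseline.  Both variance-based criteria need the ratio
lambda = sigma2_e / sigma2_g; by default it is derived from a preliminary
rrBLUP fit on all phenotyped accessions (fallback: h2 = 0.5, lambda = 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

__all__ = [
    "Grm",
    "DesignCriterion",
    "TrainingDesign",
    "GaConfig",
    "vanraden_grm",
    "criterion_value",
    "optimize_training_set",
    "svd_reduce",
]

CRITERIA = ("cdmean", "pevmean", "meanrel", "random")


@dataclass
class Grm:
    matrix: np.ndarray
    allele_freq: np.ndarray
    accession_ids: list

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def inverse(self) -> np.ndarray:
        """Cached (jittered if needed) inverse of the relationship matrix."""
        if not hasattr(self, "_inv"):
            self._inv = _robust_inv(self.matrix)
        return self._inv


@dataclass
class DesignCriterion:
    name: str
    ridge_lambda: float = 1.0     # sigma2_e / sigma2_g (cdmean / pevmean)

    def __post_init__(self):
        if self.name not in CRITERIA:
            raise ValueError(f"unknown criterion {self.name!r}; choose from {CRITERIA}")
        if self.name in ("cdmean", "pevmean") and not self.ridge_lambda > 0:
            raise ValueError("ridge_lambda must be > 0 for cdmean/pevmean")

    @property
    def maximize(self) -> bool:
        return self.name in ("cdmean", "meanrel")


@dataclass
class TrainingDesign:
    training_ids: list
    validation_ids: list
    criterion: str
    value: float
    trace: list = field(default_factory=list)


@dataclass
class GaConfig:
    population: int = 100
    generations: int = 200
    mutation_rate: float = 0.02
    elitism: int = 5
    tournament: int = 3
    n_random_baseline: int = 100
    seed: int = 0


def vanraden_grm(g: GenotypeMatrix) -> Grm:
    """Additive genomic relationship matrix from centered dosages."""
    X = np.asarray(g.dosage, float)
    if np.isnan(X).any():
        raise ValueError("GRM requires imputed (complete) dosages")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic SNPs excluded from the GRM "
            "denominator", stacklevel=2,
        )
    W = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if denom == 0:
        raise ValueError("all SNPs monomorphic; GRM undefined")
    G = (W @ W.T) / denom
    return Grm(G, p, list(g.accession_ids))


def _indices(grm: Grm, ids) -> np.ndarray:
    lookup = {a: i for i, a in enumerate(grm.accession_ids)}
    return np.array([lookup[a] for a in ids], dtype=int)


def _cd_pev(grm: "Grm", train: np.ndarray, valid: np.ndarray,
            lam: float):
    """Per-validation-accession PEV and CD of genetic-value predictions.

    Mixed model on training records: y = 1 mu + g + e with
    Var(g) = sigma2_g G and lam = sigma2_e / sigma2_g.  In sigma2_g = 1
    units, PEV_i = Var(g_i | y_train) = G_ii - c_i' P c_i where
    V = G_tt + lam I, c_i = G_t,i, and P is V^-1 projected orthogonal to
    the intercept (the GLS form).  This equals the classical expression
    from the inverse coefficient matrix of the mixed-model equations when
    G is nonsingular, but stays well defined for a singular G (centering
    always costs the GRM one rank).
    """
    G = grm.matrix
    V = G[np.ix_(train, train)] + lam * np.eye(len(train))
    Vi = _robust_inv(V)
    one = np.ones((len(train), 1))
    denom = one.T @ Vi @ one
    P = Vi - (Vi @ one) @ (Vi @ one).T / denom
    C = G[np.ix_(train, valid)]
    pev = np.diag(G)[valid] - np.einsum("ij,ik,kj->j", C, P, C)
    cd = 1.0 - pev / np.diag(G)[valid]
    return pev, cd


def _robust_inv(A: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        warnings.warn("singular system: adding 1e-8 ridge jitter", stacklevel=3)
        return np.linalg.inv(A + 1e-8 * np.eye(A.shape[0]))


def criterion_value(grm: Grm, training_ids, validation_ids,
                    crit: DesignCriterion) -> float:
    """Evaluate a design criterion for one training/validation split."""
    train = _indices(grm, training_ids)
    valid = _indices(grm, validation_ids)
    if len(train) == 0 or len(valid) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if set(train) & set(valid):
        raise ValueError("training and validation sets overlap")
    G = grm.matrix
    if crit.name == "meanrel":
        return float(G[np.ix_(train, valid)].mean())
    if crit.name == "random":
        raise ValueError("'random' is a partition mode, not a computable criterion")
    pev, cd = _cd_pev(grm, train, valid, crit.ridge_lambda)
    return float(cd.mean() if crit.name == "cdmean" else pev.mean())


def _score(grm, train_idx, crit: DesignCriterion):
    n = grm.n
    mask = np.zeros(n, bool)
    mask[train_idx] = True
    valid_idx = np.where(~mask)[0]
    G = grm.matrix
    if crit.name == "meanrel":
        return float(G[np.ix_(train_idx, valid_idx)].mean())
    pev, cd = _cd_pev(grm, np.asarray(train_idx), valid_idx, crit.ridge_lambda)
    return float(cd.mean() if crit.name == "cdmean" else pev.mean())


def _greedy_meanrel(grm: Grm, k: int) -> np.ndarray:
    """Deterministic forward selection + pairwise-swap refinement.

    Forward selection greedily maximizes train-validation MeanRel; a
    first-improvement exchange pass (in lexicographic order, repeated to
    convergence) then removes greedy artifacts.  Fully deterministic, so
    repeated runs return the identical design.
    """
    n = grm.n
    crit = DesignCriterion("meanrel")
    chosen: list = []
    remaining = list(range(n))
    for _ in range(k):
        best_j, best_v = None, -np.inf
        for j in remaining:
            cand = chosen + [j]
            v = _score(grm, np.array(cand), crit)
            if v > best_v + 1e-15:
                best_v, best_j = v, j
        chosen.append(best_j)
        remaining.remove(best_j)

    current = sorted(chosen)
    cur_val = _score(grm, np.array(current), crit)
    improved = True
    while improved:
        improved = False
        outside = [j for j in range(n) if j not in current]
        for i in list(current):
            for j in outside:
                cand = sorted([x for x in current if x != i] + [j])
                v = _score(grm, np.array(cand), crit)
                if v > cur_val + 1e-12:
                    current, cur_val = cand, v
                    improved = True
                    break
            if improved:
                break
    return np.array(current)


def _ga(grm: Grm, k: int, crit: DesignCriterion, cfg: GaConfig):
    n = grm.n
    rng = np.random.default_rng(cfg.seed)
    sign = 1.0 if crit.maximize else -1.0

    def fitness(idx):
        return sign * _score(grm, idx, crit)

    # random baseline; its best member seeds the population (elitism then
    # guarantees the GA never returns anything worse)
    baseline = [np.sort(rng.choice(n, size=k, replace=False))
                for _ in range(cfg.n_random_baseline)]
    base_fit = np.array([fitness(idx) for idx in baseline])
    pop = [baseline[int(np.argmax(base_fit))]]
    while len(pop) < cfg.population:
        pop.append(np.sort(rng.choice(n, size=k, replace=False)))
    fits = np.array([fitness(idx) for idx in pop])

    trace = []
    for gen in range(cfg.generations):
        order = np.argsort(fits)[::-1]
        elite = [pop[i] for i in order[: cfg.elitism]]
        new_pop = list(elite)
        while len(new_pop) < cfg.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                cand = rng.integers(0, cfg.population, size=cfg.tournament)
                parents.append(pop[cand[np.argmax(fits[cand])]])
            # uniform crossover on membership masks, repaired to size k
            mask = np.zeros(n, bool)
            a = np.zeros(n, bool)
            b = np.zeros(n, bool)
            a[parents[0]] = True
            b[parents[1]] = True
            take_a = rng.random(n) < 0.5
            mask = np.where(take_a, a, b)
            sel = np.where(mask)[0]
            if len(sel) > k:
                sel = rng.choice(sel, size=k, replace=False)
            elif len(sel) < k:
                extra = rng.choice(np.where(~mask)[0], size=k - len(sel),
                                   replace=False)
                sel = np.concatenate([sel, extra])
            # exchange mutation
            sel_mask = np.zeros(n, bool)
            sel_mask[sel] = True
            n_mut = rng.binomial(k, cfg.mutation_rate)
            if n_mut > 0:
                out_pool = np.where(~sel_mask)[0]
                drop = rng.choice(sel, size=n_mut, replace=False)
                add = rng.choice(out_pool, size=n_mut, replace=False)
                sel_mask[drop] = False
                sel_mask[add] = True
            new_pop.append(np.sort(np.where(sel_mask)[0]))
        pop = new_pop
        fits = np.array([fitness(idx) for idx in pop])
        trace.append(float(sign * fits.max()))

    best = pop[int(np.argmax(fits))]
    return best, trace


def optimize_training_set(grm: Grm, fraction: float, crit: DesignCriterion,
                          search_cfg: Optional[GaConfig] = None,
                          method: str = "auto") -> TrainingDesign:
    """Select ceil(fraction * n) training accessions under a design criterion.

    ``method``: "auto" (greedy for meanrel, GA for cdmean/pevmean, random
    draw for random), or "exhaustive" to enumerate every subset (small
    panels only).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = grm.n
    k = int(np.ceil(fraction * n))
    if k >= n:
        raise ValueError("fraction leaves an empty validation set")
    cfg = search_cfg or GaConfig()
    trace: list = []

    if crit.name == "random":
        rng = np.random.default_rng(cfg.seed)
        idx = np.sort(rng.choice(n, size=k, replace=False))
        value = float("nan")
    elif method == "exhaustive":
        sign = 1.0 if crit.maximize else -1.0
        best, best_v = None, -np.inf
        for comb in itertools.combinations(range(n), k):
            v = sign * _score(grm, np.array(comb), crit)
            if v > best_v + 1e-15:
                best_v, best = v, np.array(comb)
        idx, value = best, sign * best_v
    elif crit.name == "meanrel":
        # deterministic either way: exact enumeration when the design space
        # is small, greedy + swap refinement otherwise
        import math
        if math.comb(n, k) <= 50_000:
            best, best_v = None, -np.inf
            for comb in itertools.combinations(range(n), k):
                v = _score(grm, np.array(comb), crit)
                if v > best_v + 1e-15:
                    best_v, best = v, np.array(comb)
            idx, value = best, best_v
        else:
            idx = _greedy_meanrel(grm, k)
            value = _score(grm, idx, crit)
    else:
        idx, trace = _ga(grm, k, crit, cfg)
        value = _score(grm, idx, crit)

    ids = np.array(grm.accession_ids, dtype=object)
    mask = np.zeros(n, bool)
    mask[idx] = True
    return TrainingDesign(
        training_ids=list(ids[mask]),
        validation_ids=list(ids[~mask]),
        criterion=crit.name,
        value=value,
        trace=trace,
    )


def svd_reduce(g: GenotypeMatrix, n_components: int):
    """Accession scores on the top singular vectors of the centered dosages.

    Optional compatibility mode: design criteria can be computed on the
    kinship implied by the scores.  Returns (scores, components,
    singular_values); if the matrix rank is below ``n_components`` the
    available components are returned with a warning.
    """
    X = np.asarray(g.dosage, float)
    if np.isnan(X).any():
        raise ValueError("impute missing dosages before SVD reduction")
    Xc = X - X.mean(axis=0)
    if n_components > min(Xc.shape):
        raise ValueError("n_components exceeds min(n_accessions, n_snps)")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0)
    rank = int((s > tol).sum())
    r = min(n_components, rank)
    if r < n_components:
        warnings.warn(
            f"rank {rank} < requested {n_components}; returning {r} components",
            stacklevel=2,
        )
    scores = U[:, :r] * s[:r]
    return scores, Vt[:r], s[:r]
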