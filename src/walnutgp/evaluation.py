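"""Cross-validation engine: density ladders, repeated partitions, accuracy.

Prediction accuracy (PA) is the Pearson correlation between predicted and
observed (adjusted) phenotypes in the held-out validation set.  Repetitions
are repeated random splits (not k-fold); an optimized partition mode routes
the split through the training-set design criteria instead.

SNP-density rungs keep the "top" fraction of markers ranked by variance:
either the estimated per-marker variance contribution u_j^2 * Var(x_j) from
an rrBLUP fit (effect_variance) or the expected genotype variance
2 p_j (1 - p_j) (genotype_variance).  By default the ranking is recomputed
inside each training partition so the hold-out never leaks into marker
selection; ``rank_on_all=True`` reproduces the simpler protocol of ranking
once on the full panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gp_models import ModelSpec, RidgeBLUP
from .io_formats import GenotypeMatrix
from .training_optim import (
    DesignCriterion,
    GaConfig,
    optimize_training_set,
    vanraden_grm,
)

__all__ = [
    "CvScheme",
    "SnpSetLadder",
    "CvResult",
    "prediction_accuracy",
    "rank_snps_by_variance",
    "run_cv",
    "run_ladder",
    "gain_percent",
    "round_half_away",
]


@dataclass
class CvScheme:
    train_fraction: float = 0.80
    n_repetitions: int = 10
    partition_mode: str = "random"          # or "optimized"
    criterion: Optional[str] = None         # cdmean / pevmean / meanrel
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")
        if self.partition_mode not in ("random", "optimized"):
            raise ValueError("partition_mode must be 'random' or 'optimized'")
        if self.partition_mode == "optimized" and self.criterion is None:
            raise ValueError("optimized partitions need a criterion")


@dataclass
class SnpSetLadder:
    """Ordered fractions of the panel to retain, largest first."""

    fractions: tuple = (1.0, 0.5, 0.1, 0.01, 0.001, 0.0001)
    ranking_statistic: str = "effect_variance"

    def __post_init__(self):
        fr = tuple(self.fractions)
        if any(b >= a for a, b in zip(fr, fr[1:])):
            raise ValueError("ladder fractions must be strictly decreasing")
        if fr[0] > 1.0 or fr[-1] <= 0.0:
            raise ValueError("fractions must lie in (0, 1]")
        self.fractions = fr

    def rung_sizes(self, n_snps: int) -> dict:
        return {f: max(1, int(round(f * n_snps))) for f in self.fractions}


@dataclass
class CvResult:
    key: dict
    accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.accuracies))

    @property
    def sd(self) -> float:
        vals = self.accuracies[np.isfinite(self.accuracies)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.accuracies)))


def prediction_accuracy(predicted, observed) -> float:
    """Pearson correlation between predictions and held-out observations.

    Undefined (NaN, with a warning) when either vector is constant.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    if len(predicted) < 3:
        raise ValueError("need at least 3 pairs for a meaningful correlation")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        warnings.warn("constant vector: prediction accuracy undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])


def _tie_break_order(snps: pd.DataFrame, score: np.ndarray) -> np.ndarray:
    """Descending score, ties broken by (chromosome, position)."""
    chrom = snps["chromosome"].astype(str).to_numpy()
    # numeric chromosome labels sort numerically, others lexically after
    num = pd.to_numeric(snps["chromosome"], errors="coerce")
    chrom_key = np.where(num.notna(), num.fillna(np.inf), np.inf)
    pos = snps["position"].to_numpy()
    return np.lexsort((pos, chrom, chrom_key, -score))


def rank_snps_by_variance(g: GenotypeMatrix, y_train: Optional[pd.Series],
                          statistic: str = "effect_variance") -> list:
    """Rank SNP ids by their variance contribution, best first.

    ``effect_variance`` fits rrBLUP on the supplied training data and ranks
    by u_j^2 * Var(x_j); ``genotype_variance`` ranks by 2 p (1 - p) and
    needs no phenotype.
    """
    if statistic == "genotype_variance":
        p = np.nanmean(g.dosage, axis=0) / 2.0
        score = 2.0 * p * (1.0 - p)
    elif statistic == "effect_variance":
        if y_train is None:
            raise ValueError("effect_variance ranking needs training phenotypes")
        common = [a for a in g.accession_ids if a in y_train.index]
        sub = g.subset_accessions(common)
        est = RidgeBLUP().fit(sub.dosage, y_train.loc[common].to_numpy(float))
        score = est.marker_effects_**2 * sub.dosage.var(axis=0)
    else:
        raise ValueError(f"unknown ranking statistic {statistic!r}")
    order = _tie_break_order(g.snps, score)
    return [g.snps.loc[i, "snp_id"] for i in order]


def _partition(g, y_index, scheme, rep, grm, opt_lambda, ga_config):
    """Training/validation accession ids for one repetition."""
    phenotyped = [a for a in g.accession_ids if a in y_index]
    n = len(phenotyped)
    n_train = int(np.ceil(scheme.train_fraction * n))
    if n - n_train < 3:
        raise ValueError(
            f"hold-out of {n - n_train} accessions is too small (< 3)"
        )
    rep_seed = int(
        np.random.SeedSequence((scheme.seed, rep)).generate_state(1)[0] % (2**31)
    )
    if scheme.partition_mode == "random":
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(n)
        train = [phenotyped[i] for i in perm[:n_train]]
        valid = [phenotyped[i] for i in perm[n_train:]]
        return train, valid, rep_seed
    sub_grm_ids = set(grm.accession_ids)
    if set(phenotyped) - sub_grm_ids:
        raise ValueError("GRM does not cover all phenotyped accessions")
    crit = DesignCriterion(scheme.criterion, ridge_lambda=opt_lambda)
    cfg = ga_config or GaConfig()
    cfg = GaConfig(**{**cfg.__dict__, "seed": rep_seed})
    design = optimize_training_set(grm, scheme.train_fraction, crit, cfg)
    return design.training_ids, design.validation_ids, rep_seed


def run_cv(g: GenotypeMatrix, y, model_spec: ModelSpec, scheme: CvScheme,
           snp_fraction: float = 1.0,
           ranking_statistic: str = "effect_variance",
           rank_on_all: bool = False,
           ga_config: Optional[GaConfig] = None,
           trait_id: Optional[str] = None) -> CvResult:
    """Repeated-split cross-validation of one model at one ladder rung.

    ``y`` is a Series of adjusted phenotypes indexed by accession (or an
    AdjustedPhenotype).  Fully reproducible under ``scheme.seed``: partition,
    marker ranking, and sampler seeds all derive from it.
    """
    if hasattr(y, "values") and hasattr(y, "h2"):
        y = y.values
    if not isinstance(y, pd.Series):
        raise TypeError("y must be a Series or AdjustedPhenotype")
    if not (0.0 < snp_fraction <= 1.0):
        raise ValueError("snp_fraction must lie in (0, 1]")

    grm = None
    opt_lambda = 1.0
    if scheme.partition_mode == "optimized":
        phenotyped = [a for a in g.accession_ids if a in y.index]
        grm = vanraden_grm(g.subset_accessions(phenotyped))
        pre = RidgeBLUP().fit(
            g.subset_accessions(phenotyped).dosage,
            y.loc[phenotyped].to_numpy(float),
        )
        opt_lambda = pre.lambda_ if np.isfinite(pre.lambda_) else 1.0

    k = max(1, int(round(snp_fraction * g.n_snps)))
    ranked_all = None
    if snp_fraction < 1.0 and rank_on_all:
        ranked_all = rank_snps_by_variance(
            g, y if ranking_statistic == "effect_variance" else None,
            ranking_statistic,
        )

    accs = np.empty(scheme.n_repetitions)
    for rep in range(scheme.n_repetitions):
        train_ids, valid_ids, rep_seed = _partition(
            g, y.index, scheme, rep, grm, opt_lambda, ga_config
        )
        g_train = g.subset_accessions(train_ids)
        if snp_fraction < 1.0:
            ranked = ranked_all if ranked_all is not None else \
                rank_snps_by_variance(
                    g_train,
                    y if ranking_statistic == "effect_variance" else None,
                    ranking_statistic,
                )
            keep = ranked[:k]
            g_fit = g_train.subset_snp_ids(keep)
            g_val = g.subset_accessions(valid_ids).subset_snp_ids(keep)
        else:
            g_fit = g_train
            g_val = g.subset_accessions(valid_ids)
        est = model_spec.build(seed=rep_seed).fit(
            g_fit.dosage, y.loc[train_ids].to_numpy(float)
        )
        pred = est.predict(g_val.dosage)
        obs = y.loc[valid_ids].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            accs[rep] = prediction_accuracy(pred, obs)
        if not np.isfinite(accs[rep]):
            warnings.warn(
                f"repetition {rep}: constant vector, accuracy recorded as "
                "missing", stacklevel=2,
            )
    key = dict(
        trait=trait_id, model=model_spec.model_name, snp_fraction=snp_fraction,
        train_fraction=scheme.train_fraction,
        optimizer=scheme.criterion if scheme.partition_mode == "optimized"
        else "random",
    )
    return CvResult(key, accs)


def run_ladder(g, y, model_spec, scheme, ladder: SnpSetLadder,
               rank_on_all=False, trait_id=None) -> dict:
    """Run the cross-validation at every rung of a SNP-density ladder."""
    out = {}
    for f in ladder.fractions:
        out[f] = run_cv(
            g, y, model_spec, scheme, snp_fraction=f,
            ranking_statistic=ladder.ranking_statistic,
            rank_on_all=rank_on_all, trait_id=trait_id,
        )
    return out


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (table convention)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def gain_percent(pa_optimized: float, pa_random: float) -> float:
    """Percentage gain of an optimized design over the random baseline:
    (optimized - random) / random * 100.  Undefined (NaN) at pa_random = 0."""
    if pa_random == 0:
        warnings.warn("gain undefined for zero baseline accuracy", stacklevel=2)
        return float("nan")
    return float((pa_optimized - pa_random) / pa_random * 100.0)
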