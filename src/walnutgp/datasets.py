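"""Bundled reference tables from a walnut core-collection study.

Two small summary tables for 25 phenology and nut-quality traits evaluated
on a 170-accession walnut core collection:

* per-trait GWAS association summaries (significant SNP counts, top and
  cumulative top-3 explained-variance percentages) together with the mean
  genomic-prediction accuracy (rrBLUP, ~3600 SNPs, 80% training) and the
  selection method each trait was ultimately recommended for;
* per-trait mean ± SD prediction accuracies under random and optimized
  (CDmean, PEVmean, MeanRel) training-set designs, with the percentage
  gains as printed in the study's summary table.

These serve as worked-example inputs for the decision framework and for
the gain arithmetic; they are observational summaries, not simulated data.
"""

from importlib import resources

import numpy as np
import pandas as pd

from .decision_framework import TraitGwasSummary

__all__ = [
    "load_decision_inputs",
    "load_decision_summaries",
    "load_training_optimization",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("walnutgp.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_decision_inputs() -> pd.DataFrame:
    """Per-trait GWAS summaries + mean GP accuracy for 25 walnut traits.

    Columns: trait_id, n_significant_snps, top_snp_pev, cum_top3_pev,
    mean_gp_accuracy, reported_method.  PEV columns are NaN for traits
    without significant associations.
    """
    return _read("walnut_decision_inputs.csv")


def load_decision_summaries():
    """The same table as (summaries, accuracies) ready for decision_table."""
    df = load_decision_inputs()
    summaries = []
    accuracies = {}
    for _, r in df.iterrows():
        has = int(r["n_significant_snps"]) > 0
        summaries.append(
            TraitGwasSummary(
                trait_id=r["trait_id"],
                n_significant_snps=int(r["n_significant_snps"]),
                top_snp_pev=float(r["top_snp_pev"]) if has else None,
                cum_top3_pev=float(r["cum_top3_pev"]) if has else None,
            )
        )
        accuracies[r["trait_id"]] = float(r["mean_gp_accuracy"])
    return summaries, accuracies


def load_training_optimization() -> pd.DataFrame:
    """Mean ± SD accuracies per training-set design for 25 walnut traits.

    Columns: trait_id, trait_group, pa_<design>_mean, pa_<design>_sd for
    design in {random, cdmean, pevmean, meanrel}, and the printed integer
    percentage gains of each optimized design over random.
    """
    df = _read("walnut_training_optimization.csv")
    df["gain_meanrel_printed"] = df["gain_meanrel_printed"].astype(float)
    return df
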