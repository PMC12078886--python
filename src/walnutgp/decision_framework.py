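"""MAS-vs-GS recommendation rule from GWAS summaries and GP accuracy.

For each trait the rule combines two signals:

* **MAS** (marker-assisted selection) is suggested when a handful of GWAS
  hits carry the trait: by default, when the cumulative percentage of
  explained variance (PEV) of the top (at most three) significant SNPs
  exceeds 30%.
* **GS** (genomic selection) is suggested when the mean genomic-prediction
  accuracy exceeds 0.40.

Both thresholds are strict inequalities and configurable.  A trait with no
significant SNP cannot get a MAS recommendation.  An alternative literal
reading of the rule ("fewer than three SNPs explain a PEV > 30%") is
available via ``rule="literal"``; the cumulative reading is the default
because it is self-consistent across edge cases (a trait tagged by exactly
three strong SNPs still qualifies for MAS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TraitGwasSummary",
    "TraitDecision",
    "decide_method",
    "decision_table",
]

LABELS = ("MAS/GS", "MAS", "GS", "No method")


@dataclass
class TraitGwasSummary:
    """Per-trait GWAS association summary feeding the decision rule."""

    trait_id: str
    n_significant_snps: int
    top_snp_pev: Optional[float] = None      # % explained variance, best SNP
    cum_top3_pev: Optional[float] = None     # % cumulative, top <= 3 SNPs

    def __post_init__(self):
        if self.n_significant_snps < 0:
            raise ValueError("negative SNP count")
        if self.n_significant_snps == 0:
            if self.top_snp_pev is not None or self.cum_top3_pev is not None:
                raise ValueError("PEV given without significant SNPs")
        else:
            for v in (self.top_snp_pev, self.cum_top3_pev):
                if v is None or not (0.0 <= v <= 100.0):
                    raise ValueError("PEV percentages must lie in [0, 100]")
            if self.cum_top3_pev < self.top_snp_pev - 1e-9:
                raise ValueError("cumulative top-3 PEV below top-SNP PEV")


@dataclass
class TraitDecision:
    trait_id: str
    mean_gp_accuracy: float
    mas_flag: bool
    gs_flag: bool

    @property
    def label(self) -> str:
        if self.mas_flag and self.gs_flag:
            return "MAS/GS"
        if self.mas_flag:
            return "MAS"
        if self.gs_flag:
            return "GS"
        return "No method"


def decide_method(s: TraitGwasSummary, mean_pa: float,
                  mas_pev_threshold: float = 30.0,
                  gs_accuracy_threshold: float = 0.40,
                  rule: str = "cumulative") -> TraitDecision:
    """Apply the MAS/GS rule to one trait (strict inequalities)."""
    if not (-1.0 <= mean_pa <= 1.0):
        raise ValueError("mean accuracy must lie in [-1, 1]")
    if rule == "cumulative":
        mas = s.cum_top3_pev is not None and s.cum_top3_pev > mas_pev_threshold
    elif rule == "literal":
        mas = (
            0 < s.n_significant_snps < 3
            and s.cum_top3_pev is not None
            and s.cum_top3_pev > mas_pev_threshold
        )
    else:
        raise ValueError(f"unknown rule {rule!r}")
    gs = mean_pa > gs_accuracy_threshold
    return TraitDecision(s.trait_id, mean_pa, mas, gs)


def decision_table(summaries, accuracies, **kwargs):
    """Decide for every trait; returns (DataFrame, counts per label).

    ``summaries`` is an iterable of :class:`TraitGwasSummary`;
    ``accuracies`` maps trait_id to mean GP accuracy.  Traits with a
    summary but no accuracy are reported as incomplete rows (no label).
    """
    rows = []
    for s in summaries:
        if s.trait_id not in accuracies or accuracies[s.trait_id] is None \
                or not np.isfinite(accuracies[s.trait_id]):
            warnings.warn(f"trait {s.trait_id!r}: no accuracy available",
                          stacklevel=2)
            rows.append(dict(
                trait_id=s.trait_id,
                n_significant_snps=s.n_significant_snps,
                top_snp_pev=s.top_snp_pev, cum_top3_pev=s.cum_top3_pev,
                mean_gp_accuracy=np.nan, mas=None, gs=None, label=None,
            ))
            continue
        d = decide_method(s, float(accuracies[s.trait_id]), **kwargs)
        rows.append(dict(
            trait_id=s.trait_id,
            n_significant_snps=s.n_significant_snps,
            top_snp_pev=s.top_snp_pev, cum_top3_pev=s.cum_top3_pev,
            mean_gp_accuracy=d.mean_gp_accuracy,
            mas=d.mas_flag, gs=d.gs_flag, label=d.label,
        ))
    table = pd.DataFrame(rows)
    counts = {lab: 0 for lab in LABELS}
    if len(table):
        for lab, c in table["label"].value_counts().items():
            if lab is not None:
                counts[lab] = int(c)
    return table, counts
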