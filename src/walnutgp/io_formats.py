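"""Genotype and phenotype containers, HapMap I/O, and SNP quality control.

Genotypes are held as an accessions × SNPs allele-dosage matrix
(:class:`GenotypeMatrix`).  Dosage counts copies of the *alternate* allele,
defined as the second allele listed in the HapMap ``alleles`` field; the
prediction layer centers marker columns, so this convention only fixes the
sign of estimated effects.  Positions are 1-based and calls are taken as
reported (no strand flipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "HapMapFormatError",
    "EmptyPanelError",
    "read_hapmap",
    "write_hapmap",
    "apply_qc",
    "impute_missing",
    "read_phenotypes",
    "write_phenotypes",
]

#: canonical HapMap metadata columns preceding the sample columns
HAPMAP_COLUMNS = (
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
)

#: accepted missing-genotype codes (common HapMap dialects)
MISSING_CODES = frozenset({"NN", "--", "N", "??"})


class HapMapFormatError(ValueError):
    """Raised when a genotype file deviates from the HapMap table layout."""


class EmptyPanelError(ValueError):
    """Raised when quality control removes every SNP."""


@dataclass
class GenotypeMatrix:
    """Accessions × SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    accession_ids : list of str
        Ordered, unique accession labels (rows of ``dosage``).
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id``, ``chromosome``, ``position``,
        ``allele_ref``, ``allele_alt``, ``call_rate``, ``maf``.
    dosage : ndarray of shape (n_accessions, n_snps)
        Count of the alternate allele in {0, 1, 2}; ``nan`` marks missing
        calls.  After imputation entries may be real-valued column means.
    """

    accession_ids: list
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.accession_ids = list(self.accession_ids)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession identifiers")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate SNP identifier: {dup!r}")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accession_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.snps)} SNPs"
            )
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list:
        return self.snps["snp_id"].tolist()

    def subset_snps(self, indices) -> "GenotypeMatrix":
        """Return a new matrix restricted to the SNP columns in ``indices``."""
        indices = np.asarray(indices)
        return GenotypeMatrix(
            accession_ids=self.accession_ids,
            snps=self.snps.iloc[indices].reset_index(drop=True),
            dosage=self.dosage[:, indices].copy(),
        )

    def subset_snp_ids(self, snp_ids) -> "GenotypeMatrix":
        pos = pd.Index(self.snps["snp_id"])
        idx = pos.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs not in panel: {missing[:5]}")
        return self.subset_snps(idx)

    def subset_accessions(self, ids) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            rows = [lookup[a] for a in ids]
        except KeyError as exc:
            raise KeyError(f"accession not in panel: {exc.args[0]!r}") from None
        return GenotypeMatrix(
            accession_ids=list(ids),
            snps=self.snps.copy(),
            dosage=self.dosage[rows].copy(),
        )

    def observed_maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency computed from the dosage columns."""
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p_alt, 1.0 - p_alt)

    def observed_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def refresh_snp_stats(self) -> "GenotypeMatrix":
        """Recompute the stored per-SNP ``call_rate`` and ``maf`` columns."""
        snps = self.snps.copy()
        snps["call_rate"] = self.observed_call_rate()
        snps["maf"] = self.observed_maf()
        return GenotypeMatrix(self.accession_ids, snps, self.dosage)


@dataclass
class PhenotypeTable:
    """Long-format accession × trait × year phenotype records.

    ``data`` has columns ``accession_id``, ``trait_id``, ``year``, ``value``;
    at most one record per (accession, trait, year).
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = ["accession_id", "trait_id", "year", "value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        key = ["accession_id", "trait_id", "year"]
        if self.data.duplicated(subset=key).any():
            bad = self.data[self.data.duplicated(subset=key)].iloc[0]
            raise ValueError(
                "duplicate phenotype record for "
                f"({bad['accession_id']}, {bad['trait_id']}, {bad['year']})"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def trait_ids(self) -> list:
        return sorted(self.data["trait_id"].unique().tolist())

    def for_trait(self, trait_id) -> pd.DataFrame:
        return self.data[self.data["trait_id"] == trait_id].copy()

    def n_years(self, trait_id) -> int:
        return self.for_trait(trait_id)["year"].nunique()

    def unmatched_accessions(self, g: GenotypeMatrix) -> list:
        """Accessions phenotyped but absent from the genotype panel."""
        known = set(g.accession_ids)
        return sorted(set(self.data["accession_id"]) - known)


# ---------------------------------------------------------------------------
# HapMap I/O


def _parse_call(call: str, ref: str, alt: str, snp_id: str) -> float:
    if call in MISSING_CODES:
        return np.nan
    if len(call) != 2:
        raise HapMapFormatError(f"SNP {snp_id!r}: malformed call {call!r}")
    d = 0
    for a in call:
        if a == alt:
            d += 1
        elif a != ref:
            raise HapMapFormatError(
                f"SNP {snp_id!r}: allele {a!r} not in {{{ref},{alt}}} (non-biallelic call)"
            )
    return float(d)


def read_hapmap(path, missing_codes=None) -> GenotypeMatrix:
    """Read a HapMap tab-separated genotype table.

    The first 11 columns must be the standard HapMap metadata columns
    (``rs#``, ``alleles``, ``chrom``, ``pos``, ``strand``, ...); the remaining
    columns are samples with two-letter diploid calls (``AA``, ``AG``) or a
    missing code.  Dosage counts the second allele of the ``alleles`` field.
    """
    missing = MISSING_CODES if missing_codes is None else frozenset(missing_codes)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 12:
        raise HapMapFormatError(
            f"expected >= 12 columns (11 metadata + samples), got {df.shape[1]}"
        )
    for i, expected in enumerate(HAPMAP_COLUMNS):
        got = df.columns[i]
        if got.strip().lower() != expected.lower():
            raise HapMapFormatError(
                f"column {i} is {got!r}, expected {expected!r}"
            )
    sample_ids = list(df.columns[11:])
    n, m = len(sample_ids), len(df)
    dosage = np.empty((n, m), dtype=float)
    meta = []
    calls = df.iloc[:, 11:].to_numpy(dtype=str)
    for j in range(m):
        snp_id = df.iloc[j, 0]
        alleles = str(df.iloc[j, 1])
        parts = alleles.split("/")
        if len(parts) != 2 or parts[0] == parts[1]:
            raise HapMapFormatError(
                f"SNP {snp_id!r}: alleles field {alleles!r} is not biallelic"
            )
        ref, alt = parts
        col = np.array(
            [np.nan if c in missing else _parse_call(c, ref, alt, snp_id)
             for c in calls[j]],
            dtype=float,
        )
        dosage[:, j] = col
        n_obs = np.isfinite(col).sum()
        call_rate = n_obs / n if n else 0.0
        if n_obs:
            p_alt = np.nansum(col) / (2 * n_obs)
            maf = min(p_alt, 1 - p_alt)
        else:
            maf = np.nan
        meta.append(
            dict(
                snp_id=snp_id,
                chromosome=df.iloc[j, 2],
                position=int(df.iloc[j, 3]),
                allele_ref=ref,
                allele_alt=alt,
                call_rate=call_rate,
                maf=maf,
            )
        )
    return GenotypeMatrix(sample_ids, pd.DataFrame(meta), dosage)


def write_hapmap(g: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as a HapMap table.

    Requires integral dosages (0/1/2 or missing); imputed real-valued entries
    cannot be represented as diploid calls.
    """
    finite = g.dosage[np.isfinite(g.dosage)]
    if not np.all(finite == np.round(finite)):
        raise ValueError("cannot write non-integral (imputed) dosages to HapMap")
    rows = []
    for j in range(g.n_snps):
        rec = g.snps.iloc[j]
        ref, alt = rec["allele_ref"], rec["allele_alt"]
        code = {0: ref + ref, 1: ref + alt, 2: alt + alt}
        calls = [
            "NN" if not np.isfinite(d) else code[int(d)] for d in g.dosage[:, j]
        ]
        rows.append(
            [rec["snp_id"], f"{ref}/{alt}", rec["chromosome"], int(rec["position"]),
             "+", "NA", "NA", "NA", "NA", "NA", "NA"] + calls
        )
    out = pd.DataFrame(rows, columns=list(HAPMAP_COLUMNS) + list(g.accession_ids))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control and imputation


def apply_qc(g: GenotypeMatrix, min_call_rate: float = 0.90,
             min_maf: float = 0.05):
    """Filter SNPs on call rate and minor-allele frequency.

    Retains exactly the SNPs with ``call_rate > min_call_rate`` **and**
    ``maf > min_maf`` (strict inequalities, matching the convention
    "call rate > 90%, MAF > 5%").  Accessions are untouched.

    Returns
    -------
    (GenotypeMatrix, pandas.DataFrame)
        The filtered panel and a QC report with one row per input SNP
        (``snp_id``, ``call_rate``, ``maf``, ``kept``, ``reason``).
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("QC thresholds must lie in [0, 1]")
    call_rate = g.observed_call_rate()
    maf = g.observed_maf()
    ok_cr = call_rate > min_call_rate
    ok_maf = np.nan_to_num(maf, nan=0.0) > min_maf
    kept = ok_cr & ok_maf
    reason = np.where(
        kept, "",
        np.where(~ok_cr & ~ok_maf, "call_rate;maf",
                 np.where(~ok_cr, "call_rate", "maf")),
    )
    report = pd.DataFrame(
        dict(snp_id=g.snps["snp_id"], call_rate=call_rate, maf=maf,
             kept=kept, reason=reason)
    )
    if not kept.any():
        raise EmptyPanelError(
            f"QC removed all {g.n_snps} SNPs "
            f"(min_call_rate={min_call_rate}, min_maf={min_maf})"
        )
    filtered = g.subset_snps(np.where(kept)[0]).refresh_snp_stats()
    return filtered, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean of the observed calls.

    Observed entries are untouched, so each column's observed mean is
    preserved.  A fully missing column is an error (cannot occur after QC
    with a positive call-rate threshold).
    """
    dosage = g.dosage.copy()
    miss = np.isnan(dosage)
    if not miss.any():
        return GenotypeMatrix(g.accession_ids, g.snps.copy(), dosage)
    fully = miss.all(axis=0)
    if fully.any():
        bad = g.snps.loc[np.where(fully)[0][0], "snp_id"]
        raise ValueError(f"SNP {bad!r} has no observed calls; cannot impute")
    col_mean = np.nanmean(dosage, axis=0)
    jj = np.where(miss)[1]
    dosage[miss] = col_mean[jj]
    return GenotypeMatrix(g.accession_ids, g.snps.copy(), dosage)


# ---------------------------------------------------------------------------
# Phenotype CSV I/O


def read_phenotypes(path) -> PhenotypeTable:
    """Read a long-format phenotype CSV (accession_id, trait_id, year, value)."""
    df = pd.read_csv(path)
    df["year"] = df["year"].astype(int)
    df["value"] = df["value"].astype(float)
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path) -> None:
    p.data.to_csv(path, index=False)
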