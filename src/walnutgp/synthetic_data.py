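"""Synthetic core-collection genotypes and multi-year phenotypes.

The generator emulates a walnut-like diversity panel: ~170 diploid
accessions, 16 chromosomes, biallelic SNPs with a minor-allele-frequency
floor, observed heterozygosity near 0.3, and within-chromosome linkage
disequilibrium that decays with physical distance.  Haplotypes come from a
first-order autoregressive latent-Gaussian process along each chromosome
(haplotype-block style), not a coalescent: adjacent markers share a latent
correlation exp(-ld_decay_rate * distance), which after thresholding at the
allele frequency yields dosage correlations that fall off with distance.

Panel haplotypes are mosaics of a small founder-haplotype pool: each
chromosome is copied founder-by-founder with occasional recombination
switches, so accessions share identical-by-descent segments.  This is what
gives the panel the two properties genomic prediction feeds on — genomic
relatedness between accessions and marker-QTL association — without a full
coalescent simulation.

Phenotypes are generated under the same year + genotype model the
adjustment stage fits::

    P_ik = mu + Y_i + g_k + e_ik

with the genetic value ``g_k`` a sum of major-QTL effects (scaled to hit
per-QTL explained-variance targets) and a polygenic tail, and the residual
variance set from the broad-sense-heritability target
H^2 = sigma_G^2 / (sigma_G^2 + sigma_eps^2 / n_years).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import GenotypeMatrix, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "TraitArchitecture",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
]

_NUCS = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """Panel-level simulation settings.

    Defaults are a desk-scale mirror of a 170-accession core collection
    genotyped on a dense array: 10,000 SNPs over 16 chromosomes, so the 1%
    ladder rung is ~100 SNPs and ladder *proportions* are preserved.
    """

    n_accessions: int = 170
    n_chromosomes: int = 16
    n_snps: int = 10_000
    chrom_length_bp: int = 1_000_000
    ld_decay_rate: float = 2e-5   # per-bp founder-pool latent correlation decay
    n_founder_haplotypes: int = 32
    recomb_rate: float = 3e-6     # per-bp switch rate of the copying process
    maf_floor: float = 0.05
    target_heterozygosity: float = 0.30
    seed: int = 0

    def validate(self):
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must lie in (0, 0.5)")
        f = self.maf_floor
        lo = 2 * f * (1 - f)  # all SNPs at the floor
        hi = 0.5              # all SNPs at p = 0.5
        if not (lo < self.target_heterozygosity < hi):
            raise ValueError(
                f"target_heterozygosity {self.target_heterozygosity} unreachable "
                f"with maf_floor {f} (feasible range ({lo:.3f}, {hi:.3f}))"
            )


@dataclass
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    ``n_qtl`` causal SNPs in total; the first ``len(qtl_pev_targets)`` are
    major loci scaled so each explains the stated fraction of the variance of
    genotype-mean phenotypes (the scale on which GWAS "percent explained
    variance" is reported); the remainder form a polygenic tail.  An empty
    target list gives a fully polygenic trait.
    """

    trait_id: str
    n_qtl: int = 30
    qtl_pev_targets: tuple = ()
    h2_broad: float = 0.9
    n_years: int = 2
    year_effects: tuple = (0.0, 0.0)
    mu: float = 10.0
    first_year: int = 2017

    def validate(self, n_snps: int):
        if not (0.0 <= self.h2_broad <= 1.0):
            raise ValueError("h2_broad must lie in [0, 1]")
        if self.n_years not in (1, 2):
            raise ValueError("n_years must be 1 or 2")
        if len(self.year_effects) != self.n_years:
            raise ValueError("year_effects length must equal n_years")
        if len(self.qtl_pev_targets) > self.n_qtl:
            raise ValueError("more PEV targets than QTL")
        if self.n_qtl > n_snps:
            raise ValueError("more QTL than SNPs in the panel")
        s = float(sum(self.qtl_pev_targets))
        if s > 1.0:
            raise ValueError(f"qtl_pev_targets sum to {s} > 1")
        if self.h2_broad > 0 and s > self.h2_broad + 1e-12:
            raise ValueError(
                "sum of PEV targets exceeds the broad-sense heritability: "
                "major loci cannot explain more variance than all genetics"
            )
        if self.h2_broad == 0 and (self.qtl_pev_targets or False):
            raise ValueError("h2_broad = 0 is incompatible with PEV targets")


@dataclass
class GroundTruth:
    """Stored truth for one simulated trait (acceptance oracle)."""

    trait_id: str
    causal_snp_ids: list
    effects: np.ndarray                 # aligned with causal_snp_ids
    genetic_values: pd.Series           # indexed by accession_id
    realized_sigma2_G: float
    realized_sigma2_eps: float
    n_years: int
    realized_qtl_pev: np.ndarray        # fraction per targeted major QTL

    @property
    def realized_h2(self) -> float:
        vg, ve = self.realized_sigma2_G, self.realized_sigma2_eps
        if vg + ve == 0:
            return float("nan")
        return vg / (vg + ve / self.n_years)

    def gwas_summary(self, min_pev_percent: float = 1.0) -> dict:
        """Summarize major loci the way a GWAS table would.

        Returns trait_id, the count of loci whose realized explained
        variance exceeds ``min_pev_percent`` (in %), the top locus' PEV%,
        and the cumulative PEV% of the top three.
        """
        pev = np.sort(self.realized_qtl_pev * 100.0)[::-1]
        sig = pev[pev > min_pev_percent]
        return dict(
            trait_id=self.trait_id,
            n_significant_snps=int(sig.size),
            top_snp_pev=float(sig[0]) if sig.size else None,
            cum_top3_pev=float(sig[:3].sum()) if sig.size else None,
        )


# ---------------------------------------------------------------------------
# Genotypes


def _beta_b_for_het(maf_floor: float, target_het: float) -> float:
    """Shape b of Beta(1, b) for the minor-allele frequency u in
    [maf_floor, 0.5] such that E[2p(1-p)] matches the heterozygosity target."""
    f, w = maf_floor, 0.5 - maf_floor

    def expected_het(b):
        eu = 1.0 / (1.0 + b)
        eu2 = 2.0 / ((1.0 + b) * (2.0 + b))
        ep = f + w * eu
        ep2 = f * f + 2 * f * w * eu + w * w * eu2
        return 2.0 * (ep - ep2)

    lo, hi = 1e-3, 200.0
    if not (expected_het(hi) <= target_het <= expected_het(lo)):
        raise ValueError("heterozygosity target outside Beta(1, b) family range")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_het(mid) > target_het:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ar1_latent(rng, n_hap: int, positions: np.ndarray, rate: float) -> np.ndarray:
    """Latent Gaussian field, AR(1) along the chromosome, for each haplotype."""
    m = positions.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        r = np.exp(-rate * np.diff(positions).astype(float))
        noise = rng.standard_normal((n_hap, m - 1))
        for j in range(1, m):
            rj = r[j - 1]
            z[:, j] = rj * z[:, j - 1] + np.sqrt(1.0 - rj * rj) * noise[:, j - 1]
    return z


def _mosaic_founders(rng, n_hap, m_c, n_founders, p_switch):
    """Founder index per (haplotype, SNP) under the copying process."""
    idx = np.empty((n_hap, m_c), dtype=np.int64)
    for h in range(n_hap):
        events = rng.random(m_c) < p_switch
        events[0] = True
        seg = np.cumsum(events) - 1
        founders = rng.integers(0, n_founders, seg[-1] + 1)
        idx[h] = founders[seg]
    return idx


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Simulate a biallelic dosage panel with LD, relatedness, and a MAF floor.

    Fully deterministic under ``cfg.seed``.  Founder haplotypes come from a
    thresholded AR(1) latent field (within-pool LD); panel haplotypes copy
    founder segments with recombination switches.  Columns whose empirical
    minor allele count falls below the floor get their founder alleles
    redrawn at a safer frequency (bounded retries), then a greedy founder
    flip enforces the floor exactly, preserving the mosaic structure.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, n_hap = cfg.n_accessions, 2 * cfg.n_accessions
    F = cfg.n_founder_haplotypes
    if F < 4:
        raise ValueError("need at least 4 founder haplotypes")
    b = _beta_b_for_het(cfg.maf_floor, cfg.target_heterozygosity)

    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1

    dosage_cols, meta = [], []
    k_min = int(np.ceil(n_hap * cfg.maf_floor))
    for c in range(cfg.n_chromosomes):
        m_c = int(per_chrom[c])
        positions = np.sort(
            rng.choice(np.arange(1, cfg.chrom_length_bp + 1), size=m_c, replace=False)
        )
        z = _ar1_latent(rng, F, positions, cfg.ld_decay_rate)
        u = cfg.maf_floor + (0.5 - cfg.maf_floor) * rng.beta(1.0, b, size=m_c)
        flip = rng.random(m_c) < 0.5          # alternate allele may be major
        p_alt = np.where(flip, 1.0 - u, u)    # alt-allele frequency
        founder_alt = z < norm.ppf(p_alt)[None, :]

        # copying process: founder mosaic per haplotype
        gaps = np.diff(positions).astype(float)
        p_switch = np.empty(m_c)
        p_switch[0] = 1.0   # placeholder; first SNP always starts a segment
        p_switch[1:] = 1.0 - np.exp(-cfg.recomb_rate * gaps)
        fidx = _mosaic_founders(rng, n_hap, m_c, F, p_switch)
        hap_alt = founder_alt[fidx, np.arange(m_c)[None, :]]

        # enforce the empirical MAF floor
        for _ in range(5):
            counts = hap_alt.sum(axis=0)
            minor = np.minimum(counts, n_hap - counts)
            bad = np.where(minor < k_min)[0]
            if bad.size == 0:
                break
            u_new = 2 * cfg.maf_floor + (0.5 - 2 * cfg.maf_floor) * rng.random(bad.size)
            p_alt[bad] = np.where(flip[bad], 1.0 - u_new, u_new)
            founder_alt[:, bad] = z[:, bad] < norm.ppf(p_alt[bad])[None, :]
            hap_alt[:, bad] = founder_alt[fidx[:, bad], bad[None, :]]
        counts = hap_alt.sum(axis=0)
        minor = np.minimum(counts, n_hap - counts)
        for j in np.where(minor < k_min)[0]:
            # flip the allele of heaviest-used majority founders until the
            # minor count clears the floor
            col = founder_alt[:, j].copy()
            usage = np.bincount(fidx[:, j], minlength=F)
            count_alt = int(col[fidx[:, j]].sum())
            minor_is_alt = count_alt <= n_hap - count_alt
            order = np.argsort(-usage)
            for f in order:
                cnt_minor = min(count_alt, n_hap - count_alt)
                if cnt_minor >= k_min:
                    break
                if col[f] != minor_is_alt:      # founder carries the major allele
                    col[f] = minor_is_alt
                    count_alt += usage[f] if minor_is_alt else -usage[f]
            founder_alt[:, j] = col
            hap_alt[:, j] = col[fidx[:, j]]
            if min(count_alt, n_hap - count_alt) < k_min:
                raise RuntimeError(
                    "could not satisfy the MAF floor after bounded retries"
                )

        dos = (hap_alt[:n, :].astype(float) + hap_alt[n:, :].astype(float))
        dosage_cols.append(dos)
        alleles = np.stack([rng.permutation(4)[:2] for _ in range(m_c)])
        for j in range(m_c):
            meta.append(
                dict(
                    snp_id=f"snp_c{c + 1}_{positions[j]}",
                    chromosome=str(c + 1),
                    position=int(positions[j]),
                    allele_ref=_NUCS[alleles[j, 0]],
                    allele_alt=_NUCS[alleles[j, 1]],
                )
            )

    dosage = np.concatenate(dosage_cols, axis=1)
    accession_ids = [f"acc{i:04d}" for i in range(1, n + 1)]
    snps = pd.DataFrame(meta)
    g = GenotypeMatrix(accession_ids, snps.assign(call_rate=1.0, maf=0.0), dosage)
    return g.refresh_snp_stats()


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_phenotypes(g: GenotypeMatrix, arch: TraitArchitecture, seed: int):
    """Simulate multi-year phenotypes with known genetic ground truth.

    Returns a :class:`PhenotypeTable` and the :class:`GroundTruth` holding
    causal SNPs, effects, per-accession genetic values, realized variance
    components (empirical, so the realized H^2 is exactly recomputable), and
    realized per-major-QTL explained-variance fractions.
    """
    arch.validate(g.n_snps)
    rng = np.random.default_rng(seed)
    n = g.n_accessions
    X = g.dosage
    if np.isnan(X).any():
        raise ValueError("impute missing dosages before simulating phenotypes")
    Xc = X - X.mean(axis=0)

    n_major = len(arch.qtl_pev_targets)
    targets = np.asarray(arch.qtl_pev_targets, dtype=float)
    causal_idx = rng.choice(g.n_snps, size=arch.n_qtl, replace=False)
    major_idx = causal_idx[:n_major]
    tail_idx = causal_idx[n_major:]

    effects = np.zeros(arch.n_qtl)
    if arch.h2_broad == 0.0:
        genetic = np.zeros(n)
        var_g = 0.0
    else:
        # target genetic variance 1; genotype-mean phenotypic variance 1/h2
        var_gm_target = 1.0 / arch.h2_broad
        # major loci: fixed-point scaling toward per-QTL PEV targets
        beta = np.zeros(n_major)
        if n_major:
            signs = rng.choice([-1.0, 1.0], size=n_major)
            col_var = Xc[:, major_idx].var(axis=0)
            if (col_var == 0).any():
                raise ValueError("monomorphic SNP drawn as major QTL")
            beta = signs * np.sqrt(targets * var_gm_target / col_var)
        # polygenic tail fills the remaining genetic variance
        tail_var_target = 1.0 - (targets * var_gm_target).sum()
        g_tail = np.zeros(n)
        u_tail = np.zeros(tail_idx.size)
        if tail_idx.size and tail_var_target > 1e-12:
            u_tail = rng.standard_normal(tail_idx.size)
            g_tail = Xc[:, tail_idx] @ u_tail
            sd = g_tail.std()
            if sd == 0:
                raise ValueError("degenerate polygenic tail (no marker variance)")
            scale = np.sqrt(tail_var_target) / sd
            u_tail *= scale
            g_tail *= scale
        for _ in range(3):  # fixed-point: realized per-QTL PEV -> targets
            g_major = Xc[:, major_idx] @ beta if n_major else np.zeros(n)
            genetic = g_major + g_tail
            var_g = genetic.var()
            var_gm = var_g + var_g * (1.0 - arch.h2_broad) / arch.h2_broad
            if n_major == 0 or var_gm == 0:
                break
            per_qtl = (Xc[:, major_idx] * beta).var(axis=0) / var_gm
            adjust = np.sqrt(np.where(per_qtl > 0, targets / per_qtl, 1.0))
            beta *= adjust
        g_major = Xc[:, major_idx] @ beta if n_major else np.zeros(n)
        genetic = g_major + g_tail
        var_g = genetic.var()
        effects = np.concatenate([beta, u_tail])

    # residual variance from the broad-sense heritability identity
    if arch.h2_broad == 0.0:
        var_e = 1.0
    elif arch.h2_broad == 1.0:
        var_e = 0.0
    else:
        var_e = arch.n_years * var_g * (1.0 - arch.h2_broad) / arch.h2_broad

    years = [arch.first_year + i for i in range(arch.n_years)]
    resid = rng.standard_normal((n, arch.n_years))
    if var_e > 0:
        resid -= resid.mean()
        resid *= np.sqrt(var_e) / resid.std()
    else:
        resid[:] = 0.0

    rows = []
    for yi, year in enumerate(years):
        vals = arch.mu + arch.year_effects[yi] + genetic + resid[:, yi]
        for k, acc in enumerate(g.accession_ids):
            rows.append((acc, arch.trait_id, year, vals[k]))
    pheno = PhenotypeTable(
        pd.DataFrame(rows, columns=["accession_id", "trait_id", "year", "value"])
    )

    var_gm = var_g + (var_e / arch.n_years if arch.n_years else 0.0)
    if n_major and var_gm > 0:
        beta_final = effects[:n_major]
        realized_pev = (Xc[:, major_idx] * beta_final).var(axis=0) / var_gm
    else:
        realized_pev = np.zeros(0)

    truth = GroundTruth(
        trait_id=arch.trait_id,
        causal_snp_ids=[g.snps.loc[i, "snp_id"] for i in causal_idx],
        effects=effects,
        genetic_values=pd.Series(genetic, index=pd.Index(g.accession_ids, name="accession_id")),
        realized_sigma2_G=float(var_g),
        realized_sigma2_eps=float(resid.var()) if var_e > 0 else 0.0,
        n_years=arch.n_years,
        realized_qtl_pev=realized_pev,
    )
    return pheno, truth
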