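import numpy as np
import pandas as pd
import pytest

from walnutgp import (
    PhenotypeTable,
    SimulationConfig,
    TraitArchitecture,
    adjust_trait,
    broad_sense_h2,
    fit_year_genotype_mixed_model,
    passthrough_single_year,
    simulate_genotypes,
    simulate_phenotypes,
)
from walnutgp.phenotype_adjust import SingleYearError


def _balanced_table(values_by_year, trait="t"):
    rows = []
    for year, vals in values_by_year.items():
        for i, v in enumerate(vals):
            rows.append((f"a{i}", trait, year, v))
    return PhenotypeTable(pd.DataFrame(
        rows, columns=["accession_id", "trait_id", "year", "value"]))


def _anova_estimates(table):
    """Closed-form one-way ANOVA estimators for balanced 2-year data with
    the year means removed (independent oracle)."""
    wide = table.data.pivot(index="accession_id", columns="year",
                            values="value").to_numpy()
    q, ny = wide.shape
    acc_mean = wide.mean(axis=1, keepdims=True)
    year_mean = wide.mean(axis=0, keepdims=True)
    grand = wide.mean()
    ss_resid = ((wide - acc_mean - year_mean + grand) ** 2).sum()
    ms_error = ss_resid / ((q - 1) * (ny - 1))
    ms_geno = ny * ((acc_mean.ravel() - grand) ** 2).sum() / (q - 1)
    s2e = ms_error
    s2g = max((ms_geno - ms_error) / ny, 0.0)
    return s2g, s2e


def test_zero_residual_data_gives_exact_means():
    base = np.arange(10, dtype=float)
    table = _balanced_table({2017: base, 2018: base + 4.0})
    m = fit_year_genotype_mixed_model(table, "t")
    assert m.sigma2_eps == pytest.approx(0.0, abs=1e-6)
    # with no residual, BLUPs are unshrunken accession deviations
    acc_dev = base - base.mean()
    np.testing.assert_allclose(m.g.loc[[f"a{i}" for i in range(10)]],
                               acc_dev, atol=1e-4)
    assert m.year_effects[2017] == pytest.approx(-2.0, abs=1e-8)
    assert m.year_effects[2018] == pytest.approx(2.0, abs=1e-8)


def test_reml_matches_anova_on_balanced_data():
    rng = np.random.default_rng(8)
    genos = rng.standard_normal(60) * 2.0
    table = _balanced_table({
        2017: genos + rng.standard_normal(60),
        2018: genos + 3.0 + rng.standard_normal(60),
    })
    m = fit_year_genotype_mixed_model(table, "t")
    s2g, s2e = _anova_estimates(table)
    assert m.sigma2_G == pytest.approx(s2g, abs=1e-6)
    assert m.sigma2_eps == pytest.approx(s2e, abs=1e-6)


def test_reml_agrees_with_statsmodels_mixedlm():
    """Independent mixed-model route (statsmodels MixedLM) on unbalanced
    data: variance components agree to 1e-4."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(15)
    genos = rng.standard_normal(50)
    rows = []
    for i in range(50):
        rows.append((f"a{i}", "t", 2017, genos[i] + rng.standard_normal()))
        if i % 5:   # drop every fifth accession's second year
            rows.append((f"a{i}", "t", 2018,
                         genos[i] + 2.0 + rng.standard_normal()))
    table = PhenotypeTable(pd.DataFrame(
        rows, columns=["accession_id", "trait_id", "year", "value"]))
    m = fit_year_genotype_mixed_model(table, "t")
    df = table.data.copy()
    df["year"] = df["year"].astype(str)
    fit = smf.mixedlm("value ~ C(year)", df, groups=df["accession_id"]).fit(
        reml=True, method="lbfgs")
    assert m.sigma2_G == pytest.approx(float(fit.cov_re.iloc[0, 0]), abs=1e-4)
    assert m.sigma2_eps == pytest.approx(float(fit.scale), abs=1e-4)


def test_blups_sum_to_zero_on_balanced_data():
    rng = np.random.default_rng(2)
    genos = rng.standard_normal(40)
    table = _balanced_table({
        2017: genos + rng.standard_normal(40) * 0.5,
        2018: genos + 1.0 + rng.standard_normal(40) * 0.5,
    })
    m = fit_year_genotype_mixed_model(table, "t")
    assert abs(m.g.mean()) < 1e-8


def test_single_year_raises_and_passthrough_identity():
    table = _balanced_table({2018: np.arange(5.0)})
    with pytest.raises(SingleYearError):
        fit_year_genotype_mixed_model(table, "t")
    adj = passthrough_single_year(table, "t")
    np.testing.assert_array_equal(
        adj.values.loc[[f"a{i}" for i in range(5)]], np.arange(5.0))
    assert adj.h2 is None


def test_h2_formula_and_monotonicity():
    from walnutgp.phenotype_adjust import BlupModel

    def model(s2g, s2e, ny=2):
        return BlupModel("t", 0.0, {}, pd.Series(dtype=float), s2g, s2e, ny)

    assert broad_sense_h2(model(1.0, 0.0)) == pytest.approx(1.0)
    assert broad_sense_h2(model(1.0, 1.0, 2)) == pytest.approx(2 / 3, abs=1e-4)
    # increasing in sigma2_G; increasing in n_y for positive residual
    h = [broad_sense_h2(model(s, 1.0)) for s in (0.5, 1.0, 2.0)]
    assert h == sorted(h) and len(set(h)) == 3
    assert broad_sense_h2(model(1.0, 1.0, 2)) < broad_sense_h2(model(1.0, 1.0, 3))
    with pytest.warns(UserWarning):
        assert np.isnan(broad_sense_h2(model(0.0, 0.0)))


def test_dispatch_mixed_and_single_year_traits(small_panel):
    arch2 = TraitArchitecture("two", n_qtl=10, h2_broad=0.8, n_years=2)
    arch1 = TraitArchitecture("one", n_qtl=10, h2_broad=0.8, n_years=1,
                              year_effects=(0.0,))
    p2, _ = simulate_phenotypes(small_panel, arch2, 3)
    p1, _ = simulate_phenotypes(small_panel, arch1, 4)
    both = PhenotypeTable(pd.concat([p1.data, p2.data], ignore_index=True))
    a2 = adjust_trait(both, "two")
    a1 = adjust_trait(both, "one")
    assert a2.h2 is not None and 0 <= a2.h2 <= 1
    assert a1.h2 is None


def test_h2_estimates_recover_simulation_target():
    """Mean REML H2 over replicates is within +-0.05 of the 0.9 target."""
    g = simulate_genotypes(SimulationConfig(n_snps=400, n_chromosomes=4,
                                            seed=31))
    ests = []
    for rep in range(12):
        arch = TraitArchitecture("t", n_qtl=30, h2_broad=0.9)
        pheno, _ = simulate_phenotypes(g, arch, 1000 + rep)
        m = fit_year_genotype_mixed_model(pheno, "t")
        ests.append(broad_sense_h2(m))
    assert np.mean(ests) == pytest.approx(0.9, abs=0.05)


def test_blup_truth_correlation_increases_with_heritability(small_panel):
    cors = []
    for h2 in (0.3, 0.6, 0.9):
        arch = TraitArchitecture("t", n_qtl=30, h2_broad=h2)
        pheno, truth = simulate_phenotypes(small_panel, arch, 77)
        adj = adjust_trait(pheno, "t")
        cors.append(np.corrcoef(
            adj.values.loc[truth.genetic_values.index],
            truth.genetic_values)[0, 1])
    assert cors[0] < cors[1] < cors[2]
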