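import numpy as np
import pandas as pd
import pytest

from walnutgp import (
    BayesianAlphabet,
    FixedCofactorSet,
    ModelSpec,
    RidgeBLUP,
    SimulationConfig,
    TraitArchitecture,
    adjust_trait,
    fit_rrblup,
    gblup_predict,
    predict,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="module")
def polygenic_xy(small_panel, small_polygenic):
    adj, _ = small_polygenic
    y = adj.values.loc[small_panel.accession_ids].to_numpy()
    return small_panel.dosage, y


def test_ridge_effects_match_closed_form_at_fixed_lambda(toy_genotypes):
    """On a 5 x 8 toy at fixed lambda, marker effects equal the dense ridge
    solution (X'X + lambda I)^-1 X'y on centered X with the GLS intercept."""
    rng = np.random.default_rng(1)
    X = toy_genotypes.dosage
    y = rng.standard_normal(5)
    lam = 3.7
    est = RidgeBLUP(ridge_lambda=lam).fit(X, y)
    Xc = X - X.mean(axis=0)
    # joint mixed-model equations with an intercept (dense oracle)
    n, m = Xc.shape
    A = np.zeros((1 + m, 1 + m))
    A[0, 0] = n
    A[0, 1:] = Xc.sum(axis=0)
    A[1:, 0] = Xc.sum(axis=0)
    A[1:, 1:] = Xc.T @ Xc + lam * np.eye(m)
    rhs = np.concatenate([[y.sum()], Xc.T @ y])
    sol = np.linalg.solve(A, rhs)
    assert est.intercept_ == pytest.approx(sol[0], abs=1e-8)
    np.testing.assert_allclose(est.marker_effects_, sol[1:], atol=1e-8)


def test_rrblup_equals_gblup_predictions(polygenic_xy):
    X, y = polygenic_xy
    tr, va = np.arange(140), np.arange(140, 170)
    est = RidgeBLUP().fit(X[tr], y[tr])
    via_kinship = gblup_predict(X[tr], y[tr], X[va], est.lambda_)
    np.testing.assert_allclose(est.predict(X[va]), via_kinship, atol=1e-8)


def test_constant_phenotype_degenerates_to_intercept(toy_genotypes):
    with pytest.warns(UserWarning, match="constant"):
        est = RidgeBLUP().fit(toy_genotypes.dosage, np.full(5, 2.5))
    assert est.intercept_ == 2.5
    np.testing.assert_array_equal(est.marker_effects_, 0.0)
    np.testing.assert_array_equal(est.predict(toy_genotypes.dosage),
                                  np.full(5, 2.5))


def test_ridge_shrinkage_is_monotone(polygenic_xy):
    X, y = polygenic_xy
    norms = [np.linalg.norm(RidgeBLUP(ridge_lambda=lam).fit(X, y).marker_effects_)
             for lam in (0.1, 1.0, 10.0, 100.0)]
    assert all(a >= b for a, b in zip(norms, norms[1:]))


def test_collinear_cofactors_rejected(toy_genotypes):
    X = toy_genotypes.dosage.copy()
    X[:, 1] = X[:, 0]
    with pytest.raises(ValueError, match="collinear"):
        RidgeBLUP(fixed_idx=[0, 1]).fit(X, np.arange(5.0))


def test_prediction_of_training_set_reproduces_fit(polygenic_xy):
    X, y = polygenic_xy
    est = RidgeBLUP().fit(X, y)
    fitted = est.intercept_ + est.fitted_genetic_values_
    np.testing.assert_allclose(est.predict(X), fitted, atol=1e-8)


def test_mean_dosage_accession_predicts_intercept(polygenic_xy):
    X, y = polygenic_xy
    est = RidgeBLUP().fit(X, y)
    x_mean = X.mean(axis=0, keepdims=True)
    assert est.predict(x_mean)[0] == pytest.approx(est.intercept_, abs=1e-10)


def test_predict_by_id_invariant_to_column_order(small_panel, small_polygenic):
    adj, _ = small_polygenic
    fit = fit_rrblup(small_panel, adj.values, trait_id="poly")
    base = predict(fit, small_panel)
    rng = np.random.default_rng(0)
    perm = rng.permutation(small_panel.n_snps)
    shuffled = small_panel.subset_snps(perm)
    np.testing.assert_allclose(predict(fit, shuffled), base, atol=1e-10)


def test_predict_reports_missing_snps(small_panel, small_polygenic):
    adj, _ = small_polygenic
    fit = fit_rrblup(small_panel, adj.values)
    clipped = small_panel.subset_snps(np.arange(10, small_panel.n_snps))
    with pytest.raises(KeyError, match="not in panel"):
        predict(fit, clipped)


def test_fixed_cofactors_absorb_major_locus(small_panel):
    arch = TraitArchitecture("m", n_qtl=10, qtl_pev_targets=(0.6,),
                             h2_broad=0.9)
    pheno, truth = simulate_phenotypes(small_panel, arch, 44)
    adj = adjust_trait(pheno, "m")
    cof = FixedCofactorSet([truth.causal_snp_ids[0]])
    fit = fit_rrblup(small_panel, adj.values, cofactors=cof)
    j = small_panel.snp_ids.index(truth.causal_snp_ids[0])
    # the cofactor column left the random set: no random effect there
    assert fit.estimator.marker_effects_[j] == 0.0
    assert len(fit.estimator.fixed_effects_) == 1
    # and its fixed coefficient has the sign of the true effect
    assert np.sign(fit.estimator.fixed_effects_[0]) == np.sign(truth.effects[0])


def test_gibbs_determinism_and_brr_matches_rrblup(polygenic_xy):
    X, y = polygenic_xy
    rr = RidgeBLUP().fit(X, y)
    a = BayesianAlphabet("brr", n_iter=2000, burn_in=500, seed=5).fit(X, y)
    b = BayesianAlphabet("brr", n_iter=2000, burn_in=500, seed=5).fit(X, y)
    np.testing.assert_array_equal(a.marker_effects_, b.marker_effects_)
    r = np.corrcoef(a.predict(X), rr.predict(X))[0, 1]
    assert r >= 0.95


def test_bayes_c_with_vanishing_spike_approaches_brr(polygenic_xy):
    X, y = polygenic_xy
    brr = BayesianAlphabet("brr", n_iter=2000, burn_in=500, seed=5).fit(X, y)
    bc = BayesianAlphabet("bayes_c", pi=0.001, n_iter=2000, burn_in=500,
                          seed=5).fit(X, y)
    r = np.corrcoef(bc.predict(X), brr.predict(X))[0, 1]
    assert r >= 0.9


@pytest.mark.parametrize("model", ["bayes_a", "bayes_b", "bayes_lasso"])
def test_bayesian_models_track_polygenic_signal(polygenic_xy, model):
    X, y = polygenic_xy
    est = BayesianAlphabet(model, n_iter=2000, burn_in=500, seed=5).fit(X, y)
    rr = RidgeBLUP().fit(X, y)
    assert np.corrcoef(est.predict(X), rr.predict(X))[0, 1] > 0.9
    assert est.rhat_sigma2_e_ < 1.2


def test_bayes_b_concentrates_on_major_locus():
    """Oligogenic trait: BayesB ranks the causal marker's |effect| better
    than BRR does, in most replicates."""
    g = simulate_genotypes(SimulationConfig(
        n_snps=300, n_chromosomes=4, seed=13))
    wins = 0
    n_rep = 8
    for rep in range(n_rep):
        arch = TraitArchitecture("o", n_qtl=5, qtl_pev_targets=(0.5,),
                                 h2_broad=0.9)
        pheno, truth = simulate_phenotypes(g, arch, 500 + rep)
        adj = adjust_trait(pheno, "o")
        y = adj.values.loc[g.accession_ids].to_numpy()
        j = g.snp_ids.index(truth.causal_snp_ids[0])
        ranks = {}
        for name in ("bayes_b", "brr"):
            est = BayesianAlphabet(name, n_iter=2000, burn_in=500,
                                   seed=rep).fit(g.dosage, y)
            order = np.argsort(-np.abs(est.marker_effects_))
            ranks[name] = int(np.where(order == j)[0][0])
        if ranks["bayes_b"] <= ranks["brr"]:
            wins += 1
    assert wins >= n_rep - 2


def test_model_spec_validation():
    with pytest.raises(ValueError, match="unknown model"):
        ModelSpec(model_name="gblup2")
    with pytest.raises(ValueError, match="burn_in"):
        ModelSpec(n_iter=100, burn_in=100)
    with pytest.raises(ValueError, match="pi"):
        BayesianAlphabet("bayes_b", pi=1.5).fit(
            np.random.default_rng(0).integers(0, 3, (10, 4)).astype(float),
            np.arange(10.0))
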