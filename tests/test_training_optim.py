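import itertools

import numpy as np
import pandas as pd
import pytest

from walnutgp import (
    DesignCriterion,
    GaConfig,
    GenotypeMatrix,
    SimulationConfig,
    criterion_value,
    optimize_training_set,
    simulate_genotypes,
    svd_reduce,
    vanraden_grm,
)


def _panel_from_dosage(dosage, ids=None):
    n, m = dosage.shape
    ids = ids or [f"a{i}" for i in range(n)]
    snps = pd.DataFrame(dict(
        snp_id=[f"s{j}" for j in range(m)], chromosome="1",
        position=np.arange(1, m + 1) * 10, allele_ref="A", allele_alt="G",
        call_rate=1.0, maf=0.0,
    ))
    return GenotypeMatrix(ids, snps, np.asarray(dosage, float))


@pytest.fixture(scope="module")
def family_grm():
    """Two planted families: high relatedness within, low between."""
    rng = np.random.default_rng(9)
    founders = rng.integers(0, 2, size=(4, 400)).astype(float)
    rows = []
    for fam in range(2):
        pa, pb = founders[2 * fam], founders[2 * fam + 1]
        for _ in range(6):
            pick = rng.random(400) < 0.5
            h1 = np.where(pick, pa, pb)
            pick = rng.random(400) < 0.5
            h2 = np.where(pick, pa, pb)
            rows.append(h1 + h2)
    return vanraden_grm(_panel_from_dosage(np.array(rows)))


def test_grm_single_snp_hand_computation():
    g = _panel_from_dosage(np.array([[0.0], [1.0], [2.0]]))
    grm = vanraden_grm(g)
    # p = 0.5, centered w = (-1, 0, 1), denominator 2 * 0.25 = 0.5
    expect = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
    np.testing.assert_allclose(grm.matrix, expect, atol=1e-12)


def test_grm_duplicate_accessions_symmetry():
    rng = np.random.default_rng(4)
    row = rng.integers(0, 3, 200).astype(float)
    other = rng.integers(0, 3, 200).astype(float)
    grm = vanraden_grm(_panel_from_dosage(np.vstack([row, row, other])))
    assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0], abs=1e-10)
    assert grm.matrix[0, 1] == pytest.approx(grm.matrix[1, 1], abs=1e-10)


def test_grm_mean_diagonal_near_one_under_hwe(small_panel):
    grm = vanraden_grm(small_panel)
    assert 0.9 < grm.matrix.diagonal().mean() < 1.1
    # symmetric PSD up to tolerance
    np.testing.assert_allclose(grm.matrix, grm.matrix.T, atol=1e-10)
    assert np.linalg.eigvalsh(grm.matrix).min() > -1e-8


def test_cd_matches_dense_mme_oracle():
    """CD/PEV equal the classical route through the inverse coefficient
    matrix of the densely assembled mixed-model equations (independent
    oracle; needs a nonsingular kinship, so one is built directly)."""
    from walnutgp.training_optim import Grm, _cd_pev

    rng = np.random.default_rng(12)
    A = rng.standard_normal((12, 12))
    G = A @ A.T / 12 + 0.3 * np.eye(12)
    grm = Grm(G, np.full(1, 0.5), [f"a{i}" for i in range(12)])
    tr = np.arange(9)
    va = np.arange(9, 12)
    lam = 1.7
    # dense MME: [[n_t, 1'Z], [Z'1, Z'Z + lam G^-1]], PEV_i = lam [C22]_ii
    n = 12
    z_counts = np.zeros(n)
    z_counts[tr] = 1.0
    M = np.zeros((n + 1, n + 1))
    M[0, 0] = len(tr)
    M[0, 1:] = z_counts
    M[1:, 0] = z_counts
    M[1:, 1:] = np.diag(z_counts) + lam * np.linalg.inv(G)
    C = np.linalg.inv(M)
    pev_oracle = lam * np.diag(C)[1:][va]
    pev, cd = _cd_pev(grm, tr, va, lam)
    np.testing.assert_allclose(pev, pev_oracle, atol=1e-8)
    np.testing.assert_allclose(cd, 1 - pev_oracle / np.diag(G)[va], atol=1e-8)
    # spec-level bounds
    assert np.all(pev > 0)
    assert np.all((cd >= 0) & (cd < 1))


def test_meanrel_two_accessions_is_entry(family_grm):
    ids = family_grm.accession_ids
    v = criterion_value(family_grm, [ids[0]], [ids[1]],
                        DesignCriterion("meanrel"))
    assert v == pytest.approx(family_grm.matrix[0, 1])


def test_identical_validation_accession_has_cd_near_one():
    """A validation accession duplicated in the training set is predicted
    almost perfectly at small lambda; the residual PEV is the share due to
    estimating the intercept, which shrinks with training size."""
    from walnutgp.training_optim import _cd_pev

    rng = np.random.default_rng(5)
    row = rng.integers(0, 3, 500).astype(float)
    others = rng.integers(0, 3, size=(60, 500)).astype(float)
    g = _panel_from_dosage(np.vstack([row, row, others]))
    grm = vanraden_grm(g)
    train = np.concatenate([[0], np.arange(2, 62)])
    pev, cd = _cd_pev(grm, train, np.array([1]), 1e-4)
    assert cd[0] > 0.95
    assert pev[0] < 0.05 * grm.matrix[1, 1] + 1e-6


@pytest.mark.parametrize("crit_name", ["cdmean", "pevmean", "meanrel"])
def test_optimizers_match_exhaustive_enumeration(family_grm, crit_name):
    crit = DesignCriterion(crit_name, ridge_lambda=1.0)
    cfg = GaConfig(population=30, generations=30, seed=2)
    best = optimize_training_set(family_grm, 0.75, crit, cfg,
                                 method="exhaustive")
    found = optimize_training_set(family_grm, 0.75, crit, cfg)
    assert found.value == pytest.approx(best.value, abs=1e-10)


def test_meanrel_greedy_deterministic(family_grm):
    a = optimize_training_set(family_grm, 0.8, DesignCriterion("meanrel"))
    b = optimize_training_set(family_grm, 0.8, DesignCriterion("meanrel"))
    assert a.training_ids == b.training_ids
    assert set(a.training_ids) | set(a.validation_ids) == \
        set(family_grm.accession_ids)
    assert not set(a.training_ids) & set(a.validation_ids)


def test_cdmean_beats_random_baseline(small_panel):
    grm = vanraden_grm(small_panel.subset_accessions(
        small_panel.accession_ids[:40]))
    crit = DesignCriterion("cdmean", ridge_lambda=1.0)
    cfg = GaConfig(population=20, generations=15, n_random_baseline=100,
                   seed=7)
    design = optimize_training_set(grm, 0.8, crit, cfg)
    rng = np.random.default_rng(123)
    ids = np.array(grm.accession_ids)
    rand_vals = []
    for _ in range(100):
        sel = rng.choice(40, size=32, replace=False)
        mask = np.zeros(40, bool)
        mask[sel] = True
        rand_vals.append(criterion_value(grm, list(ids[mask]),
                                         list(ids[~mask]), crit))
    assert design.value >= max(rand_vals) - 1e-9


def test_pevmean_decreases_with_training_superset(family_grm):
    ids = family_grm.accession_ids
    crit = DesignCriterion("pevmean", ridge_lambda=1.0)
    valid = ids[10:]
    small = criterion_value(family_grm, ids[:4], valid, crit)
    large = criterion_value(family_grm, ids[:10], valid, crit)
    assert large <= small + 1e-12


def test_meanrel_prefers_relatives_of_validation(family_grm):
    """With two families, the greedy MeanRel training set over-represents
    relatives of the validation accessions."""
    design = optimize_training_set(family_grm, 0.5,
                                   DesignCriterion("meanrel"))
    G = family_grm.matrix
    ids = family_grm.accession_ids
    tr = [ids.index(a) for a in design.training_ids]
    va = [ids.index(a) for a in design.validation_ids]
    picked = G[np.ix_(tr, va)].mean()
    rng = np.random.default_rng(1)
    rand = []
    for _ in range(200):
        sel = rng.permutation(12)
        rand.append(G[np.ix_(sel[:6], sel[6:])].mean())
    assert picked >= np.quantile(rand, 0.95)


def test_svd_reduce_lossless_and_orthonormal(small_panel):
    sub = small_panel.subset_accessions(small_panel.accession_ids[:30])
    Xc = sub.dosage - sub.dosage.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    scores, comps, s = svd_reduce(sub, rank)
    np.testing.assert_allclose(scores @ scores.T, Xc @ Xc.T, atol=1e-6)
    np.testing.assert_allclose(comps @ comps.T, np.eye(rank), atol=1e-10)
    with pytest.warns(UserWarning, match="rank"):
        more, _, _ = svd_reduce(sub, min(sub.dosage.shape))
    assert more.shape[1] == rank
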