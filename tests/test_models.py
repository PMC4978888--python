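"""Whole-genome regression models: closed forms, oracles, sampler behavior."""

import numpy as np
import pandas as pd
import pytest

from germpred import (
    GBLUP,
    BayesB,
    BayesianLasso,
    GenotypeMatrix,
    KinshipMatrix,
    ModelSpec,
    compute_grm,
    fit_bayes_b,
    fit_gblup,
    predict_new,
)
from germpred.exceptions import ValidationError
from conftest import random_inbred_panel

MCMC_FAST = dict(n_iter=1200, burn_in=400, thin=2, seed=3)


# ------------------------------------------------------------------- G-BLUP
def test_infinite_shrinkage_collapses_to_mean(rng):
    g = random_inbred_panel(rng, 20, 60)
    K = compute_grm(g)
    y = rng.normal(5.0, 1.0, 20)
    est = GBLUP(kernel="precomputed", lambda_=1e9).fit(K.G, y)
    assert np.abs(est.g_).max() < 1e-5
    assert est.intercept_ == pytest.approx(y.mean(), abs=1e-6)


def test_identity_kernel_halves_centered_response(rng):
    y = rng.normal(0.0, 1.0, 12)
    y -= y.mean()
    est = GBLUP(kernel="precomputed", lambda_=1.0).fit(np.eye(12), y)
    np.testing.assert_allclose(est.g_, y / 2.0, atol=1e-10)


def test_fixed_lambda_matches_explicit_inverse(rng):
    """ghat = [I + lambda G^{-1}]^{-1} ytilde, evaluated with a literal
    matrix inverse on an invertible 8-accession kinship.  In-sample
    frequencies make G exactly singular (rows sum to zero), so external
    frequencies are supplied to obtain an invertible G."""
    g = random_inbred_panel(rng, 8, 300)
    g.theta = np.clip(g.theta + rng.uniform(-0.05, 0.05, g.n_markers), 0.02, 0.98)
    K = compute_grm(g)
    y = rng.normal(0.0, 1.0, 8)
    lam = 0.5
    est = GBLUP(kernel="precomputed", lambda_=lam).fit(K.G, y)
    yc = y - est.beta_[0]
    direct = np.linalg.solve(np.eye(8) + lam * np.linalg.inv(K.G), yc)
    np.testing.assert_allclose(est.g_, direct, atol=1e-8)


def test_reml_recovers_h2_and_genetic_values(rng):
    h2s, cors = [], []
    for seed in range(3):
        r = np.random.default_rng(seed)
        theta = r.uniform(0.05, 0.95, 1000)
        X = (2.0 * (r.random((500, 1000)) < theta))
        b = r.normal(0, 1, 1000)
        g = X @ b
        g = (g - g.mean()) * np.sqrt(0.5) / g.std()
        y = g + r.normal(0, np.sqrt(0.5), 500)
        gm = GenotypeMatrix([str(i) for i in range(500)],
                            [str(j) for j in range(1000)], X).with_theta()
        est = GBLUP(kernel="precomputed").fit(compute_grm(gm).G, y)
        h2s.append(est.h2_)
        cors.append(np.corrcoef(est.g_, g)[0, 1])
    assert abs(np.mean(h2s) - 0.5) < 0.1
    assert np.mean(cors) > 0.6


def test_gblup_equals_ridge_marker_regression(rng):
    """Core oracle: with G = WW'/p (standardized centered scores) and a
    matched penalty, G-BLUP predictions equal explicit ridge regression."""
    for seed in range(4):
        r = np.random.default_rng(seed)
        n, p = r.integers(15, 50), r.integers(40, 200)
        g = random_inbred_panel(r, int(n), int(p))
        theta = g.theta
        W = (g.dosages - 2 * theta) / np.sqrt(2 * theta * (1 - theta))
        G = W @ W.T / p
        y = r.normal(0, 1, n)
        lam = float(r.uniform(0.2, 3.0))
        est = GBLUP(kernel="precomputed", lambda_=lam).fit(G, y)
        yc = y - est.beta_[0]
        b_ridge = W.T @ np.linalg.solve(W @ W.T + lam * p * np.eye(int(n)), yc)
        np.testing.assert_allclose(est.g_, W @ b_ridge, atol=1e-8)


def test_gblup_two_step_prediction_equals_ridge_projection(rng):
    """Predicting a held-out accession through the kinship cross-block
    agrees with refitting the equivalent ridge marker model and projecting."""
    g = random_inbred_panel(rng, 30, 120)
    theta = g.theta
    W = (g.dosages - 2 * theta) / np.sqrt(2 * theta * (1 - theta))
    G = W @ W.T / g.n_markers
    y = rng.normal(0, 1, 30)
    lam = 0.8
    train, new = np.arange(25), np.arange(25, 30)
    est = GBLUP(kernel="precomputed", lambda_=lam).fit(G[np.ix_(train, train)], y[train])
    pred = est.predict(G[np.ix_(new, train)])
    yc = y[train] - est.beta_[0]
    b_ridge = W[train].T @ np.linalg.solve(
        W[train] @ W[train].T + lam * g.n_markers * np.eye(25), yc
    )
    np.testing.assert_allclose(pred, est.beta_[0] + W[new] @ b_ridge, atol=1e-8)


def test_prediction_invariant_to_constant_shift(rng):
    g = random_inbred_panel(rng, 25, 80)
    K = compute_grm(g)
    y = rng.normal(0, 1, 25)
    e1 = GBLUP(kernel="precomputed", lambda_=1.0).fit(K.G, y)
    e2 = GBLUP(kernel="precomputed", lambda_=1.0).fit(K.G, y + 10.0)
    np.testing.assert_allclose(e2.g_, e1.g_, atol=1e-8)
    assert e2.intercept_ - e1.intercept_ == pytest.approx(10.0, abs=1e-8)


def test_gblup_multi_record_incidence(rng):
    """Accessions with repeated records shrink toward their record mean;
    the record-to-accession mapping must produce one g per accession."""
    g = random_inbred_panel(rng, 15, 60)
    K = compute_grm(g)
    idx = np.concatenate([np.arange(15), np.arange(5)])  # first 5 have 2 records
    y = rng.normal(0, 1, 20)
    est = GBLUP(kernel="precomputed", lambda_=1.0).fit(K.G, y, accession_idx=idx)
    assert est.g_.shape == (15,)


# ----------------------------------------------------------------- Bayes B
def test_bayes_b_all_null_mixture_degenerates(rng):
    g = random_inbred_panel(rng, 40, 80)
    y = rng.normal(2.0, 1.0, 40)
    est = BayesB(pi0=1.0, sample_pi=False, **MCMC_FAST).fit(g.dosages, y)
    assert np.abs(est.g_).max() == 0.0
    assert est.intercept_ == pytest.approx(y.mean(), abs=0.2)


def test_bayes_b_ranks_true_qtl(rng):
    r = np.random.default_rng(77)
    g = random_inbred_panel(r, 300, 500)
    qtl = r.choice(500, 20, replace=False)
    b = np.zeros(500)
    b[qtl] = r.normal(0, 1, 20)
    gv = g.dosages @ b
    gv = (gv - gv.mean()) * np.sqrt(0.5) / gv.std()
    y = gv + r.normal(0, np.sqrt(0.5), 300)
    est = BayesB(**MCMC_FAST).fit(g.dosages, y)
    null = np.setdiff1d(np.arange(500), qtl)
    assert est.pip_[qtl].mean() > est.pip_[null].mean()
    assert np.corrcoef(est.g_, gv)[0, 1] > 0.6


def test_samplers_bit_reproducible(rng):
    g = random_inbred_panel(rng, 50, 60)
    y = rng.normal(0, 1, 50)
    kw = dict(n_iter=300, burn_in=100, thin=2, seed=9)
    b1 = BayesB(**kw).fit(g.dosages, y)
    b2 = BayesB(**kw).fit(g.dosages, y)
    assert np.array_equal(b1.b_, b2.b_)
    l1 = BayesianLasso(**kw).fit(g.dosages, y)
    l2 = BayesianLasso(**kw).fit(g.dosages, y)
    assert np.array_equal(l1.b_, l2.b_)


def test_noise_variance_calibrated(rng):
    """Posterior mean of sigma2_e on pure noise covers the truth."""
    g = random_inbred_panel(rng, 200, 300)
    y = rng.normal(0.0, 1.0, 200)
    est = BayesB(**MCMC_FAST).fit(g.dosages, y)
    trace = est.diagnostics_["sigma2_e_trace"]
    assert abs(est.sigma2_e_ - 1.0) < 2 * trace.std() + 0.1


# --------------------------------------------------------- Bayesian LASSO
def test_lasso_shrinks_on_pure_noise(rng):
    r = np.random.default_rng(21)
    g = random_inbred_panel(r, 200, 500)
    y = r.normal(0, 1, 200)
    est = BayesianLasso(**MCMC_FAST).fit(g.dosages, y)
    Xc = g.dosages - g.dosages.mean(axis=0)
    yc = y - y.mean()
    ols_single = np.abs(Xc.T @ yc / np.einsum("ij,ij->j", Xc, Xc))
    assert np.abs(est.b_).max() < 0.10 * ols_single.max()


def test_lasso_single_marker_matches_quadrature(rng):
    """Conjugate-style subcase: one marker, residual variance pinned by a
    near-degenerate prior and the regularization parameter held fixed; the
    sampled posterior mean of b matches 1-D quadrature of the exact
    posterior under the double-exponential prior."""
    r = np.random.default_rng(5)
    n = 60
    x = (2.0 * (r.random(n) < 0.5))
    sigma2 = 0.25
    b_true = 0.3
    y = b_true * x + r.normal(0, np.sqrt(sigma2), n)
    lam2 = 4.0
    est = BayesianLasso(
        n_iter=18000, burn_in=3000, thin=1, seed=2,
        lambda2=lam2, sample_lambda=False,
        df_e=1e7, s_e=sigma2 * 1e7,  # pins sigma2_e at 0.25
    ).fit(x[:, None], y)
    xc = x - x.mean()
    yc = y - y.mean()
    # exact posterior: N(yc; xc b, sigma2 I) * DE(b; rate sqrt(lam2/sigma2))
    rate = np.sqrt(lam2 / sigma2)
    bs = np.linspace(-2, 2, 4001)
    loglik = -0.5 * np.sum((yc[:, None] - np.outer(xc, bs)) ** 2, axis=0) / sigma2
    logp = loglik - rate * np.abs(bs)
    w = np.exp(logp - logp.max())
    post_mean = np.sum(bs * w) / np.sum(w)
    assert est.b_[0] == pytest.approx(post_mean, abs=0.02)


def test_duplicated_markers_leave_predictions_unchanged(rng):
    r = np.random.default_rng(8)
    g = random_inbred_panel(r, 120, 150)
    b = r.normal(0, 0.1, 150)
    y = g.dosages @ b + r.normal(0, 0.5, 120)
    kw = dict(n_iter=2000, burn_in=500, thin=2, seed=4)
    e1 = BayesianLasso(**kw).fit(g.dosages, y)
    e2 = BayesianLasso(**kw).fit(np.hstack([g.dosages, g.dosages]), y)
    r_dup = np.corrcoef(e1.g_, e2.g_)[0, 1]
    assert r_dup > 0.98
    assert np.abs(e1.g_ - e2.g_).max() < 0.5 * np.std(y)


# ----------------------------------------------------------- predict_new
def _toy_fit(rng):
    g = random_inbred_panel(rng, 30, 50)
    y = rng.normal(0, 1, 30)
    ph = pd.DataFrame({
        "accession_id": g.accession_ids, "trial_id": "T1", "state": "S1",
        "maturity_group": "2", "trait": "oil", "value": y,
        "lodging": np.nan, "shattering": np.nan,
    })
    spec = ModelSpec(model="bayes_b", trait="oil", n_iter=600, burn_in=200, thin=2, seed=1)
    return g, ph, fit_bayes_b(ph, g, spec)


def test_predict_new_identical_accession_reproduces_fit(rng):
    g, ph, fit = _toy_fit(rng)
    clone = GenotypeMatrix(["clone"], g.marker_ids, g.dosages[[0]], g.theta)
    pred = predict_new(fit, g_new=clone)
    assert pred["clone"] == pytest.approx(fit.predictions["prediction"].iloc[0], abs=1e-10)


def test_predict_new_mean_dosage_gives_mu(rng):
    g, ph, fit = _toy_fit(rng)
    est = fit.diagnostics["estimator"]
    x_mean = (2.0 * est.theta_)[None, :]
    pred = est.predict(x_mean)
    assert pred[0] == pytest.approx(fit.mu, abs=1e-10)


def test_predict_new_marker_mismatch_errors(rng):
    g, ph, fit = _toy_fit(rng)
    missing = GenotypeMatrix(["n1"], g.marker_ids[:-1], g.dosages[[0], :-1], None)
    with pytest.raises(ValidationError, match="lack training markers"):
        predict_new(fit, g_new=missing)


def test_gblup_predict_new_through_joint_kinship(rng):
    g = random_inbred_panel(rng, 40, 100)
    K = compute_grm(g)
    y = rng.normal(0, 1, 35)
    ph = pd.DataFrame({
        "accession_id": g.accession_ids[:35], "trial_id": "T1", "state": "S1",
        "maturity_group": "2", "trait": "oil", "value": y,
        "lodging": np.nan, "shattering": np.nan,
    })
    fit = fit_gblup(ph, KinshipMatrix(g.accession_ids, K.G, K.p_markers),
                    ModelSpec(model="gblup", trait="oil"))
    preds = predict_new(fit, K_joint=K)
    assert list(preds.index) == g.accession_ids[35:]
    assert np.isfinite(preds).all()
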