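"""Whole-genome regression models.

Three estimators share the record-level linear predictor
``y = F beta + Z g + eps`` with ``g_i = sum_l x_il b_l``:

* :class:`GBLUP` — ``g ~ N(0, G sigma2_g)`` with G the genomic relationship
  matrix; the variance ratio ``lambda = sigma2_e / sigma2_g`` is estimated
  by REML and the BLUP of g is ``G (G + lambda I)^{-1} ytilde`` in the
  single-record case (computed inversion-free, so a singular G is fine).
* :class:`BayesianLasso` — marker effects with IID exponential prior
  variances, i.e. a double-exponential marginal prior, sampled by Gibbs.
* :class:`BayesB` — point-mass-at-zero/normal mixture prior with null
  proportion ``pi`` given a beta prior; per-marker slab variances are
  scaled-inverse-chi-squared; sampled by Gibbs with marginalized
  inclusion updates.

All three follow the scikit-learn estimator protocol (``fit``/``predict``,
``get_params``; fitted attributes carry a trailing underscore) and accept
two optional fit keywords: ``accession_idx`` mapping records to accession
rows (so an accession evaluated in several trials contributes several
records to one genetic value) and ``fixed``, a record-level fixed-effect
design matrix (default: intercept only).

Hyperparameters default to the variance-partition rule: a prior trait
heritability ``r2_prior`` splits ``var(y)`` between markers and residual;
residual scale ``S_e = var(y) (1 - R2) (df_e + 2)``, Bayes B slab scale
``S_b = var(y) R2 (df_b + 2) / ((1 - pi0) MSx)`` and LASSO regularization
``lambda2 = 2 (1 - R2) MSx / R2`` with ``MSx = sum_l 2 theta_l (1 - theta_l)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

from ._samplers import sweep_bayes_b, sweep_lasso
from .containers import GenotypeMatrix, KinshipMatrix, ModelFit
from .exceptions import ConvergenceError, ValidationError
from .kinship import compute_grm
from .mixedlm import blup_with_fixed_ratio, reml_fit
from .pheno import AdjustedPhenotypes, design_matrix


@dataclass
class ModelSpec:
    """Settings bundle for the module-level fit wrappers."""

    model: str = "gblup"
    trait: str = "yield"
    covariates: tuple[str, ...] = ()
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0
    r2_prior: float = 0.5
    df_b: float = 5.0
    s_b: float | None = None
    pi0: float = 0.5
    p0: float = 10.0
    df_e: float = 5.0
    s_e: float | None = None
    lambda2: float | None = None
    lambda_: float | None = None  # fixed variance ratio for G-BLUP (skip REML)

    def __post_init__(self) -> None:
        if not (self.n_iter > self.burn_in >= 0):
            raise ValidationError("require iterations > burn-in >= 0")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValidationError("pi0 must lie in [0, 1]")
        if self.p0 <= 0:
            raise ValidationError("p0 must be positive")
        if not (0.0 < self.r2_prior < 1.0):
            raise ValidationError("r2_prior must lie in (0, 1)")


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"expected a 2-D array, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValidationError("input matrix has non-finite entries")
    return X


def _incidence(accession_idx, n_records: int, n_acc: int) -> np.ndarray:
    Z = np.zeros((n_records, n_acc))
    Z[np.arange(n_records), accession_idx] = 1.0
    return Z


class GBLUP(BaseEstimator, RegressorMixin):
    """Genomic BLUP with REML variance components.

    Parameters
    ----------
    kernel : {"grm", "precomputed"}
        With ``"grm"``, ``X`` passed to :meth:`fit` is an accession x marker
        dosage matrix and the GRM is built internally (in-sample allele
        frequencies unless ``theta`` is given).  With ``"precomputed"``,
        ``X`` is the accession x accession relationship matrix itself.
    lambda_ : float, optional
        Fix the variance ratio ``sigma2_e / sigma2_g`` instead of REML.
    bounds, tol
        Search interval and tolerance for the 1-D REML profile in lambda.

    Attributes
    ----------
    g_ : ndarray — BLUP genetic value per training accession.
    lambda_opt_, sigma2_g_, sigma2_e_, h2_ : variance-component estimates.
    beta_ : fixed-effect estimates; ``intercept_`` the overall mean.
    """

    def __init__(self, kernel: str = "grm", theta=None, lambda_: float | None = None,
                 bounds: tuple[float, float] = (1e-6, 1e6), tol: float = 1e-8):
        self.kernel = kernel
        self.theta = theta
        self.lambda_ = lambda_
        self.bounds = bounds
        self.tol = tol

    def fit(self, X, y, accession_idx=None, fixed=None):
        X = _as_2d(X)
        y = np.asarray(y, dtype=float).ravel()
        if self.kernel == "precomputed":
            if X.shape[0] != X.shape[1]:
                raise ValidationError("precomputed kernel must be square")
            if np.abs(X - X.T).max(initial=0.0) > 1e-8:
                raise ValidationError("precomputed kernel must be symmetric")
            G = X
            self.theta_ = None
        elif self.kernel == "grm":
            gm = GenotypeMatrix.__new__(GenotypeMatrix)
            gm.accession_ids = [str(i) for i in range(X.shape[0])]
            gm.marker_ids = [str(j) for j in range(X.shape[1])]
            gm.dosages = X
            gm.theta = np.asarray(self.theta, dtype=float) if self.theta is not None else None
            km = compute_grm(gm.with_theta())
            G = km.G
            self.theta_ = gm.theta
            self._W_train = X - 2.0 * gm.theta
            self._denom = 2.0 * gm.theta * (1.0 - gm.theta)
        else:
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        n_acc = G.shape[0]

        if accession_idx is None:
            if y.size != n_acc:
                raise ValidationError("y length does not match accession count")
            accession_idx = np.arange(n_acc)
        accession_idx = np.asarray(accession_idx, dtype=int)
        n_rec = accession_idx.size
        if y.size != n_rec:
            raise ValidationError("y length does not match accession_idx length")
        Z = _incidence(accession_idx, n_rec, n_acc)
        F = np.ones((n_rec, 1)) if fixed is None else _as_2d(fixed)

        K_rec = Z @ G @ Z.T
        if self.lambda_ is not None:
            res = blup_with_fixed_ratio(K_rec, F, y, float(self.lambda_))
        else:
            res = reml_fit(K_rec, F, y, bounds=self.bounds, tol=self.tol)
        self.lambda_opt_ = float(res.delta)
        self.sigma2_g_ = float(res.sigma2_g) if self.lambda_ is None else np.nan
        self.sigma2_e_ = float(res.sigma2_e) if self.lambda_ is None else np.nan
        # genomic heritability: the per-accession genetic variance is
        # sigma2_g * mean(diag G), which matters when the GRM diagonal is
        # not 1 (fully inbred panels sit near 2); reduces to
        # sigma2_g / (sigma2_g + sigma2_e) for a unit-diagonal GRM
        mdiag = float(np.mean(np.diag(G)))
        self.h2_ = (
            float(res.sigma2_g * mdiag / (res.sigma2_g * mdiag + res.sigma2_e))
            if self.lambda_ is None
            else mdiag / (mdiag + self.lambda_opt_)
        )
        self.beta_ = res.beta
        if fixed is None:
            self.intercept_ = float(res.beta[0])
        else:
            self.intercept_ = float(np.mean(F @ res.beta))
        self.loglik_ = res.loglik
        # sigma2_g * Z' V^{-1}(y - F beta); genetic values are G @ alpha_acc_
        self.alpha_acc_ = res.sigma2_g * (Z.T @ res.alpha)
        self.g_ = G @ self.alpha_acc_
        self.G_ = G
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Predict ``intercept_ + g`` for new accessions.

        With ``kernel="grm"``, ``X`` holds new-accession dosages on the
        training marker set; with ``kernel="precomputed"``, ``X`` is the
        new x training relationship block.
        """
        X = _as_2d(X)
        if self.kernel == "grm":
            if X.shape[1] != self._W_train.shape[1]:
                raise ValidationError("marker count mismatch with training panel")
            G_no = ((X - 2.0 * self.theta_) / self._denom) @ self._W_train.T / X.shape[1]
        else:
            G_no = X
        return self.intercept_ + G_no @ self.alpha_acc_


class _GibbsRegressor(BaseEstimator, RegressorMixin):
    """Shared machinery for the marker-effect Gibbs samplers."""

    def _prepare(self, X, y, accession_idx, fixed):
        X = _as_2d(X)
        y = np.asarray(y, dtype=float).ravel()
        n_acc, p = X.shape
        theta = (
            np.asarray(self.theta, dtype=float)
            if self.theta is not None
            else X.mean(axis=0) / 2.0
        )
        Xc = X - 2.0 * theta
        if accession_idx is None:
            if y.size != n_acc:
                raise ValidationError("y length does not match accession count")
            accession_idx = np.arange(n_acc)
        accession_idx = np.asarray(accession_idx, dtype=int)
        if y.size != accession_idx.size:
            raise ValidationError("y length does not match accession_idx length")
        Xr = np.asfortranarray(Xc[accession_idx])
        F = np.ones((y.size, 1)) if fixed is None else _as_2d(fixed)
        if not (self.n_iter > self.burn_in >= 0):
            raise ValidationError("require n_iter > burn_in >= 0")
        return Xc, Xr, F, y, theta, accession_idx

    def _sample_fixed(self, rng, F, FtF_chol, e, beta, sigma2_e):
        e_full = e + F @ beta
        bhat = cho_solve(FtF_chol, F.T @ e_full)
        L = np.linalg.cholesky(np.linalg.inv(F.T @ F) * sigma2_e)
        beta_new = bhat + L @ rng.standard_normal(beta.size)
        return beta_new, e_full - F @ beta_new

    def predict(self, X):
        """``intercept_ + (X - 2 theta) @ b_`` for new accessions on the
        training marker set."""
        X = _as_2d(X)
        if X.shape[1] != self.b_.size:
            raise ValidationError("marker count mismatch with training panel")
        return self.intercept_ + (X - 2.0 * self.theta_) @ self.b_


class BayesB(_GibbsRegressor):
    """Mixture-prior whole-genome regression (variable selection).

    ``p(b_l) = pi * delta_0 + (1 - pi) * N(0, sigma2_bl)`` with
    ``sigma2_bl ~ scaled-inv-chi2(df_b, S_b)`` and ``pi ~ Beta`` with mean
    ``pi0`` and concentration ``p0``.  Posterior inclusion probabilities
    are reported in ``pip_``.
    """

    def __init__(self, n_iter: int = 12000, burn_in: int = 2000, thin: int = 5,
                 seed: int = 0, pi0: float = 0.5, p0: float = 10.0,
                 df_b: float = 5.0, s_b: float | None = None,
                 df_e: float = 5.0, s_e: float | None = None,
                 r2_prior: float = 0.5, theta=None, sample_pi: bool = True):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.pi0 = pi0
        self.p0 = p0
        self.df_b = df_b
        self.s_b = s_b
        self.df_e = df_e
        self.s_e = s_e
        self.r2_prior = r2_prior
        self.theta = theta
        self.sample_pi = sample_pi

    def fit(self, X, y, accession_idx=None, fixed=None):
        Xc, Xr, F, y, theta, _ = self._prepare(X, y, accession_idx, fixed)
        n, p = Xr.shape
        rng = np.random.default_rng(self.seed)
        vy = float(np.var(y))
        R2 = self.r2_prior
        msx = float(np.sum(2.0 * theta * (1.0 - theta)))
        pi0_eff = min(self.pi0, 1.0 - 1e-3)
        s_e = self.s_e if self.s_e is not None else vy * (1.0 - R2) * (self.df_e + 2.0)
        s_b = (
            self.s_b
            if self.s_b is not None
            else vy * R2 * (self.df_b + 2.0) / ((1.0 - pi0_eff) * max(msx, 1e-12))
        )
        c = np.einsum("ij,ij->j", Xr, Xr)

        b = np.zeros(p)
        incl = np.zeros(p, dtype=np.int64)
        var_b = np.full(p, s_b / (self.df_b + 2.0))
        beta = np.zeros(F.shape[1])
        FtF_chol = cho_factor(F.T @ F)
        sigma2_e = vy * (1.0 - R2)
        pi = self.pi0
        e = y - F @ beta

        n_keep = 0
        b_sum = np.zeros(p)
        pip_sum = np.zeros(p)
        beta_sum = np.zeros(F.shape[1])
        s2e_sum = 0.0
        pi_sum = 0.0
        s2e_trace, n_in_trace = [], []
        for it in range(self.n_iter):
            beta, e = self._sample_fixed(rng, F, FtF_chol, e, beta, sigma2_e)
            log_prior_odds = np.log((1.0 - pi) / max(pi, 1e-12)) if pi < 1.0 else -np.inf
            if pi >= 1.0:
                # degenerate all-null mixture: every effect is zero
                e += Xr @ b
                b[:] = 0.0
                incl[:] = 0
                n_in = 0
            else:
                n_in = sweep_bayes_b(
                    Xr, e, b, incl, var_b, c, sigma2_e, log_prior_odds,
                    rng.standard_normal(p), rng.random(p),
                )
            chi_in = rng.chisquare(self.df_b + 1.0, size=p)
            chi_out = rng.chisquare(self.df_b, size=p)
            var_b = np.where(
                incl == 1, (s_b + b**2) / chi_in, s_b / np.maximum(chi_out, 1e-12)
            )
            if self.sample_pi:
                pi = rng.beta(self.pi0 * self.p0 + (p - n_in), (1.0 - self.pi0) * self.p0 + n_in)
            sigma2_e = (e @ e + s_e) / rng.chisquare(n + self.df_e)
            if not np.isfinite(sigma2_e) or sigma2_e <= 0:
                raise ConvergenceError(f"divergent chain at iteration {it}: sigma2_e={sigma2_e!r}")
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                n_keep += 1
                b_sum += b
                pip_sum += incl
                beta_sum += beta
                s2e_sum += sigma2_e
                pi_sum += pi
                s2e_trace.append(sigma2_e)
                n_in_trace.append(n_in)

        self.b_ = b_sum / n_keep
        self.pip_ = pip_sum / n_keep
        self.beta_ = beta_sum / n_keep
        self.intercept_ = (
            float(self.beta_[0]) if fixed is None else float(np.mean(F @ self.beta_))
        )
        self.sigma2_e_ = s2e_sum / n_keep
        self.pi_ = pi_sum / n_keep
        self.theta_ = theta
        self.g_ = Xc @ self.b_
        self.n_features_in_ = p
        self.diagnostics_ = {
            "sigma2_e_trace": np.array(s2e_trace),
            "n_included_trace": np.array(n_in_trace),
            "n_samples": n_keep,
            "s_b": s_b,
            "s_e": s_e,
        }
        return self


class BayesianLasso(_GibbsRegressor):
    """Whole-genome regression with a double-exponential marker prior.

    Marker-specific prior variances are IID exponential with rate
    ``lambda2 / 2``; marginally the effects are Laplace.  The
    regularization parameter ``lambda2`` carries a gamma hyperprior whose
    mode sits at the variance-partition rule value, and is updated by
    Gibbs unless ``sample_lambda=False``.
    """

    def __init__(self, n_iter: int = 12000, burn_in: int = 2000, thin: int = 5,
                 seed: int = 0, df_e: float = 5.0, s_e: float | None = None,
                 r2_prior: float = 0.5, lambda2: float | None = None,
                 sample_lambda: bool = True, shape_lambda: float = 1.1, theta=None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.df_e = df_e
        self.s_e = s_e
        self.r2_prior = r2_prior
        self.lambda2 = lambda2
        self.sample_lambda = sample_lambda
        self.shape_lambda = shape_lambda
        self.theta = theta

    def fit(self, X, y, accession_idx=None, fixed=None):
        Xc, Xr, F, y, theta, _ = self._prepare(X, y, accession_idx, fixed)
        n, p = Xr.shape
        rng = np.random.default_rng(self.seed)
        vy = float(np.var(y))
        R2 = self.r2_prior
        msx = float(np.sum(2.0 * theta * (1.0 - theta)))
        s_e = self.s_e if self.s_e is not None else vy * (1.0 - R2) * (self.df_e + 2.0)
        lam2_0 = (
            self.lambda2
            if self.lambda2 is not None
            else 2.0 * (1.0 - R2) * max(msx, 1e-12) / R2
        )
        rate_lambda = (self.shape_lambda - 1.0) / lam2_0 if self.shape_lambda > 1.0 else 1e-4
        c = np.einsum("ij,ij->j", Xr, Xr)

        b = np.zeros(p)
        lam2 = lam2_0
        inv_tau2 = np.full(p, lam2 / 2.0)  # 1 / E[tau2]
        beta = np.zeros(F.shape[1])
        FtF_chol = cho_factor(F.T @ F)
        sigma2_e = vy * (1.0 - R2)
        e = y - F @ beta

        n_keep = 0
        b_sum = np.zeros(p)
        beta_sum = np.zeros(F.shape[1])
        s2e_sum = 0.0
        lam2_sum = 0.0
        s2e_trace = []
        for it in range(self.n_iter):
            beta, e = self._sample_fixed(rng, F, FtF_chol, e, beta, sigma2_e)
            sweep_lasso(Xr, e, b, inv_tau2, c, sigma2_e, rng.standard_normal(p))
            b2 = np.maximum(b**2, 1e-12)
            mean_ig = np.minimum(np.sqrt(lam2 * sigma2_e / b2), 1e8)
            inv_tau2 = rng.wald(mean_ig, lam2)
            tau2 = 1.0 / inv_tau2
            if self.sample_lambda:
                lam2 = rng.gamma(p + self.shape_lambda, 1.0 / (tau2.sum() / 2.0 + rate_lambda))
            sigma2_e = (e @ e + b2 @ inv_tau2 + s_e) / rng.chisquare(n + p + self.df_e)
            if not np.isfinite(sigma2_e) or sigma2_e <= 0 or not np.isfinite(b).all():
                raise ConvergenceError(f"divergent chain at iteration {it}")
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                n_keep += 1
                b_sum += b
                beta_sum += beta
                s2e_sum += sigma2_e
                lam2_sum += lam2
                s2e_trace.append(sigma2_e)

        self.b_ = b_sum / n_keep
        self.beta_ = beta_sum / n_keep
        self.intercept_ = (
            float(self.beta_[0]) if fixed is None else float(np.mean(F @ self.beta_))
        )
        self.sigma2_e_ = s2e_sum / n_keep
        self.lambda2_ = lam2_sum / n_keep
        self.theta_ = theta
        self.g_ = Xc @ self.b_
        self.n_features_in_ = p
        self.diagnostics_ = {
            "sigma2_e_trace": np.array(s2e_trace),
            "n_samples": n_keep,
            "s_e": s_e,
            "lambda2_init": lam2_0,
        }
        return self


# ---------------------------------------------------------------------------
# Module-level wrappers producing ModelFit objects
# ---------------------------------------------------------------------------
def _resolve_inputs(adj, trait: str, covariates: tuple[str, ...]):
    """Accept AdjustedPhenotypes (two-stage) or a raw phenotype frame (joint).

    Returns (y, accession order, accession_idx, F or None, used trait).
    """
    if isinstance(adj, AdjustedPhenotypes):
        df = adj.records
        accs = sorted(df["accession_id"].unique())
        idx = {a: i for i, a in enumerate(accs)}
        accession_idx = df["accession_id"].map(idx).to_numpy()
        return df["ytilde"].to_numpy(dtype=float), accs, accession_idx, None, adj.trait
    df = adj[adj["trait"] == trait].copy()
    if covariates:
        df = df.dropna(subset=list(covariates))
    if df.empty:
        raise ValidationError(f"no records for trait {trait!r}")
    F, _, _, _ = design_matrix(df, covariates)
    accs = sorted(df["accession_id"].unique())
    idx = {a: i for i, a in enumerate(accs)}
    accession_idx = df["accession_id"].map(idx).to_numpy()
    return df["value"].to_numpy(dtype=float), accs, accession_idx, F, trait


def fit_gblup(adj, K: KinshipMatrix, spec: ModelSpec | None = None) -> ModelFit:
    """G-BLUP fit; ``adj`` is an AdjustedPhenotypes (intercept-only fixed
    part on adjusted records) or a raw phenotype frame (joint fit of trial
    and MG-within-trial effects)."""
    spec = spec or ModelSpec(model="gblup")
    y, accs, accession_idx, F, trait = _resolve_inputs(adj, spec.trait, spec.covariates)
    missing = set(accs) - set(K.accession_ids)
    if missing:
        raise ValidationError(f"accessions missing from kinship: {sorted(missing)[:5]}")
    Ksub = K.subset(accs)
    est = GBLUP(kernel="precomputed", lambda_=spec.lambda_)
    est.fit(Ksub.G, y, accession_idx=accession_idx, fixed=F)
    preds = pd.DataFrame(
        {
            "accession_id": accs,
            "trait": trait,
            "prediction": est.intercept_ + est.g_,
            "phenotyped": True,
        }
    )
    fit = ModelFit(
        model="gblup",
        trait=trait,
        mu=est.intercept_,
        sigma2_g=est.sigma2_g_,
        sigma2_e=est.sigma2_e_,
        lambda_=est.lambda_opt_,
        h2=est.h2_,
        genetic_values=pd.Series(est.g_, index=accs),
        predictions=preds,
        diagnostics={"estimator": est, "loglik": est.loglik_},
    )
    return fit


def _fit_marker_model(adj, g: GenotypeMatrix, spec: ModelSpec, cls) -> ModelFit:
    y, accs, accession_idx, F, trait = _resolve_inputs(adj, spec.trait, spec.covariates)
    missing = set(accs) - set(g.accession_ids)
    if missing:
        raise ValidationError(f"accessions missing from genotypes: {sorted(missing)[:5]}")
    gsub = g.subset_accessions(accs)
    if np.isnan(gsub.dosages).any():
        raise ValidationError("genotypes contain missing calls; impute first")
    common = dict(n_iter=spec.n_iter, burn_in=spec.burn_in, thin=spec.thin,
                  seed=spec.seed, df_e=spec.df_e, s_e=spec.s_e,
                  r2_prior=spec.r2_prior, theta=gsub.theta)
    if cls is BayesB:
        est = BayesB(pi0=spec.pi0, p0=spec.p0, df_b=spec.df_b, s_b=spec.s_b, **common)
    else:
        est = BayesianLasso(lambda2=spec.lambda2, **common)
    est.fit(gsub.dosages, y, accession_idx=accession_idx, fixed=F)
    preds = pd.DataFrame(
        {
            "accession_id": accs,
            "trait": trait,
            "prediction": est.intercept_ + est.g_,
            "phenotyped": True,
        }
    )
    return ModelFit(
        model="bayes_b" if cls is BayesB else "bayesian_lasso",
        trait=trait,
        mu=est.intercept_,
        sigma2_e=est.sigma2_e_,
        genetic_values=pd.Series(est.g_, index=accs),
        marker_effects=pd.Series(est.b_, index=gsub.marker_ids),
        inclusion_prob=pd.Series(est.pip_, index=gsub.marker_ids) if cls is BayesB else None,
        predictions=preds,
        diagnostics={"estimator": est, **est.diagnostics_},
    )


def fit_bayes_b(adj, g: GenotypeMatrix, spec: ModelSpec | None = None) -> ModelFit:
    return _fit_marker_model(adj, g, spec or ModelSpec(model="bayes_b"), BayesB)


def fit_bayesian_lasso(adj, g: GenotypeMatrix, spec: ModelSpec | None = None) -> ModelFit:
    return _fit_marker_model(adj, g, spec or ModelSpec(model="bayesian_lasso"), BayesianLasso)


def predict_new(fit: ModelFit, g_new: GenotypeMatrix | None = None,
                K_joint: KinshipMatrix | None = None) -> pd.Series:
    """Predictions for non-phenotyped accessions, on the observed scale.

    Marker models require ``g_new`` on the training marker set; G-BLUP
    requires ``K_joint``, a kinship matrix covering training plus new
    accessions (the new/observed block is extracted here).
    """
    est = fit.diagnostics.get("estimator")
    if est is None:
        raise ValidationError("fit carries no estimator; refit before predicting")
    train_ids = list(fit.genetic_values.index)
    if fit.model == "gblup":
        if K_joint is None:
            raise ValidationError("G-BLUP prediction needs the joint kinship matrix")
        new_ids = [a for a in K_joint.accession_ids if a not in set(train_ids)]
        G_no = K_joint.block(new_ids, train_ids)
        return pd.Series(est.predict(G_no), index=new_ids, name=fit.trait)
    if g_new is None:
        raise ValidationError("marker-model prediction needs new genotypes")
    missing = [m for m in fit.marker_effects.index if m not in set(g_new.marker_ids)]
    if missing:
        raise ValidationError(f"new genotypes lack training markers: {missing[:5]}")
    order = [g_new.marker_ids.index(m) for m in fit.marker_effects.index]
    X = g_new.dosages[:, order]
    if np.isnan(X).any():
        raise ValidationError("new genotypes contain missing calls; impute first")
    return pd.Series(est.predict(X), index=g_new.accession_ids, name=fit.trait)
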