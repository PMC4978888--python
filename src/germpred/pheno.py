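"""Fixed-effect structure of the record-level model and adjusted phenotypes.

The record-level linear predictor is

    y_ijk = mu + e_j + m_k(j) + g_i + eps_ijk

with ``e_j`` the trial effect, ``m_k(j)`` the maturity-group effect nested
within trial (maturity adaptation changes with trial latitude), and
optionally lodging/shattering scores as fixed covariates.  Effects are
estimated by ordinary least squares under sum-to-zero constraints; the
adjusted phenotype removes the fitted fixed part while keeping the grand
mean, ``ytilde = y - (fitted - mu)``.

Entry-mean broad-sense heritability for a replicated trial is estimated
from the rep (fixed) + accession (random) model via REML,
``H2 = s2_A / (s2_A + s2_e / r)`` with ``r`` the harmonic-mean rep count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .mixedlm import reml_fit

logger = logging.getLogger(__name__)


def _effects_coding(labels: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L-1 columns, last level coded -1."""
    n = len(labels)
    cols = np.zeros((n, len(levels) - 1))
    index = {lv: i for i, lv in enumerate(levels)}
    codes = labels.map(index).to_numpy()
    for j in range(len(levels) - 1):
        cols[codes == j, j] = 1.0
    cols[codes == len(levels) - 1, :] = -1.0
    return cols


def design_matrix(
    df: pd.DataFrame, covariates: tuple[str, ...] = ()
) -> tuple[np.ndarray, list[str], list, dict]:
    """Sum-to-zero fixed-effect design: intercept, trial, MG nested in trial,
    plus numeric covariate columns.  Returns (X, column names, trial levels,
    observed MG levels per trial)."""
    n = len(df)
    trials = sorted(df["trial_id"].unique())
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["mu"]
    if len(trials) > 1:
        blocks.append(_effects_coding(df["trial_id"], trials))
        names += [f"trial[{t}]" for t in trials[:-1]]
    mg_levels: dict = {}
    for t in trials:
        sub = df["trial_id"] == t
        mgs = sorted(df.loc[sub, "maturity_group"].unique())
        mg_levels[t] = mgs
        if len(mgs) > 1:
            cols = np.zeros((n, len(mgs) - 1))
            cols[sub.to_numpy()] = _effects_coding(df.loc[sub, "maturity_group"], mgs)
            blocks.append(cols)
            names += [f"mg[{t}:{m}]" for m in mgs[:-1]]
    for cov in covariates:
        blocks.append(df[cov].to_numpy(dtype=float)[:, None])
        names.append(cov)
    return np.hstack(blocks), names, trials, mg_levels


@dataclass
class FixedEffectDesign:
    """Fitted fixed-effect structure for one trait."""

    trait: str
    covariates: tuple[str, ...]
    mu: float
    trial_effects: pd.Series              # e_j, sum to zero
    mg_effects: dict                      # (trial, mg) -> m_k(j), sum to zero within trial
    covariate_coefs: pd.Series
    sigma2_eps: float
    cells: set = field(default_factory=set)   # observed (trial, mg) combinations

    def fixed_part(self, df: pd.DataFrame) -> np.ndarray:
        """Fitted fixed part (including mu and covariates) for records."""
        unseen = set(zip(df["trial_id"], df["maturity_group"])) - self.cells
        if unseen:
            raise ValidationError(f"record(s) from unseen (trial, MG) cell(s): {sorted(unseen)[:5]}")
        out = np.full(len(df), self.mu, dtype=float)
        out += df["trial_id"].map(self.trial_effects).fillna(0.0).to_numpy()
        mg_map = {k: v for k, v in self.mg_effects.items()}
        keys = list(zip(df["trial_id"], df["maturity_group"]))
        out += np.array([mg_map.get(k, 0.0) for k in keys])
        for cov in self.covariates:
            out += self.covariate_coefs[cov] * df[cov].to_numpy(dtype=float)
        return out


def fit_fixed_effects(
    pheno: pd.DataFrame,
    trait: str,
    covariates: tuple[str, ...] = (),
) -> FixedEffectDesign:
    """OLS fit of trial + MG(trial) (+ covariate) fixed effects for one trait.

    Records lacking a requested covariate are dropped with a logged count.
    Sum-to-zero constraints make the parametrization full rank; a residual
    rank deficiency (aliased cells) raises naming the offending columns.
    """
    covariates = tuple(covariates)
    bad = set(covariates) - {"lodging", "shattering"}
    if bad:
        raise ValidationError(f"unsupported covariate(s): {sorted(bad)}")
    df = pheno[pheno["trait"] == trait].copy()
    if df.empty:
        raise ValidationError(f"no records for trait {trait!r}")
    if covariates:
        before = len(df)
        df = df.dropna(subset=list(covariates))
        if len(df) < before:
            logger.info("dropped %d records lacking covariate scores", before - len(df))
        if df.empty:
            raise ValidationError("no records with complete covariate scores")

    y = df["value"].to_numpy(dtype=float)
    n = len(df)
    X, names, trials, mg_levels = design_matrix(df, covariates)

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in np.flatnonzero(np.abs(np.diag(R)) < 1e-8)]
        raise ValidationError(f"rank-deficient fixed-effect design; aliased: {aliased}")
    fitted = X @ coef
    dof = n - rank
    sigma2 = float(np.sum((y - fitted) ** 2) / dof) if dof > 0 else 0.0

    pos = 1
    mu = float(coef[0])
    trial_eff = pd.Series(0.0, index=trials)
    if len(trials) > 1:
        vals = coef[pos : pos + len(trials) - 1]
        trial_eff[:] = np.append(vals, -vals.sum())
        pos += len(trials) - 1
    mg_eff: dict = {}
    for t in trials:
        mgs = mg_levels[t]
        if len(mgs) > 1:
            vals = coef[pos : pos + len(mgs) - 1]
            full = np.append(vals, -vals.sum())
            for m, v in zip(mgs, full):
                mg_eff[(t, m)] = float(v)
            pos += len(mgs) - 1
        else:
            mg_eff[(t, mgs[0])] = 0.0
    cov_coefs = pd.Series({c: float(coef[pos + i]) for i, c in enumerate(covariates)})

    cells = set(zip(df["trial_id"], df["maturity_group"]))
    return FixedEffectDesign(
        trait, covariates, mu, trial_eff, mg_eff, cov_coefs, sigma2, cells
    )


@dataclass
class AdjustedPhenotypes:
    """Record-level and accession-aggregated adjusted phenotypes."""

    trait: str
    records: pd.DataFrame        # original columns + "ytilde"
    by_accession: pd.Series      # mean ytilde per accession
    mu: float


def adjust_phenotypes(pheno: pd.DataFrame, design: FixedEffectDesign) -> AdjustedPhenotypes:
    """Remove fitted trial/MG (and covariate) effects, keeping the grand mean.

    ``ytilde = y - (fixed_part - mu)``; the accession-level value is the
    mean of that accession's record-level ytilde.
    """
    df = pheno[pheno["trait"] == design.trait].copy()
    if design.covariates:
        df = df.dropna(subset=list(design.covariates))
    fitted = design.fixed_part(df)
    df["ytilde"] = df["value"].to_numpy(dtype=float) - (fitted - design.mu)
    agg = df.groupby("accession_id")["ytilde"].mean()
    return AdjustedPhenotypes(design.trait, df, agg, design.mu)


def entry_mean_heritability(records: pd.DataFrame, value_col: str = "value",
                            rep_col: str = "rep", accession_col: str = "accession_id") -> float:
    """Broad-sense heritability on an entry-mean basis for one replicated trial.

    Fits ``y = rep (fixed) + accession (random)`` by REML and returns
    ``H2 = s2_A / (s2_A + s2_e / r)`` with ``r`` the harmonic mean of
    per-accession rep counts.  Negative component estimates are truncated
    at zero (REML is non-negative by construction).
    """
    df = records.dropna(subset=[value_col])
    reps = sorted(df[rep_col].unique())
    if len(reps) < 2:
        raise ValidationError("heritability undefined on entry-mean basis: single rep")
    accs = sorted(df[accession_col].unique())
    if len(accs) < 2:
        raise ValidationError("need at least 2 accessions")
    y = df[value_col].to_numpy(dtype=float)
    n = len(df)
    F = np.hstack([np.ones((n, 1)), _effects_coding(df[rep_col], reps)]) if len(reps) > 1 else np.ones((n, 1))
    acc_index = {a: i for i, a in enumerate(accs)}
    Z = np.zeros((n, len(accs)))
    Z[np.arange(n), df[accession_col].map(acc_index).to_numpy()] = 1.0
    res = reml_fit(Z @ Z.T, F, y)
    s2a = max(res.sigma2_g, 0.0)
    s2e = max(res.sigma2_e, 0.0)
    counts = df.groupby(accession_col)[value_col].count()
    r = len(counts) / np.sum(1.0 / counts.to_numpy(dtype=float))
    if s2a == 0.0 and s2e == 0.0:
        return 1.0
    if s2e == 0.0:
        return 1.0
    return float(s2a / (s2a + s2e / r))
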