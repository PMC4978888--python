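"""Grouping criteria and the four cross-validation schemes.

Groups are trials, states, or genetic clusters.  The four schemes mimic
predicting accessions with no data of their own:

* ``one_group`` — leave-one-accession-out within each group (run as
  accession-level k-fold for tractability; set ``loo=True`` for literal
  leave-one-out);
* ``one_all``  — same folds, but training draws on all groups;
* ``group_all`` — each whole group predicted from all other groups;
* ``group_group`` — every ordered pair: train on one group, predict another.

The leakage rule is enforced in every fold: all phenotypic records of any
accession in the validation set are removed from the training set, and an
assertion verifies the training/validation accession sets are disjoint.
Predictive ability is the Pearson correlation between predictions and
observed phenotypes adjusted for trial and MG effects, compiled per group,
with percentile bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import KinshipMatrix, MembershipTable
from .evaluate import bootstrap_ci, predictive_ability
from .exceptions import ValidationError
from .models import GBLUP
from .pheno import adjust_phenotypes, fit_fixed_effects

logger = logging.getLogger(__name__)

SCHEMES = ("one_group", "one_all", "group_all", "group_group")
CRITERIA = ("trial", "state", "cluster")


@dataclass
class Grouping:
    """Record- or accession-level group labels under one criterion."""

    criterion: str                 # trial | state | cluster
    accession_groups: pd.Series | None   # for cluster: accession -> label
    record_column: str | None            # for trial/state: phenotype column name

    def groups_of(self, pheno: pd.DataFrame) -> dict[str, set]:
        """Map group label -> set of accession ids with records in it."""
        if self.criterion == "cluster":
            present = set(pheno["accession_id"])
            out: dict[str, set] = {}
            for acc, lab in self.accession_groups.items():
                if acc in present:
                    out.setdefault(str(lab), set()).add(acc)
            return out
        return {
            str(k): set(v)
            for k, v in pheno.groupby(self.record_column)["accession_id"].unique().items()
        }

    def record_mask(self, pheno: pd.DataFrame, group: str) -> np.ndarray:
        """Boolean mask of records belonging to ``group``."""
        if self.criterion == "cluster":
            accs = {a for a, lab in self.accession_groups.items() if str(lab) == group}
            return pheno["accession_id"].isin(accs).to_numpy()
        return (pheno[self.record_column].astype(str) == group).to_numpy()


def grouping_by(criterion: str, membership: MembershipTable | None = None) -> Grouping:
    if criterion == "trial":
        return Grouping("trial", None, "trial_id")
    if criterion == "state":
        return Grouping("state", None, "state")
    if criterion == "cluster":
        if membership is None:
            raise ValidationError("cluster grouping needs a membership table")
        return assign_clusters(membership)
    raise ValidationError(f"unknown grouping criterion {criterion!r}")


def assign_clusters(m: MembershipTable) -> Grouping:
    """Assign each accession to its highest-probability subpopulation.

    Ties are broken by the lowest cluster index (logged).
    """
    probs = m.probabilities
    best = probs.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    n_tied = int((np.sum(probs == probs.max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_tied:
        logger.info("assign_clusters: %d tie(s) broken toward the lowest cluster index", n_tied)
    labels = pd.Series((best + 1).astype(str), index=m.accession_ids)
    return Grouping("cluster", labels, None)


def select_k_plateau(cv_errors, tol: float, k_values=None) -> int:
    """Pick the subpopulation count where the drop in CV error plateaus.

    ``delta_K = error_{K-1} - error_K``; returns the smallest K at which
    this drop, and every subsequent drop, falls below ``tol``.  If the
    errors never plateau, the largest K is returned with a warning.
    """
    errors = np.asarray(cv_errors, dtype=float)
    if errors.size < 3:
        raise ValidationError("need at least 3 consecutive K values")
    ks = list(k_values) if k_values is not None else list(range(1, errors.size + 1))
    delta = errors[:-1] - errors[1:]  # delta[i] belongs to K = ks[i + 1]
    for i in range(delta.size):
        if np.all(delta[i:] < tol):
            return ks[i + 1]
    warnings.warn("CV error never plateaued within the K range; returning the largest K")
    return ks[-1]


@dataclass
class CVReport:
    """Per-group predictive abilities for one scheme x criterion."""

    scheme: str
    criterion: str
    trait: str
    table: pd.DataFrame  # group[, train_group], r, ci_low, ci_high, n_train, n_val
    predictions: pd.DataFrame  # accession_id, group, prediction, observed

    def mean_r(self) -> float:
        return float(self.table["r"].mean(skipna=True))


def _fold_assignments(accessions: list, n_folds: int, rng: np.random.Generator,
                      loo: bool) -> list[list]:
    accs = sorted(accessions)
    order = rng.permutation(len(accs))
    k = len(accs) if loo else min(n_folds, len(accs))
    folds: list[list] = [[] for _ in range(k)]
    for pos, j in enumerate(order):
        folds[pos % k].append(accs[j])
    return [f for f in folds if f]


def _score_group(pred: pd.Series, obs: pd.Series, n_boot: int, seed: int,
                 min_val: int) -> tuple[float, float, float]:
    if len(pred) < min_val:
        return np.nan, np.nan, np.nan
    try:
        r = predictive_ability(pred.to_numpy(), obs.to_numpy())
    except ValidationError:
        return np.nan, np.nan, np.nan
    lo, hi = bootstrap_ci(pred.to_numpy(), obs.to_numpy(), reps=n_boot, seed=seed)
    return r, lo, hi


def run_scheme(
    scheme: str,
    grouping: Grouping,
    pheno: pd.DataFrame,
    trait: str,
    K: KinshipMatrix,
    covariates: tuple[str, ...] = (),
    n_folds: int = 10,
    loo: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
    min_val: int = 3,
    lambda_: float | None = None,
) -> CVReport:
    """Run one CV scheme under one grouping criterion with G-BLUP.

    Phenotypes are adjusted for trial and MG (and optional covariate)
    effects with a design fitted on all records of the trait; the model is
    then trained on accession-level adjusted means.  Validation
    observations are the adjusted phenotypes aggregated per accession
    within the group being scored.  Groups with fewer than ``min_val``
    validation accessions report an undefined (NaN) predictive ability.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    design = fit_fixed_effects(pheno, trait, covariates)
    adj = adjust_phenotypes(pheno, design)
    records = adj.records.reset_index(drop=True)
    groups = grouping.groups_of(records)
    if not groups:
        raise ValidationError("grouping produced no groups for these records")
    group_names = sorted(groups)
    acc_ids = K.accession_ids
    missing = set(records["accession_id"]) - set(acc_ids)
    if missing:
        raise ValidationError(f"phenotyped accessions missing from kinship: {sorted(missing)[:5]}")

    rows = []
    pred_rows = []

    def fit_predict(train_mask: np.ndarray, val_accs: list) -> pd.Series:
        train = records[train_mask]
        train_accs = sorted(set(train["accession_id"]))
        overlap = set(train_accs) & set(val_accs)
        assert not overlap, f"leakage: accession(s) in both training and validation: {sorted(overlap)[:5]}"
        if len(train_accs) < 5:
            return pd.Series(np.nan, index=list(val_accs))
        ytr = train.groupby("accession_id")["ytilde"].mean().loc[train_accs]
        est = GBLUP(kernel="precomputed", lambda_=lambda_)
        est.fit(K.subset(train_accs).G, ytr.to_numpy())
        G_no = K.block(list(val_accs), train_accs)
        return pd.Series(est.predict(G_no), index=list(val_accs))

    def obs_within(group: str, accs: list) -> pd.Series:
        mask = grouping.record_mask(records, group)
        sub = records[mask & records["accession_id"].isin(accs)]
        return sub.groupby("accession_id")["ytilde"].mean().reindex(accs)

    if scheme in ("one_group", "one_all"):
        for gi, gname in enumerate(group_names):
            rng = np.random.default_rng([seed, gi])
            group_accs = sorted(groups[gname])
            in_group = grouping.record_mask(records, gname)
            preds = {}
            for fold in _fold_assignments(group_accs, n_folds, rng, loo):
                val = sorted(fold)
                not_val = ~records["accession_id"].isin(val).to_numpy()
                train_mask = not_val & in_group if scheme == "one_group" else not_val
                preds.update(fit_predict(train_mask, val).to_dict())
                n_train = int(train_mask.sum())
            pred = pd.Series(preds).reindex(group_accs)
            obs = obs_within(gname, group_accs)
            r, lo, hi = _score_group(pred, obs, n_boot, seed + gi, min_val)
            rows.append((gname, r, lo, hi, n_train, len(group_accs)))
            pred_rows.append(pd.DataFrame({"accession_id": group_accs, "group": gname,
                                           "prediction": pred.to_numpy(),
                                           "observed": obs.to_numpy()}))
    elif scheme == "group_all":
        for gi, gname in enumerate(group_names):
            val = sorted(groups[gname])
            in_group = grouping.record_mask(records, gname)
            train_mask = (~in_group) & (~records["accession_id"].isin(val).to_numpy())
            if not train_mask.any():
                rows.append((gname, np.nan, np.nan, np.nan, 0, len(val)))
                continue
            pred = fit_predict(train_mask, val)
            obs = obs_within(gname, val)
            r, lo, hi = _score_group(pred, obs, n_boot, seed + gi, min_val)
            rows.append((gname, r, lo, hi, int(train_mask.sum()), len(val)))
            pred_rows.append(pd.DataFrame({"accession_id": val, "group": gname,
                                           "prediction": pred.to_numpy(),
                                           "observed": obs.to_numpy()}))
    else:  # group_group: ordered (train -> validate) pairs
        for gi, gtrain in enumerate(group_names):
            in_train_group = grouping.record_mask(records, gtrain)
            for gj, gval in enumerate(group_names):
                if gval == gtrain:
                    continue
                val = sorted(groups[gval])
                train_mask = in_train_group & (~records["accession_id"].isin(val).to_numpy())
                if not train_mask.any():
                    rows.append(((gval, gtrain), np.nan, np.nan, np.nan, 0, len(val)))
                    continue
                pred = fit_predict(train_mask, val)
                obs = obs_within(gval, val)
                r, lo, hi = _score_group(pred, obs, n_boot, seed + gi * len(group_names) + gj, min_val)
                rows.append(((gval, gtrain), r, lo, hi, int(train_mask.sum()), len(val)))
                pred_rows.append(pd.DataFrame({"accession_id": val, "group": f"{gtrain}->{gval}",
                                               "prediction": pred.to_numpy(),
                                               "observed": obs.to_numpy()}))

    if scheme == "group_group":
        table = pd.DataFrame(
            [(g[0], g[1], r, lo, hi, nt, nv) for g, r, lo, hi, nt, nv in rows],
            columns=["group", "train_group", "r", "ci_low", "ci_high", "n_train", "n_val"],
        )
    else:
        table = pd.DataFrame(rows, columns=["group", "r", "ci_low", "ci_high", "n_train", "n_val"])
    predictions = (
        pd.concat(pred_rows, ignore_index=True) if pred_rows
        else pd.DataFrame(columns=["accession_id", "group", "prediction", "observed"])
    )
    return CVReport(scheme, grouping.criterion, trait, table, predictions)
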