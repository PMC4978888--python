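"""Predictive-ability statistics, bootstrap intervals and selection enrichment.

Predictive ability is the plain Pearson correlation between genomic
predictions and observed phenotypes adjusted for trial and MG effects —
deliberately not divided by the square root of heritability, so values are
conservative relative to true prediction accuracy.  Confidence intervals
use the percentile bootstrap over paired resampling.  Selection enrichment
mimics choosing the top fraction of accessions by prediction and checking
how they actually performed: the share observed above the group mean, and
the share falling in the observed bottom decile.
"""

from __future__ import annotations

import logging
from math import ceil

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


def predictive_ability(pred, obs) -> float:
    """Pearson correlation between predictions and (adjusted) observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValidationError("pred and obs must be 1-D arrays of equal length")
    keep = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[keep], obs[keep]
    if pred.size < 3:
        raise ValidationError("need at least 3 paired values")
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        raise ValidationError("predictive ability undefined: zero variance in a vector")
    return float(np.corrcoef(pred, obs)[0, 1])


def bootstrap_ci(pred, obs, reps: int = 10000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for the Pearson predictive ability.

    Resamples pairs with replacement; degenerate resamples (zero variance
    in either vector) are redrawn with a logged count.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    keep = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[keep], obs[keep]
    n = pred.size
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    rng = np.random.default_rng(seed)
    rs = np.empty(reps)
    filled = 0
    redrawn = 0
    while filled < reps:
        m = reps - filled
        idx = rng.integers(0, n, size=(m, n))
        p = pred[idx]
        o = obs[idx]
        pc = p - p.mean(axis=1, keepdims=True)
        oc = o - o.mean(axis=1, keepdims=True)
        sp = np.sqrt((pc**2).sum(axis=1))
        so = np.sqrt((oc**2).sum(axis=1))
        ok = (sp > 0) & (so > 0)
        vals = (pc * oc).sum(axis=1)[ok] / (sp[ok] * so[ok])
        rs[filled : filled + vals.size] = vals
        redrawn += int(m - vals.size)
        filled += vals.size
    if redrawn:
        logger.info("bootstrap_ci: redrew %d degenerate resample(s)", redrawn)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(rs, alpha)), float(np.quantile(rs, 1.0 - alpha))


def covariate_reduction(report_raw, report_adj) -> pd.DataFrame:
    """Per-group % reduction in predictive ability after covariate correction.

    ``100 * (r_raw - r_adj) / r_raw`` per group; groups with ``r_raw <= 0``
    are flagged undefined.  A ``mean`` row over defined groups is appended.
    """
    raw = report_raw.table.set_index("group")["r"] if hasattr(report_raw, "table") else report_raw
    adj = report_adj.table.set_index("group")["r"] if hasattr(report_adj, "table") else report_adj
    if set(raw.index) != set(adj.index):
        raise ValidationError("reports cover different groups")
    rows = []
    for g in raw.index:
        r0, r1 = raw[g], adj[g]
        if not np.isfinite(r0) or r0 <= 0:
            rows.append((g, r0, r1, np.nan, True))
        else:
            rows.append((g, r0, r1, 100.0 * (r0 - r1) / r0, False))
    out = pd.DataFrame(rows, columns=["group", "r_raw", "r_adj", "pct_reduction", "undefined"])
    mean_val = out.loc[~out["undefined"], "pct_reduction"].mean()
    out.loc[len(out)] = ("mean", np.nan, np.nan, mean_val, False)
    return out


def enrichment(pred, obs, top_frac: float = 0.10) -> tuple[float, float]:
    """Outcome of selecting the top fraction of accessions by prediction.

    Returns ``(pct_better_than_mean, pct_in_bottom_decile)``: among the
    ``ceil(top_frac * n)`` accessions with the highest predictions (ties
    broken by stable input order), the percentage observed above the mean
    of ``obs`` and the percentage observed at or below the empirical 10th
    percentile of ``obs``.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    n = pred.size
    if n < 10:
        raise ValidationError("enrichment undefined: need at least 10 accessions")
    k = ceil(top_frac * n)
    top = np.argsort(-pred, kind="stable")[:k]
    sel = obs[top]
    pct_better = 100.0 * float(np.mean(sel > obs.mean()))
    q10 = np.quantile(obs, 0.10)  # type-7 (linear) quantile
    pct_bottom = 100.0 * float(np.mean(sel <= q10))
    return pct_better, pct_bottom


def enrichment_by_group(predictions: pd.DataFrame, top_frac: float = 0.10) -> pd.DataFrame:
    """Per-group enrichment from a CV predictions frame
    (columns accession_id, group, prediction, observed)."""
    rows = []
    for g, sub in predictions.groupby("group"):
        sub = sub.dropna(subset=["prediction", "observed"])
        if len(sub) < 10:
            rows.append((g, np.nan, np.nan, len(sub)))
            continue
        better, bottom = enrichment(sub["prediction"].to_numpy(), sub["observed"].to_numpy(), top_frac)
        rows.append((g, better, bottom, len(sub)))
    out = pd.DataFrame(rows, columns=["group", "pct_gt_mean", "pct_bottom10", "n"])
    out.loc[len(out)] = ("mean", out["pct_gt_mean"].mean(), out["pct_bottom10"].mean(), out["n"].sum())
    return out
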