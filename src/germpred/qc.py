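"""Marker filtering and missing-data handling.

Markers with a missing fraction strictly greater than ``max_missing_frac``
or a minor-allele frequency strictly below ``min_maf`` are removed; markers
at exactly the thresholds are kept.  Missing calls are imputed with the
marker mean ``2*theta_l``, which leaves the allele frequency of every
marker unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .exceptions import EmptyPanelError, ValidationError

logger = logging.getLogger(__name__)


def filter_markers(
    g: GenotypeMatrix,
    max_missing_frac: float = 0.80,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove markers by missingness then minor-allele frequency.

    Retains marker ``l`` iff ``missing_frac(l) <= max_missing_frac`` and
    ``maf(l) >= min_maf`` with ``maf = min(theta, 1 - theta)``; markers with
    no non-missing call are always removed (frequency undefined).  Returns
    the filtered panel (theta recomputed on non-missing calls) and a report
    with one row per removed marker and its reason.
    """
    if not (0.0 <= max_missing_frac <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValidationError("thresholds must lie in [0, 1]")
    n = g.n_accessions
    mask = g.missing_mask
    n_obs = (~mask).sum(axis=0)
    missing_frac = mask.sum(axis=0) / n
    theta = g.compute_theta()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(theta, 1.0 - theta)

    drop_missing = (missing_frac > max_missing_frac) | (n_obs == 0)
    drop_maf = ~drop_missing & (maf < min_maf)
    keep = ~(drop_missing | drop_maf)

    rows = []
    for j in np.flatnonzero(drop_missing):
        rows.append((g.marker_ids[j], "missingness", missing_frac[j], np.nan))
    for j in np.flatnonzero(drop_maf):
        rows.append((g.marker_ids[j], "maf", missing_frac[j], maf[j]))
    report = pd.DataFrame(rows, columns=["marker_id", "reason", "missing_frac", "maf"])

    if not keep.any():
        raise EmptyPanelError("empty panel: all markers removed by QC filters")
    out = GenotypeMatrix(
        g.accession_ids,
        [g.marker_ids[j] for j in np.flatnonzero(keep)],
        g.dosages[:, keep],
        theta[keep],
    )
    logger.info("QC retained %d/%d markers", out.n_markers, g.n_markers)
    return out, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call at marker ``l`` with the marker mean ``2*theta_l``.

    Non-missing cells are untouched; the pre-imputation theta is frozen in
    the result so downstream kinship uses a single frequency definition.
    Imputed dosages are fractional by construction.
    """
    theta = g.theta if g.theta is not None else g.compute_theta()
    if np.isnan(theta).any():
        bad = [g.marker_ids[j] for j in np.flatnonzero(np.isnan(theta))[:5]]
        raise ValidationError(
            f"marker(s) with zero non-missing calls cannot be imputed: {bad}"
        )
    dosages = g.dosages.copy()
    mask = np.isnan(dosages)
    fill = np.broadcast_to(2.0 * theta, dosages.shape)
    dosages[mask] = fill[mask]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    # bypass {0,1,2} domain validation: imputed cells are fractional means
    out.accession_ids = list(g.accession_ids)
    out.marker_ids = list(g.marker_ids)
    out.dosages = dosages
    out.theta = np.asarray(theta, dtype=float).copy()
    return out
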