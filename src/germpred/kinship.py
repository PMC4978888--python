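"""Genomic relationship matrix (GRM).

The entry for accessions ``i, i'`` is

    G_ii' = (1/p) * sum_l (x_il - 2*theta_l) * (x_i'l - 2*theta_l) / (2*theta_l*(1-theta_l))

i.e. markers are centered at twice their allele frequency and standardized
per marker before averaging over the ``p`` markers.  With in-sample
frequencies the centered scores sum to zero over accessions, so every row
of G sums to zero; for fully inbred panels the expected diagonal is
``1 + F = 2``.
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix, KinshipMatrix
from .exceptions import ValidationError


def compute_grm(g: GenotypeMatrix) -> KinshipMatrix:
    """Compute the per-marker-standardized GRM from an imputed genotype panel.

    ``g`` must be free of missing calls (impute first); allele frequencies
    ``theta`` must lie strictly inside (0, 1) for every marker — fixed
    markers should have been removed by the MAF filter.
    """
    if np.isnan(g.dosages).any():
        raise ValidationError("genotype matrix has missing calls; impute before the GRM")
    theta = g.theta if g.theta is not None else g.compute_theta()
    fixed = (theta <= 0.0) | (theta >= 1.0)
    if fixed.any():
        bad = [g.marker_ids[j] for j in np.flatnonzero(fixed)[:5]]
        raise ValidationError(
            f"marker(s) with allele frequency 0 or 1 (division by zero): {bad}"
        )
    w = g.dosages - 2.0 * theta
    denom = 2.0 * theta * (1.0 - theta)
    G = (w / denom) @ w.T / g.n_markers
    G = (G + G.T) / 2.0  # symmetrize away float round-off
    return KinshipMatrix(list(g.accession_ids), G, p_markers=g.n_markers)
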