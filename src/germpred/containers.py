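"""In-memory containers shared across the pipeline.

Genotypes are allele dosages of fully inbred (or near-inbred) accessions:
an ``n_accessions x n_markers`` matrix with entries in {0, 1, 2} and NaN for
missing calls.  Phenotypes are long-format records keyed by
(accession, trial, trait), carrying the trial's state, the maturity group
the trial blocked the accession into, and optional lodging/shattering
scores on the 1-5 field scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

PHENO_COLUMNS = [
    "accession_id",
    "trial_id",
    "state",
    "maturity_group",
    "trait",
    "value",
    "lodging",
    "shattering",
]


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} id(s): {sorted(set(dups))[:5]}")


@dataclass
class GenotypeMatrix:
    """Accessions x markers allele-dosage matrix with missingness mask.

    Parameters
    ----------
    accession_ids, marker_ids
        Ordered unique string identifiers.
    dosages
        Float array of shape ``(n, p)`` with entries in {0, 1, 2}; missing
        calls are ``np.nan``.
    theta
        Per-marker allele frequency of the dosage-counted allele.  When
        ``None`` it is (re)computed from the non-missing calls as
        ``sum(dosages) / (2 * n_nonmissing)``.  After imputation the
        pre-imputation value is frozen here so downstream kinship uses a
        single definition.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.marker_ids, "marker")
        vals = self.dosages[~np.isnan(self.dosages)]
        bad = ~np.isin(vals, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValidationError(
                f"dosage entries outside {{0,1,2,missing}}: e.g. {vals[bad][:3]}"
            )
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape != (len(self.marker_ids),):
                raise ValidationError("theta length does not match marker count")

    # ------------------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def compute_theta(self) -> np.ndarray:
        """Allele frequency per marker from non-missing calls."""
        n_obs = (~np.isnan(self.dosages)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.nansum(self.dosages, axis=0) / (2.0 * n_obs)
        return theta

    def with_theta(self) -> "GenotypeMatrix":
        """Return self with ``theta`` populated (computed if absent)."""
        if self.theta is None:
            self.theta = self.compute_theta()
        return self

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        theta = self.theta[keep] if self.theta is not None else None
        return GenotypeMatrix(
            self.accession_ids,
            [self.marker_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.marker_ids[i] for i in keep],
            self.dosages[:, keep],
            theta,
        )

    def subset_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [index[a] for a in ids]
        return GenotypeMatrix(list(ids), self.marker_ids, self.dosages[rows], self.theta)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table and return it.

    Enforces: required columns; lodging/shattering in 1..5 when present;
    (accession, trial, trait) unique; each trial maps to exactly one state.
    """
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table lacks column(s): {missing}")
    for col in ("lodging", "shattering"):
        vals = df[col].dropna()
        bad = ~vals.isin([1, 2, 3, 4, 5])
        if bad.any():
            raise ValidationError(f"{col} scores outside 1-5 scale: {sorted(vals[bad].unique())[:5]}")
    dup = df.duplicated(subset=["accession_id", "trial_id", "trait"])
    if dup.any():
        rows = df.loc[dup, ["accession_id", "trial_id", "trait"]].iloc[0].tolist()
        raise ValidationError(f"duplicate (accession, trial, trait) record, e.g. {rows}")
    states = df.groupby("trial_id")["state"].nunique()
    multi = states[states > 1]
    if len(multi):
        raise ValidationError(f"trial(s) mapped to multiple states: {list(multi.index)[:5]}")
    return df


@dataclass
class MembershipTable:
    """Per-accession subpopulation membership probabilities (K clusters)."""

    accession_ids: list[str]
    probabilities: np.ndarray  # n x K

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        _check_unique(self.accession_ids, "accession")
        if self.probabilities.ndim != 2 or self.probabilities.shape[0] != len(self.accession_ids):
            raise ValidationError("membership probabilities must be n_accessions x K")
        if (self.probabilities < 0).any():
            raise ValidationError("negative membership probability")
        sums = self.probabilities.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-8
        if off.any():
            i = int(np.flatnonzero(off)[0])
            raise ValidationError(
                f"membership row for {self.accession_ids[i]} sums to {sums[i]!r}, not 1"
            )

    @property
    def n_clusters(self) -> int:
        return self.probabilities.shape[1]


@dataclass
class KinshipMatrix:
    """Symmetric accession x accession genomic relationship matrix."""

    accession_ids: list[str]
    G: np.ndarray
    p_markers: int = 0

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.accession_ids)
        if self.G.shape != (n, n):
            raise ValidationError(f"kinship shape {self.G.shape} does not match {n} ids")
        if not np.isfinite(self.G).all():
            raise ValidationError("kinship matrix has non-finite entries")
        if np.abs(self.G - self.G.T).max(initial=0.0) > 1e-10:
            raise ValidationError("kinship matrix is not symmetric to 1e-10")

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        rows = np.array([index[a] for a in ids])
        return KinshipMatrix(list(ids), self.G[np.ix_(rows, rows)], self.p_markers)

    def block(self, rows_ids: list[str], cols_ids: list[str]) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.accession_ids)}
        r = np.array([index[a] for a in rows_ids])
        c = np.array([index[a] for a in cols_ids])
        return self.G[np.ix_(r, c)]


@dataclass
class ModelFit:
    """Result of a whole-genome regression fit.

    ``genetic_values`` is indexed by training accession id; ``marker_effects``
    is present for the marker-based models, ``lambda_`` (= sigma2_e/sigma2_g)
    for G-BLUP.  ``predictions`` holds accession-level trait predictions on
    the observed scale (intercept added) together with a phenotyped flag.
    """

    model: str
    trait: str
    mu: float
    fixed_effects: dict = field(default_factory=dict)
    sigma2_g: float = np.nan
    sigma2_e: float = np.nan
    lambda_: float = np.nan
    h2: float = np.nan
    genetic_values: pd.Series | None = None
    genetic_value_sd: pd.Series | None = None
    marker_effects: pd.Series | None = None
    inclusion_prob: pd.Series | None = None
    predictions: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)
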