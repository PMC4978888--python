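"""Readers and writers for every on-disk artifact.

Dialects fixed here once:

* dosage table — tab-separated, first column ``accession_id``, header row of
  marker ids, missing encoded ``NA``;
* VCF v4.x — GT field only, samples treated as inbred (heterozygotes are
  accepted as dosage 1 and counted);
* phenotype CSV — long format with the columns of
  :data:`germpred.containers.PHENO_COLUMNS`;
* predictions CSV — ``accession_id, trait, prediction, phenotyped``;
* GRM TSV — square matrix, ids in first row and first column;
* membership CSV — ``accession_id`` followed by one probability column per
  cluster.

All writers round-trip losslessly through the matching reader (floats are
written at full shortest-repr precision).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    PHENO_COLUMNS,
    GenotypeMatrix,
    KinshipMatrix,
    MembershipTable,
    ModelFit,
    validate_phenotypes,
)
from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

_ALLOWED_DOSAGES = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


# ----------------------------------------------------------------- genotypes
def read_dosage_table(path) -> GenotypeMatrix:
    """Read the tab-separated dosage dialect."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: line 1: empty header")
        marker_ids = header.split("\t")[1:]
        accession_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(marker_ids) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(marker_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            accession_ids.append(parts[0])
            row = []
            for j, tok in enumerate(parts[1:]):
                try:
                    row.append(_ALLOWED_DOSAGES[tok])
                except KeyError:
                    raise ParseError(
                        f"{path}: line {lineno}: invalid dosage {tok!r} "
                        f"for marker {marker_ids[j]!r}"
                    ) from None
            rows.append(row)
    g = GenotypeMatrix(accession_ids, marker_ids, np.array(rows, dtype=float).reshape(
        len(accession_ids), len(marker_ids)))
    return g.with_theta()


def write_dosage_table(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("accession_id\t" + "\t".join(g.marker_ids) + "\n")
        for i, acc in enumerate(g.accession_ids):
            toks = [
                "NA" if np.isnan(v) else str(int(v)) for v in g.dosages[i]
            ]
            fh.write(acc + "\t" + "\t".join(toks) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field only), coding samples as inbred.

    Diploid calls map to dosages 0/1/2 by ALT-allele count; heterozygotes
    become dosage 1 and their count is logged (germplasm accessions are
    expected to be near-fully inbred).  Missing calls become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accession_ids = list(vcf.samples)
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    het_count = 0
    for var in vcf:
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        het_count += int((gt == 1).sum())
        gt[gt == 3] = np.nan
        cols.append(gt)
    if het_count:
        logger.warning("VCF %s: %d heterozygous calls accepted as dosage 1", path, het_count)
    dosages = np.column_stack(cols) if cols else np.empty((len(accession_ids), 0))
    return GenotypeMatrix(accession_ids, marker_ids, dosages).with_theta()


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``dosage-table`` format.

    When ``format`` is None it is inferred from the file extension.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "dosage-table"
    if format == "vcf":
        return read_vcf(path)
    if format == "dosage-table":
        return read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------- phenotypes
def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"accession_id": str, "trial_id": str, "state": str,
                                  "maturity_group": str, "trait": str})
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df)
    df.to_csv(path, index=False, columns=PHENO_COLUMNS)


# --------------------------------------------------------------- predictions
def write_predictions(fit: ModelFit, path) -> None:
    """Write per-accession predictions as CSV.

    Columns: ``accession_id, trait, prediction, phenotyped``.
    """
    if fit.predictions is None or len(fit.predictions) == 0:
        logger.warning("writing header-only predictions file: fit has no predictions")
        pd.DataFrame(columns=["accession_id", "trait", "prediction", "phenotyped"]).to_csv(
            path, index=False
        )
        return
    out = fit.predictions.copy()
    required = {"accession_id", "prediction", "phenotyped"}
    if not required.issubset(out.columns):
        raise ValidationError(f"predictions frame lacks columns {required - set(out.columns)}")
    if "trait" not in out.columns:
        out["trait"] = fit.trait
    out[["accession_id", "trait", "prediction", "phenotyped"]].to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"accession_id": str, "trait": str})


# ----------------------------------------------------------------------- GRM
def write_grm(k: KinshipMatrix, path) -> None:
    """Square tab-separated matrix; ids in first row and first column."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(k.accession_ids) + "\n")
        for i, acc in enumerate(k.accession_ids):
            fh.write(acc + "\t" + "\t".join(repr(float(v)) for v in k.G[i]) + "\n")


def read_grm(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ParseError(f"{path}: row ids do not match column ids")
    return KinshipMatrix(ids, df.to_numpy(dtype=float))


# ---------------------------------------------------------------- membership
def write_membership(m: MembershipTable, path) -> None:
    cols = [f"prob_{k + 1}" for k in range(m.n_clusters)]
    df = pd.DataFrame(m.probabilities, columns=cols)
    df.insert(0, "accession_id", m.accession_ids)
    df.to_csv(path, index=False)


def read_membership(path) -> MembershipTable:
    df = pd.read_csv(path, dtype={"accession_id": str})
    prob_cols = [c for c in df.columns if c.startswith("prob_")]
    if not prob_cols:
        raise ParseError(f"{path}: no prob_* columns found")
    return MembershipTable(df["accession_id"].tolist(), df[prob_cols].to_numpy(dtype=float))
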