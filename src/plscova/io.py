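"""Readers and writers for the external file formats.

Genotypes arrive as VCF (GT field converted to alternate-allele counts),
PLINK ``.raw`` dosage exports, or plain TSV matrices; phenotypes, covariates
and medication logs as CSV; gene annotation as BED4 or 1-based TSV; gene
sets as GMT. Internal genomic coordinates are 1-based inclusive throughout —
BED's 0-based half-open intervals are converted on read.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSetCollection,
    GenotypeMatrix,
    MedicationRecord,
    PhenotypeBlock,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "read_phenotypes",
    "read_covariates",
    "read_medication_log",
    "read_gene_annotation",
    "read_gene_sets",
    "read_regulatory_links",
    "load_yaml",
]


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a subjects x SNPs allele-count matrix.

    Parameters
    ----------
    path : str or Path
    format : {"vcf", "plink_raw", "tsv"}
        ``vcf`` converts GT fields to alt-allele counts (``./.`` -> missing)
        and skips non-biallelic sites with a warning. ``plink_raw`` is the
        whitespace-delimited PLINK ``--recode A`` export. ``tsv`` is a plain
        matrix with a header row of SNP ids and a first column of subject
        ids; SNP coordinates are parsed from ids of the form ``chrom:pos``
        when present.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping non-biallelic site %s:%d (%d ALT alleles)",
                variant.CHROM, variant.POS, len(variant.ALT),
            )
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types.astype(float)
        counts = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        columns.append(counts)
    values = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(subjects), 0)),
        index=subjects,
        columns=snp_ids,
    )
    return GenotypeMatrix(values, pd.Series(chroms, index=snp_ids),
                          pd.Series(positions, index=snp_ids, dtype=int))


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in df.columns:
        raise ValueError(f"{path}: PLINK .raw file lacks an IID column")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    values = df[snp_cols].apply(pd.to_numeric, errors="raise").astype(float)
    values.index = df["IID"].astype(str)
    values.index.name = "subject_id"
    # .raw column names carry a _A suffix (counted allele); strip for SNP ids
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    values.columns = snp_ids
    chrom, pos = _coords_from_ids(snp_ids)
    return GenotypeMatrix(values, chrom, pos)


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    values = df.apply(pd.to_numeric, errors="raise").astype(float)
    chrom, pos = _coords_from_ids(list(values.columns))
    return GenotypeMatrix(values, chrom, pos)


def _coords_from_ids(snp_ids: list[str]) -> tuple[pd.Series, pd.Series]:
    """Parse chrom:pos out of SNP ids, defaulting to unknown/0."""
    chroms, positions = [], []
    for sid in snp_ids:
        if ":" in sid:
            c, _, p = sid.partition(":")
            try:
                positions.append(int(p.split(":")[0]))
                chroms.append(c)
                continue
            except ValueError:
                pass
        chroms.append("unknown")
        positions.append(0)
    return (pd.Series(chroms, index=snp_ids),
            pd.Series(positions, index=snp_ids, dtype=int))


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the allele-count matrix as TSV (round-trips with ``format='tsv'``)."""
    out = geno.values.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a subjects x transcripts TPM matrix (TSV, header row, id column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.apply(pd.to_numeric, errors="raise").astype(float))


def read_phenotypes(path: str | Path) -> PhenotypeBlock:
    """Read a phenotype CSV: subject_id column plus numeric feature columns."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty phenotype file")
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    df.index.name = "subject_id"
    try:
        values = df.apply(pd.to_numeric, errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric phenotype cell ({exc})") from exc
    return PhenotypeBlock(values)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate CSV, one row per subject, indexed by subject id."""
    df = pd.read_csv(path)
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    df.index.name = "subject_id"
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate subject ids")
    return df.apply(pd.to_numeric, errors="raise").astype(float)


def read_medication_log(path: str | Path) -> list[MedicationRecord]:
    """Read a medication CSV (subject_id, drug, dose, unit, frequency)."""
    df = pd.read_csv(path)
    required = {"subject_id", "drug", "dose", "unit", "frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        MedicationRecord(
            subject_id=str(row.subject_id),
            drug_name=str(row.drug),
            dose=float(row.dose),
            unit=str(row.unit),
            frequency=float(row.frequency),
        )
        for row in df.itertuples()
    ]


def read_gene_annotation(path: str | Path, dialect: str = "bed") -> list[GeneAnnotation]:
    """Read gene intervals.

    ``bed`` input (0-based half-open) is converted to the internal 1-based
    inclusive convention; ``tsv_1based`` is taken as-is. Both need at least
    4 columns: chrom, start, end, gene_id.
    """
    if dialect not in ("bed", "tsv_1based"):
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: need >= 4 columns (chrom, start, end, gene_id)")
    records = []
    for row in df.itertuples(index=False):
        chrom, start, end, gene_id = str(row[0]), int(row[1]), int(row[2]), str(row[3])
        if dialect == "bed":
            start = start + 1  # 0-based half-open -> 1-based inclusive
        records.append(GeneAnnotation(gene_id=gene_id, chrom=chrom, start=start, end=end))
    return records


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r}; deduplicated")
            sets[name] = unique
    return GeneSetCollection(sets)


def read_regulatory_links(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV of SNP-id -> gene-id regulatory links."""
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "gene_id"], dtype=str)
    return df


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
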