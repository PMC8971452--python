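"""Core in-memory containers for the association pipeline.

All matrices are subjects x features, held as pandas DataFrames indexed by
subject id so that block alignment is an index operation rather than a
positional convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "PhenotypeBlock",
    "GeneAnnotation",
    "GeneSetCollection",
    "MedicationRecord",
    "VisitRecord",
    "PTIF_FEATURES",
    "UPDRS_FEATURES",
]

#: The 7 global pTIF features: one per imaging modality (grey-matter density,
#: resting functional activity, dopaminergic integrity) and per non-empty
#: modality combination.
PTIF_FEATURES = ["GM", "FUNC", "DOP", "GM-FUNC", "GM-DOP", "FUNC-DOP", "GM-FUNC-DOP"]

#: The 5 treatment-response features: 4 motor subscores plus the total score.
UPDRS_FEATURES = ["tremor", "bradykinesia", "rigidity", "axial", "total"]


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs matrix of alternate-allele counts (0/1/2, NaN missing).

    ``values`` is a float DataFrame (to allow NaN) whose entries are 0, 1, 2
    or missing; ``snp_chrom`` / ``snp_pos`` give each SNP's 1-based physical
    coordinate.
    """

    values: pd.DataFrame
    snp_chrom: pd.Series
    snp_pos: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.columns, "snp_ids")
        _check_unique(self.values.index, "subject_ids")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
            bad = np.unique(finite[~np.isin(finite, [0.0, 1.0, 2.0])])
            raise ValueError(f"genotype entries outside {{0,1,2}}: {bad[:5]}")
        self.snp_chrom = pd.Series(self.snp_chrom, index=self.values.columns)
        self.snp_pos = pd.Series(self.snp_pos, index=self.values.columns).astype(int)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ExpressionMatrix:
    """Subjects x transcripts abundance matrix in TPM units (non-negative)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.columns, "transcript_ids")
        _check_unique(self.values.index, "subject_ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PhenotypeBlock:
    """Subjects x features phenotype matrix (pTIF-7 or levo-UPDRS-5)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.columns, "feature_names")
        _check_unique(self.values.index, "subject_ids")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval, 1-based inclusive at both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (set name -> member gene ids)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) != len(set(members)):
                raise ValueError(f"gene set {name} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class MedicationRecord:
    subject_id: str
    drug_name: str
    dose: float
    unit: str
    frequency: float  # doses per day

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")


@dataclass
class VisitRecord:
    """One MDS-UPDRS part III assessment: 33 item scores, each in [0, 4]."""

    subject_id: str
    visit_time: float  # years since the subject's first visit
    items: dict[str, float]
    medication_state: str = "ON"  # ON or OFF

    def __post_init__(self) -> None:
        if len(self.items) != 33:
            raise ValueError(f"expected 33 items, got {len(self.items)}")
        for name, score in self.items.items():
            if not (0 <= score <= 4):
                raise ValueError(f"item {name} score {score} outside [0, 4]")
        if self.medication_state not in ("ON", "OFF"):
            raise ValueError(f"medication_state must be ON/OFF, got {self.medication_state!r}")
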