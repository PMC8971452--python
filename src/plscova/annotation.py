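"""SNP-to-gene mapping, cross-analysis overlap, and gene-set enrichment.

A SNP is assigned to every gene whose interval strictly contains its
position (1-based inclusive at both ends, zero tolerance up- or
downstream). SNPs without a gene-body hit can fall through to an optional
user-supplied regulatory-link table; the remainder are reported as
unmapped. Gene-set over-representation uses the one-sided hypergeometric
tail with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneAnnotation, GeneSetCollection, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SnpGeneMap",
    "EnrichmentRow",
    "map_snps_to_genes",
    "feature_set_overlap",
    "enrich_gene_sets",
]


@dataclass
class SnpGeneMap:
    """snp_id -> mapped gene ids, with per-mapping provenance.

    ``provenance[snp_id]`` is ``"gene_body"`` for strict positional overlap
    or ``"regulatory"`` for a user-supplied link.
    """

    mapping: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)
    n_unmapped: int = 0

    def genes_for(self, snp_ids) -> set[str]:
        """Union of genes mapped by any of the given SNPs (each mapped gene
        counted once)."""
        out: set[str] = set()
        for sid in snp_ids:
            out.update(self.mapping.get(sid, []))
        return out


def map_snps_to_genes(
    genotypes: GenotypeMatrix,
    annotation: list[GeneAnnotation],
    regulatory_links: pd.DataFrame | None = None,
) -> SnpGeneMap:
    """Strict-overlap SNP -> gene assignment (0 bp tolerance).

    A SNP at position x maps to every gene with start <= x <= end on the
    same chromosome. SNPs with no gene-body hit fall through to the
    optional regulatory-link table (columns snp_id, gene_id); SNPs still
    unlinked are counted in ``n_unmapped``.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        # internal coords are 1-based inclusive; IntervalTree is half-open
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.end + 1, gene.gene_id)
    snp_chroms = set(genotypes.snp_chrom)
    if trees and snp_chroms.isdisjoint(trees.keys()):
        raise ValueError(
            f"no chromosome shared between SNPs ({sorted(snp_chroms)[:3]}...) and "
            f"annotation ({sorted(trees)[:3]}...); harmonize naming (e.g. 'chr1' vs '1')"
        )
    links: dict[str, list[str]] = {}
    if regulatory_links is not None:
        for row in regulatory_links.itertuples(index=False):
            links.setdefault(str(row.snp_id), []).append(str(row.gene_id))
    mapping: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    n_unmapped = 0
    for snp_id in genotypes.snp_ids:
        chrom = genotypes.snp_chrom[snp_id]
        pos = int(genotypes.snp_pos[snp_id])
        hits = sorted(iv.data for iv in trees.get(chrom, IntervalTree()).at(pos))
        if hits:
            mapping[snp_id] = hits
            provenance[snp_id] = "gene_body"
        elif snp_id in links:
            mapping[snp_id] = sorted(set(links[snp_id]))
            provenance[snp_id] = "regulatory"
        else:
            mapping[snp_id] = []
            n_unmapped += 1
    if n_unmapped:
        logger.info("%d of %d SNPs not linked to any gene", n_unmapped, len(mapping))
    return SnpGeneMap(mapping, provenance, n_unmapped)


def feature_set_overlap(genes_a, genes_b) -> dict[str, float]:
    """Exact intersection of two identifier sets with percentages relative
    to each set."""
    a, b = set(genes_a), set(genes_b)
    common = a & b
    return {
        "n_common": len(common),
        "pct_of_a": 100.0 * len(common) / len(a) if a else 0.0,
        "pct_of_b": 100.0 * len(common) / len(b) if b else 0.0,
    }


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap_count: int
    set_size: int
    universe_size: int
    query_size: int
    p_hypergeometric: float
    p_adjusted: float


def enrich_gene_sets(
    query_genes,
    universe_genes,
    gene_sets: GeneSetCollection,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation test per gene set.

    Set members are intersected with the universe before testing; p-values
    are BH-adjusted across sets and rows returned sorted by raw p.
    """
    query = set(query_genes)
    universe = set(universe_genes)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        k = len(in_universe & query)
        n_set = len(in_universe)
        # P[X >= k] for X ~ Hypergeom(M, n_set, N)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, n_set, N)) if n_set else 1.0
        rows.append((name, k, n_set, p))
    pvals = np.array([r[3] for r in rows])
    adjusted = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.empty(0)
    out = [
        EnrichmentRow(name, k, n_set, M, N, p, float(padj))
        for (name, k, n_set, p), padj in zip(rows, adjusted)
    ]
    return sorted(out, key=lambda r: r.p_hypergeometric)
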