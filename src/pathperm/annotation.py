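"""SNP-to-gene annotation and the circular genome ordering.

The permutation null treats the genome as a circle: SNPs are sorted first
by chromosome (in a configurable order, by default 1..22 then X) and then
by position, and the last SNP is adjacent to the first. SNPs are assigned
to a gene when they fall within the gene's transcription span extended by
a symmetric physical window (0 bp or, commonly, 20 kb); a SNP may be
assigned to several overlapping genes, and SNPs assigned to no gene still
occupy their place on the circle and rotate with everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import DEFAULT_CHROMOSOME_ORDER, GeneRecord, GeneSetCollection, SnpRecord, ValidationError


@dataclass(frozen=True)
class GenomeOrder:
    """Total order of SNPs along the circular genome.

    ``order[r]`` is the table index of the SNP at genome rank ``r``;
    ``rank_of[i]`` is the genome rank of table index ``i``. Ties in
    (chromosome, position) are broken by lexicographic SNP id so the order
    is deterministic. ``chrom_starts``/``chrom_sizes`` delimit each
    chromosome's contiguous block of ranks (used by per-chromosome rotation).
    """

    order: np.ndarray
    rank_of: np.ndarray
    chrom_starts: np.ndarray
    chrom_sizes: np.ndarray
    chromosomes: tuple[str, ...]

    @property
    def n_snps(self) -> int:
        return len(self.order)


def build_genome_order(
    snps: Sequence[SnpRecord],
    chromosome_order: Sequence[str] = DEFAULT_CHROMOSOME_ORDER,
) -> GenomeOrder:
    """Sort SNPs by (chromosome rank, position, snp_id) into a circular order."""
    chrom_rank = {c: i for i, c in enumerate(chromosome_order)}
    for s in snps:
        if s.chromosome not in chrom_rank:
            raise ValidationError(
                f"SNP {s.snp_id!r}: chromosome {s.chromosome!r} not in the configured "
                f"chromosome order {list(chromosome_order)}"
            )
    idx = sorted(
        range(len(snps)),
        key=lambda i: (chrom_rank[snps[i].chromosome], snps[i].position, snps[i].snp_id),
    )
    order = np.asarray(idx, dtype=np.int64)
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(len(order))

    starts, sizes, present = [], [], []
    r = 0
    while r < len(order):
        chrom = snps[order[r]].chromosome
        r0 = r
        while r < len(order) and snps[order[r]].chromosome == chrom:
            r += 1
        starts.append(r0)
        sizes.append(r - r0)
        present.append(chrom)
    return GenomeOrder(
        order=order,
        rank_of=rank_of,
        chrom_starts=np.asarray(starts, dtype=np.int64),
        chrom_sizes=np.asarray(sizes, dtype=np.int64),
        chromosomes=tuple(present),
    )


@dataclass
class AnnotationMap:
    """Bidirectional SNP <-> gene assignment at a fixed window.

    ``snp_to_genes`` holds an entry only for annotated SNPs (query via
    :meth:`genes_for`, which returns an empty set otherwise);
    ``gene_to_snps`` contains only genes with at least one SNP, each value
    an ascending list of SNP table indices.
    """

    snp_to_genes: dict[int, frozenset[str]]
    gene_to_snps: dict[str, list[int]]
    window_bp: int
    n_snps: int

    def genes_for(self, snp_index: int) -> frozenset[str]:
        return self.snp_to_genes.get(snp_index, frozenset())

    @property
    def n_annotated(self) -> int:
        return len(self.snp_to_genes)


def annotate_snps(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    window_bp: int = 0,
) -> AnnotationMap:
    """Assign SNPs to genes within ``window_bp`` of the transcription span.

    SNP i maps to gene g iff their chromosomes match and
    ``tx_start - window_bp <= position_i <= tx_end + window_bp`` (both
    boundaries inclusive). A SNP may map to several genes.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")

    # per-chromosome sorted position arrays for O(log n) interval queries
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(snps):
        by_chrom.setdefault(s.chromosome, []).append(i)
    chrom_pos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idxs in by_chrom.items():
        idx_arr = np.asarray(idxs, dtype=np.int64)
        pos = np.asarray([snps[i].position for i in idxs], dtype=np.int64)
        srt = np.argsort(pos, kind="stable")
        chrom_pos[chrom] = (pos[srt], idx_arr[srt])

    snp_to_genes: dict[int, set[str]] = {}
    gene_to_snps: dict[str, list[int]] = {}
    for g in genes:
        if g.chromosome not in chrom_pos:
            continue
        pos, idx_arr = chrom_pos[g.chromosome]
        lo = np.searchsorted(pos, g.tx_start - window_bp, side="left")
        hi = np.searchsorted(pos, g.tx_end + window_bp, side="right")
        if hi <= lo:
            continue
        hit = sorted(int(i) for i in idx_arr[lo:hi])
        gene_to_snps[g.gene_id] = hit
        for i in hit:
            snp_to_genes.setdefault(i, set()).add(g.gene_id)

    return AnnotationMap(
        snp_to_genes={i: frozenset(v) for i, v in snp_to_genes.items()},
        gene_to_snps=gene_to_snps,
        window_bp=window_bp,
        n_snps=len(snps),
    )


@dataclass(frozen=True)
class AnnotationSummary:
    n_snps: int
    n_snps_annotated: int
    fraction_annotated: float
    n_genes_with_snps: int
    n_pathway_genes_covered: int


def annotation_summary(
    amap: AnnotationMap,
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    sets: GeneSetCollection | None = None,
) -> AnnotationSummary:
    """Coverage counts for an annotation: how much of the data the test sees."""
    n = len(snps)
    n_ann = amap.n_annotated
    pathway_genes = sets.all_gene_ids() if sets is not None else frozenset()
    covered = sum(1 for g in amap.gene_to_snps if g in pathway_genes)
    return AnnotationSummary(
        n_snps=n,
        n_snps_annotated=n_ann,
        fraction_annotated=(n_ann / n) if n else 0.0,
        n_genes_with_snps=len(amap.gene_to_snps),
        n_pathway_genes_covered=covered,
    )
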