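"""Null distributions for the pathway statistic.

Three permutation schemes generate the null distribution of the
hypergeometric pathway P value:

* ``circular`` — the genome-ordered vector of SNP association P values is
  rotated by a random offset. Every SNP keeps its neighbours, so regional
  LD and the co-location of genes and pathways survive into the null; only
  which loci carry which P values is randomised. One offset serves all
  pathways within a permutation.
* ``circular-per-chrom`` — as above, but each chromosome's block rotates by
  its own independent offset.
* ``snp-random`` — the P-value vector is randomly reassigned to SNPs (a
  full shuffle), destroying all positional correlation; each gene of K SNPs
  thus receives K P values drawn without replacement from the full pool.
* ``gene-random`` — gene P values are computed once from the unpermuted
  data; each pathway of size m then repeatedly redraws m genes without
  replacement from the universe, with S and N held at their observed
  values. This scheme is the hypergeometric model itself, re-enacted by
  resampling, and serves as a consistency check.

After every rearrangement the full cascade is recomputed: gene Fisher
scores, the number of significant genes S in the universe, and the
hypergeometric tail for every pathway. Empirical P values use the
rank-based estimator (r + 1) / (n_perm + 1); the empirical significance
threshold at level q is the ceil(q * n_perm)-th smallest permuted value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import special
from scipy.stats import hypergeom

from .annotation import AnnotationMap, GenomeOrder
from .gene_stats import GeneScoreTable
from .io import GeneSetCollection, GwasTable
from .pathway_stats import Tail, hypergeom_tail_vector

logger = logging.getLogger(__name__)

Scheme = Literal["circular", "circular-per-chrom", "snp-random", "gene-random"]

UniverseMode = Literal["all-annotated", "pathway-genes"]


@dataclass
class PermutationDistribution:
    """Permuted hypergeometric P values for one pathway-trait test."""

    pathway_id: str
    trait: str
    values: np.ndarray
    n_perm: int
    scheme: str
    seed: int | None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_perm:
            raise ValueError("distribution length does not match n_perm")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def rotate_pvalues(pvalues: Sequence[float], offset: int) -> np.ndarray:
    """Rotate a genome-ordered P-value vector by ``offset`` positions.

    The value at genome position j moves to position (j + offset) mod n, so
    the first SNP's P value lands on the (offset + 1)-th SNP. Offset 0 is
    the identity.
    """
    arr = np.asarray(pvalues)
    n = len(arr)
    if not (0 <= offset < n):
        raise ValueError(f"offset must satisfy 0 <= offset < {n}, got {offset}")
    return np.roll(arr, offset)


def empirical_pvalue(observed: float, dist: PermutationDistribution | np.ndarray) -> float:
    """Rank-based empirical P value (r + 1) / (n_perm + 1).

    r counts permuted values at or below the observed statistic (ties count:
    an equal permuted value is as extreme as the observation). Never 0; 1.0
    when the observation exceeds or ties every permuted value.
    """
    values = dist.values if isinstance(dist, PermutationDistribution) else np.asarray(dist)
    if len(values) == 0:
        raise ValueError("empty permutation distribution")
    r = int(np.count_nonzero(values <= observed))
    return (1 + r) / (1 + len(values))


def empirical_threshold(dist: PermutationDistribution | np.ndarray, level: float = 0.05) -> float:
    """Empirical significance threshold: ceil(level * n_perm)-th smallest value.

    An observed theoretical P value at or below the threshold is declared
    empirically significant at ``level``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    values = dist.values if isinstance(dist, PermutationDistribution) else np.asarray(dist)
    if len(values) == 0:
        raise ValueError("empty permutation distribution")
    k = math.ceil(level * len(values))
    return float(np.sort(values)[k - 1])


class PermutationEngine:
    """Vectorised recomputation of pathway statistics under rearranged P values.

    All index bookkeeping (gene -> genome-rank lists, pathway -> gene lists)
    is done once at construction; each permutation is then evaluated by pure
    index arithmetic on the log-P vector, never by materialising a shuffled
    table.
    """

    def __init__(
        self,
        gwas: GwasTable,
        order: GenomeOrder,
        amap: AnnotationMap,
        sets: GeneSetCollection,
        trait: str,
        alpha_gene: float = 0.05,
        tail: Tail = "geq",
        universe: UniverseMode = "all-annotated",
    ):
        if trait not in gwas.traits:
            raise KeyError(f"trait {trait!r} not in GWAS table")
        if order.n_snps != len(gwas) or amap.n_snps != len(gwas):
            raise ValueError("GWAS table, genome order and annotation sizes disagree")
        self.trait = trait
        self.alpha_gene = float(alpha_gene)
        self.tail: Tail = tail
        self.n = order.n_snps

        pvec = np.asarray([s.pvalues[trait] for s in gwas], dtype=float)
        self.logp = np.log(pvec[order.order])  # in genome-rank space

        genes = sorted(amap.gene_to_snps)
        if universe == "pathway-genes":
            pw_genes = sets.all_gene_ids()
            genes = [g for g in genes if g in pw_genes]
        if not genes:
            raise ValueError("no annotated genes in the universe")
        self.universe_genes: list[str] = genes
        self.N = len(genes)
        gene_index = {g: i for i, g in enumerate(genes)}

        flat: list[np.ndarray] = []
        starts: list[int] = []
        pos = 0
        k_list: list[int] = []
        for g in genes:
            ranks = order.rank_of[np.asarray(amap.gene_to_snps[g], dtype=np.int64)]
            flat.append(ranks)
            starts.append(pos)
            pos += len(ranks)
            k_list.append(len(ranks))
        self.flat_ranks = np.concatenate(flat)
        self.gene_starts = np.asarray(starts, dtype=np.int64)
        self.k_genes = np.asarray(k_list, dtype=np.float64)

        pw_flat: list[int] = []
        pw_starts: list[int] = []
        m_list: list[int] = []
        ids: list[str] = []
        pos = 0
        for gene_set in sets:
            members = sorted(gene_index[g] for g in gene_set.gene_ids if g in gene_index)
            if not members:
                logger.info("pathway %r has no genes in the universe; skipped", gene_set.set_id)
                continue
            ids.append(gene_set.set_id)
            pw_starts.append(pos)
            pw_flat.extend(members)
            pos += len(members)
            m_list.append(len(members))
        if not ids:
            raise ValueError("no pathway overlaps the gene universe")
        self.pathway_ids: list[str] = ids
        self.pw_flat = np.asarray(pw_flat, dtype=np.int64)
        self.pw_starts = np.asarray(pw_starts, dtype=np.int64)
        self.m_arr = np.asarray(m_list, dtype=np.int64)

        # per-flat-element chromosome geometry, for per-chromosome rotation
        seg_id = np.searchsorted(order.chrom_starts, self.flat_ranks, side="right") - 1
        self._seg_start = order.chrom_starts[seg_id]
        self._seg_size = order.chrom_sizes[seg_id]
        self._seg_id = seg_id
        self._chrom_sizes = order.chrom_sizes

    # -- statistic evaluation ------------------------------------------------

    def _stats_from_sources(self, src: np.ndarray) -> tuple[np.ndarray, int]:
        """Pathway P values and S when gene SNP slots read from ``src`` ranks."""
        sums = np.add.reduceat(self.logp[src], self.gene_starts)
        gene_p = special.gammaincc(self.k_genes, -sums)
        sig = gene_p <= self.alpha_gene
        S = int(np.count_nonzero(sig))
        K = np.add.reduceat(sig[self.pw_flat].astype(np.int64), self.pw_starts)
        return hypergeom_tail_vector(self.m_arr, K, self.N, S, self.tail), S

    def observed(self) -> tuple[np.ndarray, np.ndarray, int]:
        """Observed per-pathway theoretical P values, K counts, and S."""
        sums = np.add.reduceat(self.logp[self.flat_ranks], self.gene_starts)
        gene_p = special.gammaincc(self.k_genes, -sums)
        sig = gene_p <= self.alpha_gene
        S = int(np.count_nonzero(sig))
        K = np.add.reduceat(sig[self.pw_flat].astype(np.int64), self.pw_starts)
        return hypergeom_tail_vector(self.m_arr, K, self.N, S, self.tail), K, S

    def gene_scores(self) -> GeneScoreTable:
        """Observed Fisher gene P values for the universe genes."""
        sums = np.add.reduceat(self.logp[self.flat_ranks], self.gene_starts)
        gene_p = special.gammaincc(self.k_genes, -sums)
        table = GeneScoreTable()
        for g, k, p in zip(self.universe_genes, self.k_genes, gene_p):
            table.scores[(g, self.trait)] = float(p)
            table.snp_counts[g] = int(k)
        return table

    # -- null generation -----------------------------------------------------

    def null_matrix(
        self,
        scheme: Scheme,
        n_perm: int,
        rng: np.random.Generator,
        *,
        allow_identity: bool = False,
        progress: bool = False,
    ) -> np.ndarray:
        """(n_perm, n_pathways) matrix of permuted hypergeometric P values."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        n = self.n
        out = np.empty((n_perm, len(self.pathway_ids)), dtype=float)
        iterator = range(n_perm)
        if progress:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=f"{scheme} null ({self.trait})", unit="perm")

        if scheme == "circular":
            if n < 2:
                raise ValueError("circular rotation requires at least 2 SNPs")
            lo = 0 if allow_identity else 1
            offsets = rng.integers(lo, n, size=n_perm)
            for i in iterator:
                src = (self.flat_ranks - offsets[i]) % n
                out[i], _ = self._stats_from_sources(src)
        elif scheme == "circular-per-chrom":
            lo = 0 if allow_identity else 1
            for i in iterator:
                # independent offset per chromosome; blocks of size 1 cannot move
                offs = np.array(
                    [int(rng.integers(lo, s)) if s >= 2 else 0 for s in self._chrom_sizes],
                    dtype=np.int64,
                )
                src = self._seg_start + (
                    self.flat_ranks - self._seg_start - offs[self._seg_id]
                ) % self._seg_size
                out[i], _ = self._stats_from_sources(src)
        elif scheme == "snp-random":
            for i in iterator:
                perm = rng.permutation(n)
                out[i], _ = self._stats_from_sources(perm[self.flat_ranks])
        else:
            raise ValueError(f"unknown scheme {scheme!r} for SNP-level permutation")
        return out


def _distributions_from_matrix(
    matrix: np.ndarray,
    pathway_ids: Sequence[str],
    trait: str,
    scheme: str,
    seed: int | None,
) -> dict[str, PermutationDistribution]:
    n_perm = matrix.shape[0]
    return {
        pid: PermutationDistribution(pid, trait, matrix[:, j].copy(), n_perm, scheme, seed)
        for j, pid in enumerate(pathway_ids)
    }


def circular_null(
    gwas: GwasTable,
    order: GenomeOrder,
    amap: AnnotationMap,
    sets: GeneSetCollection,
    trait: str,
    alpha_gene: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    *,
    tail: Tail = "geq",
    universe: UniverseMode = "all-annotated",
    allow_identity: bool = False,
    per_chromosome: bool = False,
) -> dict[str, PermutationDistribution]:
    """Circular-rotation null distributions, one per pathway.

    Per permutation a single uniform offset is drawn from the non-identity
    shifts {1, ..., n-1} (``allow_identity`` widens the support to include
    the identity rotation) and the whole genome-ordered P-value vector —
    annotated and unannotated SNPs alike — rotates by it; gene scores, S and
    every pathway's hypergeometric P value are then recomputed.
    """
    engine = PermutationEngine(gwas, order, amap, sets, trait, alpha_gene, tail, universe)
    scheme: Scheme = "circular-per-chrom" if per_chromosome else "circular"
    rng = np.random.default_rng(seed)
    matrix = engine.null_matrix(scheme, n_perm, rng, allow_identity=allow_identity)
    return _distributions_from_matrix(matrix, engine.pathway_ids, trait, scheme, seed)


def snp_random_null(
    gwas: GwasTable,
    amap: AnnotationMap,
    sets: GeneSetCollection,
    trait: str,
    alpha_gene: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    *,
    order: GenomeOrder | None = None,
    tail: Tail = "geq",
    universe: UniverseMode = "all-annotated",
) -> dict[str, PermutationDistribution]:
    """SNP-level random permutation null: full shuffle of the P-value vector.

    Each gene of K SNPs receives K P values sampled without replacement from
    the complete SNP pool; all positional correlation is destroyed.
    """
    if order is None:
        from .annotation import build_genome_order

        chroms = list(dict.fromkeys(s.chromosome for s in gwas))
        order = build_genome_order(gwas.snps, chroms)
    engine = PermutationEngine(gwas, order, amap, sets, trait, alpha_gene, tail, universe)
    rng = np.random.default_rng(seed)
    matrix = engine.null_matrix("snp-random", n_perm, rng)
    return _distributions_from_matrix(matrix, engine.pathway_ids, trait, "snp_random", seed)


def gene_random_null(
    scores: GeneScoreTable,
    sets: GeneSetCollection,
    universe: Sequence[str],
    alpha_gene: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    *,
    trait: str | None = None,
    tail: Tail = "geq",
) -> dict[str, PermutationDistribution]:
    """Gene-level resampling null with S and N fixed at their observed values.

    Gene P values are computed once from the unpermuted data; per permutation
    each pathway of size m draws m genes without replacement from the
    universe and counts the significant ones. Because this is exactly
    sampling without replacement from a pool with S successes, the permuted
    K is hypergeometric by construction.
    """
    if trait is None:
        traits = scores.traits
        if len(traits) != 1:
            raise ValueError("specify trait when the score table holds several traits")
        trait = traits[0]
    universe = sorted(set(universe))
    N = len(universe)
    if N == 0:
        raise ValueError("the gene universe is empty")
    trait_scores = scores.trait_scores(trait)
    sig0 = np.asarray([trait_scores[g] <= alpha_gene for g in universe], dtype=np.int64)
    S = int(sig0.sum())

    universe_set = set(universe)
    ids: list[str] = []
    m_list: list[int] = []
    for gene_set in sets:
        m = sum(1 for g in gene_set.gene_ids if g in universe_set)
        if m == 0:
            logger.info("pathway %r has no genes in the universe; skipped", gene_set.set_id)
            continue
        if m > N:
            raise ValueError(f"pathway {gene_set.set_id!r}: m={m} exceeds universe size N={N}")
        ids.append(gene_set.set_id)
        m_list.append(m)
    m_arr = np.asarray(m_list, dtype=np.int64)

    # Tail lookup per pathway for every attainable K, then index by resampled K.
    max_k = int(min(m_arr.max(initial=0), S))
    kk = np.arange(max_k + 1)
    tables = np.vstack([
        hypergeom_tail_vector(np.full_like(kk, m), kk, N, S, tail) for m in m_arr
    ])  # (n_pathways, max_k + 1)

    rng = np.random.default_rng(seed)
    matrix = np.empty((n_perm, len(ids)), dtype=float)
    for i in range(n_perm):
        shuffled = sig0[rng.permutation(N)]
        csum = np.cumsum(shuffled)
        K = csum[m_arr - 1]  # significant count among the first m of a uniform shuffle
        matrix[i] = tables[np.arange(len(ids)), K]
    return _distributions_from_matrix(matrix, ids, trait, "gene_random", seed)
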