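"""Synthetic GWAS inputs with controllable genomic structure.

The generator emulates the two structural features the circular null is
designed to respect, without simulating genotypes:

* **LD-like correlation.** Per trait, a latent standard-normal association
  score follows a stationary AR(1) process with correlation ``ld_rho``
  along the genome order; each SNP's P value is the upper-tail normal
  probability of its score. Neighbouring SNPs therefore carry correlated
  P values, as they would under linkage disequilibrium.
* **Functional clustering.** Genes occupy contiguous runs of SNPs, and a
  configurable fraction of each pathway's genes is placed in a contiguous
  genomic block (``gene_clustering``), mimicking the co-location of
  functionally related genes.

Pathway effects are planted by shifting the latent scores of SNPs
annotated to member genes upwards by ``effect_strength``, which drags
their P values towards 0 on every simulated trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

from .io import (
    DEFAULT_CHROMOSOME_ORDER,
    GeneRecord,
    GeneSet,
    GeneSetCollection,
    GwasTable,
    SnpRecord,
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome; defaults give a mid-sized study.

    ``chromosome_lengths`` (SNP counts per chromosome) overrides the equal
    split. ``planted_pathways`` is a list of (pathway index, effect
    strength) pairs; effects are mean shifts of the latent scores and apply
    to every trait.
    """

    n_snps: int = 10_000
    n_chromosomes: int = 10
    n_genes: int = 1_000
    snps_per_gene_mean: float = 4.0
    ld_rho: float = 0.8
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 50)
    gene_clustering: float = 0.5
    planted_pathways: tuple[tuple[int, float], ...] = ()
    n_traits: int = 1
    seed: int = 0
    chromosome_lengths: tuple[int, ...] | None = None

    def validate(self) -> None:
        if min(self.n_snps, self.n_chromosomes, self.n_genes, self.n_pathways, self.n_traits) < 1:
            raise ValueError("all counts must be positive")
        if self.n_chromosomes > len(DEFAULT_CHROMOSOME_ORDER):
            raise ValueError(f"at most {len(DEFAULT_CHROMOSOME_ORDER)} chromosomes supported")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0.0 <= self.gene_clustering <= 1.0):
            raise ValueError("gene_clustering must lie in [0, 1]")
        if self.snps_per_gene_mean < 1.0:
            raise ValueError("snps_per_gene_mean must be >= 1")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("pathway_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ValueError("pathway size exceeds the number of genes")
        if self.n_genes > self.n_snps:
            raise ValueError("cannot place more genes than SNPs")
        for idx, eff in self.planted_pathways:
            if not (0 <= idx < self.n_pathways):
                raise ValueError(f"planted pathway index {idx} out of range")
            if eff < 0:
                raise ValueError("effect_strength must be >= 0")
        if self.chromosome_lengths is not None:
            if len(self.chromosome_lengths) != self.n_chromosomes:
                raise ValueError("chromosome_lengths length must equal n_chromosomes")
            if sum(self.chromosome_lengths) != self.n_snps:
                raise ValueError("chromosome_lengths must sum to n_snps")


def _split_counts(total: int, parts: int) -> np.ndarray:
    base = np.full(parts, total // parts, dtype=np.int64)
    base[: total % parts] += 1
    return base


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) path of length n."""
    eps = rng.standard_normal(n)
    if rho == 0.0:
        return eps
    x = eps * np.sqrt(1.0 - rho * rho)
    x[0] = eps[0]  # stationary start: Var(z_0) = 1
    return lfilter([1.0], [1.0, -rho], x)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GwasTable, list[GeneRecord], GeneSetCollection]:
    """Build a synthetic GWAS table, gene table and pathway collection.

    SNP positions are strictly increasing within chromosomes; each gene's
    transcription span covers a contiguous block of SNPs (so the window-0
    annotation recovers the construction exactly); pathway membership and
    planted effects follow the configuration. Identical configurations give
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    chrom_labels = DEFAULT_CHROMOSOME_ORDER[: config.n_chromosomes]
    snp_counts = (
        np.asarray(config.chromosome_lengths, dtype=np.int64)
        if config.chromosome_lengths is not None
        else _split_counts(config.n_snps, config.n_chromosomes)
    )
    gene_counts = _split_counts(config.n_genes, config.n_chromosomes)
    # every chromosome must fit its genes
    for nc, gc in zip(snp_counts, gene_counts):
        if gc > nc:
            raise ValueError("chromosome has more genes than SNPs; increase n_snps")

    snp_chrom: list[str] = []
    snp_pos: list[int] = []
    genes: list[GeneRecord] = []
    gene_snp_blocks: list[np.ndarray] = []  # global SNP indices per gene, genomic order
    global_idx = 0
    gene_no = 0
    for chrom, nc, gc in zip(chrom_labels, snp_counts, gene_counts):
        gaps_bp = rng.integers(1_000, 5_000, size=nc)
        pos = np.cumsum(gaps_bp)
        snp_chrom.extend([chrom] * int(nc))
        snp_pos.extend(int(p) for p in pos)

        sizes = 1 + rng.poisson(config.snps_per_gene_mean - 1.0, size=gc)
        # shrink if the draw does not fit on this chromosome
        while sizes.sum() > nc:
            sizes[np.argmax(sizes)] -= 1
        spare = int(nc - sizes.sum())
        gaps = rng.multinomial(spare, np.full(gc + 1, 1.0 / (gc + 1)))
        cursor = 0
        for j in range(gc):
            cursor += int(gaps[j])
            block = np.arange(global_idx + cursor, global_idx + cursor + int(sizes[j]))
            cursor += int(sizes[j])
            first = int(pos[block[0] - global_idx])
            last = int(pos[block[-1] - global_idx])
            gene_no += 1
            genes.append(
                GeneRecord(f"G{gene_no:05d}", f"SYM{gene_no}", chrom, first, last)
            )
            gene_snp_blocks.append(block)
        global_idx += int(nc)

    # pathways over gene indices (genomic order)
    lo, hi = config.pathway_size_range
    sets = GeneSetCollection()
    pathway_members: list[np.ndarray] = []
    for p in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_clust = int(round(config.gene_clustering * size))
        start = int(rng.integers(0, config.n_genes - n_clust + 1)) if n_clust else 0
        clustered = np.arange(start, start + n_clust)
        pool = np.setdiff1d(np.arange(config.n_genes), clustered)
        scattered = rng.choice(pool, size=size - n_clust, replace=False) if size > n_clust else np.empty(0, dtype=np.int64)
        members = np.sort(np.concatenate([clustered, scattered]).astype(np.int64))
        pathway_members.append(members)
        sets.add(
            GeneSet(
                f"P{p + 1:04d}",
                f"synthetic pathway {p + 1}",
                frozenset(genes[g].gene_id for g in members),
            )
        )

    # planted effects: shift latent scores of member-gene SNPs
    boost = np.zeros(config.n_snps)
    for idx, eff in config.planted_pathways:
        for g in pathway_members[idx]:
            boost[gene_snp_blocks[g]] += eff

    trait_names = tuple(f"trait_{t + 1}" for t in range(config.n_traits))
    pmat = np.empty((config.n_snps, config.n_traits))
    for t in range(config.n_traits):
        z = _ar1(rng, config.n_snps, config.ld_rho) + boost
        pmat[:, t] = np.clip(norm.sf(z), 1e-300, 1.0)

    snps = [
        SnpRecord(
            f"rs{i + 1:07d}",
            snp_chrom[i],
            snp_pos[i],
            {t: float(pmat[i, j]) for j, t in enumerate(trait_names)},
        )
        for i in range(config.n_snps)
    ]
    return GwasTable(snps, trait_names), genes, sets


def write_fixture(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write the three input files in the package's TSV/GMT formats.

    Identical config (including seed) produces byte-identical files.
    Returns the paths under keys ``gwas``, ``genes``, ``gene_sets``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gwas, genes, sets = simulate_genome(config)

    gwas_path = out_dir / "gwas.tsv"
    with open(gwas_path, "w") as fh:
        fh.write("snp\tchr\tpos\t" + "\t".join(gwas.traits) + "\n")
        for s in gwas:
            pvals = "\t".join(format(s.pvalues[t], ".17g") for t in gwas.traits)
            fh.write(f"{s.snp_id}\t{s.chromosome}\t{s.position}\t{pvals}\n")

    gene_path = out_dir / "genes.tsv"
    with open(gene_path, "w") as fh:
        fh.write("gene_id\tsymbol\tchr\ttx_start\ttx_end\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chromosome}\t{g.tx_start}\t{g.tx_end}\n")

    gmt_path = out_dir / "pathways.gmt"
    with open(gmt_path, "w") as fh:
        for gene_set in sets:
            members = "\t".join(sorted(gene_set.gene_ids))
            fh.write(f"{gene_set.set_id}\t{gene_set.name}\t{members}\n")

    return {"gwas": gwas_path, "genes": gene_path, "gene_sets": gmt_path}
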