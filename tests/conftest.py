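"""Shared fixtures: tiny hand-built tables and generated synthetic inputs."""

import pytest

from pathperm.io import GeneRecord, GeneSet, GeneSetCollection, GwasTable, SnpRecord


def make_snp(snp_id, chrom, pos, p, trait="trait_1"):
    if isinstance(p, dict):
        return SnpRecord(snp_id, chrom, pos, p)
    return SnpRecord(snp_id, chrom, pos, {trait: p})


def make_gwas(snps, traits=("trait_1",)):
    return GwasTable(list(snps), tuple(traits))


@pytest.fixture
def tiny_gwas():
    """Five SNPs on two chromosomes, one trait."""
    return make_gwas(
        [
            make_snp("rs1", "1", 100, 0.01),
            make_snp("rs2", "1", 500, 0.5),
            make_snp("rs3", "1", 1500, 0.2),
            make_snp("rs4", "2", 100, 0.9),
            make_snp("rs5", "2", 400, 0.05),
        ]
    )


@pytest.fixture
def tiny_genes():
    return [
        GeneRecord("GA", "A", "1", 90, 600),      # rs1, rs2
        GeneRecord("GB", "B", "1", 1400, 1600),   # rs3
        GeneRecord("GC", "C", "2", 50, 450),      # rs4, rs5
    ]


@pytest.fixture
def tiny_sets():
    c = GeneSetCollection()
    c.add(GeneSet("P1", "first", frozenset({"GA", "GB"})))
    c.add(GeneSet("P2", "second", frozenset({"GC"})))
    return c


@pytest.fixture
def gwas_file(tmp_path, tiny_gwas):
    path = tmp_path / "gwas.tsv"
    with open(path, "w") as fh:
        fh.write("snp\tchr\tpos\ttrait_1\n")
        for s in tiny_gwas:
            fh.write(f"{s.snp_id}\t{s.chromosome}\t{s.position}\t{s.pvalues['trait_1']}\n")
    return path


@pytest.fixture
def gene_file(tmp_path, tiny_genes):
    path = tmp_path / "genes.tsv"
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchr\ttx_start\ttx_end\n")
        for g in tiny_genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chromosome}\t{g.tx_start}\t{g.tx_end}\n")
    return path


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("P1\tfirst\tGA\tGB\nP2\tsecond\tGC\n")
    return path
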