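"""Model/results interface tying the pipeline together.

:class:`PathwayEnrichment` is constructed from the three inputs (GWAS
summary statistics, gene annotations, gene sets) plus the analysis
parameters; :meth:`PathwayEnrichment.fit` runs the permutation-calibrated
enrichment analysis and returns a :class:`PathwayEnrichmentResults`
carrying, for every pathway-trait combination, the observed hypergeometric
P value, its permutation-based empirical P value and the empirical
significance threshold.

    >>> model = PathwayEnrichment.from_files("gwas.tsv", "genes.tsv", "kegg.gmt",
    ...                                      window_bp=20_000)
    >>> res = model.fit(scheme="circular", n_perm=10_000, seed=7)
    >>> print(res.summary())
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationSummary,
    annotate_snps,
    annotation_summary,
    build_genome_order,
)
from .gene_stats import GeneScoreTable
from .io import (
    DEFAULT_CHROMOSOME_ORDER,
    GeneRecord,
    GeneSetCollection,
    GwasTable,
    read_gene_table,
    read_gmt,
    read_gwas_table,
    write_results,
)
from .pathway_stats import PathwayTestResult, Tail
from .permutation import (
    PermutationDistribution,
    PermutationEngine,
    Scheme,
    UniverseMode,
    empirical_pvalue,
    empirical_threshold,
    gene_random_null,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunSummary:
    """Headline counts of a finished analysis."""

    n_tests: int
    level: float
    expected_by_chance: int
    n_theoretical_significant: int
    n_empirical_significant: int
    overlap: int


def summarize(results: pd.DataFrame | Sequence[PathwayTestResult], level: float = 0.05) -> RunSummary:
    """Count significant tests and the number expected by chance.

    ``expected_by_chance`` is level x n_tests rounded to the nearest
    integer. Theoretical significance is ``theoretical_p <= level``;
    empirical significance is ``empirical_p <= level`` (absent empirical
    columns count as not significant).
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                {
                    "theoretical_p": r.theoretical_p,
                    "empirical_p": r.empirical_p,
                }
                for r in results
            ]
        )
    if len(results) == 0:
        raise ValueError("empty results table")
    if level < 0 or level > 1:
        raise ValueError("level must lie in [0, 1]")
    n = len(results)
    theo = int((results["theoretical_p"] <= level).sum())
    if "empirical_p" in results and results["empirical_p"].notna().any():
        emp_mask = results["empirical_p"].fillna(np.inf) <= level
        emp = int(emp_mask.sum())
        overlap = int((emp_mask & (results["theoretical_p"] <= level)).sum())
    else:
        emp = 0
        overlap = 0
    return RunSummary(
        n_tests=n,
        level=level,
        expected_by_chance=int(round(level * n)),
        n_theoretical_significant=theo,
        n_empirical_significant=emp,
        overlap=overlap,
    )


class PathwayEnrichment:
    """Pathway enrichment analysis of GWAS summary statistics.

    Parameters
    ----------
    gwas
        Validated GWAS table (one association P value per SNP per trait).
    genes
        Gene transcription spans.
    gene_sets
        Pathways (e.g. KEGG) as a :class:`GeneSetCollection`.
    window_bp
        Physical annotation window around each gene's transcription span
        (0 = within the gene; 20 000 is the common alternative).
    chromosome_order
        Circular chromosome order; defaults to 1..22, X restricted to the
        chromosomes present.
    alpha_gene
        Gene-significance cutoff applied to the Fisher-combined gene P values.
    tail
        ``"geq"`` for the inclusive hypergeometric tail P(X >= K) (default)
        or ``"gt"`` for the strict tail.
    universe
        ``"all-annotated"`` counts every gene with >= 1 annotated SNP in the
        universe; ``"pathway-genes"`` restricts it to pathway members.
    """

    def __init__(
        self,
        gwas: GwasTable,
        genes: Sequence[GeneRecord],
        gene_sets: GeneSetCollection,
        *,
        window_bp: int = 0,
        chromosome_order: Sequence[str] | None = None,
        alpha_gene: float = 0.05,
        tail: Tail = "geq",
        universe: UniverseMode = "all-annotated",
    ):
        if chromosome_order is None:
            chromosome_order = DEFAULT_CHROMOSOME_ORDER
        self.gwas = gwas
        self.genes = list(genes)
        self.gene_sets = gene_sets
        self.window_bp = int(window_bp)
        self.alpha_gene = float(alpha_gene)
        self.tail: Tail = tail
        self.universe_mode: UniverseMode = universe
        self.chromosome_order = tuple(chromosome_order)

        self.order = build_genome_order(gwas.snps, self.chromosome_order)
        self.annotation = annotate_snps(gwas.snps, self.genes, self.window_bp)
        logger.info(
            "annotation: %d/%d SNPs annotated (%.1f%%) at window %d bp; %d genes with SNPs",
            self.annotation.n_annotated, len(gwas),
            100.0 * self.annotation.n_annotated / max(len(gwas), 1),
            self.window_bp, len(self.annotation.gene_to_snps),
        )
        self._engines: dict[str, PermutationEngine] = {}

    @classmethod
    def from_files(
        cls,
        gwas_path: str | Path,
        gene_path: str | Path,
        gmt_path: str | Path,
        traits: Sequence[str] | None = None,
        **kwargs,
    ) -> "PathwayEnrichment":
        """Build the model from the three TSV/GMT input files."""
        gwas = read_gwas_table(gwas_path, traits)
        genes = read_gene_table(gene_path)
        sets = read_gmt(gmt_path)
        return cls(gwas, genes, sets, **kwargs)

    def _engine(self, trait: str) -> PermutationEngine:
        if trait not in self._engines:
            self._engines[trait] = PermutationEngine(
                self.gwas, self.order, self.annotation, self.gene_sets,
                trait, self.alpha_gene, self.tail, self.universe_mode,
            )
        return self._engines[trait]

    def annotation_report(self) -> AnnotationSummary:
        return annotation_summary(self.annotation, self.gwas.snps, self.genes, self.gene_sets)

    def score_genes(self, traits: Sequence[str] | None = None) -> GeneScoreTable:
        """Observed Fisher-combined gene P values for the chosen traits."""
        table = GeneScoreTable()
        for trait in traits or self.gwas.traits:
            table.update(self._engine(trait).gene_scores())
        return table

    def fit(
        self,
        scheme: Scheme = "circular",
        n_perm: int = 10_000,
        seed: int | None = None,
        level: float = 0.05,
        traits: Sequence[str] | None = None,
        *,
        allow_identity: bool = False,
        shared_offsets: bool = False,
        return_distributions: bool = False,
        progress: bool = False,
    ) -> "PathwayEnrichmentResults":
        """Run the enrichment tests with permutation calibration.

        ``scheme`` selects the null: ``circular`` (genome rotation, the
        default), ``circular-per-chrom``, ``snp-random`` or ``gene-random``.
        Each trait receives an independent seeded random stream derived from
        ``seed`` unless ``shared_offsets`` reuses one stream for all traits.
        """
        traits = tuple(traits or self.gwas.traits)
        if shared_offsets or seed is None:
            child_seeds = [seed] * len(traits)
        else:
            child_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(len(traits))]

        results: list[PathwayTestResult] = []
        dists: dict[tuple[str, str], PermutationDistribution] = {}
        thr_index = math.ceil(level * n_perm) - 1
        for trait, child in zip(traits, child_seeds):
            engine = self._engine(trait)
            p_obs, K_obs, S_obs = engine.observed()
            if scheme == "gene-random":
                scores = engine.gene_scores()
                dist_map = gene_random_null(
                    scores, self.gene_sets, engine.universe_genes,
                    self.alpha_gene, n_perm, child, trait=trait, tail=self.tail,
                )
                matrix = np.column_stack([dist_map[pid].values for pid in engine.pathway_ids])
            else:
                rng = np.random.default_rng(child)
                matrix = engine.null_matrix(
                    scheme, n_perm, rng, allow_identity=allow_identity, progress=progress,
                )
            emp_p = (1 + (matrix <= p_obs[None, :]).sum(axis=0)) / (1 + n_perm)
            thresholds = np.sort(matrix, axis=0)[thr_index]
            for j, pid in enumerate(engine.pathway_ids):
                results.append(
                    PathwayTestResult(
                        pathway_id=pid,
                        trait=trait,
                        m=int(engine.m_arr[j]),
                        K=int(K_obs[j]),
                        N=engine.N,
                        S=S_obs,
                        theoretical_p=float(p_obs[j]),
                        alpha_gene=self.alpha_gene,
                        empirical_p=float(emp_p[j]),
                        empirical_threshold=float(thresholds[j]),
                        n_permutations=n_perm,
                    )
                )
                if return_distributions:
                    dists[(pid, trait)] = PermutationDistribution(
                        pid, trait, matrix[:, j].copy(), n_perm, scheme, child,
                    )
            logger.info(
                "trait %s: %d pathways, universe N=%d, S=%d, scheme=%s, n_perm=%d",
                trait, len(engine.pathway_ids), engine.N, S_obs, scheme, n_perm,
            )
        return PathwayEnrichmentResults(
            self, results, scheme=scheme, n_perm=n_perm, seed=seed, level=level,
            distributions=dists if return_distributions else None,
        )


class PathwayEnrichmentResults:
    """Fitted pathway-enrichment results.

    Iterable over :class:`PathwayTestResult`; convert with
    :meth:`to_frame`, persist with :meth:`save`, inspect with
    :meth:`summary`.
    """

    def __init__(
        self,
        model: PathwayEnrichment,
        results: list[PathwayTestResult],
        *,
        scheme: str,
        n_perm: int,
        seed: int | None,
        level: float,
        distributions: dict[tuple[str, str], PermutationDistribution] | None = None,
    ):
        self.model = model
        self.results = results
        self.scheme = scheme
        self.n_perm = n_perm
        self.seed = seed
        self.level = level
        self.distributions = distributions

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pathway_id": r.pathway_id,
                    "trait": r.trait,
                    "genes_in_pathway": r.m,
                    "significant_genes": r.K,
                    "universe": r.N,
                    "significant_universe": r.S,
                    "theoretical_p": r.theoretical_p,
                    "empirical_p": r.empirical_p,
                    "empirical_threshold": r.empirical_threshold,
                    "n_permutations": r.n_permutations,
                }
                for r in self.results
            ]
        )

    def save(self, path: str | Path) -> None:
        write_results(self.results, path)

    def summarize(self, level: float | None = None) -> RunSummary:
        return summarize(self.to_frame(), self.level if level is None else level)

    def summary(self, level: float | None = None, top: int = 10) -> str:
        """Human-readable overview: headline counts and the top pathways."""
        s = self.summarize(level)
        df = self.to_frame().sort_values("empirical_p").head(top)
        lines = [
            "Pathway enrichment (permutation-calibrated hypergeometric test)",
            "=" * 66,
            f"scheme: {self.scheme}    permutations: {self.n_perm}    seed: {self.seed}",
            f"annotation window: {self.model.window_bp} bp    "
            f"alpha_gene: {self.model.alpha_gene}    level: {s.level}",
            f"tests: {s.n_tests}    expected by chance: {s.expected_by_chance}",
            f"theoretically significant (P <= {s.level}): {s.n_theoretical_significant}",
            f"empirically significant  (P <= {s.level}): {s.n_empirical_significant}"
            f"    (overlap {s.overlap})",
            "",
            f"top {min(top, len(df))} tests by empirical P:",
            df.to_string(
                index=False,
                columns=[
                    "pathway_id", "trait", "genes_in_pathway", "significant_genes",
                    "theoretical_p", "empirical_p", "empirical_threshold",
                ],
                float_format=lambda x: f"{x:.4g}",
            ),
        ]
        return "\n".join(lines)

    def plot_calibration(self, ax=None):
        """Scatter of theoretical vs empirical P values (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        ax.scatter(df["theoretical_p"], df["empirical_p"], s=8, alpha=0.6)
        ax.plot([0, 1], [0, 1], color="red", lw=1)
        ax.set_xlabel("hypergeometric-theoretical P")
        ax.set_ylabel("hypergeometric-empirical P")
        ax.set_title(f"{self.scheme} permutation calibration")
        return ax
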