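"""Hypergeometric over-representation test for pathways.

With a universe of N scored genes of which S are "significant" (gene
P value at or below the gene-level cutoff alpha), a pathway covering m
universe genes with K significant members is tested against the
hypergeometric distribution: the reported P value is the tail probability
P(X >= K) of drawing at least K significant genes in m draws without
replacement (``tail="gt"`` gives the strict-tail variant P(X > K)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom

from .gene_stats import GeneScoreTable
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

Tail = Literal["geq", "gt"]


@dataclass
class PathwayTestResult:
    """One pathway-trait enrichment test.

    m genes of the pathway are in the universe (N genes, S significant);
    K of the pathway's genes are significant. ``theoretical_p`` is the
    hypergeometric tail; the empirical fields are filled in after a
    permutation run, else None.
    """

    pathway_id: str
    trait: str
    m: int
    K: int
    N: int
    S: int
    theoretical_p: float
    alpha_gene: float
    empirical_p: float | None = None
    empirical_threshold: float | None = None
    n_permutations: int | None = None


def _check_bounds(m: int, K: int, N: int, S: int) -> None:
    if not (0 <= K <= m <= N):
        raise ValueError(f"require 0 <= K <= m <= N, got K={K}, m={m}, N={N}")
    if not (K <= S <= N):
        raise ValueError(f"require K <= S <= N, got K={K}, S={S}, N={N}")


def hypergeom_tail(m: int, K: int, N: int, S: int, tail: Tail = "geq") -> float:
    """Tail probability of the hypergeometric enrichment test.

    Population N with S successes, m draws; returns P(X >= K) (inclusive,
    the default) or P(X > K) (``tail="gt"``). K = 0 with the inclusive tail
    covers the whole support and returns 1.
    """
    _check_bounds(m, K, N, S)
    k = K - 1 if tail == "geq" else K
    p = float(hypergeom.sf(k, N, S, m))
    return min(max(p, 0.0), 1.0)


def hypergeom_tail_vector(
    m: np.ndarray, K: np.ndarray, N: int, S: int | np.ndarray, tail: Tail = "geq"
) -> np.ndarray:
    """Vectorised tail over arrays of (m, K) pairs; used by the permutation engine."""
    k = np.asarray(K, dtype=np.int64)
    if tail == "geq":
        k = k - 1
    return np.clip(hypergeom.sf(k, N, S, m), 0.0, 1.0)


def test_pathways(
    scores: GeneScoreTable,
    sets: GeneSetCollection,
    alpha_gene: float,
    universe: Iterable[str],
    *,
    traits: Sequence[str] | None = None,
    tail: Tail = "geq",
) -> list[PathwayTestResult]:
    """Run the hypergeometric test for every pathway and trait.

    The universe must be a subset of the scored genes; a gene is significant
    when its gene P value is <= ``alpha_gene`` (boundary inclusive). Pathways
    with no gene in the universe are skipped with a logged notice.
    """
    if not (0.0 < alpha_gene < 1.0):
        raise ValueError(f"alpha_gene must be in (0, 1), got {alpha_gene}")
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("the gene universe is empty")
    if traits is None:
        traits = scores.traits

    results: list[PathwayTestResult] = []
    for trait in traits:
        trait_scores = scores.trait_scores(trait)
        missing = [g for g in universe if g not in trait_scores]
        if missing:
            raise ValueError(
                f"universe contains {len(missing)} genes without a score for trait "
                f"{trait!r} (e.g. {missing[:5]})"
            )
        N = len(universe)
        universe_set = set(universe)
        sig = {g for g in universe if trait_scores[g] <= alpha_gene}
        S = len(sig)
        for gene_set in sets:
            members = [g for g in gene_set.gene_ids if g in universe_set]
            m = len(members)
            if m == 0:
                logger.info(
                    "pathway %r has no genes in the universe for trait %r; skipped",
                    gene_set.set_id, trait,
                )
                continue
            K = sum(1 for g in members if g in sig)
            results.append(
                PathwayTestResult(
                    pathway_id=gene_set.set_id,
                    trait=trait,
                    m=m,
                    K=K,
                    N=N,
                    S=S,
                    theoretical_p=hypergeom_tail(m, K, N, S, tail),
                    alpha_gene=alpha_gene,
                )
            )
    return results
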