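"""Gene-level P values via Fisher's combination test.

Each gene inherits the association P values of its K annotated SNPs, which
are collapsed into one gene P value with Fisher's statistic

    Z_F = -2 * sum_{i=1..K} ln(P_i)

referred to the upper tail of a chi-square distribution with 2K degrees of
freedom. For K = 1 this is the identity on (0, 1]. No within-gene LD
correction is applied here: correlation between neighbouring SNPs is
deliberately left to be absorbed by the circular permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .annotation import AnnotationMap
from .io import GwasTable


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Combine K P values with Fisher's method.

    Returns the survival probability of Z_F = -2 Σ ln(P_i) under
    chi-square(2K). Inputs must be non-empty and lie in (0, 1].
    """
    if len(pvalues) == 0:
        raise ValueError("fisher_combine requires at least one P value")
    arr = np.asarray(pvalues, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError(f"P values must lie in (0, 1]; got {list(arr)}")
    z_half = -np.log(arr).sum()  # Z_F / 2
    # chi2.sf(z, 2K) == gammaincc(K, z/2); regularised upper incomplete gamma
    return float(special.gammaincc(len(arr), z_half))


@dataclass
class GeneScoreTable:
    """Gene P values for one or more traits.

    ``scores`` maps (gene_id, trait) to the combined gene P value;
    ``snp_counts`` maps gene_id to K, the number of SNPs combined.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    snp_counts: dict[str, int] = field(default_factory=dict)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(t for (_, t) in self.scores))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.snp_counts)

    def score(self, gene_id: str, trait: str) -> float:
        return self.scores[(gene_id, trait)]

    def trait_scores(self, trait: str) -> dict[str, float]:
        return {g: p for (g, t), p in self.scores.items() if t == trait}

    def update(self, other: "GeneScoreTable") -> None:
        self.scores.update(other.scores)
        self.snp_counts.update(other.snp_counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "trait": t, "n_snps": self.snp_counts[g], "gene_p": p}
            for (g, t), p in self.scores.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "trait", "n_snps", "gene_p"])


def score_genes(gwas: GwasTable, amap: AnnotationMap, trait: str) -> GeneScoreTable:
    """Fisher-combine each annotated gene's SNP P values for one trait.

    Genes with no annotated SNP are absent from the result. A SNP annotated
    to several genes contributes its P value to each of them.
    """
    if trait not in gwas.traits:
        raise KeyError(f"trait {trait!r} not in GWAS table (has {list(gwas.traits)})")
    table = GeneScoreTable()
    pvec = np.asarray([s.pvalues[trait] for s in gwas], dtype=float)
    for gene_id in sorted(amap.gene_to_snps):
        idx = amap.gene_to_snps[gene_id]
        z_half = float(-np.log(pvec[idx]).sum())
        table.scores[(gene_id, trait)] = float(special.gammaincc(len(idx), z_half))
        table.snp_counts[gene_id] = len(idx)
    return table
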