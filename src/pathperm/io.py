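"""Readers and writers for the three pathway-analysis input tables.

Three tab-separated inputs drive a run:

* a GWAS summary-statistics table (``snp``, ``chr``, ``pos``, then one
  column of association P values per trait),
* a gene annotation table (``gene_id``, ``symbol``, ``chr``, ``tx_start``,
  ``tx_end``; 1-based inclusive coordinates),
* gene sets in GMT format (set id, description, member gene ids).

All accepted P values lie in the half-open interval (0, 1]: zeros are
rejected (Fisher's combination takes logarithms) unless the caller opts in
to clamping them to a stated floor.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

logger = logging.getLogger(__name__)

#: Default circular chromosome order: autosomes 1..22 then X.
DEFAULT_CHROMOSOME_ORDER: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)

#: Floor applied to P = 0 when zero-clamping is requested.
PMIN_FLOOR = 1e-300


class FormatError(ValueError):
    """The file does not conform to the documented layout."""


class ValidationError(ValueError):
    """The file parses but violates a content invariant."""


@dataclass(frozen=True)
class SnpRecord:
    """One genotyped SNP with its per-trait association P values."""

    snp_id: str
    chromosome: str
    position: int
    pvalues: Mapping[str, float]

    def pvalue(self, trait: str) -> float:
        try:
            return self.pvalues[trait]
        except KeyError:
            raise KeyError(f"trait {trait!r} not present for SNP {self.snp_id!r}") from None


@dataclass(frozen=True)
class GeneRecord:
    """A gene's transcription span, 1-based inclusive."""

    gene_id: str
    symbol: str
    chromosome: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValidationError(
                f"gene {self.gene_id!r}: tx_start {self.tx_start} > tx_end {self.tx_end}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: identifier, free-text description, member gene ids."""

    set_id: str
    name: str
    gene_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneSetCollection:
    """Ordered mapping of pathway id -> :class:`GeneSet`."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self.sets:
            raise ValidationError(f"duplicate pathway id {gene_set.set_id!r}")
        if not gene_set.gene_ids:
            raise ValidationError(f"pathway {gene_set.set_id!r} has no member genes")
        self.sets[gene_set.set_id] = gene_set

    def all_gene_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s.gene_ids
        return frozenset(out)


class GwasTable(Sequence):
    """A validated GWAS summary table: a sequence of :class:`SnpRecord`.

    Also records the trait names and how many rows were rejected during
    reading (bad P value or missing position), so callers can audit input
    quality without re-parsing.
    """

    def __init__(
        self,
        snps: list[SnpRecord],
        traits: tuple[str, ...],
        rejections: list[str] | None = None,
    ):
        self.snps = snps
        self.traits = traits
        self.rejections = rejections or []

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def __len__(self) -> int:
        return len(self.snps)

    def __getitem__(self, i):
        return self.snps[i]

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.snps)


def _valid_pvalue(p: float) -> bool:
    return isinstance(p, (int, float)) and not math.isnan(p) and 0.0 < p <= 1.0


def read_gwas_table(
    path: str | Path,
    trait_columns: Sequence[str] | None = None,
    *,
    clamp_pmin: bool = False,
) -> GwasTable:
    """Read a GWAS summary-statistics TSV into a validated :class:`GwasTable`.

    Parameters
    ----------
    path
        Tab-separated file with header ``snp``, ``chr``, ``pos`` followed by
        one column per trait.
    trait_columns
        Traits to load; defaults to every column after the three fixed ones.
    clamp_pmin
        If true, P values exactly 0 are replaced by ``PMIN_FLOOR`` instead of
        causing the row to be rejected (for inputs that underflowed upstream).

    Rows with any P value outside (0, 1] or a missing/invalid position are
    logged and dropped (counted in ``GwasTable.rejections``); a duplicated
    SNP id is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str},
                     float_precision="round_trip")
    for col in ("snp", "chr", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if trait_columns is None:
        trait_columns = [c for c in df.columns if c not in ("snp", "chr", "pos")]
        if not trait_columns:
            raise FormatError(f"{path}: no trait columns found after snp/chr/pos")
    else:
        for col in trait_columns:
            if col not in df.columns:
                raise FormatError(f"{path}: missing trait column {col!r}")

    dup = df["snp"][df["snp"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate snp ids: {', '.join(map(str, dup[:10]))}")

    snps: list[SnpRecord] = []
    rejections: list[str] = []
    traits = tuple(trait_columns)
    for row in df.itertuples(index=False):
        d = row._asdict()
        pos = d["pos"]
        if pd.isna(pos) or int(pos) < 1:
            rejections.append(f"{d['snp']}: missing or non-positive position")
            continue
        pvals: dict[str, float] = {}
        bad = None
        for t in traits:
            p = d[t]
            if clamp_pmin and p == 0.0:
                p = PMIN_FLOOR
            if not _valid_pvalue(p):
                bad = f"{d['snp']}: P value {p!r} for trait {t!r} outside (0, 1]"
                break
            pvals[t] = float(p)
        if bad is not None:
            rejections.append(bad)
            continue
        snps.append(SnpRecord(str(d["snp"]), str(d["chr"]), int(pos), pvals))

    if rejections:
        logger.warning("%s: rejected %d rows during validation", path, len(rejections))
        for msg in rejections[:20]:
            logger.warning("  rejected %s", msg)
    return GwasTable(snps, traits, rejections)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the gene annotation TSV (``gene_id symbol chr tx_start tx_end``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chr": str})
    for col in ("gene_id", "symbol", "chr", "tx_start", "tx_end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene ids: {', '.join(map(str, dup[:10]))}")
    genes: list[GeneRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        start, end = int(row.tx_start), int(row.tx_end)
        if start > end:
            raise ValidationError(
                f"{path}:{lineno}: gene {row.gene_id!r} has tx_start {start} > tx_end {end}"
            )
        genes.append(GeneRecord(str(row.gene_id), str(row.symbol), str(row.chr), start, end))
    return genes


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (id, description, then member genes).

    Duplicate member ids on one line are deduplicated with a warning;
    duplicate set ids across lines are an error.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields, got {len(fields)}"
                )
            set_id, name, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r lists %d duplicate gene ids (deduplicated)",
                    path, lineno, set_id, len(members) - len(unique),
                )
            collection.add(GeneSet(set_id, name, frozenset(unique)))
    return collection


#: Column order of the results TSV.
RESULT_COLUMNS = (
    "pathway_id", "trait", "genes_in_pathway", "significant_genes",
    "universe", "significant_universe", "theoretical_p", "empirical_p",
    "empirical_threshold", "n_permutations",
)


def write_results(results: Sequence, path: str | Path) -> None:
    """Write pathway test results to a TSV, 15 significant digits.

    ``results`` is a sequence of :class:`pathperm.pathway_stats.PathwayTestResult`.
    Absent empirical fields are written as ``NA``.
    """
    if not results:
        raise ValidationError("refusing to write an empty result table")
    path = Path(path)

    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, float):
            return format(x, ".15g")
        return str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            row = (
                r.pathway_id, r.trait, r.m, r.K, r.N, r.S,
                r.theoretical_p, r.empirical_p, r.empirical_threshold,
                r.n_permutations,
            )
            fh.write("\t".join(fmt(x) for x in row) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (``NA`` -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"pathway_id": str, "trait": str},
                       float_precision="round_trip")
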