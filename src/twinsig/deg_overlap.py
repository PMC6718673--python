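"""Sex-specificity overlap statistics for differential-expression gene lists.

Given a DEG list (e.g. genes differing between affected and unaffected female
twins), a reference set (genes differentially expressed between healthy males
and females, i.e. sex-specific genes) and a gene universe (all detectable
genes), this module computes the overlap proportion, Fisher exact and Pearson
chi-square tests on the 2x2 membership table, Venn partitions for 2-4 sets,
and the small fold-change / GSEA ranking-score arithmetic used alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .errors import ContainmentError


@dataclass(frozen=True)
class DEGRecord:
    """One differential-expression result: gene id, log2 fold change, adjusted p."""

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not (0 < self.padj <= 1):
            raise ValueError(f"{self.gene_id}: padj must be in (0, 1], got {self.padj}")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"{self.gene_id}: log2fc must be finite")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, genes=frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapEnrichment:
    """Overlap of a DEG list with a reference set against a universe.

    ``fisher_p`` and ``chi2_p`` come from the standard disjoint 2x2 table
    ``[[overlap, list - overlap], [reference - overlap, rest of universe]]``.
    ``fisher_p_marginal`` uses the alternative construction that compares the
    list proportion against the raw reference/universe margin without removing
    the list from the background — both are reported because published overlap
    p-values do not always state which table was used.
    """

    n_list: int
    n_overlap: int
    proportion: float
    universe_size: int
    universe_hits: int
    baseline_proportion: float
    fisher_p: float
    fisher_p_marginal: float
    chi2_p: float
    odds_ratio: float


def filter_degs(
    table: Sequence[DEGRecord],
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    name: str = "DEGs",
) -> GeneSet:
    """Select significant DEGs: adjusted p strictly below ``alpha`` AND
    at least ``lfc_min`` absolute log2 fold change (inclusive).

    The defaults encode "adjusted p < 0.05 and at least twofold (one-fold
    log2) up- or downregulation". Duplicate gene ids are ambiguous and raise.
    """
    seen: set[str] = set()
    hits: list[str] = []
    for rec in table:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene id {rec.gene_id!r} in DEG table")
        seen.add(rec.gene_id)
        if rec.padj < alpha and abs(rec.log2fc) >= lfc_min:
            hits.append(rec.gene_id)
    return GeneSet.from_iterable(name, hits)


def fold_from_log2(lfc: float) -> float:
    """Linear fold change from a log2 fold change: 2**lfc."""
    if not math.isfinite(lfc):
        raise ValueError("log2 fold change must be finite")
    return 2.0 ** lfc


def rank_score(log2fc: float, padj: float) -> float:
    """Signed GSEA-style ranking score: log2fc * -log10(padj)."""
    if not (0 < padj <= 1):
        raise ValueError(f"padj must be in (0, 1], got {padj}")
    return log2fc * (-math.log10(padj))


def overlap_enrichment(
    deg_list: GeneSet,
    reference: GeneSet,
    universe: GeneSet,
    yates: bool = False,
    alternative: str = "two-sided",
) -> OverlapEnrichment:
    """Enrichment of ``reference`` membership within ``deg_list``.

    Builds the 2x2 table [[overlap, list-only], [reference-only, neither]]
    over ``universe`` and computes the Fisher exact p (``alternative``:
    "two-sided" by default, "greater" for a one-sided enrichment test), the
    Pearson chi-square p (no continuity correction unless ``yates``), and the
    sample odds ratio. Both sets must be contained in the universe.
    """
    if not deg_list.genes <= universe.genes:
        raise ContainmentError(f"DEG list {deg_list.name!r} is not contained in the universe")
    if not reference.genes <= universe.genes:
        raise ContainmentError(f"reference {reference.name!r} is not contained in the universe")
    n_list = len(deg_list)
    n_hits = len(reference)
    n_univ = len(universe)
    k = len(deg_list.genes & reference.genes)
    table = [[k, n_list - k], [n_hits - k, n_univ - n_list - (n_hits - k)]]
    fisher_p = 1.0
    chi2_p = 1.0
    if n_list > 0:
        fisher_p = float(stats.fisher_exact(table, alternative=alternative).pvalue)
        try:
            chi2_p = float(stats.chi2_contingency(table, correction=yates).pvalue)
        except ValueError:  # a zero margin makes chi-square undefined
            chi2_p = float("nan")
    marg = [[k, n_list - k], [n_hits, n_univ - n_hits]]
    fisher_p_marg = (
        float(stats.fisher_exact(marg, alternative=alternative).pvalue) if n_list else 1.0
    )
    a, b = table[0]
    c, d = table[1]
    odds = (a * d) / (b * c) if b * c > 0 else (0.0 if a == 0 else float("inf"))
    return OverlapEnrichment(
        n_list=n_list,
        n_overlap=k,
        proportion=k / n_list if n_list else 0.0,
        universe_size=n_univ,
        universe_hits=n_hits,
        baseline_proportion=n_hits / n_univ if n_univ else 0.0,
        fisher_p=fisher_p,
        fisher_p_marginal=fisher_p_marg,
        chi2_p=chi2_p,
        odds_ratio=odds,
    )


def venn_counts(sets: Sequence[GeneSet]) -> dict[str, int]:
    """Exact counts for every non-empty membership region of 2-4 gene sets.

    Region keys join the member set names with ``&`` (e.g. ``"A&B"`` is the
    region of elements in A and B but in none of the other sets). Counts sum
    to the size of the union.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"venn_counts supports 2-4 sets, got {len(sets)}")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("gene set names must be distinct")
    union = frozenset().union(*(s.genes for s in sets))
    counts: dict[str, int] = {}
    for g in union:
        members = tuple(s.name for s in sets if g in s.genes)
        key = "&".join(members)
        counts[key] = counts.get(key, 0) + 1
    return counts
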