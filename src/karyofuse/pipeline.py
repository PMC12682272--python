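"""End-to-end convenience wrappers: synteny table in, homology graph,
fate calls and per-fused-pair mixing statistics out."""

from __future__ import annotations

from dataclasses import dataclass, field

from .homology import (
    FateCall,
    HomologyGraph,
    HomologyMatrix,
    all_fates,
    classify_fused_pair,
    fused_reference_pairs,
    shared_ortholog_matrix,
    significant_homologies,
    score_homologies,
)
from .io_formats import SyntenyTable
from .mixing import fused_pair_quartiles, pairwise_mixing
from .orthology import filter_scaffolds


@dataclass
class HomologyAnalysis:
    """Results of the homology stage on one pairwise synteny table."""

    table: SyntenyTable            # after the min-genes scaffold filter
    matrix: HomologyMatrix
    graph: HomologyGraph
    fates: list[FateCall]

    @property
    def fused_pairs(self) -> set[frozenset[str]]:
        return fused_reference_pairs(self.graph)

    def count_fused(self) -> tuple[int, int, int]:
        fused = sum(1 for f in self.fates if f.fate == "fused")
        return fused, len(self.fates) - fused, len(self.fates)


def analyze_homology(
    table: SyntenyTable, min_genes: int = 15, alpha: float = 0.05
) -> HomologyAnalysis:
    """Filter scaffolds, test all scaffold pairs (one-sided Fisher,
    Bonferroni over tested pairs) and call reference-chromosome fates."""
    filtered = filter_scaffolds(table, min_genes=min_genes, side="both")
    matrix = score_homologies(shared_ortholog_matrix(filtered))
    graph = significant_homologies(matrix, alpha=alpha)
    return HomologyAnalysis(filtered, matrix, graph, all_fates(graph))


def mixing_by_fused_pair(
    analysis: HomologyAnalysis, normalization: str = "minmax"
) -> list[dict]:
    """Normalized turbulence for every fused reference pair, measured
    along the shared derived scaffold(s); one record per (pair,
    scaffold), classified sharp/mixed against the dataset quartiles
    once >= 4 values exist."""
    records = []
    for b, refs in sorted(analysis.graph.b_partners.items()):
        if len(refs) < 2:
            continue
        for r1, r2 in _pairs(sorted(refs)):
            try:
                t_norm = pairwise_mixing(
                    analysis.table, b, r1, r2, normalization=normalization
                )
            except ValueError:
                continue  # a ref with significant association but no genes kept
            records.append(
                {"query_scaffold": b, "ref1": r1, "ref2": r2, "t_norm": t_norm}
            )
    values = [r["t_norm"] for r in records]
    if len(values) >= 4:
        quartiles = fused_pair_quartiles(values)
        for r in records:
            r["classification"] = classify_fused_pair(r["t_norm"], quartiles)
    return records


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]
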