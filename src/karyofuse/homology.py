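"""Chromosome-homology statistics: shared-ortholog matrices, one-sided
Fisher exact tests with Bonferroni correction, contig co-occurrence
tests for fusion-with-mixing (FWM), and chromosome-fate / fusion
counting.

The homology test for a scaffold pair (i, j) collapses the
shared-ortholog matrix to a 2x2 table

    a = C[i, j]          b = row_i - a
    c = col_j - a        d = N - a - b - c

and asks for enrichment: the one-sided (greater) Fisher exact p-value
is the hypergeometric tail P(X >= a) with population N, successes
row_i, draws col_j.  All hypotheses here are enrichment hypotheses, so
one-sided tests are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import SyntenyTable

FATES = ("one_to_one", "fused", "split", "complex", "unplaced")


@dataclass
class HomologyMatrix:
    """Shared-ortholog counts per scaffold pair, with raw and
    Bonferroni-adjusted one-sided Fisher p-values."""

    scaffolds_a: list[str]
    scaffolds_b: list[str]
    counts: np.ndarray
    p_raw: np.ndarray | None = None
    p_adj: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.scaffolds_a), len(self.scaffolds_b)):
            raise ValueError("counts shape does not match scaffold id lists")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def index_a(self, scaffold: str) -> int:
        return self.scaffolds_a.index(scaffold)

    def index_b(self, scaffold: str) -> int:
        return self.scaffolds_b.index(scaffold)

    def to_frame(self) -> pd.DataFrame:
        """Long-format TSV-ready table (one row per scaffold pair)."""
        rows = []
        for i, sa in enumerate(self.scaffolds_a):
            for j, sb in enumerate(self.scaffolds_b):
                rows.append(
                    {
                        "scaffold_a": sa,
                        "scaffold_b": sb,
                        "shared": int(self.counts[i, j]),
                        "p_raw": None if self.p_raw is None else float(self.p_raw[i, j]),
                        "p_adj": None if self.p_adj is None else float(self.p_adj[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FateCall:
    """Inferred fate of one reference scaffold in the association graph."""

    scaffold: str
    fate: str
    partners: tuple[str, ...]
    p_adj: tuple[float, ...] = ()


@dataclass
class HomologyGraph:
    """Bipartite significant-association graph between reference (a)
    and query (b) scaffolds, including degree-0 nodes."""

    a_partners: dict[str, set[str]]
    b_partners: dict[str, set[str]]
    p_adj: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(a, b) for a, bs in self.a_partners.items() for b in bs}

    @property
    def n_edges(self) -> int:
        return sum(len(bs) for bs in self.a_partners.values())


def shared_ortholog_matrix(table: SyntenyTable) -> HomologyMatrix:
    """Count shared orthologs per (scaffold_a, scaffold_b) pair."""
    if len(table) == 0:
        raise ValueError("empty synteny table")
    ct = pd.crosstab(table.df["scaffold_a"], table.df["scaffold_b"])
    ct = ct.sort_index(axis=0).sort_index(axis=1)
    return HomologyMatrix(
        scaffolds_a=ct.index.tolist(),
        scaffolds_b=ct.columns.tolist(),
        counts=ct.to_numpy(),
    )


def fisher_pvalues(counts: np.ndarray) -> np.ndarray:
    """One-sided (greater) Fisher exact p-value for every cell of a
    contingency matrix, vectorized: P(X >= a) with X hypergeometric."""
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.sum()
    if n == 0:
        raise ValueError("matrix has no observations (N = 0)")
    rows = counts.sum(axis=1, keepdims=True)
    cols = counts.sum(axis=0, keepdims=True)
    # sf(a-1) = P(X >= a)
    return hypergeom.sf(counts - 1, n, rows, cols)


def fisher_association(matrix: HomologyMatrix, i: int, j: int) -> float:
    """One-sided Fisher exact p-value for enrichment of cell (i, j)."""
    n = matrix.n_total
    if n == 0:
        raise ValueError("matrix has no observations (N = 0)")
    a = int(matrix.counts[i, j])
    return float(hypergeom.sf(a - 1, n, int(matrix.row_totals[i]), int(matrix.col_totals[j])))


def bonferroni(p_raw: np.ndarray, m: int | None = None) -> np.ndarray:
    """Elementwise Bonferroni adjustment ``min(1, m * p)``; ``m``
    defaults to the number of tested cells."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def score_homologies(matrix: HomologyMatrix, m: int | None = None) -> HomologyMatrix:
    """Fill ``p_raw`` and ``p_adj`` in place (and return the matrix).

    The Bonferroni family size defaults to the number of scaffold pairs
    in the (already filtered) matrix.
    """
    matrix.p_raw = fisher_pvalues(matrix.counts)
    matrix.p_adj = bonferroni(matrix.p_raw, m)
    return matrix


def significant_homologies(matrix: HomologyMatrix, alpha: float = 0.05) -> HomologyGraph:
    """Bipartite graph with an edge (i, j) iff ``p_adj[i, j] < alpha``."""
    if matrix.p_adj is None:
        score_homologies(matrix)
    a_partners: dict[str, set[str]] = {a: set() for a in matrix.scaffolds_a}
    b_partners: dict[str, set[str]] = {b: set() for b in matrix.scaffolds_b}
    p_adj: dict[tuple[str, str], float] = {}
    sig = np.argwhere(matrix.p_adj < alpha)
    for i, j in sig:
        a, b = matrix.scaffolds_a[i], matrix.scaffolds_b[j]
        a_partners[a].add(b)
        b_partners[b].add(a)
        p_adj[(a, b)] = float(matrix.p_adj[i, j])
    return HomologyGraph(a_partners, b_partners, p_adj)


def chromosome_fate(graph: HomologyGraph, reference: str) -> FateCall:
    """Classify one reference scaffold by its significant partners.

    - ``unplaced``: no significant partner;
    - ``one_to_one``: a single partner that associates only with it;
    - ``fused``: some partner also associates with another reference
      scaffold (the partner aggregates several ancestral units);
    - ``split``: several partners, each exclusive to this reference;
    - ``complex``: anything else.
    """
    if reference not in graph.a_partners:
        raise KeyError(f"scaffold {reference!r} not in association graph")
    partners = sorted(graph.a_partners[reference])
    pvals = tuple(graph.p_adj.get((reference, b), float("nan")) for b in partners)
    if not partners:
        fate = "unplaced"
    elif len(partners) == 1 and graph.b_partners[partners[0]] == {reference}:
        fate = "one_to_one"
    elif any(len(graph.b_partners[b]) >= 2 for b in partners):
        fate = "fused"
    elif len(partners) >= 2:
        fate = "split"
    else:  # pragma: no cover - unreachable under the rules above
        fate = "complex"
    return FateCall(reference, fate, tuple(partners), pvals)


def all_fates(graph: HomologyGraph) -> list[FateCall]:
    return [chromosome_fate(graph, a) for a in sorted(graph.a_partners)]


def fused_reference_pairs(graph: HomologyGraph) -> set[frozenset[str]]:
    """Reference-scaffold pairs joined by a shared derived partner
    (the pairwise fusion calls implied by the graph)."""
    pairs: set[frozenset[str]] = set()
    for refs in graph.b_partners.values():
        for a1, a2 in combinations(sorted(refs), 2):
            pairs.add(frozenset((a1, a2)))
    return pairs


def _presence_matrix(table: SyntenyTable, ref_side: str, presence_min: int) -> pd.DataFrame:
    query_side = "b" if ref_side == "a" else "a"
    ct = pd.crosstab(
        table.df[f"scaffold_{query_side}"], table.df[f"scaffold_{ref_side}"]
    )
    return ct >= presence_min


def cooccurrence_fwm_test(
    table: SyntenyTable,
    ref1: str,
    ref2: str,
    presence_min: int = 1,
    ref_side: str = "a",
) -> float:
    """Contig-level FWM test for one reference-chromosome pair.

    Each query contig is classified by whether it carries at least
    ``presence_min`` orthologs from ``ref1`` and from ``ref2``; a
    one-sided Fisher exact test asks whether the two presences are
    positively associated across contigs.  Interleaved contigs carrying
    both signatures are the hallmark of fusion-with-mixing surviving
    assembly fragmentation.
    """
    presence = _presence_matrix(table, ref_side, presence_min)
    for ref in (ref1, ref2):
        if ref not in presence.columns:
            raise KeyError(f"reference scaffold {ref!r} absent from table")
    has1 = presence[ref1].to_numpy()
    has2 = presence[ref2].to_numpy()
    n = len(presence)
    a = int((has1 & has2).sum())
    return float(hypergeom.sf(a - 1, n, int(has1.sum()), int(has2.sum())))


def cooccurrence_fwm_pairs(
    table: SyntenyTable,
    alpha: float = 0.05,
    presence_min: int = 1,
    ref_side: str = "a",
    correct: bool = False,
) -> dict[frozenset[str], float]:
    """All-pairs contig co-occurrence FWM scan (vectorized).

    Returns the significant reference pairs with their p-values;
    uncorrected at ``alpha`` by default, with optional Bonferroni over
    the number of tested pairs.
    """
    presence = _presence_matrix(table, ref_side, presence_min)
    refs = presence.columns.tolist()
    p = presence.to_numpy(dtype=np.int64)
    n = p.shape[0]
    both = p.T @ p  # co-presence counts per reference pair
    margins = p.sum(axis=0)
    pvals = hypergeom.sf(both - 1, n, margins[:, None], margins[None, :])
    n_pairs = len(refs) * (len(refs) - 1) // 2
    out: dict[frozenset[str], float] = {}
    for i, j in combinations(range(len(refs)), 2):
        pv = float(pvals[i, j])
        if correct:
            pv = min(1.0, n_pairs * pv)
        if pv < alpha:
            out[frozenset((refs[i], refs[j]))] = pv
    return out


def count_fused(
    obj: HomologyGraph | SyntenyTable,
    mode: str = "chromosome",
    alpha: float = 0.05,
    presence_min: int = 1,
    ref_side: str = "a",
    correct: bool = False,
) -> tuple[int, int, int]:
    """Count reference scaffolds participating in at least one
    fusion/FWM call; returns ``(n_fused, n_unfused, total)``.

    ``chromosome`` mode reads fate calls off a significant-association
    graph (query side assembled to chromosomes); ``contig`` mode runs
    the all-pairs co-occurrence FWM scan on a contig-level table,
    uncorrected at ``alpha`` unless ``correct`` is set.
    """
    if mode == "chromosome":
        if isinstance(obj, SyntenyTable):
            matrix = score_homologies(shared_ortholog_matrix(obj))
            obj = significant_homologies(matrix, alpha)
        refs = sorted(obj.a_partners)
        fused = {f.scaffold for f in all_fates(obj) if f.fate == "fused"}
    elif mode == "contig":
        if not isinstance(obj, SyntenyTable):
            raise TypeError("contig mode needs a contig-level SyntenyTable")
        refs = obj.scaffolds(ref_side)
        pairs = cooccurrence_fwm_pairs(
            obj, alpha=alpha, presence_min=presence_min, ref_side=ref_side,
            correct=correct,
        )
        fused = {r for pair in pairs for r in pair}
    else:
        raise ValueError("mode must be 'chromosome' or 'contig'")
    total = len(refs)
    n_fused = len(fused)
    return n_fused, total - n_fused, total


def classify_fused_pair(
    turbulence_value: float, quartiles: tuple[float, float]
) -> str:
    """Label a fused pair ``"sharp"`` (below the dataset's lower
    quartile of normalized turbulence, i.e. little mixing — a recent
    sharp fusion or translocation) or ``"mixed"`` otherwise.  A value
    exactly at Q1 counts as mixed."""
    q1, q3 = quartiles
    if q1 > q3:
        raise ValueError(f"invalid quartiles: Q1={q1} > Q3={q3}")
    return "sharp" if turbulence_value < q1 else "mixed"
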