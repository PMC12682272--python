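"""Mutual-best ortholog placement and pairwise synteny-table construction.

A single reference peptide set is mapped independently to two genomes;
an ortholog pair is the (best-in-A, best-in-B) placement of one
peptide, with each placement passing an identity floor and a
uniqueness guard (second-best/best score ratio).  This realizes
"mutual best" deterministically and auditably from per-genome mapping
output alone.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import PSYNT_COLUMNS, MappingHit, SyntenyTable


@dataclass
class PlacementSet:
    """Best placement per reference peptide in one genome."""

    placements: dict[str, MappingHit]
    genome_tag: str = ""
    score_attribute: str = "score"

    def __len__(self) -> int:
        return len(self.placements)


def best_placement(
    hits: list[MappingHit],
    min_identity: float = 0.0,
    score_ratio: float = 0.9,
    genome_tag: str = "",
) -> PlacementSet:
    """Keep, per peptide, its unique best placement.

    The highest-scoring hit survives iff its identity is at least
    ``min_identity`` and the runner-up scores at most ``score_ratio``
    of it (an exact tie is ambiguous and drops the peptide).  Peptides
    failing either guard are excluded entirely, trading recall for
    one-to-one confidence.
    """
    if not 0 <= min_identity <= 1:
        raise ValueError(f"min_identity {min_identity} outside [0, 1]")
    by_peptide: dict[str, list[MappingHit]] = defaultdict(list)
    for hit in hits:
        by_peptide[hit.peptide_id].append(hit)
    placements: dict[str, MappingHit] = {}
    for peptide, phits in by_peptide.items():
        ranked = sorted(phits, key=lambda h: (-h.score, h.scaffold_id, h.start))
        best = ranked[0]
        if best.identity < min_identity:
            continue
        if len(ranked) > 1:
            second = ranked[1]
            if best.score <= 0 or second.score / best.score > score_ratio:
                continue  # ambiguous placement
        placements[peptide] = best
    return PlacementSet(placements, genome_tag=genome_tag)


def build_psynt(pa: PlacementSet, pb: PlacementSet) -> SyntenyTable:
    """Join two placement sets into a synteny table.

    One row per peptide placed in both genomes; positions are placement
    midpoints; per-scaffold ranks are dense orders by (pos, ortholog id).
    Symmetric up to column swap in its two arguments.
    """
    shared = sorted(set(pa.placements) & set(pb.placements))
    rows = []
    for pep in shared:
        ha, hb = pa.placements[pep], pb.placements[pep]
        rows.append(
            (pep, ha.scaffold_id, ha.midpoint, 0, hb.scaffold_id, hb.midpoint, 0)
        )
    df = pd.DataFrame(rows, columns=PSYNT_COLUMNS)
    _assign_ranks(df)
    return SyntenyTable(df)


def _assign_ranks(df: pd.DataFrame) -> None:
    """Recompute dense per-scaffold ranks in place, ordering by position
    with ties broken by ortholog id."""
    for side in ("a", "b"):
        df[f"rank_{side}"] = 0
        for _, idx in df.groupby(f"scaffold_{side}", sort=False).groups.items():
            sub = df.loc[idx].sort_values([f"pos_{side}", "ortholog"], kind="stable")
            df.loc[sub.index, f"rank_{side}"] = range(len(sub))


def filter_scaffolds(
    table: SyntenyTable, min_genes: int = 15, side: str = "both"
) -> SyntenyTable:
    """Drop scaffolds carrying fewer than ``min_genes`` orthologs.

    Filtering one side can push scaffolds on the other side below
    threshold, so with ``side="both"`` the filter iterates to a fixed
    point; the operation is therefore idempotent.  Ranks are recomputed
    densely on the surviving rows.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if side not in ("a", "b", "both"):
        raise ValueError("side must be 'a', 'b' or 'both'")
    sides = ("a", "b") if side == "both" else (side,)
    df = table.df.copy()
    changed = True
    while changed:
        changed = False
        for s in sides:
            counts = df[f"scaffold_{s}"].value_counts()
            bad = counts[counts < min_genes].index
            if len(bad):
                df = df[~df[f"scaffold_{s}"].isin(bad)]
                changed = True
    df = df.reset_index(drop=True)
    _assign_ranks(df)
    return SyntenyTable(df)
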