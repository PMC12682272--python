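"""Karyotype-evolution simulator.

Simulates descent of multi-chromosome genomes from a shared ancestor
under chromosome fusion (sharp or with mixing), fission,
inter-chromosomal translocation, intra-chromosomal shuffling and gene
loss, plus draft-assembly fragmentation.  Every gene carries an
immutable ancestral-chromosome label, so downstream inference (homology
tests, fusion counting, mixing statistics) can be scored against ground
truth.

A genome is an ordered map ``scaffold_id -> ordered gene-id list``; gene
order is the only positional currency (the analysis pipeline works on
order statistics, not physical distances).  Fusion-with-mixing applies a
mixing operator of intensity ``m``: ``m >= 1`` draws a uniform random
permutation of the merged gene order, ``0 < m < 1`` performs
``ceil(m*n)`` random adjacent transpositions per gene (``n`` = merged
length), a monotone dial from a sharp boundary to full interleaving.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import PSYNT_COLUMNS, GeneRecord, SyntenyTable

EVENT_TYPES = ("FUSE", "FUSE_MIX", "FISSION", "TRANSLOCATE", "INTRA_SHUFFLE", "LOSS")

#: fixed inter-gene spacing (bp) used when synthesizing coordinates from ranks
GENE_SPACING = 10_000


@dataclass
class SimGenome:
    """A simulated genome: ordered scaffolds of ordered genes, each gene
    labelled with the ancestral chromosome it descends from."""

    scaffolds: dict[str, list[str]]
    ancestry: dict[str, str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for scaf, genes in self.scaffolds.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene id {g!r} occurs twice")
                seen.add(g)
                if g not in self.ancestry:
                    raise ValueError(f"gene {g!r} has no ancestral label")

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.scaffolds.values())

    @property
    def gene_ids(self) -> set[str]:
        return {g for genes in self.scaffolds.values() for g in genes}

    def copy(self) -> "SimGenome":
        return SimGenome(
            {k: list(v) for k, v in self.scaffolds.items()}, dict(self.ancestry)
        )

    def label_runs(self, scaffold_id: str) -> list[str]:
        """Ancestral labels in gene order along one scaffold."""
        return [self.ancestry[g] for g in self.scaffolds[scaffold_id]]

    def to_gene_records(self, species_tag: str = "") -> list[GeneRecord]:
        """Synthesize coordinates from ranks at fixed spacing."""
        out = []
        for scaf, genes in self.scaffolds.items():
            for i, g in enumerate(genes):
                start = i * GENE_SPACING
                out.append(
                    GeneRecord(g, scaf, start, start + 1000, "+", species_tag)
                )
        return out

    @classmethod
    def from_gene_records(cls, records: Sequence[GeneRecord]) -> "SimGenome":
        """Build a genome from coordinate records (order by midpoint);
        ancestry defaults to each gene's own scaffold."""
        by_scaf: dict[str, list[GeneRecord]] = {}
        for rec in records:
            by_scaf.setdefault(rec.scaffold_id, []).append(rec)
        scaffolds = {
            scaf: [r.gene_id for r in sorted(recs, key=lambda r: (r.midpoint, r.gene_id))]
            for scaf, recs in sorted(by_scaf.items())
        }
        ancestry = {g: scaf for scaf, genes in scaffolds.items() for g in genes}
        return cls(scaffolds, ancestry)


@dataclass(frozen=True)
class Event:
    """One karyotype-evolution event.

    ``params`` by type:

    - FUSE: none
    - FUSE_MIX: ``m`` mixing intensity in [0, 1] (default 1)
    - FISSION: ``index`` split position (random if absent)
    - TRANSLOCATE: ``length`` segment length, ``start`` segment start in
      the source (both random if absent), ``insert_at`` position in the
      destination (random if absent)
    - LOSS: ``rate`` per-gene deletion probability
    """

    type: str
    participants: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        object.__setattr__(self, "participants", tuple(self.participants))
        m = self.params.get("m")
        if m is not None and not 0 <= m <= 1:
            raise ValueError(f"mixing intensity m={m} outside [0, 1]")


@dataclass(frozen=True)
class FragmentationProfile:
    """Empirical multiset of genes-per-contig counts for draft-assembly
    fragmentation."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("fragmentation profile is empty")
        if any(c < 1 for c in self.counts):
            raise ValueError("genes-per-contig counts must be >= 1")

    @classmethod
    def from_genome(cls, genome: SimGenome) -> "FragmentationProfile":
        """Profile observed in an already-fragmented assembly."""
        return cls(tuple(len(v) for v in genome.scaffolds.values()))

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))


def make_ancestor(k: int = 46, genes_per_chrom: int = 100, seed: int | None = None) -> SimGenome:
    """Build the shared ancestor: ``k`` chromosomes of ``genes_per_chrom``
    genes each; every gene's ancestral label is its own chromosome.

    The default ``k=46`` mirrors the squid/cuttlefish-like karyotype the
    simulator is calibrated to emulate.  ``seed`` is accepted for
    interface symmetry; construction is deterministic.
    """
    if k < 1 or genes_per_chrom < 1:
        raise ValueError("k and genes_per_chrom must be >= 1")
    width = max(2, len(str(k)))
    scaffolds = {}
    ancestry = {}
    for i in range(1, k + 1):
        cid = f"anc{i:0{width}d}"
        genes = [f"{cid}_g{j:04d}" for j in range(genes_per_chrom)]
        scaffolds[cid] = genes
        for g in genes:
            ancestry[g] = cid
    return SimGenome(scaffolds, ancestry)


def _mix_order(genes: list[str], m: float, rng: np.random.Generator) -> list[str]:
    n = len(genes)
    if n < 2 or m == 0:
        return list(genes)
    if m >= 1:
        return [genes[i] for i in rng.permutation(n)]
    out = list(genes)
    n_swaps = math.ceil(m * n) * n  # ceil(m*n) adjacent transpositions per gene
    idx = rng.integers(0, n - 1, size=n_swaps)
    for i in idx:
        out[i], out[i + 1] = out[i + 1], out[i]
    return out


def apply_event(genome: SimGenome, event: Event, rng: np.random.Generator) -> SimGenome:
    """Apply one event, returning a new genome (input untouched).

    Gene count is conserved by every event except LOSS; ancestral labels
    never change.  Mixing is modelled as forward-only: no event restores
    a pre-mixing order, reflecting the effective irreversibility of
    fusion-with-mixing.
    """
    g = genome.copy()
    for scaf in event.participants:
        if scaf not in g.scaffolds:
            raise KeyError(f"scaffold {scaf!r} not present at event time")

    if event.type in ("FUSE", "FUSE_MIX"):
        if len(event.participants) != 2:
            raise ValueError(f"{event.type} needs exactly 2 participants")
        a, b = event.participants
        merged = g.scaffolds.pop(a) + g.scaffolds.pop(b)
        if event.type == "FUSE_MIX":
            merged = _mix_order(merged, float(event.params.get("m", 1.0)), rng)
        g.scaffolds[f"{a}+{b}"] = merged

    elif event.type == "FISSION":
        (s,) = event.participants
        genes = g.scaffolds.pop(s)
        index = event.params.get("index")
        if index is None:
            index = int(rng.integers(1, len(genes))) if len(genes) > 1 else 1
        if not 1 <= index <= len(genes) - 1:
            raise ValueError(
                f"FISSION index {index} out of range for {s!r} ({len(genes)} genes)"
            )
        g.scaffolds[f"{s}_f1"] = genes[:index]
        g.scaffolds[f"{s}_f2"] = genes[index:]

    elif event.type == "TRANSLOCATE":
        src, dst = event.participants
        genes = g.scaffolds[src]
        if not genes:
            raise ValueError(f"TRANSLOCATE from empty scaffold {src!r}")
        length = event.params.get("length")
        if length is None:
            length = int(rng.integers(1, len(genes) + 1))
        if not 1 <= length <= len(genes):
            raise ValueError(f"TRANSLOCATE length {length} out of range")
        start = event.params.get("start")
        if start is None:
            start = int(rng.integers(0, len(genes) - length + 1))
        if not 0 <= start <= len(genes) - length:
            raise ValueError(f"TRANSLOCATE start {start} out of range")
        segment = genes[start : start + length]
        g.scaffolds[src] = genes[:start] + genes[start + length :]
        target = g.scaffolds[dst]
        insert_at = event.params.get("insert_at")
        if insert_at is None:
            insert_at = int(rng.integers(0, len(target) + 1))
        g.scaffolds[dst] = target[:insert_at] + segment + target[insert_at:]
        if not g.scaffolds[src]:
            del g.scaffolds[src]

    elif event.type == "INTRA_SHUFFLE":
        (s,) = event.participants
        genes = g.scaffolds[s]
        g.scaffolds[s] = [genes[i] for i in rng.permutation(len(genes))]

    elif event.type == "LOSS":
        rate = float(event.params.get("rate", 0.0))
        if not 0 <= rate <= 1:
            raise ValueError(f"LOSS rate {rate} outside [0, 1]")
        targets = event.participants or tuple(g.scaffolds)
        for scaf in targets:
            genes = g.scaffolds[scaf]
            keep = rng.random(len(genes)) >= rate
            g.scaffolds[scaf] = [gi for gi, k in zip(genes, keep) if k]

    return g


def evolve(
    ancestor: SimGenome, scenario: Sequence[Event], seed: int | None = None
) -> tuple[SimGenome, list[dict]]:
    """Apply an ordered event list, returning the descendant and the
    event log (ground truth for recovery tests).

    A single generator seeded once drives every stochastic choice, in
    event order, so a fixed seed reproduces the run bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    genome = ancestor.copy()
    log: list[dict] = []
    for order, event in enumerate(scenario):
        before = set(genome.scaffolds)
        genome = apply_event(genome, event, rng)
        after = set(genome.scaffolds)
        log.append(
            {
                "order": order,
                "type": event.type,
                "participants": list(event.participants),
                "params": {k: v for k, v in event.params.items()},
                "created": sorted(after - before),
                "removed": sorted(before - after),
            }
        )
    return genome, log


def write_event_log(log: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(log, indent=2) + "\n")
    return path


def emit_observed(
    genome_a: SimGenome,
    genome_b: SimGenome,
    retention: float = 1.0,
    seed: int | None = None,
) -> SyntenyTable:
    """Bridge simulator to pipeline: emit the synteny table an orthology
    pipeline would recover from two descendants of one ancestor.

    Each shared gene is kept independently with probability
    ``retention`` (modelling incomplete orthology recovery); positions
    are synthesized as ordinal rank x 10 kb on the retained set, so
    ranks are dense per scaffold.
    """
    if not 0 < retention <= 1:
        raise ValueError(f"retention {retention} outside (0, 1]")
    shared = genome_a.gene_ids & genome_b.gene_ids
    if not shared:
        raise ValueError("genomes share no gene ids (disjoint gene sets)")
    rng = np.random.default_rng(seed)
    shared_sorted = sorted(shared)
    if retention < 1:
        keep_mask = rng.random(len(shared_sorted)) < retention
        kept = {g for g, k in zip(shared_sorted, keep_mask) if k}
    else:
        kept = set(shared_sorted)

    def _placements(genome: SimGenome) -> dict[str, tuple[str, int]]:
        out = {}
        for scaf, genes in genome.scaffolds.items():
            rank = 0
            for g in genes:
                if g in kept:
                    out[g] = (scaf, rank)
                    rank += 1
        return out

    pa = _placements(genome_a)
    pb = _placements(genome_b)
    rows = []
    for g in sorted(kept):
        sa, ra = pa[g]
        sb, rb = pb[g]
        rows.append((g, sa, float(ra * GENE_SPACING), ra, sb, float(rb * GENE_SPACING), rb))
    return SyntenyTable(pd.DataFrame(rows, columns=PSYNT_COLUMNS))


def fragment_genome(
    genome: SimGenome,
    profile: FragmentationProfile,
    seed: int | None = None,
) -> SimGenome:
    """Cut each scaffold into consecutive contig-like blocks whose sizes
    are drawn with replacement from the genes-per-contig profile (last
    block truncated to fit).

    Fragment ids are ``<parent>:f<i>`` with a zero-padded index, so
    sorting fragment ids and concatenating their gene lists reproduces
    the parent genome exactly.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(profile.counts)
    scaffolds: dict[str, list[str]] = {}
    for scaf, genes in genome.scaffolds.items():
        pos = 0
        blocks = []
        while pos < len(genes):
            size = int(counts[rng.integers(0, len(counts))])
            blocks.append(genes[pos : pos + size])  # last block truncated
            pos += size
        width = max(3, len(str(len(blocks))))
        for i, block in enumerate(blocks):
            scaffolds[f"{scaf}:f{i:0{width}d}"] = block
    return SimGenome(scaffolds, dict(genome.ancestry))


def unfragment_genome(fragmented: SimGenome) -> SimGenome:
    """Invert :func:`fragment_genome` by concatenating fragments in id
    order under each parent scaffold."""
    parents: dict[str, list[str]] = {}
    for frag_id in sorted(fragmented.scaffolds):
        parent = frag_id.rsplit(":f", 1)[0]
        parents.setdefault(parent, []).extend(fragmented.scaffolds[frag_id])
    return SimGenome(parents, dict(fragmented.ancestry))


def random_fusion_scenario(
    ancestor: SimGenome,
    n_fuse: int = 0,
    n_fuse_mix: int = 20,
    m: float = 1.0,
    seed: int | None = None,
) -> list[Event]:
    """Draw a scenario of disjoint pairwise fusions: ``n_fuse`` sharp
    fusions and ``n_fuse_mix`` fusions-with-mixing over distinct
    chromosome pairs (each chromosome used at most once)."""
    n_events = n_fuse + n_fuse_mix
    chroms = sorted(ancestor.scaffolds)
    if 2 * n_events > len(chroms):
        raise ValueError(
            f"{n_events} pairwise fusions need {2 * n_events} chromosomes, "
            f"have {len(chroms)}"
        )
    rng = np.random.default_rng(seed)
    chosen = [chroms[i] for i in rng.permutation(len(chroms))[: 2 * n_events]]
    events = []
    for i in range(n_events):
        a, b = sorted(chosen[2 * i : 2 * i + 2])
        etype = "FUSE" if i < n_fuse else "FUSE_MIX"
        params = {} if etype == "FUSE" else {"m": m}
        events.append(Event(etype, (a, b), params))
    return events
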