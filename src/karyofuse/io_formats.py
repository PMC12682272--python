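"""Readers and writers for gene coordinates, protein-to-genome mapping GFF,
and the ``.psynt`` pairwise synteny table.

All coordinates are handled internally as 0-based half-open intervals.
GFF (1-based closed) is converted at the parsing boundary; BED is taken
as-is.  The ``.psynt`` dialect used throughout the package is a 7-column
tab-separated table with a ``#``-prefixed header::

    #ortholog  scaffold_a  pos_a  rank_a  scaffold_b  pos_b  rank_b

One row per mutual-best ortholog; ``pos`` is the placement midpoint in
base pairs and ``rank`` the ordinal gene rank within its scaffold
(0-based, dense after sorting by ``pos``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger("karyofuse")

PSYNT_COLUMNS = [
    "ortholog",
    "scaffold_a",
    "pos_a",
    "rank_a",
    "scaffold_b",
    "pos_b",
    "rank_b",
]
PSYNT_HEADER = "#" + "\t".join(PSYNT_COLUMNS)


class PsyntFormatError(ValueError):
    """Raised when a .psynt file violates the 7-column dialect."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene placed on a scaffold (0-based half-open coordinates)."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "."
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.scaffold_id:
            raise ValueError(f"gene {self.gene_id!r}: empty scaffold_id")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start must be < end "
                f"(got {self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class MappingHit:
    """One spliced-alignment placement of a reference peptide on a genome."""

    peptide_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    score: float
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"hit {self.peptide_id!r}: start must be < end "
                f"(got {self.start}, {self.end})"
            )
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError(f"hit {self.peptide_id!r}: score not finite")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(
                f"hit {self.peptide_id!r}: identity {self.identity} outside [0, 1]"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class SyntenyTable:
    """A pairwise synteny table: mutual-best orthologs with coordinates
    and ordinal ranks in two genomes (the in-memory form of ``.psynt``).

    Backed by a :class:`pandas.DataFrame` with columns
    ``ortholog, scaffold_a, pos_a, rank_a, scaffold_b, pos_b, rank_b``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PSYNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise PsyntFormatError(f"missing columns: {missing}")
        self.df = self.df[PSYNT_COLUMNS].reset_index(drop=True)
        dup = self.df["ortholog"].duplicated()
        if dup.any():
            dups = sorted(self.df.loc[dup, "ortholog"].unique().tolist())
            raise PsyntFormatError(f"duplicate ortholog ids: {dups[:10]}")

    def __len__(self) -> int:
        return len(self.df)

    def scaffolds(self, side: str) -> list[str]:
        """Distinct scaffold ids on side ``'a'`` or ``'b'``, sorted."""
        if side not in ("a", "b"):
            raise ValueError("side must be 'a' or 'b'")
        return sorted(self.df[f"scaffold_{side}"].unique().tolist())

    def validate_ranks(self) -> None:
        """Check that per-scaffold ranks are dense 0..k-1 after sorting by pos."""
        for side in ("a", "b"):
            for scaf, grp in self.df.groupby(f"scaffold_{side}", sort=False):
                ranks = grp.sort_values(f"pos_{side}")[f"rank_{side}"].to_numpy()
                if sorted(ranks.tolist()) != list(range(len(grp))):
                    raise PsyntFormatError(
                        f"ranks on scaffold_{side} {scaf!r} are not dense 0..k-1"
                    )


def read_gene_coordinates(
    path: str | Path,
    format: str = "gff3",
    feature_type: str = "gene",
    species_tag: str = "",
) -> list[GeneRecord]:
    """Read gene coordinates from GFF3 or BED into :class:`GeneRecord` s.

    GFF3 coordinates (1-based closed) are converted to the internal
    0-based half-open convention; BED is already 0-based half-open.
    Records are returned sorted by ``(scaffold_id, start)``.

    Parameters
    ----------
    path
        Input file.
    format
        ``"gff3"`` or ``"bed"``.
    feature_type
        GFF3 feature type to select (ignored for BED).
    species_tag
        Free-text tag copied into every record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gff3":
        records = _read_gff3_genes(path, feature_type, species_tag)
    elif format == "bed":
        records = _read_bed_genes(path, species_tag)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'gff3' or 'bed')")
    if not records:
        logger.warning("no gene records parsed from %s", path)
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.gene_id] = seen.get(rec.gene_id, 0) + 1
    dups = sorted(g for g, k in seen.items() if k > 1)
    if dups:
        raise ValueError(f"duplicate gene ids in {path}: {dups[:10]}")
    records.sort(key=lambda r: (r.scaffold_id, r.start))
    return records


def _read_gff3_genes(path: Path, feature_type: str, species_tag: str) -> list[GeneRecord]:
    records = []
    for lineno, feature in enumerate(_iter_gff(path), start=1):
        if feature.featuretype != feature_type:
            continue
        gene_id = feature.id or feature.attributes.get("ID", [""])[0]
        if not gene_id:
            raise ValueError(f"{path}: {feature_type} feature without ID near line {lineno}")
        records.append(
            GeneRecord(
                gene_id=gene_id,
                scaffold_id=feature.seqid,
                start=feature.start - 1,  # 1-based closed -> 0-based half-open
                end=feature.end,
                strand=feature.strand or ".",
                species_tag=species_tag,
            )
        )
    return records


def _read_bed_genes(path: Path, species_tag: str) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: BED line has {len(fields)} fields, need >= 4 "
                    "(chrom, start, end, name)"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            records.append(
                GeneRecord(
                    gene_id=fields[3],
                    scaffold_id=fields[0],
                    start=start,
                    end=end,
                    strand=strand,
                    species_tag=species_tag,
                )
            )
    return records


def _iter_gff(path: Path):
    """Stream GFF features without building a database."""
    try:
        yield from gffutils.iterators.DataIterator(str(path))
    except Exception as exc:  # gffutils raises bare ValueError on bad lines
        raise ValueError(f"{path}: malformed GFF ({exc})") from exc


def parse_mapping_gff(
    path: str | Path,
    score_attribute: str = "score",
    feature_type: str = "mRNA",
    identity_attribute: str = "Identity",
) -> list[MappingHit]:
    """Parse protein-to-genome mapping output in GFF dialect into hits.

    Expects one top-level alignment feature (default type ``mRNA``, as
    written by spliced protein aligners such as miniprot with ``--gff``)
    per placement.  The alignment score is taken from GFF column 6 when
    ``score_attribute="score"``, otherwise from the named attribute.  The
    peptide id is the first token of the ``Target`` attribute, falling
    back to the feature ``ID``.  Multiple placements per peptide are
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits = []
    for feature in _iter_gff(path):
        if feature.featuretype != feature_type:
            continue
        id_attr = feature.attributes.get("ID", [None])[0]
        label = id_attr or feature.id or f"{feature.seqid}:{feature.start}-{feature.end}"
        if score_attribute == "score":
            raw_score = feature.score
        else:
            vals = feature.attributes.get(score_attribute, [])
            raw_score = vals[0] if vals else None
        if raw_score in (None, "", "."):
            raise ValueError(f"{path}: feature {label!r} missing score ({score_attribute})")
        try:
            score = float(raw_score)
        except ValueError as exc:
            raise ValueError(
                f"{path}: feature {label!r} has non-numeric score {raw_score!r}"
            ) from exc
        target = feature.attributes.get("Target", [])
        peptide_id = target[0].split()[0] if target else label
        ident_vals = feature.attributes.get(identity_attribute, [])
        identity = float(ident_vals[0]) if ident_vals else 1.0
        hits.append(
            MappingHit(
                peptide_id=peptide_id,
                scaffold_id=feature.seqid,
                start=feature.start - 1,
                end=feature.end,
                strand=feature.strand,
                score=score,
                identity=identity,
            )
        )
    if not hits:
        logger.warning("no mapping hits parsed from %s", path)
    return hits


def read_psynt(path: str | Path) -> SyntenyTable:
    """Read a ``.psynt`` file (tab-separated, 7 columns, '#' header)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(PSYNT_COLUMNS):
                raise PsyntFormatError(
                    f"{path}:{lineno}: expected {len(PSYNT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                rows.append(
                    (
                        fields[0],
                        fields[1],
                        float(fields[2]),
                        int(fields[3]),
                        fields[4],
                        float(fields[5]),
                        int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise PsyntFormatError(f"{path}:{lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=PSYNT_COLUMNS)
    return SyntenyTable(df)


def write_psynt(table: SyntenyTable, path: str | Path) -> Path:
    """Write a :class:`SyntenyTable` to ``.psynt``; rows kept in order."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(PSYNT_HEADER + "\n")
        for row in table.df.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.ortholog),
                        str(row.scaffold_a),
                        _fmt_pos(row.pos_a),
                        str(int(row.rank_a)),
                        str(row.scaffold_b),
                        _fmt_pos(row.pos_b),
                        str(int(row.rank_b)),
                    ]
                )
                + "\n"
            )
    return path


def _fmt_pos(x: float) -> str:
    # positions are base-pair midpoints: integers or half-integers
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_bed(records: Iterable[GeneRecord], path: str | Path) -> Path:
    """Write gene records as 6-column BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.scaffold_id}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t0\t{rec.strand}\n"
            )
    return path
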