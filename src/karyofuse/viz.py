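"""Oxford-grid dotplots, clustering-based axis ordering, and summary
reports.

Dotplots place one dot per ortholog at its cumulative ordinal rank on
each axis (scaffolds concatenated in a chosen order); base-pair
coordinates are deliberately not used, since the genomes compared can
differ enormously in physical size while sharing gene order structure.
Dots in scaffold-pair cells whose Bonferroni-adjusted Fisher p-value
falls below alpha are drawn black, the rest gray.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .homology import FateCall, HomologyMatrix
from .io_formats import SyntenyTable
from .mixing import fused_pair_quartiles

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


@dataclass
class AxisOrder:
    """Ordered scaffold ids for one dotplot axis."""

    scaffolds: list[str]
    source: str = "given"  # "given" | "cluster"

    def __post_init__(self) -> None:
        if len(set(self.scaffolds)) != len(self.scaffolds):
            raise ValueError("axis order contains duplicate scaffolds")


def cluster_order(matrix: HomologyMatrix, axis: str = "a") -> AxisOrder:
    """Order one axis by Ward clustering of shared-ortholog profiles.

    Agglomerative clustering with the Ward criterion on Euclidean
    distances between the scaffolds' shared-ortholog count vectors
    (ward.D2 semantics: squared update on unsquared distances), leaf
    order returned.  Scaffolds are pre-sorted lexicographically so
    merge ties resolve deterministically by id.
    """
    if axis == "a":
        ids, vectors = matrix.scaffolds_a, matrix.counts
    elif axis == "b":
        ids, vectors = matrix.scaffolds_b, matrix.counts.T
    else:
        raise ValueError("axis must be 'a' or 'b'")
    order = np.argsort(np.asarray(ids, dtype=object))
    ids = [ids[i] for i in order]
    vectors = vectors[order]
    if len(ids) < 2:
        warnings.warn(f"axis {axis!r} has a single scaffold; returned as-is")
        return AxisOrder(list(ids), source="cluster")
    link = linkage(vectors.astype(float), method="ward")
    leaves = leaves_list(link)
    return AxisOrder([ids[i] for i in leaves], source="cluster")


def _offsets(table: SyntenyTable, order: AxisOrder, side: str) -> dict[str, int]:
    sizes = table.df[f"scaffold_{side}"].value_counts()
    missing = set(sizes.index) - set(order.scaffolds)
    if missing:
        raise ValueError(f"scaffolds in table missing from axis order: {sorted(missing)}")
    offsets, cum = {}, 0
    for scaf in order.scaffolds:
        offsets[scaf] = cum
        cum += int(sizes.get(scaf, 0))
    return offsets


def render_dotplot(
    table: SyntenyTable,
    order_a: AxisOrder,
    order_b: AxisOrder,
    matrix: HomologyMatrix | None = None,
    alpha: float = 0.05,
    color_by: str = "significance",
    out: str | Path = "dotplot.svg",
    dot_size: float = 4.0,
) -> Path:
    """Render the Oxford grid to SVG/PNG/PDF (by extension).

    One dot per table row at (cumulative rank_a, cumulative rank_b);
    scaffold boundaries drawn as grid lines.  ``color_by
    ="significance"`` paints dots black when the scaffold pair's
    adjusted p-value is below ``alpha`` (gray otherwise);
    ``"reference_label"`` colors by scaffold_a.
    """
    if color_by not in ("significance", "reference_label"):
        raise ValueError(f"unknown color_by {color_by!r}")
    off_a = _offsets(table, order_a, "a")
    off_b = _offsets(table, order_b, "b")
    df = table.df
    x = df["scaffold_a"].map(off_a).to_numpy() + df["rank_a"].to_numpy()
    y = df["scaffold_b"].map(off_b).to_numpy() + df["rank_b"].to_numpy()

    if color_by == "significance":
        if matrix is None or matrix.p_adj is None:
            raise ValueError("significance coloring needs a tested HomologyMatrix")
        ia = {s: i for i, s in enumerate(matrix.scaffolds_a)}
        ib = {s: i for i, s in enumerate(matrix.scaffolds_b)}
        sig = np.array(
            [
                matrix.p_adj[ia[ra], ib[rb]] < alpha
                for ra, rb in zip(df["scaffold_a"], df["scaffold_b"])
            ]
        )
        colors = np.where(sig, "black", "0.75")
    else:
        cats = pd.Categorical(df["scaffold_a"])
        cmap = plt.get_cmap("tab20")
        colors = [cmap(c % 20) for c in cats.codes]

    with plt.rc_context({"svg.hashsalt": "karyofuse"}):
        fig, ax = plt.subplots(figsize=(7, 7))
        ax.scatter(x, y, s=dot_size, c=colors, marker="o", linewidths=0)
        sizes_a = df["scaffold_a"].value_counts()
        sizes_b = df["scaffold_b"].value_counts()
        for scaf, off in off_a.items():
            ax.axvline(off + int(sizes_a.get(scaf, 0)), lw=0.3, color="0.85", zorder=0)
        for scaf, off in off_b.items():
            ax.axhline(off + int(sizes_b.get(scaf, 0)), lw=0.3, color="0.85", zorder=0)
        mids_a = {s: off_a[s] + int(sizes_a.get(s, 0)) / 2 for s in order_a.scaffolds}
        mids_b = {s: off_b[s] + int(sizes_b.get(s, 0)) / 2 for s in order_b.scaffolds}
        ax.set_xticks(list(mids_a.values()))
        ax.set_xticklabels(order_a.scaffolds, rotation=90, fontsize=5)
        ax.set_yticks(list(mids_b.values()))
        ax.set_yticklabels(order_b.scaffolds, fontsize=5)
        ax.set_xlabel("genome A (cumulative gene rank)")
        ax.set_ylabel("genome B (cumulative gene rank)")
        out = Path(out)
        save_kwargs = {}
        if out.suffix == ".svg":
            save_kwargs["metadata"] = {"Date": None}  # byte-determinism
        fig.savefig(out, **save_kwargs)
        plt.close(fig)
    return out


def summary_report(
    fates: list[FateCall],
    mixing_records: list[dict] | None = None,
    out_prefix: str | Path | None = None,
) -> dict:
    """Aggregate fate calls and per-pair mixing into a machine-readable
    report (dict; optionally written as ``<prefix>.json`` and
    ``<prefix>.tsv`` with identical content).

    ``mixing_records`` rows carry at least ``ref1, ref2, t_norm`` (and
    usually the query scaffold and classification).  Quartile fields
    are null when fewer than 4 mixing values exist.
    """
    mixing_records = mixing_records or []
    fused = sorted(f.scaffold for f in fates if f.fate == "fused")
    total = len(fates)
    t_values = [r["t_norm"] for r in mixing_records if r.get("t_norm") is not None]
    if len(t_values) >= 4:
        q1, q3 = fused_pair_quartiles(t_values)
    else:
        q1 = q3 = None
    report = {
        "n_fused": len(fused),
        "n_unfused": total - len(fused),
        "total": total,
        "fates": [
            {"scaffold": f.scaffold, "fate": f.fate, "partners": list(f.partners)}
            for f in fates
        ],
        "mixing": mixing_records,
        "turbulence_q1": q1,
        "turbulence_q3": q3,
    }
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.with_suffix(".json").write_text(json.dumps(report, indent=2) + "\n")
        rows = [
            {
                "scaffold": f["scaffold"],
                "fate": f["fate"],
                "partners": ",".join(f["partners"]),
            }
            for f in report["fates"]
        ]
        pd.DataFrame(rows).to_csv(out_prefix.with_suffix(".tsv"), sep="\t", index=False)
    return report
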