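"""Entropic-mixing statistics for ancestral-label sequences.

When two chromosomes fuse and their genes subsequently interleave
(fusion-with-mixing), the sequence of ancestral-chromosome labels read
along the derived scaffold becomes "turbulent": many short spells in
unpredictable arrangement.  This module quantifies that with Elzinga's
sequence-turbulence composite

    T(x) = log2( phi(x) * (s2_max + 1) / (s2 + 1) )

where ``phi`` is the number of distinct subsequences of the
distinct-successive-states (DSS, run-length compressed) sequence, ``s2``
the population variance of spell durations, and
``s2_max = (d - 1) * (1 - tbar)^2`` its maximum at fixed spell count
``d`` and mean duration ``tbar = n / d``.  A min-max normalization maps
T onto [0, 1] between the single-spell sequence (no mixing) and the
strictly alternating sequence (maximal mixing) of the same length and
alphabet; the normalization is pluggable because other conventions
exist in sequence-analysis software.

``phi`` is computed in exact integer arithmetic (it grows exponentially
in the DSS length) and only its base-2 logarithm is taken at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby
from typing import Callable, Hashable, Sequence

import numpy as np

from .io_formats import SyntenyTable


@dataclass(frozen=True)
class LabelSequence:
    """Ancestral-chromosome labels ordered along one derived scaffold."""

    scaffold_id: str
    labels: tuple
    ranks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError(f"scaffold {self.scaffold_id!r}: empty label sequence")
        if self.ranks and list(self.ranks) != sorted(self.ranks):
            raise ValueError("source ranks must be increasing")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TurbulenceResult:
    """Turbulence decomposition for one label sequence."""

    n: int
    d: int                      # spell count
    durations: tuple[int, ...]  # spell durations, genes
    phi: int                    # distinct subsequences of the DSS (exact)
    s2: float                   # population variance of durations
    s2max: float
    T: float                    # turbulence, bits
    T_norm: float | None = None

    @property
    def tbar(self) -> float:
        return self.n / self.d


def label_sequence(
    table: SyntenyTable,
    query_scaffold: str,
    restrict_labels: tuple[str, str] | None = None,
    query_side: str = "b",
) -> LabelSequence:
    """Read the reference-scaffold labels along one query scaffold.

    Genes are ordered by their rank on the query scaffold; with
    ``restrict_labels`` only genes whose reference scaffold is in the
    given pair are kept (order preserved), isolating the mixing signal
    of that candidate fused pair.
    """
    if query_side not in ("a", "b"):
        raise ValueError("query_side must be 'a' or 'b'")
    ref_side = "a" if query_side == "b" else "b"
    df = table.df
    sub = df[df[f"scaffold_{query_side}"] == query_scaffold]
    if sub.empty:
        raise KeyError(f"scaffold {query_scaffold!r} absent from table")
    sub = sub.sort_values(f"rank_{query_side}")
    if restrict_labels is not None:
        sub = sub[sub[f"scaffold_{ref_side}"].isin(restrict_labels)]
        if sub.empty:
            raise ValueError(
                f"no informative genes on {query_scaffold!r} for labels "
                f"{tuple(restrict_labels)}"
            )
    return LabelSequence(
        scaffold_id=query_scaffold,
        labels=tuple(sub[f"scaffold_{ref_side}"].tolist()),
        ranks=tuple(int(r) for r in sub[f"rank_{query_side}"].tolist()),
    )


def dss(labels: Sequence[Hashable]) -> tuple[tuple, tuple[int, ...]]:
    """Run-length encode into distinct successive states and durations."""
    if len(labels) < 1:
        raise ValueError("empty sequence")
    states, durations = [], []
    for state, run in groupby(labels):
        states.append(state)
        durations.append(sum(1 for _ in run))
    return tuple(states), tuple(durations)


def count_distinct_subsequences(states: Sequence[Hashable]) -> int:
    """Number of distinct subsequences (including the empty one).

    Standard dynamic programme ``phi_i = 2*phi_{i-1} - phi_{j-1}``,
    where ``j`` is the previous occurrence of the i-th symbol (the
    subtracted term is 0 if the symbol is new); exact integers.
    """
    phi = [1]  # phi_0: the empty subsequence
    last: dict[Hashable, int] = {}
    for i, sym in enumerate(states, start=1):
        value = 2 * phi[i - 1]
        if sym in last:
            value -= phi[last[sym] - 1]
        phi.append(value)
        last[sym] = i
    return phi[-1]


def turbulence(seq: LabelSequence | Sequence[Hashable]) -> TurbulenceResult:
    """Compute the turbulence composite for one label sequence."""
    labels = seq.labels if isinstance(seq, LabelSequence) else tuple(seq)
    states, durations = dss(labels)
    n = len(labels)
    d = len(states)
    phi = count_distinct_subsequences(states)
    dur = np.asarray(durations, dtype=float)
    s2 = float(dur.var())  # population variance (divide by d)
    tbar = n / d
    s2max = (d - 1) * (1 - tbar) ** 2
    T = math.log2(phi) + math.log2((s2max + 1.0) / (s2 + 1.0))
    return TurbulenceResult(
        n=n, d=d, durations=durations, phi=phi, s2=s2, s2max=s2max, T=T
    )


def _alternating(n: int, alphabet: Sequence[Hashable]) -> list:
    """Strictly alternating sequence of length n cycling the alphabet."""
    k = len(alphabet)
    return [alphabet[i % k] for i in range(n)]


def minmax_normalization(labels: Sequence[Hashable], T: float) -> float:
    """Min-max rescaling of T between the single-spell sequence (T=1,
    no mixing) and the strictly alternating sequence over the observed
    alphabet (maximal mixing) of the same length."""
    n = len(labels)
    alphabet = sorted(set(labels), key=repr)
    T_min = turbulence([alphabet[0]] * n).T  # = 1 for any n
    T_max = turbulence(_alternating(n, alphabet)).T
    if T_max <= T_min:
        return 0.0
    return min(1.0, max(0.0, (T - T_min) / (T_max - T_min)))


#: pluggable normalization strategies, name -> callable(labels, T) -> [0, 1]
NORMALIZATIONS: dict[str, Callable[[Sequence, float], float]] = {
    "minmax": minmax_normalization,
}


def normalized_turbulence(
    seq: LabelSequence | Sequence[Hashable],
    normalization: str | Callable[[Sequence, float], float] = "minmax",
) -> TurbulenceResult:
    """Turbulence with its normalized value in [0, 1] attached."""
    labels = seq.labels if isinstance(seq, LabelSequence) else tuple(seq)
    res = turbulence(labels)
    norm = NORMALIZATIONS[normalization] if isinstance(normalization, str) else normalization
    t_norm = norm(labels, res.T)
    return TurbulenceResult(
        n=res.n, d=res.d, durations=res.durations, phi=res.phi,
        s2=res.s2, s2max=res.s2max, T=res.T, T_norm=t_norm,
    )


def pairwise_mixing(
    table: SyntenyTable,
    query_scaffold: str,
    ref1: str,
    ref2: str,
    query_side: str = "b",
    normalization: str | Callable = "minmax",
) -> float:
    """Normalized turbulence of the two-state label sequence a fused
    reference pair traces along one query scaffold.  Symmetric in
    (ref1, ref2)."""
    seq = label_sequence(
        table, query_scaffold, restrict_labels=(ref1, ref2), query_side=query_side
    )
    present = set(seq.labels)
    for ref in (ref1, ref2):
        if ref not in present:
            raise ValueError(
                f"reference {ref!r} contributes no genes to {query_scaffold!r}"
            )
    return float(normalized_turbulence(seq, normalization).T_norm)


def fused_pair_quartiles(values: Sequence[float]) -> tuple[float, float]:
    """(Q1, Q3) of normalized-turbulence values over all fused pairs,
    by linear interpolation between order statistics (quantile q of
    sorted v_1..v_k at position 1 + (k-1)q)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 4:
        raise ValueError(f"need >= 4 values for quartiles, got {vals.size}")
    q1, q3 = np.percentile(vals, [25, 75], method="linear")
    return float(q1), float(q3)
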