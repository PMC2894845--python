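"""Distance-based trees from multiple alignments: p-distances and
neighbor joining with Newick output.

Distances are uncorrected (p-distances): the trees here are descriptive
cluster diagrams, not dated phylogenies, so no substitution-model
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .msa_consensus import MultipleAlignment
from .pairwise import GAP


class UndefinedDistanceError(ValueError):
    """A sequence pair shares no aligned (mutually non-gap) columns."""


@dataclass
class DistanceMatrix:
    labels: List[str]
    d: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(D)):
            raise ValueError("distances must be finite")
        self.d = D


def distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise p-distances: 1 - fractional identity over mutually non-gap
    columns."""
    if msa.n_rows < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    rows = [row for _, row in msa.rows]
    labels = [sid for sid, _ in msa.rows]
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ident = 0
            for x, y in zip(rows[i], rows[j]):
                if x != GAP and y != GAP:
                    shared += 1
                    ident += x == y
            if shared == 0:
                raise UndefinedDistanceError(
                    f"{labels[i]!r} and {labels[j]!r} share no aligned columns"
                )
            D[i, j] = D[j, i] = 1.0 - ident / shared
    return DistanceMatrix(labels, D)


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Ties in the Q-criterion resolve to the lowest index pair, so the output
    is deterministic.  Branch lengths may be negative for non-additive
    input; they are reported as computed.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.d.copy()
    nodes = list(dm.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        new_label = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new_label]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    return (
        f"({nodes[0]}:{_fmt(l0)},{nodes[1]}:{_fmt(l1)},{nodes[2]}:{_fmt(l2)});"
    )


def tree_from_alignment(msa: MultipleAlignment) -> str:
    return neighbor_joining(distance_matrix(msa))
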