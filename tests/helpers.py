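"""Independent oracles used across the test suite.

These deliberately avoid the package's dynamic-programming machinery: the
alignment oracle enumerates every global alignment explicitly and scores
each path from first principles.
"""

from __future__ import annotations

from typing import List, Tuple

Column = Tuple[int, int]  # residue indices, -1 for gap


def score_alignment_path(
    a: str,
    b: str,
    cols: List[Column],
    score_fn,
    gap_open_total: float,
    gap_extend: float,
    free_end_gaps: bool,
) -> float:
    """Score one explicit alignment path (affine gaps, optional free ends)."""
    q = 0.0
    for i, j in cols:
        if i >= 0 and j >= 0:
            q += score_fn(a[i], b[j])
    for row in (0, 1):
        runs = []
        start = None
        for k, col in enumerate(cols):
            if col[row] == -1:
                if start is None:
                    start = k
            elif start is not None:
                runs.append((start, k - 1))
                start = None
        if start is not None:
            runs.append((start, len(cols) - 1))
        for s, e in runs:
            if free_end_gaps and (s == 0 or e == len(cols) - 1):
                continue
            q -= gap_open_total + (e - s) * gap_extend
    return q


def brute_force_best_score(
    a: str,
    b: str,
    score_fn,
    gap_open_total: float,
    gap_extend: float,
    free_end_gaps: bool,
) -> float:
    """Maximum score over an exhaustive enumeration of all global
    alignments of ``a`` and ``b``."""
    best = [float("-inf")]

    def rec(i: int, j: int, cols: List[Column]):
        if i == len(a) and j == len(b):
            q = score_alignment_path(
                a, b, cols, score_fn, gap_open_total, gap_extend, free_end_gaps
            )
            if q > best[0]:
                best[0] = q
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(i, j)])
        if i < len(a):
            rec(i + 1, j, cols + [(i, -1)])
        if j < len(b):
            rec(i, j + 1, cols + [(-1, j)])

    rec(0, 0, [])
    return best[0]


def flood_fill_components(nodes, edges) -> List[set]:
    """Connected components by explicit flood fill (graph-library-free)."""
    adjacency = {n: set() for n in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    seen = set()
    components = []
    for n in nodes:
        if n in seen:
            continue
        comp = set()
        stack = [n]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adjacency[x] - comp)
        seen |= comp
        components.append(comp)
    return components
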