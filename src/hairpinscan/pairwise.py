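"""Global (Needleman-Wunsch) alignment with affine gap penalties.

The total alignment score -- substitution scores minus gap penalties -- is
called the *quality*, following GCG GAP terminology.  The default scoring
scheme is BLOSUM62 with gap open 8, gap extend 2 and free end gaps, an
approximation of the GAP program's protein defaults; every parameter is
configurable because different choices shift alignments by a column or two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Tuple

import numpy as np

from . import _gotoh
from .sequences import ALPHABET, AMINO_ACIDS, ProteinSequence

GAP = "-"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}


@lru_cache(maxsize=1)
def _blosum62_matrix() -> np.ndarray:
    """21x21 BLOSUM62 over ACDE...Y + X, with X scoring 0 against anything."""
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    S = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            S[i, j] = bl[a, b]
    return S


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    ``matrix`` is a 21x21 symmetric array over the alphabet ACDEFGHIKLMNP
    QRSTVWYX.  The first gap position costs ``gap_open + gap_extend``; each
    further position ``gap_extend``.  End gaps are free unless
    ``penalize_end_gaps``.
    """

    matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: float = 8.0
    gap_extend: float = 2.0
    penalize_end_gaps: bool = False

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=np.float64)
        if M.shape != (21, 21):
            raise ValueError("matrix must be 21x21 over the 20 amino acids plus X")
        if not np.array_equal(M, M.T):
            raise ValueError("substitution matrix must be symmetric")
        if np.any(np.diag(M)[:20] <= 0):
            raise ValueError("diagonal entries must be positive for the 20 residues")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        object.__setattr__(self, "matrix", M)

    @property
    def open_total(self) -> float:
        return self.gap_open + self.gap_extend

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_INDEX[a], _INDEX[b]])


_DEFAULT: ScoringScheme | None = None


def default_scheme() -> ScoringScheme:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ScoringScheme()
    return _DEFAULT


def encode(residues: str) -> np.ndarray:
    return np.fromiter((_INDEX[c] for c in residues), dtype=np.int64, count=len(residues))


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of two sequences plus Table-1-style stats.

    ``n_gap_openings`` counts maximal runs of gap characters over both rows
    (the "No. of Gaps" of a GAP report); ``n_similar`` counts aligned pairs
    with a positive substitution score, identities included.
    """

    seq_a: ProteinSequence
    seq_b: ProteinSequence
    row_a: str
    row_b: str
    quality: float
    scheme: ScoringScheme
    n_columns: int = 0
    n_aligned: int = 0
    n_identity: int = 0
    n_similar: int = 0
    n_gap_openings: int = 0

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        self.n_columns = len(self.row_a)
        n_aligned = n_id = n_sim = 0
        for x, y in zip(self.row_a, self.row_b):
            if x == GAP and y == GAP:
                raise ValueError("column with gaps in both rows")
            if x == GAP or y == GAP:
                continue
            n_aligned += 1
            if x == y:
                n_id += 1
            if self.scheme.score(x, y) > 0:
                n_sim += 1
        self.n_aligned, self.n_identity, self.n_similar = n_aligned, n_id, n_sim
        self.n_gap_openings = _count_gap_runs(self.row_a) + _count_gap_runs(self.row_b)

    @property
    def pct_identity(self) -> float:
        if self.n_aligned == 0:
            return float("nan")
        return 100.0 * self.n_identity / self.n_aligned

    @property
    def pct_similarity(self) -> float:
        if self.n_aligned == 0:
            return float("nan")
        return 100.0 * self.n_similar / self.n_aligned


def _count_gap_runs(row: str) -> int:
    runs = 0
    in_gap = False
    for c in row:
        if c == GAP:
            if not in_gap:
                runs += 1
            in_gap = True
        else:
            in_gap = False
    return runs


def global_align(
    a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of ``a`` and ``b`` under ``scheme``.

    Traceback ties prefer diagonal, then up (gap in ``b``), then left, so
    the result is deterministic.
    """
    if scheme is None:
        scheme = default_scheme()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty sequence")
    ai, bi = encode(a.residues), encode(b.residues)
    M = scheme.matrix[ai[:, None], bi[None, :]]
    free = not scheme.penalize_end_gaps
    Hm, Ix, Iy = _gotoh.gotoh_fill(M, scheme.open_total, scheme.gap_extend, free)
    cols, score = _gotoh.traceback(
        M, Hm, Ix, Iy, scheme.open_total, scheme.gap_extend, free
    )
    row_a = "".join(a.residues[i] if i >= 0 else GAP for i, _ in cols)
    row_b = "".join(b.residues[j] if j >= 0 else GAP for _, j in cols)
    return PairwiseAlignment(a, b, row_a, row_b, float(score), scheme)


def align_score(
    a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme | None = None
) -> float:
    """Quality only (no traceback); used heavily by the shuffle test."""
    if scheme is None:
        scheme = default_scheme()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty sequence")
    return float(
        _gotoh.gotoh_score(
            encode(a.residues),
            encode(b.residues),
            scheme.matrix,
            scheme.open_total,
            scheme.gap_extend,
            not scheme.penalize_end_gaps,
        )
    )


def alignment_stats(aln: PairwiseAlignment) -> Tuple[float, float, int, int]:
    """(pct_identity, pct_similarity, n_gap_openings, n_aligned)."""
    if aln.n_aligned == 0:
        raise ValueError("no aligned residue pairs: percentages are undefined")
    return (aln.pct_identity, aln.pct_similarity, aln.n_gap_openings, aln.n_aligned)


def _midline_char(x: str, y: str, scheme: ScoringScheme) -> str:
    if x == GAP or y == GAP:
        return " "
    if x == y:
        return "|"
    s = scheme.score(x, y)
    if s >= 2:
        return ":"
    if s > 0:
        return "."
    return " "


def render(aln: PairwiseAlignment, width: int = 60) -> str:
    """Render in the classic pairwise-figure convention: ``|`` identity,
    ``:`` close similarity, ``.`` more distant similarity, with residue
    numbers at line ends."""
    mid = "".join(
        _midline_char(x, y, aln.scheme) for x, y in zip(aln.row_a, aln.row_b)
    )
    out = []
    pos_a = pos_b = 0
    name_w = max(len(aln.seq_a.id), len(aln.seq_b.id), 1)
    for off in range(0, aln.n_columns, width):
        ra = aln.row_a[off : off + width]
        rb = aln.row_b[off : off + width]
        rm = mid[off : off + width]
        start_a = pos_a + 1 if len(ra) - ra.count(GAP) else pos_a
        start_b = pos_b + 1 if len(rb) - rb.count(GAP) else pos_b
        pos_a += len(ra) - ra.count(GAP)
        pos_b += len(rb) - rb.count(GAP)
        out.append(f"{aln.seq_a.id:<{name_w}} {start_a:>4} {ra} {pos_a}")
        out.append(f"{'':<{name_w}}      {rm}")
        out.append(f"{aln.seq_b.id:<{name_w}} {start_b:>4} {rb} {pos_b}")
        out.append("")
    return "\n".join(out)


def to_aligned_fasta(aln: PairwiseAlignment) -> str:
    return (
        f">{aln.seq_a.id}\n{aln.row_a}\n>{aln.seq_b.id}\n{aln.row_b}\n"
    )
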