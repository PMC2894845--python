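"""Minimal progressive multiple alignment, alignment ingestion, per-column
profiles and maximum-probability consensus sequences.

The progressive aligner is intentionally small: a UPGMA guide tree over
pairwise identity distances, profiles merged by profile-profile global
alignment under the pairwise scoring scheme ("once a gap, always a gap").
It stands in for a full multiple-alignment package where families of a few
dozen diverged homologues need a joint alignment for consensus derivation
and averaged hydropathy plots.

The consensus is the modal (highest-frequency) residue of each retained
column -- the "highest probability amino acid at that position" -- which
reproduces what a profile-HMM consensus emits without the HMM machinery;
the approximation is documented in the methods note.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from . import _gotoh
from .pairwise import (
    GAP,
    PairwiseAlignment,
    ScoringScheme,
    _INDEX,
    default_scheme,
    global_align,
)
from .sequences import ALPHABET, ProteinSequence


class AlignmentFormatError(ValueError):
    pass


class EmptyConsensusError(ValueError):
    pass


@dataclass
class MultipleAlignment:
    """Rows of (seq_id, gapped string), all the same length."""

    rows: List[Tuple[str, str]]
    source: str = "internal"

    def __post_init__(self):
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        ncol = len(self.rows[0][1])
        for sid, row in self.rows:
            if len(row) != ncol:
                raise AlignmentFormatError(
                    f"row {sid!r} has length {len(row)}, expected {ncol}"
                )
        # all-gap columns carry no information; drop them
        keep = [
            j for j in range(ncol) if any(row[j] != GAP for _, row in self.rows)
        ]
        if len(keep) != ncol:
            self.rows = [
                (sid, "".join(row[j] for j in keep)) for sid, row in self.rows
            ]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def sequences(self) -> List[ProteinSequence]:
        return [
            ProteinSequence(sid, row.replace(GAP, "")) for sid, row in self.rows
        ]


@dataclass
class ColumnProfile:
    """Per-column frequencies over the 21 residue symbols plus gap.

    ``freqs`` has shape (n_columns, 22): columns of :data:`SYMBOLS`,
    pseudocounted and normalized to sum to 1 per alignment column.
    """

    freqs: np.ndarray
    n_rows: int
    pseudocount: float = 0.01

    SYMBOLS = ALPHABET + GAP  # 21 residues + gap


def _profile_matrix(rows: Sequence[Tuple[str, str]]) -> np.ndarray:
    """(n_columns, 21) residue frequencies (gap mass simply dilutes)."""
    ncol = len(rows[0][1])
    F = np.zeros((ncol, 21))
    for _, row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                F[j, _INDEX[c]] += 1.0
    return F / len(rows)


def _merge(
    rows_a: List[Tuple[str, str]],
    rows_b: List[Tuple[str, str]],
    scheme: ScoringScheme,
) -> List[Tuple[str, str]]:
    """Profile-profile global alignment; gaps already present are kept."""
    Fa, Fb = _profile_matrix(rows_a), _profile_matrix(rows_b)
    M = Fa @ scheme.matrix @ Fb.T
    free = not scheme.penalize_end_gaps
    Hm, Ix, Iy = _gotoh.gotoh_fill(M, scheme.open_total, scheme.gap_extend, free)
    cols, _ = _gotoh.traceback(
        M, Hm, Ix, Iy, scheme.open_total, scheme.gap_extend, free
    )
    out: List[Tuple[str, str]] = []
    for sid, row in rows_a:
        out.append(
            (sid, "".join(row[i] if i >= 0 else GAP for i, _ in cols))
        )
    for sid, row in rows_b:
        out.append(
            (sid, "".join(row[j] if j >= 0 else GAP for _, j in cols))
        )
    return out


def progressive_align(
    seqs: Sequence[ProteinSequence], scheme: ScoringScheme | None = None
) -> MultipleAlignment:
    """Progressive alignment along a UPGMA guide tree.

    Guide distances are 1 - fractional identity (shorter-sequence
    denominator) from pairwise global alignments.  A single sequence is
    returned unchanged as a one-row alignment.
    """
    if scheme is None:
        scheme = default_scheme()
    if not seqs:
        raise ValueError("no sequences to align")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 1:
        return MultipleAlignment([(seqs[0].id, seqs[0].residues)])

    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], scheme)
            ident = aln.n_identity / min(len(seqs[i]), len(seqs[j]))
            D[i, j] = D[j, i] = 1.0 - ident
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(D, checks=False), method="average")
    clusters: dict[int, List[Tuple[str, str]]] = {
        i: [(seqs[i].id, seqs[i].residues)] for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        clusters[n + k] = _merge(clusters.pop(int(a)), clusters.pop(int(b)), scheme)
    (rows,) = clusters.values()
    order = {sid: i for i, sid in enumerate(ids)}
    rows.sort(key=lambda r: order[r[0]])
    return MultipleAlignment(rows)


def from_pairwise(aln: PairwiseAlignment) -> MultipleAlignment:
    return MultipleAlignment(
        [(aln.seq_a.id, aln.row_a), (aln.seq_b.id, aln.row_b)]
    )


def read_alignment(path: str | os.PathLike, format: str = "fasta") -> MultipleAlignment:
    """Read an external alignment (aligned-FASTA or Clustal) via Bio.AlignIO.

    Clustal conservation lines are ignored; rows are reassembled across
    blocks.  Ragged rows raise :class:`AlignmentFormatError`.
    """
    from Bio import AlignIO

    fmt = {"fasta": "fasta", "aligned-fasta": "fasta", "clustal": "clustal"}.get(
        format.lower()
    )
    if fmt is None:
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentFormatError(str(exc)) from exc
    rows = [(rec.id, str(rec.seq).upper()) for rec in msa]
    return MultipleAlignment(rows, source=f"external:{fmt}")


def write_alignment(
    msa: MultipleAlignment, path: str | os.PathLike, format: str = "fasta"
) -> None:
    fmt = format.lower()
    if fmt in ("fasta", "aligned-fasta"):
        with open(path, "w") as fh:
            for sid, row in msa.rows:
                fh.write(f">{sid}\n{row}\n")
    elif fmt == "clustal":
        with open(path, "w") as fh:
            fh.write("CLUSTAL W formatted alignment\n\n")
            width = 60
            name_w = max(len(sid) for sid, _ in msa.rows) + 3
            for off in range(0, msa.n_columns, width):
                for sid, row in msa.rows:
                    fh.write(f"{sid:<{name_w}}{row[off:off + width]}\n")
                fh.write("\n")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


def column_profile(msa: MultipleAlignment, pseudocount: float = 0.01) -> ColumnProfile:
    """Column frequencies over residues + gap, with a uniform pseudocount."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    symbols = ColumnProfile.SYMBOLS
    idx = {c: i for i, c in enumerate(symbols)}
    F = np.full((msa.n_columns, len(symbols)), pseudocount, dtype=float)
    for _, row in msa.rows:
        for j, c in enumerate(row):
            F[j, idx[c]] += 1.0
    F /= F.sum(axis=1, keepdims=True)
    return ColumnProfile(F, msa.n_rows, pseudocount)


def consensus_sequence(
    profile: ColumnProfile, max_gap_fraction: float = 0.5, seq_id: str = "consensus"
) -> ProteinSequence:
    """Highest-probability residue per retained column.

    Columns whose gap frequency exceeds ``max_gap_fraction`` are dropped;
    ties break alphabetically (the symbol order is alphabetical for the 20
    amino acids).
    """
    symbols = ColumnProfile.SYMBOLS
    gap_col = symbols.index(GAP)
    out = []
    for row in profile.freqs:
        if row[gap_col] > max_gap_fraction:
            continue
        residues = row[:21]
        out.append(symbols[int(np.argmax(residues))])  # argmax -> first max (alphabetical)
    if not out:
        raise EmptyConsensusError("every column is gap-dominated")
    return ProteinSequence(seq_id, "".join(out))


def consensus_of(
    seqs_or_msa, max_gap_fraction: float = 0.5, seq_id: str = "consensus",
    scheme: ScoringScheme | None = None,
) -> ProteinSequence:
    """Convenience: align (if needed), profile, and take the consensus."""
    if isinstance(seqs_or_msa, MultipleAlignment):
        msa = seqs_or_msa
    else:
        msa = progressive_align(seqs_or_msa, scheme)
    return consensus_sequence(column_profile(msa), max_gap_fraction, seq_id)
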