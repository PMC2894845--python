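"""Core protein-sequence types, FASTA I/O and greedy redundancy clustering.

The sequence alphabet is the 20 standard amino acids plus ``X`` for
ambiguous/unknown residues.  All sequences are case-normalized to upper
case on construction; terminal stop characters (``*``) are stripped by
the FASTA reader.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_ALLOWED = frozenset(ALPHABET)


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with a whitespace-free identifier.

    Residues are upper-cased on construction and restricted to the 20
    amino-acid letters plus X.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceCluster:
    """A redundancy cluster: a representative plus every member matching it
    at >= ``cutoff`` fractional identity."""

    representative: ProteinSequence
    members: List[ProteinSequence] = field(default_factory=list)
    cutoff: float = 0.9


def read_fasta(path: str | os.PathLike) -> List[ProteinSequence]:
    """Read a (multi-record) FASTA file.

    Terminal ``*`` stop characters are stripped and residues are upper
    cased.  Malformed headers or illegal residue characters raise
    :class:`FastaParseError` naming the line number.
    """
    records: List[ProteinSequence] = []
    header: str | None = None
    desc = ""
    chunks: List[str] = []
    header_line = 0

    def flush(line_no: int):
        if header is None:
            return
        residues = "".join(chunks).rstrip("*")
        if not residues:
            raise FastaParseError(f"record {header!r} has no residues", header_line)
        try:
            records.append(ProteinSequence(header, residues, desc))
        except ValueError as exc:
            raise FastaParseError(str(exc), line_no) from exc

    with open(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no - 1)
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FastaParseError("empty FASTA header", line_no)
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        "sequence data before the first '>' header", line_no
                    )
                chunk = line.replace(" ", "").upper()
                bad = set(chunk) - _ALLOWED - {"*"}
                if bad:
                    raise FastaParseError(
                        f"illegal residue character(s) {sorted(bad)}", line_no
                    )
                chunks.append(chunk)
        flush(line_no)
    return records


def write_fasta(
    seqs: Iterable[ProteinSequence], path: str | os.PathLike, width: int = 60
) -> None:
    """Write sequences as wrapped FASTA, re-readable by :func:`read_fasta`."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w") as fh:
        for seq in seqs:
            head = f">{seq.id}"
            if seq.description:
                head += f" {seq.description}"
            fh.write(head + "\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def extract_subsequence(seq: ProteinSequence, start: int, end: int) -> ProteinSequence:
    """Extract residues ``start``..``end`` (1-based, inclusive).

    The returned id is suffixed with the coordinate range, e.g.
    ``myseq/3-51``.
    """
    if not (1 <= start <= end <= len(seq)):
        raise IndexError(
            f"coordinates {start}-{end} out of range for {seq.id!r} "
            f"(length {len(seq)})"
        )
    return ProteinSequence(
        f"{seq.id}/{start}-{end}", seq.residues[start - 1 : end], seq.description
    )


def pairwise_identity(a: ProteinSequence, b: ProteinSequence, scheme=None) -> float:
    """Fractional identity from a global alignment, with the CD-HIT
    convention of dividing by the length of the shorter sequence."""
    from . import pairwise

    aln = pairwise.global_align(a, b, scheme)
    return aln.n_identity / min(len(a), len(b))


def greedy_identity_cluster(
    seqs: Sequence[ProteinSequence], cutoff: float, scheme=None
) -> List[SequenceCluster]:
    """Greedy longest-first identity clustering (CD-HIT style, without the
    k-mer prefilter).

    Sequences are visited longest first (ties by id); each joins the first
    cluster whose representative it matches at >= ``cutoff`` identity, else
    founds a new cluster.  The result is a partition of the input;
    representatives are not guaranteed to be globally < cutoff identical to
    each other (greedy order decides).
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    clusters: List[SequenceCluster] = []
    for seq in ordered:
        for cl in clusters:
            if pairwise_identity(seq, cl.representative, scheme) >= cutoff:
                cl.members.append(seq)
                break
        else:
            clusters.append(SequenceCluster(seq, [seq], cutoff))
    return clusters


def write_cluster_tsv(
    clusters: Sequence[SequenceCluster], path: str | os.PathLike, scheme=None
) -> None:
    """Cluster report: representative_id, member_id, identity."""
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\tidentity\n")
        for cl in clusters:
            for member in cl.members:
                ident = (
                    1.0
                    if member.id == cl.representative.id
                    else pairwise_identity(member, cl.representative, scheme)
                )
                fh.write(f"{cl.representative.id}\t{member.id}\t{ident:.4f}\n")
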