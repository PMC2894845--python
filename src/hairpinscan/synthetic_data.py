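"""Synthetic families realizing the hairpin triplication/loss model.

The model: a primordial 2-TMS hairpin underwent intragenic triplication to
produce a 6-TMS carrier (CDF-like); loss of the N-terminal hairpin then
yielded a 4-TMS channel (Orai-like).  The generator builds families under
this scenario and under controls (direct duplication of an independent
hairpin; architecture-matched families with no internal repeats), recording
ground-truth TMS coordinates and the ancestral hairpin unit of every TMS.

Divergence model: each site substitutes with probability ``divergence``,
the replacement drawn among the other 19 residues with probability
proportional to ``exp(BLOSUM62 score)`` -- a simple matrix-consistent
scheme that preserves the hydrophobic character of TMS residues.  Indels
(1-3 residues) occur only inside loops, so TMS architecture is conserved.
The three hairpin copies diverge from the primordial unit by half the
nominal divergence each *before* the family radiates, so paralogous
hairpins within one protein differ by about the nominal divergence --
without this, freshly triplicated hairpins would be indistinguishable and
unit ancestry untestable.

Everything is deterministic given ``FamilySpec.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pairwise import default_scheme
from .sequences import AMINO_ACIDS, ProteinSequence
from .topology import TmsAnnotation, write_annotations

# Residue compositions (weights renormalized).  TMS blocks are strongly
# hydrophobic (mean Kyte-Doolittle ~3.8, like real TM helices); loops mix
# charged residues with small/polar ones (mean ~ -1.9) so that a 19-residue
# window still resolves a 21-residue helix flanked by loops -- uniformly
# charged loops would erode the windowed peak below detection length.
TMS_COMPOSITION: Dict[str, float] = {
    "I": 0.22, "L": 0.22, "V": 0.18, "F": 0.12, "A": 0.09, "M": 0.06,
    "C": 0.03, "G": 0.03, "S": 0.03, "T": 0.02,
}
LOOP_COMPOSITION: Dict[str, float] = {
    "S": 0.16, "T": 0.14, "G": 0.13, "P": 0.09, "N": 0.08, "Q": 0.08,
    "D": 0.06, "E": 0.06, "K": 0.05, "A": 0.04, "R": 0.03, "H": 0.03,
    "Y": 0.03,
}

SCENARIOS = ("triplication", "hairpin_loss", "direct_duplication", "null")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family.

    ``divergence`` is the expected per-site substitution fraction of each
    member relative to the family ancestor; ``paralog_divergence`` (default:
    same value) is the expected divergence *between* hairpin copies within
    the ancestor.  ``indel_rate`` is the per-loop-site indel probability.
    """

    n_members: int = 4
    tms_len: int = 21
    loop_len_range: Tuple[int, int] = (10, 20)
    divergence: float = 0.3
    indel_rate: float = 0.02
    scenario: str = "triplication"
    seed: int = 0
    paralog_divergence: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.divergence < 1):
            raise ValueError("divergence must be in [0, 1)")
        if not (0 <= self.indel_rate <= 1):
            raise ValueError("indel_rate must be in [0, 1]")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def effective_paralog_divergence(self) -> float:
        return (
            self.divergence
            if self.paralog_divergence is None
            else self.paralog_divergence
        )


# A segment is (kind, text, unit): kind "loop" or "tms"; unit tags the
# ancestral hairpin copy a TMS descends from (None for loops).
Segment = Tuple[str, str, Optional[int]]


@dataclass
class SyntheticFamily:
    """Generated members plus full ground truth."""

    members: List[ProteinSequence]
    truth: Dict[str, TmsAnnotation]
    ancestry: Dict[str, Dict[int, int]]  # member id -> {tms index -> unit}
    scenario: str
    ancestor: ProteinSequence
    spec: FamilySpec
    member_segments: List[List[Segment]] = field(default_factory=list, repr=False)
    ancestor_segments: List[Segment] = field(default_factory=list, repr=False)


def _draw(rng: np.random.Generator, composition: Dict[str, float], n: int) -> str:
    letters = list(composition)
    w = np.array([composition[c] for c in letters], dtype=float)
    w /= w.sum()
    return "".join(rng.choice(letters, size=n, p=w))


_SUB_TABLE: Optional[np.ndarray] = None


def _substitution_table() -> np.ndarray:
    """P[a, x] proportional to exp(BLOSUM62[a, x]), x != a, over the 20 AAs."""
    global _SUB_TABLE
    if _SUB_TABLE is None:
        S = default_scheme().matrix[:20, :20]
        P = np.exp(S)
        np.fill_diagonal(P, 0.0)
        _SUB_TABLE = P / P.sum(axis=1, keepdims=True)
    return _SUB_TABLE


_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}


def _substitute(text: str, rng: np.random.Generator, fraction: float) -> str:
    if fraction <= 0:
        return text
    table = _substitution_table()
    chars = list(text)
    hits = np.nonzero(rng.random(len(chars)) < fraction)[0]
    for i in hits:
        row = table[_AA_INDEX[chars[i]]]
        chars[i] = AMINO_ACIDS[rng.choice(20, p=row)]
    return "".join(chars)


def _indel(text: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return text
    out: List[str] = []
    i = 0
    while i < len(text):
        if rng.random() < rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                out.append(text[i])
                out.append(_draw(rng, LOOP_COMPOSITION, size))
                i += 1
            else:
                i += size  # deletion
        else:
            out.append(text[i])
            i += 1
    s = "".join(out)
    return s if s else text[:1]  # loops never vanish entirely


def _mutate_segments(
    segments: Sequence[Segment],
    rng: np.random.Generator,
    sub_fraction: float,
    indel_rate: float = 0.0,
) -> List[Segment]:
    out: List[Segment] = []
    for kind, text, unit in segments:
        text = _substitute(text, rng, sub_fraction)
        if kind == "loop":
            text = _indel(text, rng, indel_rate)
        out.append((kind, text, unit))
    return out


def _segments_to_protein(
    segments: Sequence[Segment], seq_id: str
) -> Tuple[ProteinSequence, TmsAnnotation, Dict[int, int]]:
    parts: List[str] = []
    coords: List[Tuple[int, int]] = []
    ancestry: Dict[int, int] = {}
    pos = 0
    tms_index = 0
    for kind, text, unit in segments:
        if kind == "tms":
            tms_index += 1
            coords.append((pos + 1, pos + len(text)))
            if unit is not None:
                ancestry[tms_index] = unit
        parts.append(text)
        pos += len(text)
    seq = ProteinSequence(seq_id, "".join(parts))
    return seq, TmsAnnotation(seq_id, coords), ancestry


def sample_hairpin(
    rng: np.random.Generator,
    tms_len: int = 21,
    loop_len_range: Tuple[int, int] = (10, 16),
) -> Tuple[str, List[Tuple[int, int]]]:
    """One 2-TMS hairpin fragment: short terminal loops, two hydrophobic
    blocks, one polar connecting loop.  Returns (fragment, TMS coords)."""
    segs = _hairpin_segments(rng, tms_len, loop_len_range)
    seq, ann, _ = _segments_to_protein(segs, "hairpin")
    return seq.residues, ann.segments


def _hairpin_segments(
    rng: np.random.Generator, tms_len: int, loop_len_range: Tuple[int, int]
) -> List[Segment]:
    lo, hi = loop_len_range
    if tms_len < 1 or lo < 1 or hi < lo:
        raise ValueError("invalid hairpin dimensions")
    term = max(3, lo // 2)
    return [
        ("loop", _draw(rng, LOOP_COMPOSITION, int(rng.integers(term, term + 4))), None),
        ("tms", _draw(rng, TMS_COMPOSITION, tms_len), None),
        ("loop", _draw(rng, LOOP_COMPOSITION, int(rng.integers(lo, hi + 1))), None),
        ("tms", _draw(rng, TMS_COMPOSITION, tms_len), None),
        ("loop", _draw(rng, LOOP_COMPOSITION, int(rng.integers(term, term + 4))), None),
    ]


def _tag_unit(segments: Sequence[Segment], unit: int) -> List[Segment]:
    return [
        (kind, text, unit if kind == "tms" else None) for kind, text, _ in segments
    ]


def _radiate(
    ancestor: List[Segment], spec: FamilySpec, rng: np.random.Generator, prefix: str
) -> SyntheticFamily:
    anc_seq, _, _ = _segments_to_protein(ancestor, f"{prefix}_ancestor")
    members, truth, ancestry, all_segs = [], {}, {}, []
    for i in range(spec.n_members):
        segs = _mutate_segments(ancestor, rng, spec.divergence, spec.indel_rate)
        seq, ann, anc = _segments_to_protein(segs, f"{prefix}{i + 1}")
        members.append(seq)
        truth[seq.id] = ann
        ancestry[seq.id] = anc
        all_segs.append(segs)
    return SyntheticFamily(
        members=members,
        truth=truth,
        ancestry=ancestry,
        scenario=spec.scenario,
        ancestor=anc_seq,
        spec=spec,
        member_segments=all_segs,
        ancestor_segments=list(ancestor),
    )


def build_cdf_like(spec: FamilySpec) -> SyntheticFamily:
    """Triplicated 6-TMS family: primordial hairpin -> three diverged tandem
    copies (units 1-3) -> independently diverged members."""
    if spec.scenario != "triplication":
        raise ValueError("build_cdf_like requires scenario 'triplication'")
    rng = np.random.default_rng(spec.seed)
    template = _hairpin_segments(rng, spec.tms_len, spec.loop_len_range)
    half = spec.effective_paralog_divergence / 2.0
    ancestor: List[Segment] = []
    for unit in (1, 2, 3):
        copy = _mutate_segments(template, rng, half)
        ancestor.extend(_tag_unit(copy, unit))
    return _radiate(ancestor, spec, rng, "cdf")


def _drop_first_hairpin(segments: Sequence[Segment]) -> List[Segment]:
    """Remove TMSs 1-2 and intervening loops, keeping the N-terminal loop."""
    tms_seen = 0
    out: List[Segment] = [segments[0]]  # N-terminal loop
    for seg in segments[1:]:
        if seg[0] == "tms":
            tms_seen += 1
        if tms_seen >= 3:
            out.append(seg)
    return out


def build_orai_like(cdf_family: SyntheticFamily, spec: FamilySpec) -> SyntheticFamily:
    """Hairpin-loss family: every 6-TMS member loses TMSs 1-2 (plus the
    intervening loops) and accumulates further divergence.  The new TMSs
    1-2 descend from ancestral unit 2, TMSs 3-4 from unit 3."""
    if cdf_family.scenario != "triplication":
        raise ValueError("build_orai_like requires a triplicated input family")
    if any(ann.n_tms != 6 for ann in cdf_family.truth.values()):
        raise ValueError("input family members must have 6 TMSs")
    rng = np.random.default_rng(spec.seed)
    anc_lost = _drop_first_hairpin(cdf_family.ancestor_segments)
    anc_seq, _, _ = _segments_to_protein(anc_lost, "orai_ancestor")

    members, truth, ancestry, all_segs = [], {}, {}, []
    n = min(spec.n_members, len(cdf_family.member_segments))
    for i in range(n):
        segs = _drop_first_hairpin(cdf_family.member_segments[i])
        segs = _mutate_segments(segs, rng, spec.divergence, spec.indel_rate)
        seq, ann, anc = _segments_to_protein(segs, f"orai{i + 1}")
        members.append(seq)
        truth[seq.id] = ann
        ancestry[seq.id] = anc
        all_segs.append(segs)
    return SyntheticFamily(
        members=members,
        truth=truth,
        ancestry=ancestry,
        scenario="hairpin_loss",
        ancestor=anc_seq,
        spec=spec,
        member_segments=all_segs,
        ancestor_segments=anc_lost,
    )


def build_direct_duplication(spec: FamilySpec) -> SyntheticFamily:
    """Alternative-scenario control: an independent hairpin duplicated once
    (4 TMSs), sharing no ancestry with any triplicated family."""
    if spec.scenario != "direct_duplication":
        raise ValueError("build_direct_duplication requires scenario 'direct_duplication'")
    rng = np.random.default_rng(spec.seed)
    template = _hairpin_segments(rng, spec.tms_len, spec.loop_len_range)
    half = spec.effective_paralog_divergence / 2.0
    ancestor: List[Segment] = []
    for unit in (1, 2):
        copy = _mutate_segments(template, rng, half)
        ancestor.extend(_tag_unit(copy, unit))
    return _radiate(ancestor, spec, rng, "dup")


def build_null_family(spec: FamilySpec, n_tms: int = 6) -> SyntheticFamily:
    """Architecture-matched negative control: every TMS block and loop is
    sampled independently, so there are no internal repeats."""
    if spec.scenario != "null":
        raise ValueError("build_null_family requires scenario 'null'")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.loop_len_range
    term = max(3, lo // 2)
    ancestor: List[Segment] = [
        ("loop", _draw(rng, LOOP_COMPOSITION, int(rng.integers(term, term + 4))), None)
    ]
    for unit in range(1, n_tms + 1):
        ancestor.append(("tms", _draw(rng, TMS_COMPOSITION, spec.tms_len), unit))
        ancestor.append(
            ("loop", _draw(rng, LOOP_COMPOSITION, int(rng.integers(lo, hi + 1))), None)
        )
    return _radiate(ancestor, spec, rng, "null")


def family_composition(seqs: Sequence[ProteinSequence]) -> Dict[str, float]:
    """Average residue composition of a set of sequences."""
    counts: Dict[str, int] = {}
    total = 0
    for seq in seqs:
        for c in seq.residues:
            counts[c] = counts.get(c, 0) + 1
            total += 1
    return {c: n / total for c, n in sorted(counts.items())}


def sample_null_protein(
    rng: np.random.Generator,
    length: int,
    composition: Optional[Dict[str, float]] = None,
) -> ProteinSequence:
    """I.i.d. random sequence, by default uniform over the 20 amino acids;
    pass :func:`family_composition` output for composition-matched nulls."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if composition is None:
        composition = {c: 1.0 for c in AMINO_ACIDS}
    return ProteinSequence("null", _draw(rng, composition, length))


def realized_substitution_fraction(family: SyntheticFamily) -> float:
    """Fraction of substituted sites, pooled over all members' TMS blocks
    (TMS blocks are indel-free, so the comparison is positional)."""
    anc_tms = [t for k, t, _ in family.ancestor_segments if k == "tms"]
    diff = total = 0
    for segs in family.member_segments:
        mem_tms = [t for k, t, _ in segs if k == "tms"]
        for a, m in zip(anc_tms, mem_tms):
            total += len(a)
            diff += sum(1 for x, y in zip(a, m) if x != y)
    return diff / total


def write_family(
    family: SyntheticFamily, outdir: str | os.PathLike, prefix: str = "family"
) -> Dict[str, str]:
    """Emit FASTA + truth TSV (TMS coords), ancestry TSV, and the generating
    FamilySpec as a JSON sidecar.  Returns the paths written."""
    from .sequences import write_fasta

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, f"{prefix}.faa"),
        "tms": os.path.join(outdir, f"{prefix}.tms.tsv"),
        "ancestry": os.path.join(outdir, f"{prefix}.ancestry.tsv"),
        "spec": os.path.join(outdir, f"{prefix}.spec.json"),
    }
    write_fasta(family.members + [family.ancestor], paths["fasta"])
    write_annotations([family.truth[m.id] for m in family.members], paths["tms"])
    with open(paths["ancestry"], "w") as fh:
        fh.write("seq_id\ttms_index\tancestral_unit\n")
        for m in family.members:
            for idx, unit in sorted(family.ancestry[m.id].items()):
                fh.write(f"{m.id}\t{idx}\t{unit}\n")
    with open(paths["spec"], "w") as fh:
        json.dump(
            {**dataclasses.asdict(family.spec), "scenario": family.scenario},
            fh,
            indent=2,
        )
        fh.write("\n")
    return paths
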