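"""Hairpin repeat scanning, homology graphs, superfamily closure, and the
evolutionary-scenario test.

The core analysis: excised 2-TMS hairpin segments are compared all-vs-all
within a family (internal repeats) and across two families, each comparison
scored by the Monte-Carlo shuffle statistic.  Per hairpin-class pair the
single best cross-protein comparison is tabulated -- published repeat
tables report best cross-species pairs, not family averages.  Passing
comparisons become edges of a homology graph whose connected components
are superfamilies: if A is homologous to B and B to C, A and C share
ancestry even when their direct comparison falls short (the transitivity,
or superfamily, principle).

The scenario test asks which mapping of hairpin classes explains a
6-TMS-carrier / 4-TMS-channel cross table: the offset mapping
{carrier 3-4 -> channel 1-2, carrier 5-6 -> channel 3-4} implied by loss of
the carrier's first hairpin, or the identity mapping implied by an
independent origin of the channel from a direct hairpin duplication.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .pairwise import ScoringScheme, alignment_stats, default_scheme, global_align
from .sequences import ProteinSequence
from .significance import ComparisonScore, call_homology, comparison_z, pair_seed
from .topology import HairpinSegment, TmsAnnotation, excise_hairpin

#: hairpin classes of a 6-TMS triplicated carrier and a 4-TMS channel
CDF_CLASSES = ((1, 2), (3, 4), (5, 6))
ORAI_CLASSES = ((1, 2), (3, 4))
#: class mapping implied by loss of the carrier's first hairpin
OFFSET_MAPPING = (("3-4", "1-2"), ("5-6", "3-4"))
#: class mapping implied by an independent direct duplication
IDENTITY_MAPPING = (("1-2", "1-2"), ("3-4", "3-4"))


def class_label(pair: Tuple[int, int]) -> str:
    return f"{pair[0]}-{pair[1]}"


@dataclass
class RepeatComparisonRow:
    """One Table-1-style row: the best comparison for a hairpin class pair."""

    class_a: str
    class_b: str
    segment_a: str  # segment label ("seqid:tms1-2")
    segment_b: str
    n_residues_compared: int
    sd_units: float
    pct_identity: float
    pct_similarity: float
    n_gap_openings: int


@dataclass
class RepeatComparisonTable:
    rows: List[RepeatComparisonRow] = field(default_factory=list)

    def sorted_by_sd(self) -> "RepeatComparisonTable":
        return RepeatComparisonTable(
            sorted(self.rows, key=lambda r: -r.sd_units)
        )

    def row(self, class_a: str, class_b: str) -> RepeatComparisonRow:
        for r in self.rows:
            if (r.class_a, r.class_b) == (class_a, class_b):
                return r
        raise KeyError((class_a, class_b))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rows])

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(
                "class_a\tclass_b\tsegment_a\tsegment_b\tn_residues_compared\t"
                "comparison_score_sd\tpct_identity\tpct_similarity\tn_gaps\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.class_a}\t{r.class_b}\t{r.segment_a}\t{r.segment_b}\t"
                    f"{r.n_residues_compared}\t{r.sd_units:.1f}\t"
                    f"{r.pct_identity:.1f}\t{r.pct_similarity:.1f}\t"
                    f"{r.n_gap_openings}\n"
                )


def excise_family(
    family: Sequence[ProteinSequence],
    annotations: Dict[str, TmsAnnotation],
    hairpin_pairs: Iterable[Tuple[int, int]] = CDF_CLASSES,
    flank: int = 5,
) -> Dict[str, List[HairpinSegment]]:
    """Hairpin segments per class label; members lacking a TMS pair are
    skipped for that class."""
    out: Dict[str, List[HairpinSegment]] = {}
    for pair in hairpin_pairs:
        label = class_label(pair)
        segs: List[HairpinSegment] = []
        for seq in family:
            ann = annotations.get(seq.id)
            if ann is None or ann.n_tms < pair[1]:
                continue
            segs.append(excise_hairpin(seq, ann, pair[0], flank))
        if segs:
            out[label] = segs
    return out


def _best_pair_row(
    class_a: str,
    class_b: str,
    segs_a: Sequence[HairpinSegment],
    segs_b: Sequence[HairpinSegment],
    scheme: ScoringScheme,
    n_shuffles: int,
    n_runs: int,
    seed: int,
    cross_protein_only: bool,
) -> RepeatComparisonRow:
    best: Optional[Tuple[ComparisonScore, HairpinSegment, HairpinSegment]] = None
    multi = len({s.seq_id for s in segs_a} | {s.seq_id for s in segs_b}) > 1
    for sa in segs_a:
        for sb in segs_b:
            if cross_protein_only and multi and sa.seq_id == sb.seq_id:
                continue
            # unordered label pair -> the same draws regardless of scan
            # direction, so transposed tables agree up to argument order
            score = comparison_z(
                sa.to_sequence(),
                sb.to_sequence(),
                scheme,
                n_shuffles=n_shuffles,
                n_runs=n_runs,
                seed=pair_seed(seed, "|".join(sorted((sa.label, sb.label)))),
            )
            if best is None or score.sd_units > best[0].sd_units:
                best = (score, sa, sb)
    assert best is not None
    score, sa, sb = best
    aln = global_align(sa.to_sequence(), sb.to_sequence(), scheme)
    pid, psim, ngap, nali = alignment_stats(aln)
    return RepeatComparisonRow(
        class_a=class_a,
        class_b=class_b,
        segment_a=sa.label,
        segment_b=sb.label,
        n_residues_compared=nali,
        sd_units=score.sd_units,
        pct_identity=pid,
        pct_similarity=psim,
        n_gap_openings=ngap,
    )


def repeat_scan(
    family: Sequence[ProteinSequence],
    annotations: Dict[str, TmsAnnotation],
    hairpin_pairs: Iterable[Tuple[int, int]] = CDF_CLASSES,
    scheme: ScoringScheme | None = None,
    n_shuffles: int = 500,
    n_runs: int = 1,
    seed: int = 0,
    flank: int = 5,
) -> RepeatComparisonTable:
    """Internal-repeat scan: best cross-protein comparison per unordered
    hairpin class pair (e.g. 1-2 vs 3-4, 3-4 vs 5-6, 1-2 vs 5-6)."""
    if not family:
        raise ValueError("empty family")
    if scheme is None:
        scheme = default_scheme()
    segments = excise_family(family, annotations, hairpin_pairs, flank)
    labels = [class_label(p) for p in hairpin_pairs if class_label(p) in segments]
    missing = [class_label(p) for p in hairpin_pairs if class_label(p) not in segments]
    if missing:
        raise ValueError(f"no member provides hairpin class(es) {missing}")
    table = RepeatComparisonTable()
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            table.rows.append(
                _best_pair_row(
                    la, lb, segments[la], segments[lb],
                    scheme, n_shuffles, n_runs, seed, cross_protein_only=True,
                )
            )
    return table


def cross_family_scan(
    segments_a: Dict[str, List[HairpinSegment]],
    segments_b: Dict[str, List[HairpinSegment]],
    scheme: ScoringScheme | None = None,
    n_shuffles: int = 500,
    n_runs: int = 1,
    seed: int = 0,
) -> RepeatComparisonTable:
    """Full cross table of hairpin classes between two families (for a
    6-TMS vs 4-TMS comparison: 3 x 2 = 6 rows), sorted by sd_units
    descending."""
    if not segments_a or not segments_b:
        raise ValueError("both segment sets must be non-empty")
    if scheme is None:
        scheme = default_scheme()
    table = RepeatComparisonTable()
    for la in sorted(segments_a):
        for lb in sorted(segments_b):
            table.rows.append(
                _best_pair_row(
                    la, lb, segments_a[la], segments_b[lb],
                    scheme, n_shuffles, n_runs, seed, cross_protein_only=False,
                )
            )
    return table.sorted_by_sd()


@dataclass
class HomologyGraph:
    """Segments/classes as nodes; comparisons as edges with homology calls."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_table(
        cls,
        table: RepeatComparisonTable,
        threshold: float = 9.0,
        min_length: int = 60,
        prefix_a: str = "",
        prefix_b: str = "",
    ) -> "HomologyGraph":
        g = nx.Graph()
        for r in table.rows:
            a = prefix_a + r.class_a
            b = prefix_b + r.class_b
            call = call_homology(
                _as_score(r.sd_units), r.n_residues_compared, threshold, min_length
            )
            g.add_edge(
                a, b,
                sd_units=r.sd_units,
                n_aligned=r.n_residues_compared,
                is_homologous=call.is_homologous,
                status=call.status,
            )
        return cls(g)

    def add_edge(self, a: str, b: str, sd_units: float, n_aligned: int,
                 threshold: float = 9.0, min_length: int = 60) -> None:
        call = call_homology(_as_score(sd_units), n_aligned, threshold, min_length)
        self.graph.add_edge(
            a, b, sd_units=sd_units, n_aligned=n_aligned,
            is_homologous=call.is_homologous, status=call.status,
        )

    def to_edge_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tsd_units\tn_aligned\tis_homologous\tstatus\n")
            for a, b, d in self.graph.edges(data=True):
                fh.write(
                    f"{a}\t{b}\t{d['sd_units']:.1f}\t{d['n_aligned']}\t"
                    f"{int(d['is_homologous'])}\t{d['status']}\n"
                )


def _as_score(sd_units: float) -> ComparisonScore:
    # wrap a bare sd value for the decision rule
    return ComparisonScore(
        quality=0.0, average_quality=0.0, std_quality=1.0,
        sd_units=sd_units, n_shuffles=2, n_runs=1, seed=0,
    )


@dataclass
class SuperfamilyComponents:
    """Connected components over passing edges, with transitivity witnesses."""

    components: List[List[str]]
    witness: Dict[Tuple[str, str], List[str]]  # node pair -> path of nodes


def superfamily_closure(graph: HomologyGraph) -> SuperfamilyComponents:
    """Transitive closure of homology: components over passing edges.

    Every within-component pair is homologous-by-transitivity; the witness
    is a shortest path of passing comparisons connecting the pair (the
    chain "A~B, B~C, therefore A~C").
    """
    passing = nx.Graph()
    passing.add_nodes_from(graph.graph.nodes)
    for a, b, d in graph.graph.edges(data=True):
        if d.get("is_homologous"):
            passing.add_edge(a, b)
    components = [sorted(c) for c in nx.connected_components(passing)]
    components.sort(key=lambda c: (-len(c), c))
    witness: Dict[Tuple[str, str], List[str]] = {}
    for comp in components:
        for i, a in enumerate(comp):
            for b in comp[i + 1 :]:
                witness[(a, b)] = nx.shortest_path(passing, a, b)
    return SuperfamilyComponents(components, witness)


@dataclass
class ScenarioVerdict:
    """Outcome of the hairpin-loss vs direct-duplication comparison."""

    verdict: str  # "hairpin-loss" | "direct-duplication"
    margin: float  # offset_sum - identity_sum
    offset_sum: float
    identity_sum: float
    best_offset_sd: float
    threshold: float
    offset_rows: List[RepeatComparisonRow]
    identity_rows: List[RepeatComparisonRow]

    def to_json(self) -> str:
        return json.dumps(
            {
                "verdict": self.verdict,
                "margin": round(self.margin, 3),
                "offset_sum": round(self.offset_sum, 3),
                "identity_sum": round(self.identity_sum, 3),
                "best_offset_sd": round(self.best_offset_sd, 3),
                "threshold": self.threshold,
                "offset_rows": [
                    (r.class_a, r.class_b, round(r.sd_units, 2))
                    for r in self.offset_rows
                ],
                "identity_rows": [
                    (r.class_a, r.class_b, round(r.sd_units, 2))
                    for r in self.identity_rows
                ],
            }
        )


def scenario_test(
    table: RepeatComparisonTable, threshold: float = 9.0
) -> ScenarioVerdict:
    """Decide between hairpin loss and direct duplication from the 6-row
    carrier-vs-channel cross table.

    The verdict is "hairpin-loss" when the offset mapping outscores the
    identity mapping by summed sd_units *and* its best row passes the
    significance threshold; otherwise "direct-duplication".  The
    significance gate matters: for two unrelated families both mapping sums
    are noise and the sign of their difference alone would be a coin flip.
    """
    try:
        offset_rows = [table.row(a, b) for a, b in OFFSET_MAPPING]
        identity_rows = [table.row(a, b) for a, b in IDENTITY_MAPPING]
    except KeyError as exc:
        raise ValueError(f"cross table is missing class pair {exc.args[0]}") from exc
    offset_sum = sum(r.sd_units for r in offset_rows)
    identity_sum = sum(r.sd_units for r in identity_rows)
    best_offset = max(r.sd_units for r in offset_rows)
    verdict = (
        "hairpin-loss"
        if offset_sum > identity_sum and best_offset >= threshold
        else "direct-duplication"
    )
    return ScenarioVerdict(
        verdict=verdict,
        margin=offset_sum - identity_sum,
        offset_sum=offset_sum,
        identity_sum=identity_sum,
        best_offset_sd=best_offset,
        threshold=threshold,
        offset_rows=offset_rows,
        identity_rows=identity_rows,
    )
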