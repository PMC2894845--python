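"""Hydropathy and amphipathicity profiles, TMS calling and hairpin excision.

Transmembrane segments (TMSs) are called from Kyte-Doolittle hydropathy
averaged over a sliding window (default 19 residues, threshold 1.6), the
standard sliding-window settings for alpha-helical membrane proteins.
User-supplied annotations always take precedence over the caller.  A
*hairpin* is a pair of adjacent TMSs plus the connecting loop; hairpin
excision cuts that span plus a small flank for use in repeat scans.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .pairwise import GAP, ScoringScheme, default_scheme
from .sequences import ProteinSequence, extract_subsequence

#: Kyte-Doolittle hydropathy index; X is treated as neutral.
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass
class TmsAnnotation:
    """Ordered, non-overlapping TMS coordinates (1-based inclusive)."""

    seq_id: str
    segments: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        prev_end = 0
        for s, e in self.segments:
            if s <= prev_end or e < s:
                raise ValueError(
                    f"{self.seq_id}: TMS segments must be sorted and non-overlapping"
                )
            prev_end = e

    @property
    def n_tms(self) -> int:
        return len(self.segments)


@dataclass
class HairpinSegment:
    """An excised 2-TMS hairpin: TMS pair plus loop and flanks."""

    seq_id: str
    tms_pair: Tuple[int, int]  # 1-based TMS indices (i, i+1)
    start: int
    end: int
    residues: str

    @property
    def label(self) -> str:
        return f"{self.seq_id}:tms{self.tms_pair[0]}-{self.tms_pair[1]}"

    def to_sequence(self) -> ProteinSequence:
        return ProteinSequence(
            f"{self.seq_id}/{self.start}-{self.end}", self.residues
        )


@dataclass
class AlignmentProfilePlot:
    """Per-alignment-column averaged tracks (AveHAS-style)."""

    positions: np.ndarray
    avg_hydropathy: np.ndarray
    avg_amphipathicity: np.ndarray
    avg_similarity: np.ndarray
    occupancy: np.ndarray


def _check_window(window: int, length: int):
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > length:
        raise ValueError("window exceeds sequence length")


def hydropathy_profile(seq: ProteinSequence | str, window: int = 19) -> np.ndarray:
    """Mean Kyte-Doolittle index over a centered window; edge positions use
    truncated windows."""
    residues = seq if isinstance(seq, str) else seq.residues
    _check_window(window, len(residues))
    vals = np.array([KYTE_DOOLITTLE[c] for c in residues])
    return _smooth(vals, window)


def _smooth(vals: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated edge windows (NaN-aware)."""
    half = window // 2
    n = len(vals)
    finite = np.isfinite(vals)
    v = np.where(finite, vals, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(v)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(int))))
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        cnt = ccnt[hi] - ccnt[lo]
        out[i] = (csum[hi] - csum[lo]) / cnt if cnt else np.nan
    return out


def amphipathicity_profile(
    seq: ProteinSequence | str, window: int = 19, angle: float = 100.0
) -> np.ndarray:
    """Normalized hydrophobic moment at the alpha-helical angle (100 deg).

    Value at position i is |sum_k h_k * exp(i*theta*k)| / n over the
    centered window; a window of 1 degenerates to |h_i|.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    _check_window(window, len(residues))
    vals = np.array([KYTE_DOOLITTLE[c] for c in residues])
    theta = math.radians(angle)
    phases = np.exp(1j * theta * np.arange(len(vals)))
    terms = vals * phases
    half = window // 2
    n = len(vals)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = abs(terms[lo:hi].sum()) / (hi - lo)
    return out


def _step_fit_edge(p_fine: np.ndarray, lo: int, hi: int, left: bool) -> int | None:
    """Change-point fit of one helix edge on the fine-window profile.

    Around a block/loop boundary the fine profile is plateau / short ramp /
    plateau; the least-squares two-level change point lands at the ramp
    midpoint, i.e. the underlying helix edge, and averages out noise.
    Levels are self-calibrated from the window's own ends.
    """
    seg = p_fine[lo : hi + 1]
    if len(seg) < 6:
        return None
    low = float(seg[:4].mean()) if left else float(seg[-4:].mean())
    high = float(seg[-4:].mean()) if left else float(seg[:4].mean())
    best_b, best_cost = 0, None
    for b in range(len(seg) + 1):
        if left:
            cost = float(np.sum((seg[:b] - low) ** 2) + np.sum((seg[b:] - high) ** 2))
        else:
            cost = float(np.sum((seg[:b] - high) ** 2) + np.sum((seg[b:] - low) ** 2))
        if best_cost is None or cost < best_cost:
            best_cost, best_b = cost, b
    return lo + best_b if left else lo + best_b - 1


#: fine window used to refine run edges (the detection window is too wide
#: to localize boundaries: its threshold crossings sit several residues
#: inside the helix and jitter with composition noise)
EDGE_WINDOW = 7
#: runs are merged when the profile between them never drops below this
#: fraction of the threshold (a genuine loop dips far below threshold;
#: a noise dip inside a helix hovers just beneath it)
HEAL_FRACTION = 0.75


def call_tms(
    seq: ProteinSequence,
    window: int = 19,
    threshold: float = 1.6,
    min_tms_len: int = 15,
    max_tms_len: int = 30,
    min_loop: int = 3,
) -> TmsAnnotation:
    """Call TMSs from maximal runs of windowed hydropathy >= ``threshold``.

    Candidate runs come from the wide detection window.  Because window
    averaging erodes a helix's above-threshold run to roughly
    ``L - 2*(k - w/2)`` positions (k grows with loop polarity), each run
    edge is then refined by a change-point fit on a fine-window profile
    (:data:`EDGE_WINDOW`), which recovers the underlying helix boundary;
    refinement only ever extends a run.  Runs separated by fewer than
    ``min_loop`` positions, or by a dip that never leaves the threshold's
    neighbourhood (:data:`HEAL_FRACTION`), are merged first.  Refined
    segments shorter than ``min_tms_len`` are dropped; segments longer than
    ``max_tms_len`` are split recursively at their internal hydropathy
    minimum (a merged hairpin splits back into its two helices).
    """
    profile = hydropathy_profile(seq, window)
    p_fine = hydropathy_profile(seq, min(EDGE_WINDOW, window))
    above = profile >= threshold
    runs: List[Tuple[int, int]] = []  # 0-based inclusive
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))

    merged: List[Tuple[int, int]] = []
    for run in runs:
        if merged:
            gap = profile[merged[-1][1] + 1 : run[0]]
            if run[0] - merged[-1][1] - 1 < min_loop or (
                len(gap) and gap.min() >= HEAL_FRACTION * threshold
            ):
                merged[-1] = (merged[-1][0], run[1])
                continue
        merged.append(run)

    corrected: List[Tuple[int, int]] = []
    for idx, (s, e) in enumerate(merged):
        lo_lim = merged[idx - 1][1] + 1 if idx > 0 else 0
        hi_lim = merged[idx + 1][0] - 1 if idx + 1 < len(merged) else len(profile) - 1
        new_s = _step_fit_edge(p_fine, max(lo_lim, s - 14), min(e, s + 7), left=True)
        new_e = _step_fit_edge(p_fine, max(s, e - 7), min(hi_lim, e + 14), left=False)
        # the raw run is certainly helix: refinement may only extend it
        new_s = s if new_s is None else min(s, new_s)
        new_e = e if new_e is None else max(e, new_e)
        if corrected and new_s <= corrected[-1][1]:
            new_s = corrected[-1][1] + 1
        corrected.append((new_s, new_e))
    merged = corrected

    kept = [r for r in merged if r[1] - r[0] + 1 >= min_tms_len]

    def split(run: Tuple[int, int]) -> List[Tuple[int, int]]:
        s, e = run
        if e - s + 1 <= max_tms_len:
            return [run]
        interior = profile[s + 1 : e]
        cut = s + 1 + int(np.argmin(interior))
        left, right = (s, cut - 1), (cut + 1, e)
        out = []
        for part in (left, right):
            if part[1] - part[0] + 1 >= min_tms_len:
                out.extend(split(part))
        return out

    final: List[Tuple[int, int]] = []
    for run in kept:
        final.extend(split(run))
    return TmsAnnotation(seq.id, [(s + 1, e + 1) for s, e in sorted(final)])


def excise_hairpin(
    seq: ProteinSequence,
    annotation: TmsAnnotation,
    pair_index: int,
    flank: int = 5,
) -> HairpinSegment:
    """Excise TMS ``pair_index`` and ``pair_index + 1`` (1-based) plus the
    connecting loop and ``flank`` residues on each side, clipped to the
    sequence bounds."""
    if not (1 <= pair_index < annotation.n_tms + 1) or pair_index + 1 > annotation.n_tms:
        raise ValueError(
            f"{seq.id}: TMS pair ({pair_index}, {pair_index + 1}) not present "
            f"in an annotation with {annotation.n_tms} TMSs"
        )
    first = annotation.segments[pair_index - 1]
    second = annotation.segments[pair_index]
    start = max(1, first[0] - flank)
    end = min(len(seq), second[1] + flank)
    sub = extract_subsequence(seq, start, end)
    return HairpinSegment(
        seq_id=seq.id,
        tms_pair=(pair_index, pair_index + 1),
        start=start,
        end=end,
        residues=sub.residues,
    )


def average_profiles(
    rows: Sequence[Tuple[str, str]],
    window: int = 19,
    min_occupancy: float = 0.5,
    scheme: ScoringScheme | None = None,
) -> AlignmentProfilePlot:
    """AveHAS-style averaged tracks over a gapped multiple alignment.

    Hydropathy is the per-column mean Kyte-Doolittle value over non-gap
    residues, smoothed along alignment columns; amphipathicity averages the
    per-row moment profiles scattered back to their columns; similarity is
    the mean pairwise substitution score among the column's residues,
    smoothed.  Columns with occupancy below ``min_occupancy`` are masked
    (NaN).
    """
    if not rows:
        raise ValueError("empty alignment")
    if scheme is None:
        scheme = default_scheme()
    ncol = len(rows[0][1])
    if any(len(r) != ncol for _, r in rows):
        raise ValueError("alignment rows differ in length")
    nrow = len(rows)

    occupancy = np.zeros(ncol)
    hyd = np.full(ncol, np.nan)
    sim = np.full(ncol, np.nan)
    amph_sum = np.zeros(ncol)
    amph_cnt = np.zeros(ncol, dtype=int)

    for _, row in rows:
        degapped = row.replace(GAP, "")
        if len(degapped) >= window:
            am = amphipathicity_profile(degapped, window)
            k = 0
            for j, c in enumerate(row):
                if c != GAP:
                    amph_sum[j] += am[k]
                    amph_cnt[j] += 1
                    k += 1

    for j in range(ncol):
        col = [row[j] for _, row in rows if row[j] != GAP]
        occupancy[j] = len(col) / nrow
        if not col:
            continue
        hyd[j] = float(np.mean([KYTE_DOOLITTLE[c] for c in col]))
        if len(col) >= 2:
            scores = [
                scheme.score(col[i], col[k])
                for i in range(len(col))
                for k in range(i + 1, len(col))
            ]
            sim[j] = float(np.mean(scores))

    mask = occupancy < min_occupancy
    hyd[mask] = np.nan
    sim[mask] = np.nan
    amph = np.where(amph_cnt > 0, amph_sum / np.maximum(amph_cnt, 1), np.nan)
    amph[mask] = np.nan
    return AlignmentProfilePlot(
        positions=np.arange(1, ncol + 1),
        avg_hydropathy=_smooth(hyd, window),
        avg_amphipathicity=amph,
        avg_similarity=_smooth(sim, window),
        occupancy=occupancy,
    )


def read_annotations(path: str | os.PathLike) -> Dict[str, TmsAnnotation]:
    """Read TMS annotations from TSV: seq_id, tms_index, start, end."""
    rows: Dict[str, List[Tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("seq_id"):
                continue
            seq_id, idx, start, end = line.split("\t")
            rows.setdefault(seq_id, []).append((int(idx), int(start), int(end)))
    return {
        sid: TmsAnnotation(sid, [(s, e) for _, s, e in sorted(v)])
        for sid, v in rows.items()
    }


def write_annotations(
    annotations: Sequence[TmsAnnotation], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\ttms_index\tstart\tend\n")
        for ann in annotations:
            for i, (s, e) in enumerate(ann.segments, start=1):
                fh.write(f"{ann.seq_id}\t{i}\t{s}\t{e}\n")


def profile_plot_tsv(plot: AlignmentProfilePlot, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("position\tavg_hydropathy\tavg_amphipathicity\tavg_similarity\toccupancy\n")
        for i in range(len(plot.positions)):
            fh.write(
                f"{plot.positions[i]}\t{plot.avg_hydropathy[i]:.4f}\t"
                f"{plot.avg_amphipathicity[i]:.4f}\t{plot.avg_similarity[i]:.4f}\t"
                f"{plot.occupancy[i]:.4f}\n"
            )


def plot_profiles(plot: AlignmentProfilePlot, ax=None):
    """Render the averaged tracks with matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    ax.plot(plot.positions, plot.avg_hydropathy, color="0.1", label="hydropathy")
    ax.plot(plot.positions, plot.avg_similarity, color="0.6", label="similarity")
    ax.plot(
        plot.positions, plot.avg_amphipathicity, color="tab:blue",
        alpha=0.6, label="amphipathicity",
    )
    ax.axhline(0.0, color="0.8", lw=0.5)
    ax.set_xlabel("alignment position")
    ax.legend(loc="upper right", fontsize="small")
    return ax
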