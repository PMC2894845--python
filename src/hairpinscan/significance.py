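"""Monte-Carlo shuffle significance for global alignments.

The homology statistic is the standardized comparison score

    sd_units = (quality - average_quality) / std_quality

where ``average_quality`` and ``std_quality`` summarize the qualities of
alignments between randomly shuffled copies of the two sequences.  Shuffling
preserves composition and length, so the null measures what this pair of
compositions achieves by chance.  Following common practice for repeats of
more than sixty residues, a score of 9-10 S.D. is taken as sufficient to
infer common ancestry; 9 S.D. corresponds to a one-sided Gaussian tail of
order 1e-19 and 10 S.D. to order 1e-24.

The Gaussian-tail conversion is an interpretation aid; it is not a claim
that shuffle nulls are exactly Gaussian.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import norm

from . import _gotoh
from .pairwise import ScoringScheme, default_scheme, encode
from .sequences import ProteinSequence

#: shuffle-test preset matching the GAP program: 100 shuffles, 5 runs averaged
GAP_MODE = {"n_shuffles": 100, "n_runs": 5}
#: preset for internal-segment work: 500 shuffles in a single run
SEGMENT_MODE = {"n_shuffles": 500, "n_runs": 1}


class DegenerateShuffleError(ValueError):
    """Shuffled-quality distribution has zero spread (e.g. homopolymers)."""


@dataclass(frozen=True)
class ComparisonScore:
    """Native quality versus its shuffle null, in S.D. units.

    ``sd_units`` is the mean of the per-run standardized scores;
    ``average_quality``/``std_quality`` are the grand mean and (sample)
    standard deviation over all shuffled qualities.
    """

    quality: float
    average_quality: float
    std_quality: float
    sd_units: float
    n_shuffles: int
    n_runs: int
    seed: int

    def __post_init__(self):
        if self.n_shuffles < 1 or self.n_runs < 1:
            raise ValueError("n_shuffles and n_runs must be >= 1")


@dataclass(frozen=True)
class HomologyCall:
    """Outcome of the 9-10 S.D. decision rule.

    ``status`` is ``"homologous"`` (score and length both sufficient),
    ``"suggestive"`` (score passes on fewer than ``min_length`` residues, so
    common ancestry is not claimed from this comparison alone), or
    ``"not_homologous"``.
    """

    sd_units: float
    n_aligned: int
    is_homologous: bool
    threshold: float
    min_length: int
    status: str


def shuffle_sequence(seq: ProteinSequence, rng: np.random.Generator) -> ProteinSequence:
    """Uniform random permutation of the residues (composition preserved)."""
    if len(seq) == 0:
        raise ValueError("cannot shuffle an empty sequence")
    arr = np.frombuffer(seq.residues.encode(), dtype="S1")
    return ProteinSequence(seq.id, b"".join(rng.permutation(arr)).decode(), seq.description)


def _sd_units(quality: float, average_quality: float, std_quality: float) -> float:
    if std_quality <= 0:
        raise DegenerateShuffleError("shuffled-quality standard deviation is zero")
    return (quality - average_quality) / std_quality


def comparison_z(
    a: ProteinSequence,
    b: ProteinSequence,
    scheme: ScoringScheme | None = None,
    n_shuffles: int = 500,
    n_runs: int = 1,
    seed: int = 0,
    shuffle_both: bool = True,
) -> ComparisonScore:
    """Standardized comparison score for a pair of sequences.

    Per run, both sequences (or only ``b`` when ``shuffle_both`` is false)
    are independently shuffled ``n_shuffles`` times and re-aligned; the
    run's sd_units uses that run's mean and sample standard deviation.  The
    reported ``sd_units`` averages the runs.  Fully reproducible from
    ``seed``.
    """
    if scheme is None:
        scheme = default_scheme()
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compare empty sequences")
    rng = np.random.default_rng(seed)
    ai, bi = encode(a.residues), encode(b.residues)
    S = scheme.matrix
    go, ge = scheme.open_total, scheme.gap_extend
    free = not scheme.penalize_end_gaps

    native = float(_gotoh.gotoh_score(ai, bi, S, go, ge, free))
    per_run_sd = []
    all_q = []
    for run in range(n_runs):
        qs = np.empty(n_shuffles)
        for k in range(n_shuffles):
            sa = rng.permutation(ai) if shuffle_both else ai
            sb = rng.permutation(bi)
            qs[k] = _gotoh.gotoh_score(sa, sb, S, go, ge, free)
        std = float(qs.std(ddof=1))
        if std <= 0:
            raise DegenerateShuffleError(
                f"run {run + 1}: shuffled-quality distribution is degenerate"
            )
        per_run_sd.append((native - float(qs.mean())) / std)
        all_q.append(qs)
    allq = np.concatenate(all_q)
    return ComparisonScore(
        quality=native,
        average_quality=float(allq.mean()),
        std_quality=float(allq.std(ddof=1)),
        sd_units=float(np.mean(per_run_sd)),
        n_shuffles=n_shuffles,
        n_runs=n_runs,
        seed=seed,
    )


def z_to_probability(sd_units: float) -> Tuple[float, float]:
    """One-sided Gaussian upper-tail probability and its order of magnitude.

    Returns ``(tail_probability, order_of_magnitude)`` where the order of
    magnitude is ``10 ** floor(log10(tail))``; e.g. 9 -> 1e-19, 10 -> 1e-24.
    """
    if not math.isfinite(sd_units):
        raise ValueError("sd_units must be finite")
    tail = float(norm.sf(sd_units))
    # log-space exponent is robust when the tail underflows
    log10_tail = float(norm.logsf(sd_units)) / math.log(10.0)
    exponent = math.floor(log10_tail)
    return tail, 10.0 ** exponent


def pair_seed(base_seed: int, label: str) -> int:
    """Stable 31-bit seed for a labelled comparison: reproducible, and
    independent draws for different label pairs."""
    return (int(base_seed) ^ zlib.crc32(label.encode())) & 0x7FFFFFFF


def best_segment_pair(
    a: ProteinSequence,
    b: ProteinSequence,
    scheme: ScoringScheme | None = None,
    window_range: Tuple[int, int] = (60, 60),
    stride: int = 1,
    n_shuffles: int = 100,
    seed: int = 0,
) -> Tuple[ProteinSequence, ProteinSequence, ComparisonScore]:
    """IC-style scan: the pair of internal segments with the greatest
    standardized similarity.

    All windows of ``a`` are compared with all windows of ``b`` for window
    lengths in ``window_range`` (start positions and lengths advance by
    ``stride``; ``stride`` 1 is exhaustive).  Each window pair is scored
    with :func:`comparison_z` under a per-pair derived seed, so a coarser
    stride explores a subset of the stride-1 draws.  Ties prefer earlier
    coordinates.
    """
    wmin, wmax = window_range
    if wmin > min(len(a), len(b)) or wmax > min(len(a), len(b)):
        raise ValueError("window_range exceeds a sequence length")
    if wmin < 1 or wmin > wmax or stride < 1:
        raise ValueError("invalid window_range or stride")
    from .sequences import extract_subsequence

    best = None
    for wl in range(wmin, wmax + 1, stride):
        for ia in range(0, len(a) - wl + 1, stride):
            sub_a = extract_subsequence(a, ia + 1, ia + wl)
            for ib in range(0, len(b) - wl + 1, stride):
                sub_b = extract_subsequence(b, ib + 1, ib + wl)
                sd = pair_seed(seed, f"{ia}:{ib}:{wl}")
                score = comparison_z(
                    sub_a, sub_b, scheme, n_shuffles=n_shuffles, n_runs=1, seed=sd
                )
                key = (-score.sd_units, ia, ib, wl)
                if best is None or key < best[0]:
                    best = (key, sub_a, sub_b, score)
    assert best is not None
    return best[1], best[2], best[3]


def call_homology(
    score: ComparisonScore,
    n_aligned: int,
    threshold: float = 9.0,
    min_length: int = 60,
) -> HomologyCall:
    """Apply the 9-10 S.D. rule.

    Homology is concluded only when ``sd_units >= threshold`` *and* the
    comparison spans at least ``min_length`` aligned residues; a passing
    score on a shorter stretch is reported as suggestive only.
    """
    passes_sd = score.sd_units >= threshold
    passes_len = n_aligned >= min_length
    if passes_sd and passes_len:
        status = "homologous"
    elif passes_sd:
        status = "suggestive"
    else:
        status = "not_homologous"
    return HomologyCall(
        sd_units=score.sd_units,
        n_aligned=n_aligned,
        is_homologous=(passes_sd and passes_len),
        threshold=threshold,
        min_length=min_length,
        status=status,
    )
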