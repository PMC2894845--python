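# Methods

## The statistic

Every homology decision in this package rests on one number: the
standardized comparison score of a global alignment,

    sd_units = (quality − average_quality) / std_quality,

where *quality* is the optimal Needleman–Wunsch score of the native pair
under an affine gap model, and the mean and standard deviation summarize
the qualities obtained when the two sequences are independently shuffled
and re-aligned.  Shuffling preserves length and residue composition, so
the null distribution is specific to the pair being tested; the score
therefore measures order, not composition.  Scores are averaged over
independent runs when requested (`n_runs`); the GAP-style preset is 100
shuffles × 5 runs, the segment-scan default a single run of 500 shuffles.

The decision rule is the standard one for internal repeats: a comparison
of at least 9–10 S.D. spanning at least 60 aligned residues establishes
common ancestry.  A passing score on a shorter stretch is reported as
*suggestive* rather than homologous.  For interpretation,
`z_to_probability` converts S.D. units through the one-sided Gaussian
upper tail (9 S.D. → order 10⁻¹⁹, 10 S.D. → order 10⁻²⁴).  This is an
interpretive convention, not a claim that shuffle nulls are exactly
Gaussian; empirically the null is close to Gaussian in its bulk (see the
calibration below) but can be right-shifted for sequences with strong
internal architecture (see *Limitations*).

## Alignment model

Scoring is BLOSUM62 with gap open 8, gap extend 2 (the first gap position
costs 10, each further position 2) and free end gaps; `X` scores 0 against
everything.  These defaults approximate classic global-alignment protein
settings and every parameter is exposed, because published "default
settings" differ slightly between program generations and alignments can
shift by a column or two between choices.  The dynamic program is the
three-state Gotoh recursion, filled by numba kernels; the traceback
prefers diagonal over up over left so results are deterministic.  The
alignment core is verified two independent ways in the test suite:
against an explicit enumeration of *all* global alignments for short
sequences, and against Biopython's `PairwiseAligner` configured
identically.

Alignment statistics follow repeat-table conventions: percentages are
taken over aligned residue–residue columns only; "similar" means a
positive substitution score (identities included), so similarity ≥
identity by construction; the gap count is the number of gap *openings*
in either row, including end gaps.

## TMS calling

Transmembrane segments are called from Kyte–Doolittle hydropathy averaged
over a 19-residue window with threshold 1.6.  Plain threshold runs cannot
be used directly: window averaging turns each block/loop transition into a
ramp one window wide, so the above-threshold run inside a 21-residue helix
is only about `41 − 2·(30.4 + 19·l)/(h + l)` positions long (`h` = block
mean hydropathy, `l` = |loop mean|) — typically 8–14 residues, i.e. the
run both under-covers the helix and would be discarded by any sensible
minimum-length filter.  The caller therefore works in two scales:

1. **Detection** — maximal runs of the 19-window profile at threshold 1.6.
   Runs separated by fewer than `min_loop` (3) positions, or by a dip that
   stays above 0.75 × threshold (a noise dip inside a helix, not a loop,
   which drops far below threshold), are merged.
2. **Edge refinement** — each run edge is re-estimated by a least-squares
   two-level change-point fit on a 7-residue-window profile, which around
   a true boundary is plateau / short ramp / plateau; the change point
   lands at the ramp midpoint, i.e. the helix boundary, with a positional
   error of ~1.5 residues.  Refinement only ever extends a run (the raw
   run is certainly helix).
3. **Filters** — refined segments shorter than `min_tms_len` (15) are
   dropped; segments longer than `max_tms_len` (30) are split recursively
   at their internal hydropathy minimum, which separates hairpins whose
   helices merged at detection.

On synthetic 6-TMS proteins at 30 % divergence the caller recovers ≥ 90 %
of true boundaries within ±3 residues; misses are dominated by helices
whose windowed peak genuinely falls below 1.6 after divergence.
User-supplied annotations always take precedence over the caller, and the
generator's ground-truth annotations are used in the statistical
validation experiments so that they test the repeat statistics, not the
caller.

## Hairpin excision and repeat scanning

A *hairpin* is TMS *i* and *i+1* plus the connecting loop; excision adds a
5-residue flank on each side, clipped at sequence ends, giving segments of
roughly 55–80 residues for realistic helix/loop lengths.  The repeat scan
compares hairpin classes (1-2, 3-4, 5-6) all-vs-all across the members of
a family and keeps, per class pair, the single best cross-protein
comparison — repeat tables in the literature report best cross-species
pairs, not family averages.  The cross-family scan produces the full
class-pair table (3 × 2 = 6 rows for a 6-TMS vs 4-TMS comparison), sorted
by score.  Each labelled comparison draws its shuffles from a seed derived
from the base seed and a stable hash of the unordered label pair:
reproducible, independent across pairs, and symmetric under transposing
the scan.

Passing comparisons are edges of a homology graph; connected components
are superfamilies, and for any two nodes in a component the shortest path
of passing edges is reported as the transitivity witness (A ~ B and B ~ C
imply A ~ C even when the direct A–C comparison is too short to qualify).

## Scenario test

For a 6-TMS-carrier vs 4-TMS-channel cross table, two class mappings
correspond to the two candidate histories: the *offset* mapping
{3-4 → 1-2, 5-6 → 3-4} implied by loss of the carrier's first hairpin,
and the *identity* mapping {1-2 → 1-2, 3-4 → 3-4} implied by an
independent direct duplication.  The verdict is *hairpin-loss* when the
offset mapping outscores the identity mapping in summed S.D. **and** its
best row passes the 9 S.D. threshold; otherwise *direct-duplication*.
The significance gate is essential: for two unrelated families both sums
are noise and the sign of their difference alone would be a coin flip,
so a margin-only rule could not separate the scenarios.

## Synthetic evolution generator

The generator realizes the evolutionary model under test so that every
stage has ground-truthed inputs:

* **Primordial unit** — a 2-TMS hairpin: two 21-residue hydrophobic
  blocks, polar loops of 10–20 residues, short terminal tails.  Block
  composition is a realistic diverse hydrophobic mix (I/L/V/F/A/M plus
  minor C/G/S/T; mean KD ≈ 2.9); loops mix small/polar and charged
  residues (mean ≈ −2.0).  Early, more stereotyped compositions were
  rejected because they made *unrelated* hairpins score 9–12 S.D. — an
  architecture artifact absent from real negative controls, where
  architecture-matched unrelated channel proteins stay below ~6 S.D.
* **Triplication** — three tandem copies of the unit form the 6-TMS
  ancestor.  Each copy is first diverged by half the nominal divergence
  (`paralog_divergence`, default = the family divergence), so paralogous
  hairpins within one protein differ by about the nominal level; without
  this, fresh copies would be identical and unit ancestry untestable.
* **Radiation** — members diverge independently from the ancestor (star
  phylogeny).  Substitutions hit each site with probability `divergence`
  and are replaced by a residue drawn with probability ∝ exp(BLOSUM62
  score), excluding the original — a cheap matrix-consistent model that
  keeps TMS residues hydrophobic and loop residues polar.  Indels (1–3
  residues, probability `indel_rate` = 0.02/site) occur only in loops, so
  the TMS architecture and truth coordinates stay exact.
* **Hairpin loss** — each member loses TMSs 1–2 and the intervening
  loops, keeping its N-terminal tail, then diverges further; new TMSs 1–2
  descend from ancestral unit 2, TMSs 3–4 from unit 3.
* **Controls** — *direct duplication*: an independent hairpin duplicated
  once (4 TMSs, no shared ancestry with any triplicated family);
  *null*: a 6-TMS protein whose blocks and loops are all sampled
  independently (architecture without repeats); *composition-matched
  nulls*: i.i.d. sequences at a family's average composition.

Everything is deterministic given `FamilySpec.seed`.  At the default
divergence (0.30 per site against the ancestor) cross-member repeat
comparisons land at roughly 30–50 % identity over ~60–70 residues —
the regime where published hairpin repeats are found.

What the generator does *not* emulate: tree-shaped phylogenies (star
only), rate variation across sites, compositional drift between lineages,
signal peptides, re-entrant loops and large soluble domains.  Passing the
validation experiments therefore shows the statistics and scans behave
correctly on sequences with the stated architecture and divergence — not
that any particular real family passes them.

## Validation experiments and problem sizes

The acceptance suite and `scripts/acceptance.py` recompute, at these
sizes (chosen to give stable proportions at interactive runtimes):

* alignment exactness on 200 random pairs (length ≤ 7) against
  exhaustive enumeration;
* null calibration on 500 composition-matched 150-mer pairs at 100
  shuffles (expected: mean ≈ 0, s.d. ≈ 1, < 1 % at 5 S.D., none at 9);
* repeat recovery on 50 triplicated families (500-shuffle scans; all
  three class pairs ≥ 9 S.D.) versus 20 architecture nulls (full pattern
  never);
* scenario discrimination on 50 hairpin-loss and 50 direct-duplication
  family pairs at 100-shuffle scans;
* neighbor joining against additive 4- and 5-taxon matrices (path
  lengths exact to 1e-9);
* the published carrier/channel cross table (offset rows 14.6 and
  8.6 S.D.; identity rows 2.3 and 6.5) pushed through `scenario_test`:
  offset sum 23.2, margin 14.4, verdict hairpin-loss.

## Other numerical choices

* **Consensus** — per-column modal residue over a pseudocounted profile
  (gap-dominated columns dropped, ties alphabetical).  This reproduces
  the "highest probability amino acid per position" that a profile-HMM
  consensus emits, without HMM machinery; emission-order subtleties of
  true `hmmemit` output are not reproduced.
* **Guide tree** — UPGMA over (1 − identity) distances, the classic
  progressive-alignment convention; identity uses the shorter-sequence
  denominator (also used for redundancy clustering, matching CD-HIT's
  convention).
* **Neighbor joining** — Saitou–Nei with lowest-index tie-breaking;
  p-distances, no correction (trees are descriptive cluster diagrams);
  negative branch lengths are reported as computed so that additive
  matrices are recovered exactly.
* **Degenerate inputs** — shuffling a homopolymer yields a zero-spread
  null and raises an explicit error; percentage statistics are undefined
  (and raise) when an alignment has no aligned columns; empty families,
  ragged alignments and out-of-range coordinates raise immediately.

## Limitations

* Shuffle scores on *architecture-matched* segments (hydrophobic blocks
  alternating with polar loops) are right-shifted: the native alignment
  can lock block onto block while shuffles cannot.  Between unrelated
  synthetic hairpins the best-of-many-pairs maximum occasionally crosses
  9 S.D. (roughly one seed in ten at these family sizes), though the full
  three-pair repeat pattern never arises and the scenario test is not
  fooled.  Real analyses share this caveat — it is why short or marginal
  comparisons should be treated as suggestive and why decisions should
  rest on the pattern of scores, not a single row.
* The hydropathy caller requires a clear block/loop contrast; helices
  that drift amphipathic or polar fall below the 1.6 threshold and are
  missed.  Orientation (inside/outside) is not predicted.
* The progressive aligner is minimal (no iterative refinement); for
  publication-grade alignments of real families an external aligner can
  be ingested via `msa_consensus.read_alignment`.
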