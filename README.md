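# hairpinscan

Shuffle-statistic homology analysis of transmembrane hairpin repeats.

Membrane transporter and channel families frequently arose by intragenic
duplication of a primordial 2-transmembrane-segment (TMS) hairpin.
Establishing that two stretches of membrane protein share a common
ancestor — two internal repeats within one family, or a hairpin of one
family against a hairpin of another — needs a statistic that is honest
about composition: membrane segments all look alike to a naive score.
`hairpinscan` implements the classic GAP/IC-style answer and everything
needed around it, aimed at people studying the evolution of membrane
protein architectures (for example, whether a 4-TMS channel family
descends from a 6-TMS carrier family by loss of the first hairpin).

The central statistic is the standardized comparison score

    SD units = (quality − average quality) / standard deviation,

where *quality* is the affine-gap global (Needleman–Wunsch/Gotoh)
alignment score of the native pair, and the null mean and standard
deviation come from re-aligning many independently shuffled copies of the
two sequences (composition- and length-preserving Monte-Carlo).  A score
of 9–10 S.D. over at least 60 aligned residues establishes homology;
under the one-sided Gaussian tail, 9 S.D. corresponds to a chance
probability of order 10⁻¹⁹ and 10 S.D. to order 10⁻²⁴.  Homology is
transitive (the superfamily principle), so passing comparisons form a
graph whose connected components are superfamilies, with witness chains
for pairs whose direct comparison is too short to qualify.

The package provides:

* `sequences` — FASTA I/O, subsequence extraction, greedy CD-HIT-style
  redundancy clustering;
* `pairwise` — affine-gap global alignment (BLOSUM62, gap open 8 /
  extend 2, free end gaps by default), repeat-table statistics
  (% identity, % similarity, gap openings) and the `|`/`:`/`.` alignment
  rendering;
* `significance` — sequence shuffling, comparison scores in S.D. units,
  tail-probability conversion, IC-style best-segment search, and the
  9 S.D. / 60-residue homology call;
* `topology` — Kyte–Doolittle hydropathy and helical-moment profiles, a
  two-scale TMS caller, hairpin excision, AveHAS-style averaged profiles
  over an alignment;
* `msa_consensus` — a minimal progressive aligner (UPGMA guide tree,
  profile–profile merging), Clustal/aligned-FASTA ingestion, column
  profiles and modal-residue consensus sequences;
* `repeats_superfamily` — internal-repeat and cross-family hairpin scans,
  homology graphs, superfamily closure, and the hairpin-loss vs
  direct-duplication scenario test;
* `phylogeny` — p-distance matrices and neighbor-joining Newick trees;
* `synthetic_data` — a ground-truthed generator of the evolutionary
  model (hairpin triplication → 6-TMS carrier → hairpin loss → 4-TMS
  channel, plus controls);
* `pipeline_cli` / the `hairpinscan` command — end-to-end orchestration
  and plain-text reports.

## Worked example

Generate a synthetic 6-TMS carrier family and its hairpin-loss 4-TMS
derivative, then run the full analysis:

```bash
hairpinscan generate --scenario hairpin_loss --n-members 3 --seed 11 --outdir demo
hairpinscan scan --family-a demo/cdf.faa --family-b demo/orai.faa \
    --annotations-a demo/cdf.tms.tsv --annotations-b demo/orai.tms.tsv \
    --outdir demo/out --n-shuffles 200 --seed 11
```

which prints (abridged):

```
Internal repeats, family A
--------------------------
classes        residues  score(SD)  %ident  %simil  gaps  best pair
1-2 vs 3-4           63       23.6    44.4    71.4     0  cdf2:tms1-2 / cdf3:tms3-4
1-2 vs 5-6           63       26.4    42.9    73.0     0  cdf3:tms1-2 / cdf2:tms5-6
3-4 vs 5-6           63       24.5    49.2    76.2     1  cdf1:tms3-4 / cdf2:tms5-6

Cross-family comparisons
------------------------
classes        residues  score(SD)  %ident  %simil  gaps  best pair
5-6 vs 3-4           63       36.9    71.4    85.7     0  cdf3:tms5-6 / orai3:tms3-4
3-4 vs 1-2           60       35.3    80.0    93.3     1  cdf2:tms3-4 / orai2:tms1-2
1-2 vs 1-2           60       20.8    36.7    68.3     1  cdf3:tms1-2 / orai2:tms1-2
...

Scenario verdict: hairpin-loss (offset 72.2 vs identity 41.2 S.D., margin 31.0)

Superfamilies (homology components):
  A:1-2 ~ A:3-4 ~ A:5-6 ~ B:1-2 ~ B:3-4
```

Reading it: every pair of hairpin classes inside family A scores far
above 9 S.D. over ~60 residues — the three 2-TMS hairpins of the 6-TMS
family are internal repeats of one primordial unit.  In the cross-family
table the *offset* rows (A 3-4 vs B 1-2, A 5-6 vs B 3-4) lead, exactly
the pattern expected if family B arose from family A's ancestor by losing
hairpin 1-2; the verdict line quantifies that with the summed-score
margin.  The closure line states the end result: all five hairpin classes
of both families belong to one superfamily.

The same analysis runs on real data by pointing `--family-a/--family-b`
at FASTA files (with optional TMS annotation TSVs; otherwise the
hydropathy caller annotates).  The library API mirrors the CLI — see the
module docstrings and `docs/methods.md` for the model, parameter
meanings, and numerical choices.

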