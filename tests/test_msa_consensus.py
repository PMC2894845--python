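import numpy as np
import pytest

from hairpinscan.msa_consensus import (
    AlignmentFormatError,
    ColumnProfile,
    EmptyConsensusError,
    MultipleAlignment,
    column_profile,
    consensus_of,
    consensus_sequence,
    progressive_align,
    read_alignment,
    write_alignment,
)
from hairpinscan.pairwise import global_align
from hairpinscan.sequences import AMINO_ACIDS, ProteinSequence, pairwise_identity
from hairpinscan.synthetic_data import FamilySpec, build_cdf_like


def _random_seq(rng, n, name):
    return ProteinSequence(name, "".join(rng.choice(list(AMINO_ACIDS), size=n)))


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        seqs = [ProteinSequence(f"s{i}", "MKVLWAALLG") for i in range(3)]
        msa = progressive_align(seqs)
        assert all("-" not in row for _, row in msa.rows)
        assert msa.n_columns == 10

    def test_two_sequences_reduce_to_pairwise(self, rng):
        a, b = _random_seq(rng, 40, "a"), _random_seq(rng, 50, "b")
        msa = progressive_align([a, b])
        aln = global_align(a, b)
        assert dict(msa.rows) == {"a": aln.row_a, "b": aln.row_b}

    def test_single_sequence_unchanged(self):
        seq = ProteinSequence("only", "MKVLW")
        msa = progressive_align([seq])
        assert msa.rows == [("only", "MKVLW")]

    def test_degapping_recovers_inputs(self, cdf_family):
        msa = progressive_align(cdf_family.members)
        originals = {s.id: s.residues for s in cdf_family.members}
        for sid, row in msa.rows:
            assert row.replace("-", "") == originals[sid]

    def test_input_order_invariance_three_sequences(self, rng):
        seqs = [_random_seq(rng, 30, n) for n in ("a", "b", "c")]
        m1 = progressive_align(seqs)
        m2 = progressive_align(seqs[::-1])
        assert sorted(m1.rows) == sorted(m2.rows)

    def test_tms_columns_align_across_members(self):
        """Planted TMS columns co-align in the family alignment."""
        fam = build_cdf_like(FamilySpec(seed=4, n_members=8, divergence=0.2))
        msa = progressive_align(fam.members)
        col_sets = []
        for sid, row in msa.rows:
            ann = fam.truth[sid]
            cols = set()
            pos = 0
            for j, c in enumerate(row):
                if c != "-":
                    pos += 1
                    if any(s <= pos <= e for s, e in ann.segments[:1]):
                        cols.add(j)
            col_sets.append(cols)
        ref = col_sets[0]
        agreements = [
            len(ref & other) / max(len(ref | other), 1) for other in col_sets[1:]
        ]
        assert np.mean(agreements) >= 0.8


class TestReadWriteAlignment:
    def test_aligned_fasta_verbatim(self, tmp_path):
        p = tmp_path / "aln.faa"
        p.write_text(">a\nMK-VL\n>b\nMKWV-\n")
        msa = read_alignment(p, "fasta")
        assert msa.rows == [("a", "MK-VL"), ("b", "MKWV-")]

    def test_clustal_round_trip_across_blocks(self, tmp_path, cdf_family):
        msa = progressive_align(cdf_family.members[:3])
        p = tmp_path / "aln.aln"
        write_alignment(msa, p, "clustal")
        back = read_alignment(p, "clustal")
        assert back.rows == msa.rows

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.faa"
        p.write_text(">a\nMK-VL\n>b\nMKV\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(p, "fasta")

    def test_all_gap_column_dropped(self):
        msa = MultipleAlignment([("a", "M-K"), ("b", "M-K")])
        assert msa.n_columns == 2


class TestColumnProfile:
    def test_pure_column(self):
        msa = MultipleAlignment([(f"s{i}", "A") for i in range(4)])
        prof = column_profile(msa)
        a_idx = ColumnProfile.SYMBOLS.index("A")
        assert prof.freqs[0, a_idx] > 0.95
        assert prof.freqs[0].sum() == pytest.approx(1.0)

    def test_split_column(self):
        msa = MultipleAlignment([("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
        prof = column_profile(msa)
        a_idx = ColumnProfile.SYMBOLS.index("A")
        c_idx = ColumnProfile.SYMBOLS.index("C")
        assert prof.freqs[0, a_idx] == pytest.approx(prof.freqs[0, c_idx])
        assert prof.freqs[0, a_idx] == pytest.approx(0.5, abs=0.05)

    def test_matches_counting_oracle(self, rng):
        rows = [
            (f"s{i}", "".join(rng.choice(list(AMINO_ACIDS + "-"), size=12)))
            for i in range(6)
        ]
        rows = [(sid, row) for sid, row in rows]
        msa = MultipleAlignment(rows)
        prof = column_profile(msa, pseudocount=0.0)
        for j in range(msa.n_columns):
            for sym_i, sym in enumerate(ColumnProfile.SYMBOLS):
                count = sum(1 for _, row in msa.rows if row[j] == sym)
                assert prof.freqs[j, sym_i] == pytest.approx(count / msa.n_rows)


class TestConsensus:
    def test_identity_on_identical_rows(self):
        msa = MultipleAlignment([(f"s{i}", "MKVLW") for i in range(3)])
        cons = consensus_sequence(column_profile(msa))
        assert cons.residues == "MKVLW"

    def test_alphabetical_tie_break(self):
        msa = MultipleAlignment(
            [("a", "A"), ("b", "A"), ("c", "C"), ("d", "C"), ("e", "W")]
        )
        cons = consensus_sequence(column_profile(msa))
        assert cons.residues == "A"

    def test_gap_dominated_columns_dropped(self):
        msa = MultipleAlignment([("a", "M--K"), ("b", "M--K"), ("c", "MWWK")])
        cons = consensus_sequence(column_profile(msa), max_gap_fraction=0.5)
        assert cons.residues == "MK"

    def test_empty_consensus_error(self):
        msa = MultipleAlignment([("a", "M-"), ("b", "-K")])
        with pytest.raises(EmptyConsensusError):
            consensus_sequence(column_profile(msa), max_gap_fraction=0.3)

    def test_idempotent_on_gap_free_alignment(self):
        msa = MultipleAlignment([("a", "MKVLW"), ("b", "MKVLW"), ("c", "MKVIW")])
        c1 = consensus_sequence(column_profile(msa))
        msa2 = MultipleAlignment([("c1", c1.residues)])
        c2 = consensus_sequence(column_profile(msa2))
        assert c2.residues == c1.residues

    def test_consensus_closer_to_ancestor_than_leaves(self):
        """Averaging over leaves cancels independent substitutions, so the
        consensus should resemble the ancestor more than typical leaves do
        (majority of seeds)."""
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            fam = build_cdf_like(FamilySpec(seed=seed, n_members=6))
            cons = consensus_of(fam.members)
            to_anc = pairwise_identity(cons, fam.ancestor)
            to_leaves = np.mean(
                [pairwise_identity(cons, m) for m in fam.members]
            )
            wins += to_anc > to_leaves
        assert wins > n_seeds / 2

    def test_family_vs_family_consensus_comparison(self, cdf_family, orai_family):
        """Consensus-vs-consensus comparison of the two synthetic families
        detects their shared ancestry (the published workflow's
        confirmatory step)."""
        from hairpinscan.significance import comparison_z

        cons_cdf = consensus_of(cdf_family.members, seq_id="cdf_cons")
        cons_orai = consensus_of(orai_family.members, seq_id="orai_cons")
        score = comparison_z(cons_cdf, cons_orai, n_shuffles=100, seed=0)
        assert score.sd_units >= 9.0
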