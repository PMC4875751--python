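"""Pairwise/progressive alignment, identity, and query-to-master mapping."""

import subprocess

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ortho_signature.align import (DEFAULT_SCHEME, PairwiseAlignment, ScoringScheme,
                                   alignment_score, anchor_position_to_column,
                                   global_align, map_query_to_master,
                                   percent_identity, progressive_msa)
from ortho_signature.errors import LookupMissingError, ValidationError
from ortho_signature.seqio import AMINO_ACIDS, ProteinSequence, read_fasta, write_fasta

residues_st = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=40)


def seq(s, i="q"):
    return ProteinSequence(id=i, residues=s)


class TestGlobalAlign:
    def test_self_alignment(self):
        a = global_align(seq("MKR"), seq("MKR"))
        assert a.aligned_a == "MKR" and a.aligned_b == "MKR"
        assert a.identity_pct == 100.0

    def test_single_gap_case_hand_dp(self):
        # 4x3 DP table by hand: optimal is MKRL / MK-L,
        # score = M:M(5) + K:K(5) + gap open(-10) + L:L(4) = 4
        a = global_align(seq("MKRL"), seq("MKL"))
        assert (a.aligned_a, a.aligned_b) == ("MKRL", "MK-L")
        assert a.score == 4.0
        assert a.identity_pct == 100.0  # 3 identical / 3 non-gap columns

    def test_optimal_beats_fixed_alternatives(self):
        a = global_align(seq("MKRDE"), seq("MKDE"))
        alternatives = [
            PairwiseAlignment(aligned_a="MKRDE", aligned_b="MKDE-", score=0),
            PairwiseAlignment(aligned_a="MKRDE", aligned_b="-MKDE", score=0),
            PairwiseAlignment(aligned_a="MKRDE", aligned_b="MK-DE", score=0),
        ]
        for alt in alternatives:
            assert a.score >= alignment_score(alt)

    def test_emitted_score_is_self_consistent(self):
        a = global_align(seq("MKRLVDEAY"), seq("MKLVDAY"))
        assert a.score == pytest.approx(alignment_score(a))

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValidationError):
            ScoringScheme(gap_open=-0.5, gap_extend=-10.0)


class TestPercentIdentity:
    def test_identical_is_100(self):
        assert percent_identity(seq("MKRDE"), seq("MKRDE")) == 100.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(residues_st, residues_st)
    def test_symmetric(self, a, b):
        assert percent_identity(seq(a), seq(b, "r")) == percent_identity(seq(b, "r"), seq(a))

    def test_decreases_with_accumulating_mutations(self):
        import numpy as np
        from ortho_signature.jtt import JTT_ORDER, default_model
        from ortho_signature.synth import evolve_branch, sample_equilibrium
        rng = np.random.default_rng(0)
        model = default_model()
        root = sample_equilibrium(120, rng, model)
        base = "".join(JTT_ORDER[s] for s in root)
        idents = []
        for t in (0.05, 0.3, 1.0):
            child = evolve_branch(root, t, rng, model)
            idents.append(percent_identity(seq(base), seq("".join(JTT_ORDER[s] for s in child), "c")))
        assert idents[0] > idents[1] > idents[2]


class TestProgressiveMSA:
    def test_identical_sequences_no_gaps(self):
        msa = progressive_msa([seq("MKRDE", "a"), seq("MKRDE", "b"), seq("MKRDE", "c")])
        assert msa.length == 5
        assert all("-" not in r for r in msa.rows)

    def test_single_internal_gap_exhaustive_oracle(self):
        # All placements of one gap in MKR vs MKKR: aligning against MKKR,
        # the best is the one skipping one K (checked exhaustively by score).
        msa = progressive_msa([seq("MKR", "x"), seq("MKKR", "y"), seq("MKR", "z")])
        assert msa.length == 4
        assert msa.row("y") == "MKKR"
        assert msa.row("x").count("-") == 1
        assert msa.row("x")[0] == "M" and msa.row("x")[-1] == "R"

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(residues_st, min_size=2, max_size=5))
    def test_degap_invariant(self, seqs):
        records = [seq(s, f"s{i}") for i, s in enumerate(seqs)]
        msa = progressive_msa(records)
        for r in records:
            assert msa.degapped(r.id) == r.residues

    def test_agrees_with_mafft_on_easy_family(self, tmp_path, small_family):
        """Independent aligner oracle: on low-divergence sequences the
        built-in progressive aligner and mafft imply the same per-pair
        identities (within a small tolerance)."""
        from ortho_signature import SimulationConfig, simulate_family
        fam = simulate_family(SimulationConfig(n_orders=2, species_per_order=3,
                                               tree_height=0.15, seed=5))
        seqs = fam.sequences
        mine = progressive_msa(seqs)
        fa = tmp_path / "in.fasta"
        write_fasta(seqs, fa)
        out = subprocess.run(["mafft", "--quiet", str(fa)], capture_output=True,
                             text=True, check=True)
        mafft_path = tmp_path / "mafft.fasta"
        mafft_path.write_text(out.stdout)
        theirs = read_fasta(mafft_path, gapped=True)

        def pair_ident(aln, i, j):
            pairs = [(x, y) for x, y in zip(aln.row(i), aln.row(j))
                     if x != "-" and y != "-"]
            return 100.0 * sum(x == y for x, y in pairs) / len(pairs)

        ids = [s.id for s in seqs]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                assert pair_ident(mine, ids[i], ids[j]) == pytest.approx(
                    pair_ident(theirs, ids[i], ids[j]), abs=5.0)


class TestMapQueryToMaster:
    def test_identity_mapping(self, small_family):
        aln = small_family.alignment
        anchor = aln.ids[0]
        q = ProteinSequence(id="copy", residues=aln.degapped(anchor))
        mapping = map_query_to_master(q, aln, anchor)
        row = aln.row(anchor)
        assert all(mapping[c] == row[c - 1] for c in range(1, aln.length + 1))

    def test_single_substitution_keeps_mapping(self, small_family):
        aln = small_family.alignment
        anchor = aln.ids[0]
        res = list(aln.degapped(anchor))
        res[50] = "W" if res[50] != "W" else "Y"
        q = ProteinSequence(id="mut", residues="".join(res))
        mapping = map_query_to_master(q, aln, anchor)
        row = aln.row(anchor)
        diffs = [c for c in range(1, aln.length + 1) if mapping[c] != row[c - 1]]
        assert len(diffs) == 1

    def test_missing_anchor_raises(self, small_family):
        q = ProteinSequence(id="q", residues="MKR")
        with pytest.raises(LookupMissingError):
            map_query_to_master(q, small_family.alignment, "nope")

    def test_consistent_with_realignment_oracle(self):
        """Mapping through the anchor agrees with re-running the progressive
        aligner including the query (>=95% of columns)."""
        from ortho_signature import SimulationConfig, simulate_family
        fam = simulate_family(SimulationConfig(n_orders=2, species_per_order=3,
                                               tree_height=0.1, neutral=True, seed=3))
        aln = fam.alignment
        anchor = aln.ids[0]
        query = ProteinSequence(id="newseq", residues=aln.degapped(aln.ids[-1]))
        mapping = map_query_to_master(query, aln, anchor)
        re_msa = progressive_msa(fam.sequences + [query])
        # compare query residues assigned to each anchor residue
        re_anchor, re_query = re_msa.row(anchor), re_msa.row("newseq")
        oracle = {}
        k = 0
        for a_ch, q_ch in zip(re_anchor, re_query):
            if a_ch != "-":
                k += 1
                oracle[k] = q_ch
        anchor_row = aln.row(anchor)
        agree = total = 0
        k = 0
        for col in range(1, aln.length + 1):
            if anchor_row[col - 1] != "-":
                k += 1
                total += 1
                agree += mapping[col] == oracle[k]
        assert agree / total >= 0.95

    def test_anchor_position_to_column(self):
        from ortho_signature.seqio import MasterAlignment
        aln = MasterAlignment(ids=["a", "b"], rows=["M-KR", "MDKR"])
        assert anchor_position_to_column(aln, "a", 2) == 3  # K skips the gap
        with pytest.raises(ValidationError):
            anchor_position_to_column(aln, "a", 9)
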