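"""Alignment, trimming, trees, active-site typing and protein properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chi_evoscape import classify
from chi_evoscape.io_formats import SeqRecord
from chi_evoscape.synthetic_data import make_chi_proteome

from conftest import blosum62_dict, oracle_nw_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestPairwiseAlignment:
    @given(
        st.text(alphabet=AA, min_size=1, max_size=8),
        st.text(alphabet=AA, min_size=1, max_size=8),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_score_matches_recursive_nw_oracle(self, a, b):
        sub = blosum62_dict()
        got = classify.pairwise_global_score(a, b, gap_open=10.0, gap_extend=0.5)
        expected = oracle_nw_score(a, b, sub, 10.0, 0.5)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_one_gap_column_for_deletion(self):
        msa = classify.build_msa([SeqRecord("a", "ACD"), SeqRecord("b", "AD")])
        assert msa.rows[0] == "ACD"
        assert msa.rows[1] in ("A-D",)

    def test_identical_sequences_align_gap_free(self):
        msa = classify.build_msa([SeqRecord("a", "MKVW"), SeqRecord("b", "MKVW")])
        assert msa.rows == ["MKVW", "MKVW"]

    def test_two_sequence_alignment_order_invariant(self):
        r1, r2 = SeqRecord("a", "MKVLWD"), SeqRecord("b", "MKLWD")
        m1 = classify.build_msa([r1, r2])
        m2 = classify.build_msa([r2, r1])
        pairs1 = set(zip(m1.rows[0], m1.rows[1]))
        pairs2 = set(zip(m2.rows[1], m2.rows[0]))
        assert pairs1 == pairs2

    def test_single_sequence_trivial_msa(self):
        msa = classify.build_msa([SeqRecord("a", "MKV")])
        assert msa.rows == ["MKV"]


class TestTrim:
    def test_boundary_half_gap_column_kept(self):
        """A 4-row column with 2 gaps has non-gap fraction exactly 0.5 and is kept."""
        msa = classify.Msa(
            ids=list("abcd"), rows=["AK", "A-", "AK", "A-"]
        )
        trimmed = classify.trim_msa(msa, gt=0.5)
        assert trimmed.rows == ["AK", "A-", "AK", "A-"]

    def test_gap_free_alignment_unchanged(self):
        msa = classify.Msa(ids=["a", "b"], rows=["MKV", "MKV"])
        assert classify.trim_msa(msa, 0.5).rows == msa.rows

    def test_fully_trimmed_rejected(self):
        msa = classify.Msa(ids=list("abcd"), rows=["A--", "-A-", "--A", "---"])
        with pytest.raises(ValueError, match="fully trimmed"):
            classify.trim_msa(msa, 0.5)

    def test_random_alignments_every_kept_column_satisfies_threshold(self, rng):
        for _ in range(50):
            rows = [
                "".join(rng.choice(list(AA + "---"), size=20)) for _ in range(6)
            ]
            msa = classify.Msa(ids=[f"s{i}" for i in range(6)], rows=rows)
            try:
                trimmed, kept = classify.trim_msa_columns(msa, 0.5)
            except ValueError:
                kept = []
            for c in range(20):
                frac = sum(r[c] != "-" for r in rows) / 6
                assert (c in kept) == (frac >= 0.5)

    def test_colmap_round_trips(self, rng):
        rows = ["A-CD-E", "AB-DEF"]
        msa = classify.Msa(ids=["a", "b"], rows=rows)
        for sid, row in zip(msa.ids, rows):
            cm = msa.colmap(sid)
            ungapped = row.replace("-", "")
            assert len(cm) == len(ungapped)
            for pos, col in enumerate(cm):
                assert row[col] == ungapped[pos]


class TestTree:
    def test_identical_sequences_star_tree(self):
        msa = classify.Msa(ids=["a", "b", "c"], rows=["MKV", "MKV", "MKV"])
        nwk = classify.build_nj_tree(msa)
        assert set("abc") <= set(nwk.replace("(", " ").replace(")", " ").replace(",", " ").replace(":", " ").split())
        assert "0.0" in nwk

    def test_additive_distances_recover_topology(self):
        """Two cherries of an additive 4-taxon tree stay together under NJ."""
        # ((a,b),(c,d)): a-b close, c-d close, across distant
        rows = [
            "AAAAAAAAAACCCCCCCCCC",
            "AAAAAAAAAWCCCCCCCCCC",
            "GGGGGGGGGGMMMMMMMMMM",
            "GGGGGGGGGWMMMMMMMMMM",
        ]
        msa = classify.Msa(ids=list("abcd"), rows=rows)
        nwk = classify.build_nj_tree(msa)
        import io as _io

        from skbio import TreeNode

        tree = TreeNode.read(_io.StringIO(nwk))
        ab = {t.name for t in tree.lca(["a", "b"]).tips()}
        assert ab == {"a", "b"}

    def test_deterministic(self):
        msa = classify.Msa(
            ids=list("abcd"),
            rows=["MKVLW", "MKVLD", "MKALW", "MKARW"],
        )
        assert classify.build_nj_tree(msa) == classify.build_nj_tree(msa)

    def test_needs_three_sequences(self):
        msa = classify.Msa(ids=["a", "b"], rows=["MK", "MK"])
        with pytest.raises(ValueError, match="at least 3"):
            classify.build_nj_tree(msa)


def _toy_typing_setup():
    # Reference "r" carries S at ungapped position 3; tree groups g1/g2/g3
    ids = ["r", "t", "w", "gap", "c3", "c4"]
    rows = [
        "MKSVW",  # r: group3, S -> type I
        "MKTVW",  # t: group3, T -> type II
        "MKWVW",  # w: group3, W -> type V
        "MK-VW",  # gap: group3, gap -> unclassified
        "MKAVW",  # c3: group1 -> III
        "MKCVW",  # c4: group2 -> IV
    ]
    msa = classify.Msa(ids=ids, rows=rows)
    tree = "(((r:1,t:1):1,(w:1,gap:1):1):1,(c3:2,c4:2):1);"
    # group3 anchored by r and gap (lca spans r,t,w,gap); c3/c4 are their own clades
    exemplars = {"group1": ["c3"], "group2": ["c4"], "group3": ["r", "gap"]}
    return msa, tree, exemplars


class TestAssignTypes:
    def test_active_site_residue_rule(self):
        msa, tree, exemplars = _toy_typing_setup()
        out = {a.seq_id: a.chi_type for a in classify.assign_types(msa, tree, "r", 3, exemplars)}
        assert out == {
            "r": "I",
            "t": "II",
            "w": "V",
            "gap": "unclassified",
            "c3": "III",
            "c4": "IV",
        }

    def test_reference_must_exist(self):
        msa, tree, exemplars = _toy_typing_setup()
        with pytest.raises(ValueError, match="reference"):
            classify.assign_types(msa, tree, "nope", 3, exemplars)

    def test_position_outside_reference_rejected(self):
        msa, tree, exemplars = _toy_typing_setup()
        with pytest.raises(ValueError, match="ref_position"):
            classify.assign_types(msa, tree, "r", 99, exemplars)

    def test_overlapping_exemplar_clades_rejected(self):
        msa, tree, _ = _toy_typing_setup()
        bad = {"group1": ["c3", "r"], "group2": ["c4"], "group3": ["r", "gap"]}
        with pytest.raises(ValueError, match="overlap"):
            classify.assign_types(msa, tree, "r", 3, bad)

    def test_full_pipeline_recovers_planted_types(self):
        """MSA -> trim -> NJ -> residue rule recovers all planted I/II/V labels."""
        records, truth = make_chi_proteome(
            18, 0, type_mix={"I": 0.3, "II": 0.3, "V": 0.2, "III": 0.1, "IV": 0.1}, seed=11
        )
        msa = classify.build_msa(records)
        trimmed, kept = classify.trim_msa_columns(msa, 0.5)
        ref = truth.extra["reference_id"]
        assert msa.colmap(ref)[truth.extra["ref_position"] - 1] in kept
        tree = classify.build_nj_tree(trimmed)
        out = classify.assign_types(
            msa, tree, ref, truth.extra["ref_position"], truth.extra["exemplars"]
        )
        assert {a.seq_id: a.chi_type for a in out} == truth.type_labels


class TestProperties:
    def test_glycine_dipeptide_mass(self):
        _, mw, _ = classify.compute_properties(SeqRecord("g", "GG"))
        assert mw == pytest.approx(2 * 57.0519 + 18.0153, abs=1e-4)

    def test_mass_additivity(self):
        _, mw_ab, _ = classify.compute_properties(SeqRecord("x", "MKVW"))
        _, mw_a, _ = classify.compute_properties(SeqRecord("a", "MK"))
        _, mw_b, _ = classify.compute_properties(SeqRecord("b", "VW"))
        assert mw_ab == pytest.approx(mw_a + mw_b - 18.0153, abs=1e-6)

    def test_charge_balance_and_basic_vs_acidic(self):
        for seq in ("KKKKK", "DDDDD", "MKVHWRE"):
            _, _, pi = classify.compute_properties(SeqRecord("s", seq))
            assert abs(classify.net_charge(seq, pi)) < 1e-4
        pi_k = classify.compute_properties(SeqRecord("k", "K" * 8))[2]
        pi_d = classify.compute_properties(SeqRecord("d", "D" * 8))[2]
        assert pi_k > pi_d

    def test_lysine_to_aspartate_lowers_pi(self):
        base = "MKVKWE"
        swapped = "MDVKWE"
        assert (
            classify.compute_properties(SeqRecord("a", base))[2]
            > classify.compute_properties(SeqRecord("b", swapped))[2]
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify.compute_properties(SeqRecord("e", ""))
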