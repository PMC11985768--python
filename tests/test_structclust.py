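"""TM-score superposition, similarity matrices and UPGMA clustering."""

import numpy as np
import pytest

from chi_evoscape import _upgma, structclust as sc
from chi_evoscape.io_formats import Structure
from chi_evoscape.pipeline import adjusted_rand_index
from chi_evoscape.synthetic_data import (
    _random_rotation,
    make_structure_set,
    sandwich_core,
)

from conftest import oracle_upgma_scipy

SEQ = ("LVEAIGKSTDFNQRHMWYCP" * 5)


def _core_structure(sid="a", n=60):
    return Structure(sid, sandwich_core(n), 0.9, SEQ[:n])


class TestTmAlign:
    def test_d0_formula_at_length_40(self):
        assert sc.d0_tm(40) == pytest.approx(1.24 * 25 ** (1 / 3) - 1.8, rel=1e-9)
        assert sc.d0_tm(40) == pytest.approx(1.826, abs=2e-3)

    def test_d0_floor_for_short_chains(self):
        assert sc.d0_tm(16) == 0.5
        assert sc.d0_tm(21) == 0.5  # formula below the floor here

    def test_rigid_transform_invariance(self, rng):
        s1 = _core_structure()
        for _ in range(25):
            r = _random_rotation(rng)
            t = rng.uniform(-50, 50, 3)
            s2 = Structure("b", s1.ca_coords @ r.T + t, 0.9, s1.seq)
            assert sc.tm_align_pair(s1, s2) == pytest.approx(1.0, abs=1e-6)

    def test_cross_group_similarity_below_within_group(self):
        structs, truth = make_structure_set(n_groups=3, n_per_group=2, seed=4)
        by_id = {s.id: s for s in structs}
        within = sc.tm_align_pair(by_id["s1_0"], by_id["s1_1"])
        across = sc.tm_align_pair(by_id["s1_0"], by_id["s2_0"])
        assert across < within

    def test_too_short_rejected(self):
        s = Structure("s", np.random.default_rng(0).normal(size=(10, 3)), 0.9, "A" * 10)
        with pytest.raises(ValueError, match="20"):
            sc.tm_align_pair(s, s)


class TestKabsch:
    def test_exact_superposition_of_transformed_copy(self, rng):
        p = rng.normal(size=(5, 3))
        r_true = _random_rotation(rng)
        t_true = rng.uniform(-5, 5, 3)
        q = p @ r_true.T + t_true
        r, t = sc.kabsch(p, q)
        assert np.allclose(p @ r.T + t, q, atol=1e-9)

    def test_not_worse_than_random_rotation_search(self, rng):
        """Kabsch RMSD is a global optimum: no sampled rotation beats it."""
        p = rng.normal(size=(4, 3))
        q = rng.normal(size=(4, 3))
        r, t = sc.kabsch(p, q)
        best = np.sqrt(np.mean(np.sum((p @ r.T + t - q) ** 2, axis=1)))
        for _ in range(300):
            rr = _random_rotation(rng)
            diff = p @ rr.T - q
            tt = -diff.mean(axis=0)
            rmsd = np.sqrt(np.mean(np.sum((diff + tt) ** 2, axis=1)))
            assert best <= rmsd + 1e-9


class TestSimilarityMatrix:
    def test_confidence_filter_excludes_low_scoring_models(self):
        structs, _ = make_structure_set(
            n_groups=2, n_per_group=5, fraction_low_conf=0.2, seed=3
        )
        assert sum(1 for s in structs if s.confidence < 0.7) == 2
        m = sc.build_similarity_matrix(structs, conf_min=0.7)
        assert len(m.ids) == 8

    def test_minmax_scaling_definition(self):
        structs, _ = make_structure_set(n_groups=3, n_per_group=2, seed=5)
        m = sc.build_similarity_matrix(structs)
        off = ~np.eye(len(m.ids), dtype=bool)
        assert m.scaled[off].min() == pytest.approx(0.0, abs=1e-12)
        assert m.scaled[off].max() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diag(m.scaled) == 1.0)
        assert np.allclose(m.raw, m.raw.T)

    def test_fewer_than_three_survivors_rejected(self):
        structs, _ = make_structure_set(n_groups=2, n_per_group=2, seed=1)
        for s in structs[:2]:
            s.confidence = 0.5
        with pytest.raises(ValueError, match=structs[0].id):
            sc.build_similarity_matrix(structs[:4], conf_min=0.7)


class TestBrayCurtis:
    def test_hand_value(self):
        assert sc.bray_curtis(np.array([1.0, 0.5]), np.array([0.5, 1.0])) == pytest.approx(1 / 3)

    def test_all_zero_rows_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sc.bray_curtis(np.zeros(3), np.zeros(3))


class TestUpgma:
    def test_three_leaf_hand_example(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        dendro = _upgma.upgma(d, ["A", "B", "C"])
        assert dendro.heights == [1.0, 2.0]
        assert dendro.merges[0].left == 0 and dendro.merges[0].right == 1

    def test_matches_scipy_average_linkage_oracle(self, rng):
        for _ in range(30):
            n = 8
            x = rng.uniform(0.1, 5, size=(n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0)
            dendro = _upgma.upgma(d, [f"s{i}" for i in range(n)])
            z = oracle_upgma_scipy(d)
            # scipy heights are between-cluster distances; ours are half that
            assert np.allclose(sorted(h * 2 for h in dendro.heights), sorted(z[:, 2]), atol=1e-9)

    def test_heights_monotone_nondecreasing(self, rng):
        x = rng.uniform(0, 1, size=(12, 12))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        h = _upgma.upgma(d, [f"s{i}" for i in range(12)]).heights
        assert all(b >= a - 1e-12 for a, b in zip(h, h[1:]))

    def test_cut_produces_exactly_k_groups(self, rng):
        x = rng.uniform(0, 1, size=(10, 10))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        dendro = _upgma.upgma(d, [f"s{i}" for i in range(10)])
        for k in (1, 3, 7, 10):
            labels = _upgma.cut(dendro, k=k)
            assert len(set(labels.values())) == k

    def test_newick_round_trip_parses(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        dendro = _upgma.upgma(d, ["A", "B", "C x"])
        nwk = _upgma.to_newick(dendro)
        import io as _io

        from skbio import TreeNode

        tree = TreeNode.read(_io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"A", "B", "C x"}


class TestClustering:
    def test_planted_five_groups_recovered_exactly(self):
        structs, truth = make_structure_set(n_groups=5, n_per_group=4, noise_sd=0.5, seed=6)
        m = sc.build_similarity_matrix(structs)
        dendro = sc.cluster_structures(m, k=5)
        ari = adjusted_rand_index(dendro.group_labels, truth.struct_group_labels)
        assert ari == pytest.approx(1.0)

    def test_direct_metric_flag(self):
        structs, _ = make_structure_set(n_groups=3, n_per_group=2, seed=8)
        m = sc.build_similarity_matrix(structs)
        dendro = sc.cluster_structures(m, k=3, metric="direct")
        assert len(set(dendro.group_labels.values())) == 3
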