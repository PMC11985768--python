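"""Duplication-mode rules, priority resolution, and enrichment testing."""

import numpy as np
import pytest

from chi_evoscape import duplication as dup
from chi_evoscape.io_formats import GeneModel
from chi_evoscape.synthetic_data import make_duplicated_genome

MODES = ("WGD", "TD", "PD", "TRD", "DSD")


def _genome(ranks_by_chrom):
    genes = []
    for chrom, ids in ranks_by_chrom.items():
        for rank, gid in enumerate(ids):
            start = 1000 * (rank + 1)
            genes.append(GeneModel(gid, chrom, start, start + 500, "+", rank))
    return genes


class TestPairRules:
    def test_adjacent_ranks_are_tandem(self):
        genes = _genome({"chr2": [f"g{i}" for i in range(10)]})
        calls = dup.classify_duplications(set(), genes, [("g7", "g8")], [], [])
        modes = {c.gene_id: c.mode for c in calls}
        assert modes["g7"] == modes["g8"] == "TD"
        assert modes["g0"] == "singleton"

    def test_anchor_pair_outranks_adjacency(self):
        genes = _genome({"chr1": ["a", "b", "c"]})
        calls = dup.classify_duplications(set(), genes, [("a", "b")], [("a", "b")], [])
        modes = {c.gene_id: c.mode for c in calls}
        assert modes["a"] == modes["b"] == "WGD"

    def test_proximal_window(self):
        genes = _genome({"chr1": [f"g{i}" for i in range(15)]})
        calls = dup.classify_duplications(
            set(), genes, [("g0", "g5"), ("g1", "g13")], [], [], proximal_max_rank_gap=10
        )
        modes = {c.gene_id: c.mode for c in calls}
        assert modes["g0"] == "PD"  # gap 5
        assert modes["g1"] == "DSD"  # gap 12 beyond the window, no outgroup evidence

    def test_transposed_requires_exactly_one_outgroup_member(self):
        genes = _genome({"chr1": ["a"], "chr2": ["b"], "chr3": ["c"], "chr4": ["d"]})
        out_anchors = [("b", "og1"), ("c", "og2"), ("d", "og3")]
        calls = dup.classify_duplications(
            set(), genes, [("a", "b"), ("c", "d")], [], out_anchors
        )
        modes = {c.gene_id: c.mode for c in calls}
        assert modes["a"] == modes["b"] == "TRD"  # one member anchored
        assert modes["c"] == modes["d"] == "DSD"  # both anchored: not transposed

    def test_unknown_gene_rejected(self):
        genes = _genome({"chr1": ["a"]})
        with pytest.raises(ValueError, match="unknown"):
            dup.classify_duplications(set(), genes, [("a", "ghost")], [], [])

    def test_input_order_invariance(self, rng):
        genes = _genome({"chr1": [f"g{i}" for i in range(20)]})
        pairs = [("g0", "g1"), ("g0", "g5"), ("g3", "g15"), ("g5", "g6")]
        base = dup.classify_duplications(set(), genes, pairs, [], [])
        for _ in range(5):
            shuffled = [tuple(p) for p in rng.permutation(np.array(pairs, dtype=object))]
            again = dup.classify_duplications(set(), genes, shuffled, [], [])
            assert again == base


class TestPriorityOracle:
    def test_gene_mode_is_max_priority_over_pairs_random_genomes(self, rng):
        """Exhaustive rule-table oracle over random small genomes."""
        priority = {m: i for i, m in enumerate(MODES)}
        for trial in range(30):
            n = 12
            chroms = [f"chr{int(c)}" for c in rng.integers(1, 3, size=n)]
            ids = [f"g{i}" for i in range(n)]
            by_chrom: dict = {}
            for gid, ch in zip(ids, chroms):
                by_chrom.setdefault(ch, []).append(gid)
            genes = _genome(by_chrom)
            lookup = {g.gene_id: g for g in genes}
            k = int(rng.integers(1, 6))
            pairs = set()
            while len(pairs) < k:
                i, j = rng.choice(n, size=2, replace=False)
                pairs.add((ids[min(i, j)], ids[max(i, j)]))
            pairs = sorted(pairs)
            anchors = [p for p in pairs if rng.random() < 0.3]
            out_genes = {g for g in ids if rng.random() < 0.3}
            out_anchors = [(g, f"og_{g}") for g in sorted(out_genes)]

            def oracle_mode(a, b):
                ga, gb = lookup[a], lookup[b]
                if {a, b} in [set(x) for x in anchors]:
                    return "WGD"
                if ga.chrom == gb.chrom:
                    gap = abs(ga.order_rank - gb.order_rank)
                    if gap == 1:
                        return "TD"
                    if 2 <= gap <= 10:
                        return "PD"
                if (a in out_genes) + (b in out_genes) == 1:
                    return "TRD"
                return "DSD"

            calls = {
                c.gene_id: c.mode
                for c in dup.classify_duplications(
                    set(), genes, pairs, anchors, out_anchors
                )
            }
            for gid in ids:
                mine = [oracle_mode(a, b) for a, b in pairs if gid in (a, b)]
                expected = (
                    min(mine, key=lambda m: priority[m]) if mine else "singleton"
                )
                assert calls[gid] == expected, f"trial {trial}, gene {gid}"


class TestGeneratorRecovery:
    def test_all_planted_modes_recovered(self):
        genes, sa, oa, _recs, truth = make_duplicated_genome(
            1000, {m: 4 for m in MODES}, seed=9
        )
        pairs = [(a, b) for a, b, _m in truth.extra["pairs"]]
        calls = {c.gene_id: c.mode for c in dup.classify_duplications(
            truth.implanted_family_ids, genes, pairs, sa, oa
        )}
        assert all(calls[g] == m for g, m in truth.dup_mode_labels.items())


class TestEnrichment:
    @staticmethod
    def _calls(n_mode, n_other, prefix, mode="TD"):
        calls = [
            dup.DuplicationCall(f"{prefix}m{i}", mode, f"{prefix}m{i}p")
            for i in range(n_mode)
        ]
        calls += [
            dup.DuplicationCall(f"{prefix}o{i}", "singleton") for i in range(n_other)
        ]
        return calls

    def test_continuity_corrected_statistic_matches_hand_formula(self):
        """a=20,b=30,c=38,d=912: Yates chi2 = n(|ad-bc|-n/2)^2/(r1 r2 c1 c2)."""
        fam = self._calls(20, 30, "f")
        genome = fam + self._calls(38, 912, "g")
        res = {e.mode: e for e in dup.test_mode_enrichment(fam, genome)}
        td = res["TD"]
        assert (td.a, td.b, td.c, td.d) == (20, 30, 38, 912)
        assert td.chi2 == pytest.approx(106.180232, abs=1e-4)
        assert td.p < 1e-20
        assert td.direction == "enriched"

    def test_proportional_table_not_significant(self):
        fam = self._calls(5, 45, "f")
        genome = fam + self._calls(50, 450, "g")
        td = {e.mode: e for e in dup.test_mode_enrichment(fam, genome)}["TD"]
        assert td.chi2 == 0.0
        assert td.direction == "ns"

    def test_zero_family_count_direction_reduced(self):
        fam = self._calls(0, 40, "f")
        genome = fam + self._calls(100, 400, "g")
        td = {e.mode: e for e in dup.test_mode_enrichment(fam, genome)}["TD"]
        assert td.a == 0
        assert td.direction == ("reduced" if td.p < 0.05 else "ns")

    def test_row_swap_flips_direction_keeps_p(self):
        fam = self._calls(20, 30, "f")
        bg = self._calls(38, 912, "g")
        res1 = {e.mode: e for e in dup.test_mode_enrichment(fam, fam + bg)}["TD"]
        res2 = {e.mode: e for e in dup.test_mode_enrichment(bg, bg + fam)}["TD"]
        assert res1.p == pytest.approx(res2.p, rel=1e-9)
        assert {res1.direction, res2.direction} == {"enriched", "reduced"}

    def test_low_expected_cell_forces_ns(self):
        fam = self._calls(2, 3, "f")
        genome = fam + self._calls(1, 994, "g")
        with pytest.warns(UserWarning, match="expected cell"):
            td = {e.mode: e for e in dup.test_mode_enrichment(fam, genome)}["TD"]
        assert td.low_expected and td.direction == "ns"

    def test_planted_enrichment_detected_across_seeds(self):
        """Family mode fraction 0.4 vs background 0.04 is flagged enriched."""
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            fam_n = 50
            fam_td = int(r.binomial(fam_n, 0.4))
            bg_n = 950
            bg_td = int(r.binomial(bg_n, 0.04))
            fam = self._calls(fam_td, fam_n - fam_td, "f")
            genome = fam + self._calls(bg_td, bg_n - bg_td, "g")
            res = {e.mode: e for e in dup.test_mode_enrichment(fam, genome)}["TD"]
            hits += res.direction == "enriched"
        assert hits / n_rep >= 0.95
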