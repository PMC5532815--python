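"""Folding engine, structure distances, IRAlu pairing and impact metrics."""

import numpy as np
import pandas as pd
import pytest

from editvar import (DataError, ParameterError, UntestableError,
                     compare_impact_distributions, find_iralu_partner, fold,
                     simulate_iralu, snp_structure_impact, structure_distance)
from editvar.structure import (IraluPair, SnpStructureImpact,
                               pairing_from_dot_bracket)
from ._oracles import max_weighted_pairing

GU_PAIRS = {("G", "U"), ("U", "G")}


class TestFold:
    def test_no_complementarity_no_pairs(self):
        st = fold("AAAA")
        assert st.n_pairs == 0 and st.score == 0.0
        assert st.dot_bracket == "...."

    def test_simple_stem(self):
        st = fold("GGGAAACCC")
        assert st.dot_bracket == "(((...)))"
        assert st.n_pairs == 3            # the three G-C pairs
        assert st.score == 9.0            # weighted objective: 3 x GC

    def test_invalid_characters_rejected(self):
        with pytest.raises(DataError):
            fold("ACGX")

    def test_dna_alphabet_accepted(self):
        assert fold("GGGTTTCCC").n_pairs == 3      # T read as U

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), rng.integers(8, 17)))
        assert fold(seq).score == pytest.approx(max_weighted_pairing(seq))

    def test_structured_sequences_match_enumeration(self):
        for seq in ("GGCAGCAAAAGCUGCC", "GUGUGUAAAAACACAC",
                    "AAGGGCAAAAAAAGCCCAAUAAAAAAAAAA"):   # 30-mer
            assert fold(seq).score == pytest.approx(max_weighted_pairing(seq))

    def test_gu_pairs_never_terminate_helices(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGU"), rng.integers(15, 45)))
            st = fold(seq)
            pairs = {(i, int(j)) for i, j in enumerate(st.pairing)
                     if j >= 0 and i < j}
            for a, b in pairs:
                if (seq[a], seq[b]) in GU_PAIRS:
                    assert (a - 1, b + 1) in pairs and (a + 1, b - 1) in pairs

    def test_pairing_involution_and_nestedness(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGU"), rng.integers(10, 40)))
            st = fold(seq)
            p = st.pairing
            idx = np.flatnonzero(p >= 0)
            assert np.array_equal(p[p[idx]], idx)          # involution
            pairs = sorted((i, int(p[i])) for i in idx if i < p[i])
            for x, (a, b) in enumerate(pairs):             # no crossings
                for c, d in pairs[x + 1:]:
                    assert not (a < c < b < d)
            # minimum hairpin loop of 3 unpaired bases
            for a, b in pairs:
                inner = p[a + 1:b]
                if np.all(inner < 0):
                    assert b - a - 1 >= 3


class TestExternalFolder:
    def test_rnafold_adapter(self):
        st = fold("GGGAAACCC", mode="external")
        assert st.metric == "mfe_kcal_mol"
        assert st.score < 0
        assert st.n_pairs == 3

    def test_dot_bracket_parser(self):
        p = pairing_from_dot_bracket("((..).)")
        assert p[0] == 6 and p[1] == 4 and p[2] == -1


class TestStructureDistance:
    def test_backbone_and_pair_edges(self):
        st = fold("GGGAAACCC")
        assert structure_distance(st, 3, 4) == 1    # backbone
        assert structure_distance(st, 0, 8) == 1    # paired
        assert structure_distance(st, 0, 0) == 0

    def test_snp_opposite_editing_site_is_close(self):
        sim = simulate_iralu(21, 40, 0)
        st = fold(sim.sequence_allele1)
        assert structure_distance(st, sim.editing_offset, sim.snp_offset) <= 2

    def test_metric_properties_match_bfs_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), 30))
            st = fold(seq)
            g = nx.path_graph(30)
            for i, j in enumerate(st.pairing):
                if j > i:
                    g.add_edge(i, int(j))
            for _ in range(10):
                a, b = rng.integers(0, 30, 2)
                d = structure_distance(st, int(a), int(b))
                assert d == nx.shortest_path_length(g, int(a), int(b))
                assert d == structure_distance(st, int(b), int(a))


class TestIraluPartner:
    ALUS = pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "start": [1000, 1500, 8000, 20_000],
        "end": [1300, 1800, 8300, 20_300],
        "strand": ["+", "-", "-", "-"]})

    def test_inner_end_adjacency_is_tail_to_tail(self):
        pair = find_iralu_partner(1100, "chr1", self.ALUS)
        assert pair.orientation_class == "tail-to-tail"
        assert pair.alu1 == (1000, 1300, "+")
        assert pair.alu2 == (1500, 1800, "-")

    def test_closest_opposite_neighbor_wins(self):
        # host at 1000-1300 (+): candidates at 200 bp (1500) and 6.7 kb (8000)
        pair = find_iralu_partner(1200, "chr1", self.ALUS)
        assert pair.alu2[0] == 1500

    def test_head_to_head_class(self):
        alus = pd.DataFrame({"chrom": ["chr1"] * 2,
                             "start": [1000, 1500], "end": [1300, 1800],
                             "strand": ["-", "+"]})
        assert find_iralu_partner(1100, "chr1", alus).orientation_class == \
            "head-to-head"

    def test_no_partner_cases(self):
        same = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [1000, 1500],
                             "end": [1300, 1800], "strand": ["+", "+"]})
        assert find_iralu_partner(1100, "chr1", same) is None       # orientation
        assert find_iralu_partner(500, "chr1", self.ALUS) is None   # not in Alu
        assert find_iralu_partner(20_100, "chr1", self.ALUS,
                                  max_span=5000) is None            # too far


class TestSnpImpact:
    def _pair(self, sim):
        return IraluPair(chrom="", alu1=(), alu2=(), orientation_class="",
                         sequence=sim.sequence_allele1,
                         editing_offset=sim.editing_offset,
                         snp_offset=sim.snp_offset)

    def test_pair_breaking_snp_loses_at_least_one_pair(self):
        # NDE1-like geometry: allele 1 pairs with the editing-site partner,
        # allele 2 makes a mismatch bubble
        sim = simulate_iralu(5, 40, 0)
        imp = snp_structure_impact(self._pair(sim), sim.sequence_allele1,
                                   sim.sequence_allele2)
        assert imp.delta_pairs <= -1
        assert imp.delta_score < 0
        assert imp.spatial_distance <= 2

    def test_antisymmetric_in_allele_order(self):
        sim = simulate_iralu(6, 35, 4)
        fwd = snp_structure_impact(self._pair(sim), sim.sequence_allele1,
                                   sim.sequence_allele2)
        rev = snp_structure_impact(self._pair(sim), sim.sequence_allele2,
                                   sim.sequence_allele1)
        assert fwd.delta_pairs == -rev.delta_pairs
        assert fwd.delta_score == pytest.approx(-rev.delta_score)

    def test_neutral_snp_in_unpaired_context(self):
        # A -> C swap where the extra C can only displace an equivalent G-C
        # pair: the pair count is unchanged
        seq1 = "GGGGG" + "AAAAAAA" + "CCCCC" + "AAAA"
        seq2 = "GGGGG" + "AAAAAAA" + "CCCCC" + "AACA"
        pair = IraluPair(chrom="", alu1=(), alu2=(), orientation_class="",
                         sequence=seq1, editing_offset=6, snp_offset=19)
        imp = snp_structure_impact(pair, seq1, seq2)
        assert imp.delta_pairs == 0

    def test_single_difference_enforced(self):
        sim = simulate_iralu(7, 30, 0)
        with pytest.raises(DataError):
            snp_structure_impact(self._pair(sim), sim.sequence_allele1,
                                 sim.sequence_allele1)


class TestCompareImpacts:
    def test_identical_distributions_ks_zero(self):
        imps = [SnpStructureImpact(d, 0, 0.0, c)
                for c in ("significant", "control") for d in (1, 2, 3)]
        out = compare_impact_distributions(imps)
        assert out["spatial_distance"]["statistic"] == 0.0

    def test_ks_equals_brute_force_cdf_difference(self):
        rng = np.random.default_rng(4)
        sig = rng.integers(0, 5, 40)
        ctl = rng.integers(2, 12, 60)
        imps = [SnpStructureImpact(int(d), 0, 0.0, "significant") for d in sig]
        imps += [SnpStructureImpact(int(d), 0, 0.0, "control") for d in ctl]
        out = compare_impact_distributions(imps)
        grid = np.unique(np.concatenate([sig, ctl]))
        cdf_s = [(sig <= v).mean() for v in grid]
        cdf_c = [(ctl <= v).mean() for v in grid]
        brute = np.max(np.abs(np.array(cdf_s) - np.array(cdf_c)))
        assert out["spatial_distance"]["statistic"] == pytest.approx(brute)
        assert set(out["spatial_distance"]["cdf"].columns) == \
            {"value", "cdf_significant", "cdf_control"}

    def test_single_class_untestable(self):
        with pytest.raises(UntestableError):
            compare_impact_distributions(
                [SnpStructureImpact(1, 0, 0.0, "significant")])
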