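"""Distance, fold-change, agreement and couple-detection metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoflow import emt
from phenoflow.analysis import (
    ReferenceState,
    bland_altman,
    concordance_index,
    find_single_gene_couples,
    jaccard_needham,
    log2_fold_changes,
    project_to_reference,
    screen_high_efficiency,
    state_jnd,
    transformation_efficiency,
    weighted_jnd,
)
from phenoflow.dtmc_builder import PhenotypeDTMC, PhenotypeState
from phenoflow.dtmc_sim import PopulationTrajectory, simulate

from oracles import ref_jnd, ref_single_gene_pairs


class TestJaccardNeedham:
    def test_identical_patterns_distance_zero(self):
        assert jaccard_needham([1, 0, 1], [1, 0, 1]) == 0.0
        assert jaccard_needham([0, 0, 0], [0, 0, 0]) == 0.0  # empty union

    def test_published_all_off_phenotype_vs_lung_reference(self):
        pat = emt.HIGH_EFFICIENCY_PHENOTYPES[7]
        proj = project_to_reference(pat, emt.SIGNATURE_GENES, emt.A549_MESENCHYMAL)
        assert jaccard_needham(proj, emt.A549_MESENCHYMAL.bits) == 1.0

    def test_all_ones_vs_lung_reference(self):
        assert jaccard_needham(
            [1] * 7, emt.A549_MESENCHYMAL.bits
        ) == pytest.approx(2 / 7)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            jaccard_needham([1, 0], [1, 0, 1])

    def test_literal_mode_counts_shared_zeros(self):
        # both patterns all-zero: literal reading gives maximal distance
        assert jaccard_needham([0, 0], [0, 0], mode="literal") == 1.0
        assert jaccard_needham([1, 1], [1, 1], mode="literal") == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=16),
        st.integers(0, 2**16 - 1),
    )
    def test_symmetry_range_and_oracle(self, a, key):
        b = [(key >> i) & 1 for i in range(len(a))]
        d = jaccard_needham(a, b)
        assert 0.0 <= d <= 1.0
        assert d == jaccard_needham(b, a)
        assert d == pytest.approx(ref_jnd(a, b))


def _traj(prevalence, patterns, genes):
    return PopulationTrajectory(
        prevalence=np.array(prevalence, dtype=float),
        signature_genes=list(genes),
        patterns=[tuple(p) for p in patterns],
    )


class TestWeightedJND:
    REF = ReferenceState(("a", "b"), (1, 1))

    def test_all_mass_on_reference_pattern(self):
        traj = _traj([[1.0, 0.0]], [(1, 1), (0, 0)], ["a", "b"])
        assert weighted_jnd(traj, self.REF)[0] == 0.0

    def test_uniform_mass_over_zero_and_one_distance(self):
        traj = _traj([[0.5, 0.5]], [(1, 1), (0, 0)], ["a", "b"])
        assert weighted_jnd(traj, self.REF)[0] == pytest.approx(0.5)

    def test_matches_direct_summation_oracle(self, rng):
        genes = ["a", "b", "c"]
        ref = ReferenceState(("a", "c"), (1, 0))
        patterns = [tuple(rng.integers(0, 2, 3)) for _ in range(6)]
        prev = rng.dirichlet(np.ones(6), size=4)
        traj = _traj(prev, patterns, genes)
        series = weighted_jnd(traj, ref)
        d = state_jnd(patterns, genes, ref)
        for t in range(4):
            assert series[t] == pytest.approx(float(prev[t] @ d))

    def test_top_fraction_restricts_to_most_prevalent(self):
        # top-50% of 2 states = the single most prevalent one
        traj = _traj([[0.9, 0.1]], [(0, 0), (1, 1)], ["a", "b"])
        assert weighted_jnd(traj, self.REF, top_fraction=0.5)[0] == 1.0


class TestFoldChangesAndAgreement:
    def test_log2_fold_change_signs(self):
        genes = ["a", "b", "c"]
        patterns = [(1, 1, 1), (0, 1, 0)]
        prev = [[0.25, 0.75], [0.5, 0.5]]  # a: 0.25->0.5, b: 1->1, c: 0.25->0.5
        fc, excluded = log2_fold_changes(_traj(prev, patterns, genes))
        table = dict(zip(fc["gene_id"], fc["log2_fc"]))
        assert table["a"] == pytest.approx(1.0)
        assert table["b"] == pytest.approx(0.0)
        assert excluded == []

    def test_zero_initial_prevalence_excluded(self):
        genes = ["a", "b"]
        patterns = [(0, 1), (1, 1)]
        prev = [[1.0, 0.0], [0.5, 0.5]]
        fc, excluded = log2_fold_changes(_traj(prev, patterns, genes))
        assert excluded == ["a"]

    def test_concordance_counts_matching_signs(self):
        assert concordance_index([1, -1, 2], [3, -2, 1]) == 1.0
        assert concordance_index([1, -1], [-1, 1]) == 0.0
        assert concordance_index([1, 1, -1, 1, 1, 1, -1], [1, 1, -1, 1, 1, -1, 1]) \
            == pytest.approx(5 / 7)

    def test_concordance_and_bland_altman_permutation_invariant(self, rng):
        m = rng.normal(size=8)
        e = rng.normal(size=8)
        perm = rng.permutation(8)
        assert concordance_index(m, e) == concordance_index(m[perm], e[perm])
        a = bland_altman(m, e)
        b = bland_altman(m[perm], e[perm])
        assert a.bias == pytest.approx(b.bias)
        assert a.loa_high == pytest.approx(b.loa_high)

    def test_bland_altman_formula(self, rng):
        m = rng.normal(size=10)
        e = rng.normal(size=10)
        res = bland_altman(m, e)
        diffs = np.abs(m - e)
        assert res.bias == pytest.approx(diffs.mean())
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * diffs.std(ddof=1))

    def test_bland_altman_degenerate_cases(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.loa_low == res.loa_high == 0.0
        res = bland_altman([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert res.bias == pytest.approx(1.0)
        assert (res.loa_low, res.loa_high) == (pytest.approx(1.0), pytest.approx(1.0))


class TestTransformationEfficiency:
    def _two_state_chain(self):
        # state 0 (far from ref) absorbs into state 1 (= ref pattern)
        states = [PhenotypeState(0, (0, 0)), PhenotypeState(1, (1, 1))]
        P = np.array([[0.0, 1.0], [0.0, 1.0]])
        return PhenotypeDTMC(states, P, ["a", "b"])

    def test_absorbing_start_state_has_zero_efficiency(self):
        states = [PhenotypeState(0, (0, 0)), PhenotypeState(1, (1, 1))]
        P = np.eye(2)
        dtmc = PhenotypeDTMC(states, P, ["a", "b"])
        ref = ReferenceState(("a", "b"), (1, 1))
        assert transformation_efficiency(dtmc, 0, ref) == 0.0

    def test_absorption_into_reference_gives_full_drop(self):
        dtmc = self._two_state_chain()
        ref = ReferenceState(("a", "b"), (1, 1))
        assert transformation_efficiency(dtmc, 0, ref) == pytest.approx(1.0)

    def test_efficiency_bounded_by_initial_distance(self):
        from phenoflow.synthetic import random_chain

        dtmc = random_chain(n_genes=3, n_states=6, seed=5)
        ref = ReferenceState(("g0", "g1", "g2"), (1, 0, 1))
        d0 = state_jnd(dtmc.patterns(), dtmc.signature_genes, ref)
        for s in dtmc.states:
            eff = transformation_efficiency(dtmc, s.state_id, ref)
            assert eff <= d0[s.state_id] + 1e-12

    def test_screen_finds_engineered_high_efficiency_state(self):
        dtmc = self._two_state_chain()
        ref = ReferenceState(("a", "b"), (1, 1))
        assert screen_high_efficiency(dtmc, None, ref, threshold=0.40) == [0]
        assert screen_high_efficiency(dtmc, None, ref, threshold=2.0) == []


class TestSingleGeneCouples:
    def test_published_phenotype_table_yields_four_couples(self):
        couples = find_single_gene_couples(
            emt.HIGH_EFFICIENCY_PHENOTYPES, "FOXO6", emt.SIGNATURE_GENES
        )
        assert couples == [(7, 248), (13, 291), (24, 348), (77, 343)]

    def test_two_position_difference_excluded(self):
        patterns = {0: (0, 0, 0), 1: (1, 1, 0)}
        assert find_single_gene_couples(patterns, 0) == []

    def test_matches_all_pairs_oracle_on_random_sets(self, rng):
        patterns = {i: tuple(rng.integers(0, 2, 6)) for i in range(30)}
        for gene in range(6):
            ours = set(find_single_gene_couples(patterns, gene))
            assert ours == ref_single_gene_pairs(patterns, gene)
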