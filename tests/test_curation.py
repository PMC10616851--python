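"""Identity-by-state matching, duplicate sets, and misclassification flags."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import germbank as gb
from germbank import MISSING
from germbank.distance_phylo import DistanceMatrix

from conftest import matrix_from_calls

M = MISSING


class TestPairwiseIbs:
    def test_hand_example(self):
        G = matrix_from_calls(
            [[0, 0, 2, 2, 1, M, 2], [0, 2, 2, 2, M, 0, 1]], ["a", "b"]
        )
        m = gb.pairwise_ibs(G, "a", "b")
        assert (m.n_compared, m.n_matching) == (4, 3)
        assert m.ibs == 0.75

    def test_identical_and_opposite(self):
        G = matrix_from_calls([[0, 2, 0, 2]] * 2 + [[2, 0, 2, 0]], ["a", "b", "c"])
        assert gb.pairwise_ibs(G, "a", "b").ibs == 1.0
        assert gb.pairwise_ibs(G, "a", "c").ibs == 0.0

    def test_self_comparison_marker(self):
        G = matrix_from_calls([[0, 2, 1]], ["a"])
        m = gb.pairwise_ibs(G, "a", "a")
        assert m.self_comparison and m.ibs == 1.0

    def test_no_overlap_is_undefined(self):
        G = matrix_from_calls([[1, M], [M, 1]], ["a", "b"])
        assert gb.pairwise_ibs(G, "a", "b").ibs is None

    @given(
        st.lists(
            st.tuples(st.sampled_from([0, 1, 2, M]), st.sampled_from([0, 1, 2, M])),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_symmetry_and_het_missing_invariance(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        G = matrix_from_calls([a, b], ["a", "b"])
        m1, m2 = gb.pairwise_ibs(G, "a", "b"), gb.pairwise_ibs(G, "b", "a")
        assert (m1.n_compared, m1.n_matching) == (m2.n_compared, m2.n_matching)
        # appending a locus where both calls are het/missing changes nothing
        G2 = matrix_from_calls([a + [1], b + [M]], ["a", "b"])
        m3 = gb.pairwise_ibs(G2, "a", "b")
        assert (m3.n_compared, m3.n_matching) == (m1.n_compared, m1.n_matching)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1, 2, M], size=(8, 50), p=[0.4, 0.1, 0.4, 0.1])
        G = matrix_from_calls(calls)
        ibs, n_cmp = gb.ibs_matrix(G)
        for i, a in enumerate(G.accession_ids):
            for j, b in enumerate(G.accession_ids):
                m = gb.pairwise_ibs(G, a, b)
                assert n_cmp[i, j] == m.n_compared
                if m.ibs is None:
                    assert np.isnan(ibs[i, j])
                else:
                    assert ibs[i, j] == pytest.approx(m.ibs, abs=1e-12)


def _with_flips(rng, row, k):
    out = row.copy()
    idx = rng.choice(len(row), size=k, replace=False)
    out[idx] = 2 - out[idx]
    return out, set(idx)


class TestFindDuplicates:
    def test_triplet_of_copies_forms_one_group(self):
        rng = np.random.default_rng(1)
        base = rng.choice([0, 2], size=1000).astype(np.int8)
        other = rng.choice([0, 2], size=1000).astype(np.int8)
        G = matrix_from_calls([base, base, base, other], ["a", "b", "c", "d"])
        res = gb.find_duplicates(G, prefilter=None)
        assert res.groups == [["a", "b", "c"]]

    def test_sub_threshold_pair_stays_ungrouped(self):
        rng = np.random.default_rng(2)
        base = rng.choice([0, 2], size=1000).astype(np.int8)
        far, _ = _with_flips(rng, base, 50)  # ibs 0.95
        G = matrix_from_calls([base, far], ["a", "b"])
        res = gb.find_duplicates(G, prefilter=None)
        assert res.groups == []

    def test_chain_closure_with_annotated_pair(self):
        rng = np.random.default_rng(3)
        a = rng.choice([0, 2], size=1000).astype(np.int8)
        b = a.copy()
        b[:5] = 2 - b[:5]       # ibs(a,b) = 0.995
        c = b.copy()
        c[5:15] = 2 - c[5:15]   # ibs(b,c) = 0.990? no: 10 flips -> 0.99
        c[5:11] = 2 - c[5:11]   # undo some: net 4 flips vs b -> 0.996
        # now ibs(a,c): differs at 0..4 and 11..14 -> 9 flips -> 0.991?
        G = matrix_from_calls([a, b, c], ["a", "b", "c"])
        iab = gb.pairwise_ibs(G, "a", "b").ibs
        ibc = gb.pairwise_ibs(G, "b", "c").ibs
        iac = gb.pairwise_ibs(G, "a", "c").ibs
        thr = 0.992
        assert iab > thr and ibc > thr and iac <= thr + 1e-12
        res = gb.find_duplicates(G, prefilter=None, ibs_threshold=thr)
        assert res.groups == [["a", "b", "c"]]  # closure over the chain
        annotated = {(m.accession_a, m.accession_b) for m in res.sub_threshold_within_groups}
        assert ("a", "c") in annotated

    def test_low_overlap_pairs_are_excluded(self):
        a = np.array([0, 2] * 10 + [M] * 980, dtype=np.int8)
        b = np.array([0, 2] * 10 + [M] * 980, dtype=np.int8)
        G = matrix_from_calls([a, b], ["a", "b"])
        res = gb.find_duplicates(G, prefilter=None, min_overlap=100)
        assert res.groups == []
        assert [(m.accession_a, m.accession_b) for m in res.low_overlap_pairs] == [("a", "b")]

    def test_recovers_planted_duplicates_exactly(self, default_panel):
        _, G, records, truth, _ = default_panel
        res = gb.find_duplicates(G, records)
        assert [list(g) for g in res.groups] == truth.duplicate_sets

    def test_groups_are_disjoint_without_singletons(self, default_panel):
        _, G, records, _, _ = default_panel
        res = gb.find_duplicates(G, records)
        seen: set[str] = set()
        for group in res.groups:
            assert len(group) >= 2
            assert not (seen & set(group))
            seen |= set(group)


class TestFlagMisclassified:
    def _records(self, labels):
        return [gb.AccessionRecord(a, sp) for a, sp in labels.items()]

    def test_single_mislabeled_member_is_flagged(self):
        # two tight clusters of three; f is genetically in cluster 1 but
        # recorded as species2
        labels = {"a": "sp1", "b": "sp1", "f": "sp2", "c": "sp2", "d": "sp2", "e": "sp2"}
        ids = list(labels)
        pos = {"a": 0.0, "b": 0.1, "f": 0.2, "c": 10.0, "d": 10.1, "e": 10.2}
        vals = np.array([[abs(pos[x] - pos[y]) for y in ids] for x in ids])
        D = DistanceMatrix(ids, vals)
        flags = gb.flag_misclassified(D, self._records(labels), k=2)
        assert len(flags) == 1
        f = flags[0]
        assert (f.accession_id, f.suggested_species, f.support) == ("f", "sp1", 1.0)

    def test_consistent_labels_yield_no_flags(self):
        labels = {"a": "sp1", "b": "sp1", "c": "sp2", "d": "sp2"}
        ids = list(labels)
        pos = {"a": 0.0, "b": 0.1, "c": 5.0, "d": 5.1}
        D = DistanceMatrix(ids, np.array([[abs(pos[x] - pos[y]) for y in ids] for x in ids]))
        assert gb.flag_misclassified(D, self._records(labels), k=1) == []

    def test_majority_tie_produces_no_flag(self):
        labels = {"a": "sp1", "b": "sp2", "c": "sp3", "d": "sp3"}
        ids = list(labels)
        vals = np.ones((4, 4)) - np.eye(4)
        D = DistanceMatrix(ids, vals)
        # for "a" with k=2, neighbors b (sp2) and c (sp3) tie 1-1
        flags = gb.flag_misclassified(D, self._records(labels), k=2)
        assert all(f.accession_id != "a" for f in flags)

    def test_recovers_planted_label_errors(self, default_panel, default_distance):
        _, _, records, truth, _ = default_panel
        flags = gb.flag_misclassified(default_distance, records, k=5)
        flagged = {f.accession_id: f.suggested_species for f in flags}
        # every flag points at a planted error and suggests the true species
        assert flagged == truth.mislabeled
        assert all(f.support > 0.5 for f in flags)
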