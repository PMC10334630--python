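"""Unit and property tests for the persistence transformation of one spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topoms import (
    Spectrum,
    build_merge_tree,
    find_peaks,
    persistence_transformation,
    reduced_persistence_transformation,
    to_persistence_diagram,
    top_k_percent,
)
from topoms.reference import sweep_persistence


def triples(features):
    return sorted(
        (int(i), float(b), float(d))
        for i, b, d in zip(features["index"], features["birth"], features["death"])
    )


class TestFindPeaks:
    @pytest.mark.parametrize(
        "intensities, expected_indices",
        [
            ((0, 2, 2, 1), [1]),  # interior plateau collapsed to leftmost index
            ((1, 0, 1), [0, 2]),  # boundary maxima
            ((7, 7, 7), [0]),  # constant spectrum convention
            ((0, 1, 2, 3), [3]),
            ((3, 2, 1), [0]),
            ((5,), [0]),
            ((1, 2, 2, 3), [3]),  # non-peak plateau is not reported
        ],
    )
    def test_plateau_collapsed_maxima(self, intensities, expected_indices):
        peaks = find_peaks(np.array(intensities, dtype=float))
        assert peaks["index"].tolist() == expected_indices
        assert np.array_equal(peaks["apex"], np.asarray(intensities)[expected_indices])


class TestPersistenceTransformation:
    @pytest.mark.parametrize(
        "intensities, expected",
        [
            ((0, 3, 1, 2, 0), [(1, 3.0, 0.0), (3, 2.0, 1.0)]),
            ((0, 1, 2, 3), [(3, 3.0, 0.0)]),  # monotone: one component throughout
            ((2, 1, 2), [(0, 2.0, 1.0), (2, 2.0, 1.0)]),  # equal-birth tie
        ],
    )
    def test_feature_triples(self, intensities, expected):
        feats = persistence_transformation(np.array(intensities, dtype=float))
        assert triples(feats) == expected

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            persistence_transformation(np.array([]))

    def test_positions_follow_mz_axis(self):
        s = Spectrum(positions=[100.0, 200.0, 300.0], intensities=[1.0, 5.0, 2.0])
        feats = persistence_transformation(s)
        assert feats["position"].tolist() == [200.0]

    def test_feature_count_equals_peak_count(self, small_corpus):
        for vals in small_corpus:
            assert persistence_transformation(vals).size == find_peaks(vals).size

    def test_global_feature_and_value_ranges(self, small_corpus):
        for vals in small_corpus:
            feats = persistence_transformation(vals)
            lo, hi = vals.min(), vals.max()
            assert np.all(feats["birth"] >= feats["death"])
            assert np.all((feats["death"] >= lo) & (feats["birth"] <= hi))
            # The merge-tree root is the unique global feature spanning the
            # full intensity range; with tied intensities other equal-height
            # peaks may also die at the global minimum, but none exceeds it.
            mt = build_merge_tree(vals)
            root = mt.features[mt.root]
            assert root["birth"] == hi and root["death"] == lo
            assert feats["persistence"].max() == hi - lo

    def test_distinct_values_give_unique_global_feature(self, rng):
        for _ in range(60):
            q = int(rng.integers(2, 80))
            vals = rng.permutation(np.arange(q)).astype(float)
            feats = persistence_transformation(vals)
            is_global = (feats["birth"] == q - 1) & (feats["death"] == 0)
            assert is_global.sum() == 1

    def test_matches_sweep_oracle(self, small_corpus):
        for vals in small_corpus:
            ofeats, _ = sweep_persistence(vals)
            assert triples(persistence_transformation(vals)) == ofeats

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=6), min_size=1, max_size=40
        ).map(lambda xs: np.array(xs, dtype=float))
    )
    def test_oracle_agreement_property(self, vals):
        ofeats, _ = sweep_persistence(vals)
        assert triples(persistence_transformation(vals)) == ofeats

    def test_directional_barrier_rule(self, small_corpus):
        """Deaths equal the larger of the two path-minimum barriers to the
        nearest taller point (equal-height counts as taller on the left,
        where the elder lives); the global maximum dies at the global min."""
        for vals in small_corpus[:80]:
            feats = persistence_transformation(vals)
            for i, b, d in zip(feats["index"], feats["birth"], feats["death"]):
                cands = []
                run = np.inf
                for j in range(int(i) - 1, -1, -1):
                    if vals[j] >= b:
                        cands.append(run)
                        break
                    run = min(run, vals[j])
                run = np.inf
                for j in range(int(i) + 1, len(vals)):
                    if vals[j] > b:
                        cands.append(run)
                        break
                    run = min(run, vals[j])
                assert d == (max(cands) if cands else vals.min())


class TestReducedTransformation:
    def test_projection_of_full_transformation(self, small_corpus):
        for vals in small_corpus[:50]:
            full = persistence_transformation(vals)
            red = reduced_persistence_transformation(vals)
            assert np.array_equal(red["index"], full["index"])
            assert np.array_equal(red["persistence"], full["birth"] - full["death"])

    @pytest.mark.parametrize(
        "intensities, expected",
        [
            ((0, 3, 1, 2, 0), [(1, 3.0), (3, 1.0)]),
            ((7, 7, 7), [(0, 0.0)]),
        ],
    )
    def test_examples(self, intensities, expected):
        red = reduced_persistence_transformation(np.array(intensities, dtype=float))
        assert [(int(i), float(p)) for i, p in zip(red["index"], red["persistence"])] == expected


class TestPersistenceDiagram:
    def test_projection_drops_positions(self):
        feats = persistence_transformation(np.array([0.0, 3, 1, 2, 0]))
        dgm = to_persistence_diagram(feats)
        assert sorted(map(tuple, dgm)) == [(2.0, 1.0), (3.0, 0.0)]

    def test_single_point_spectrum(self):
        dgm = to_persistence_diagram(persistence_transformation(np.array([5.0])))
        assert dgm.tolist() == [[5.0, 5.0]]

    def test_mirror_spectra_share_diagram_but_not_triples(self, rng):
        """Mirror pairs are indistinguishable by the diagram yet separated by
        the position-preserving transformation."""
        for _ in range(50):
            q = int(rng.integers(8, 60))
            vals = rng.permutation(np.arange(1, q + 1)).astype(float)
            if find_peaks(vals).size < 2:
                continue
            fwd = persistence_transformation(vals)
            rev = persistence_transformation(vals[::-1])
            dgm_f = sorted(map(tuple, to_persistence_diagram(fwd)))
            dgm_r = sorted(map(tuple, to_persistence_diagram(rev)))
            assert dgm_f == dgm_r
            assert triples(fwd) != triples(rev)


class TestMergeTree:
    def test_parent_and_root(self):
        mt = build_merge_tree(np.array([0.0, 3, 1, 2, 0]))
        assert mt.features["index"][mt.root] == 1
        child = int(np.flatnonzero(mt.features["index"] == 3)[0])
        assert mt.parent[child] == mt.root

    def test_single_point(self):
        mt = build_merge_tree(np.array([5.0]))
        assert mt.features.size == 1 and mt.parent.tolist() == [-1]

    def test_equal_birth_parent_resolved_by_index(self):
        mt = build_merge_tree(np.array([2.0, 1, 2]))
        assert mt.features["index"][mt.root] == 0
        child = int(np.flatnonzero(mt.features["index"] == 2)[0])
        assert mt.parent[child] == mt.root

    def test_elder_rule_parent_birth_dominates(self, small_corpus):
        for vals in small_corpus[:60]:
            mt = build_merge_tree(vals)
            for child, parent in enumerate(mt.parent):
                if parent >= 0:
                    cb, pb = mt.features["birth"][[child, parent]]
                    ci, pi = mt.features["index"][[child, parent]]
                    assert (pb, -pi) > (cb, -ci)  # parent strictly elder
                    assert mt.features["death"][child] <= cb

    def test_matches_oracle_parents(self, small_corpus):
        for vals in small_corpus[:80]:
            mt = build_merge_tree(vals)
            got = {}
            for child, parent in enumerate(mt.parent):
                key = int(mt.features["index"][child])
                got[key] = None if parent < 0 else int(mt.features["index"][parent])
            _, oparents = sweep_persistence(vals)
            assert got == oparents


class TestTopKPercent:
    def make(self, persistences):
        red = np.zeros(len(persistences), dtype=[("index", np.int64),
                                                 ("position", np.float64),
                                                 ("persistence", np.float64)])
        red["index"] = np.arange(len(persistences))
        red["position"] = red["index"]
        red["persistence"] = persistences
        return red

    def test_ceiling_rule(self):
        feats = self.make([5.0, 3.0, 1.0, 0.5])
        assert top_k_percent(feats, 50)["persistence"].tolist() == [5.0, 3.0]
        assert top_k_percent(feats, 10)["persistence"].tolist() == [5.0]

    def test_k_100_is_identity(self):
        feats = self.make([1.0, 4.0, 2.0])
        assert np.array_equal(top_k_percent(feats, 100), feats)

    @pytest.mark.parametrize("k", [0, -5, 101])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            top_k_percent(self.make([1.0]), k)

    def test_cutoff_ties_prefer_smaller_index(self):
        feats = self.make([2.0, 1.0, 1.0, 1.0])
        kept = top_k_percent(feats, 50)
        assert kept["index"].tolist() == [0, 1]

    def test_global_feature_always_retained(self, small_corpus):
        for vals in small_corpus[:60]:
            red = reduced_persistence_transformation(vals)
            pmax = red["persistence"].max()
            global_idx = red["index"][red["persistence"] == pmax].min()
            for k in (1, 10, 33):
                kept = top_k_percent(red, k)
                assert kept.size >= 1
                assert global_idx in kept["index"]

    def test_nested_support_in_k(self, small_corpus):
        for vals in small_corpus[:40]:
            red = reduced_persistence_transformation(vals)
            prev = set()
            for k in (10, 25, 50, 100):
                kept = set(top_k_percent(red, k)["index"].tolist())
                assert prev <= kept
                prev = kept


class TestScalingContract:
    def test_long_spectrum_no_recursion_failure(self, rng):
        q = 120_000
        vals = np.abs(np.sin(np.linspace(0, 40 * np.pi, q))) * 10 + rng.random(q)
        feats = persistence_transformation(vals)
        assert feats.size == find_peaks(vals).size >= 1
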