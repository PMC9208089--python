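"""Odds ratios, correlations, clustering, moiety tagging, occurrence stats."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

from panmoiety.analysis import (
    FamilyImportanceMatrix,
    build_importance_matrix,
    cluster_families,
    importance_or_correlation,
    occurrence_percentage,
    odds_ratios,
    tag_moieties,
)
from panmoiety.explanation import ImportanceProfile
from panmoiety.featurization import FeatureMatrix


def matrix_from_bits(bits):
    bits = np.asarray(bits)
    return FeatureMatrix(
        [f"C{i}" for i in range(bits.shape[0])],
        [f"f-{j+1}" for j in range(bits.shape[1])],
        bits,
    )


def profile(family, scores, selected=None, feature_ids=None):
    scores = np.asarray(scores, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f-{i+1}" for i in range(len(scores))]
    z = (scores - scores.mean()) / (scores.std() or 1.0)
    p = ImportanceProfile(family, list(feature_ids), scores, z, 1, 1)
    p.selected = selected or []
    return p


class TestOddsRatios:
    def _table(self, a, b, c, d):
        bits = np.array([[1]] * a + [[0]] * b + [[1]] * c + [[0]] * d)
        labels = np.array([1] * (a + b) + [0] * (c + d))
        return odds_ratios(matrix_from_bits(bits), labels)

    def test_independence_gives_unity(self):
        t = self._table(10, 10, 10, 10)
        assert t.odds_ratio[0] == pytest.approx(1.0)
        assert not t.correction_used[0]

    def test_hand_computed_value(self):
        assert self._table(20, 5, 5, 20).odds_ratio[0] == pytest.approx(16.0)

    def test_zero_cell_corrected(self):
        t = self._table(10, 5, 0, 10)
        assert np.isfinite(t.odds_ratio[0]) and t.odds_ratio[0] > 0
        assert t.correction_used[0]

    def test_row_permutation_invariance(self, rng):
        bits = (rng.random((60, 5)) < 0.4).astype(int)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        perm = rng.permutation(60)
        a = odds_ratios(matrix_from_bits(bits), labels)
        b = odds_ratios(matrix_from_bits(bits[perm]), labels[perm])
        assert a.odds_ratio == pytest.approx(b.odds_ratio)

    def test_independent_feature_converges_to_unity(self):
        rng = np.random.default_rng(123)
        bits = (rng.random((20000, 1)) < 0.3).astype(int)
        labels = rng.integers(0, 2, 20000)
        t = odds_ratios(matrix_from_bits(bits), labels)
        assert t.odds_ratio[0] == pytest.approx(1.0, abs=0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            odds_ratios(matrix_from_bits([[1], [0]]), np.array([1, 1]))


class TestCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        p = profile("fam", scores, selected=["f-1", "f-2", "f-3", "f-4"])
        ors = odds_ratios(
            matrix_from_bits(np.eye(4, dtype=int)), np.array([1, 1, 0, 0])
        )
        ors.odds_ratio = 2.0 * scores + 1.0
        assert importance_or_correlation(p, ors) == pytest.approx(1.0)
        ors.odds_ratio = -2.0 * scores + 1.0
        assert importance_or_correlation(p, ors) == pytest.approx(-1.0)

    def test_shuffled_ors_decorrelate(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=15)
        ids = [f"f-{i+1}" for i in range(15)]
        p = profile("fam", scores, selected=ids)
        ors = odds_ratios(
            matrix_from_bits((rng.random((40, 15)) < 0.5).astype(int)),
            np.r_[np.ones(20, int), np.zeros(20, int)],
        )
        rs = []
        base = ors.odds_ratio.copy()
        for _ in range(1000):
            ors.odds_ratio = rng.permutation(base)
            rs.append(importance_or_correlation(p, ors))
        se = np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 1e-3

    def test_too_few_features_rejected(self):
        p = profile("fam", [1.0, 2.0], selected=["f-1", "f-2"])
        ors = odds_ratios(matrix_from_bits([[1, 0], [0, 1]]), np.array([1, 0]))
        with pytest.raises(ValueError, match=">= 3"):
            importance_or_correlation(p, ors)

    def test_zero_variance_rejected(self):
        p = profile("fam", [1.0, 1.0, 1.0], selected=["f-1", "f-2", "f-3"])
        ors = odds_ratios(matrix_from_bits(np.eye(3, dtype=int)), np.array([1, 0, 1]))
        with pytest.raises(ValueError, match="variance"):
            importance_or_correlation(p, ors)


class TestImportanceMatrix:
    def test_disjoint_selections_concatenate(self):
        scores = np.arange(40.0)
        a = profile("A", scores, selected=[f"f-{i}" for i in range(1, 16)])
        b = profile("B", scores, selected=[f"f-{i}" for i in range(16, 31)])
        m = build_importance_matrix([a, b])
        assert len(m.feature_union) == 30
        assert m.scores.shape == (2, 30)

    def test_identical_selections_do_not_duplicate(self):
        scores = np.arange(40.0)
        sel = [f"f-{i}" for i in range(1, 16)]
        m = build_importance_matrix([profile("A", scores, sel), profile("B", scores, sel)])
        assert len(m.feature_union) == 15

    def test_mismatched_feature_spaces_rejected(self):
        a = profile("A", [1.0, 2.0], selected=["f-1"])
        b = profile("B", [1.0, 2.0], selected=["f-1"], feature_ids=["g-1", "g-2"])
        with pytest.raises(ValueError, match="mismatched"):
            build_importance_matrix([a, b])

    def test_cells_are_scores(self):
        scores_a = np.array([5.0, 1.0, 0.0])
        scores_b = np.array([2.0, 4.0, 0.0])
        m = build_importance_matrix(
            [profile("A", scores_a, ["f-1"]), profile("B", scores_b, ["f-2"])]
        )
        assert m.feature_union == ["f-1", "f-2"]
        assert m.scores[0].tolist() == [5.0, 1.0]
        assert m.scores[1].tolist() == [2.0, 4.0]


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        row = np.array([1.0, 2.0, 3.0, 1.0])
        m = FamilyImportanceMatrix(["A", "B", "C"], [f"f-{i}" for i in range(4)],
                                   np.vstack([row, row, row[::-1]]))
        Z, names = cluster_families(m)
        assert names == ["A", "B", "C"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_distances_within_correlation_range(self, rng):
        scores = rng.normal(size=(5, 10))
        m = FamilyImportanceMatrix([f"F{i}" for i in range(5)],
                                   [f"f-{i}" for i in range(10)], scores)
        Z, _ = cluster_families(m)
        assert (Z[:, 2] >= -1e-12).all() and (Z[:, 2] <= 2 + 1e-12).all()

    def test_constant_profile_rejected(self):
        m = FamilyImportanceMatrix(["A", "B"], ["f-1", "f-2"],
                                   np.array([[1.0, 1.0], [0.0, 2.0]]))
        with pytest.raises(ValueError, match="A"):
            cluster_families(m)

    def test_shared_block_structure_recovers_groups(self, rng):
        # two groups of two families sharing group-level signal
        base = {"G1": rng.normal(size=12), "G2": rng.normal(size=12)}
        rows, names = [], []
        for g in ("G1", "G2"):
            for f in ("a", "b"):
                rows.append(base[g] + 0.3 * rng.normal(size=12))
                names.append(f"{g}{f}")
        m = FamilyImportanceMatrix(names, [f"f-{i}" for i in range(12)], np.array(rows))
        Z, ordered = cluster_families(m)
        clusters = fcluster(Z, 2, criterion="maxclust")
        by_cluster = {}
        for name, c in zip(ordered, clusters):
            by_cluster.setdefault(c, set()).add(name[:2])
        assert all(len(groups) == 1 for groups in by_cluster.values())


class TestTagging:
    def _profiles(self, selections):
        scores = np.arange(10.0)
        return [profile(f, scores, sel) for f, sel in selections.items()]

    def test_definitions(self):
        selections = {
            "A": ["f-1", "f-2"],
            "B": ["f-1", "f-3"],
            "C": ["f-1", "f-3"],
            "D": ["f-1", "f-4"],
        }
        profiles = self._profiles(selections)
        m = build_importance_matrix(profiles)
        g = tag_moieties(m, profiles, common_min_families=3, specific_max_families=1)
        assert g.common == ["f-1"]
        assert g.specific["A"] == ["f-2"]
        assert g.specific["D"] == ["f-4"]
        assert g.remainder == ["f-3"]  # in 2 families: neither common nor specific

    def test_partitions_the_union(self, rng):
        selections = {
            f"F{i}": list(
                np.random.default_rng(i).choice(
                    [f"f-{j}" for j in range(1, 11)], size=4, replace=False
                )
            )
            for i in range(6)
        }
        profiles = self._profiles(selections)
        m = build_importance_matrix(profiles)
        g = tag_moieties(m, profiles)
        tagged = set(g.common) | set(g.remainder)
        for fam_specific in g.specific.values():
            assert tagged.isdisjoint(fam_specific)
            tagged |= set(fam_specific)
        assert tagged == set(m.feature_union)


class TestOccurrence:
    def test_ubiquitous_moiety_is_hundred_percent(self):
        fm = matrix_from_bits(np.ones((4, 2), dtype=int))
        assert occurrence_percentage(fm, ["f-1"]) == pytest.approx(100.0)

    def test_group_average(self):
        bits = np.array([[1, 1], [1, 0], [1, 0], [0, 0]])
        fm = matrix_from_bits(bits)
        # f-1 in 3/4 ligands (75%), f-2 in 1/4 (25%) -> mean 50%
        assert occurrence_percentage(fm, ["f-1", "f-2"]) == pytest.approx(50.0)

    def test_absent_moiety_is_zero(self):
        fm = matrix_from_bits(np.zeros((3, 1), dtype=int))
        assert occurrence_percentage(fm, ["f-1"]) == pytest.approx(0.0)

    def test_empty_inputs_rejected(self):
        fm = matrix_from_bits(np.ones((2, 1), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            occurrence_percentage(fm, [])
        empty = FeatureMatrix([], ["f-1"], np.zeros((0, 1)))
        with pytest.raises(ValueError, match="empty"):
            occurrence_percentage(empty, ["f-1"])
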