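"""Selection-stage correctness against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from retestconn.selection import (
    BUNDLE_MAX_LINK_MM,
    Bundle,
    ParcelEdge,
    bundles_to_parcel_edges,
    cluster_bundles,
    connection_distance_matrix,
    modulation_direction,
    paired_t_contrast,
    parcel_aggregate,
    power_screen,
    threshold_connections,
)

from helpers import make_geometry, make_parcellation, make_tensor


class TestPairedT:
    def test_matches_textbook_formula(self):
        diffs = np.array([0.05, 0.07, 0.06, 0.08, 0.04])
        tensor = make_tensor(diffs.reshape(5, 1, 1).repeat(2, axis=1))
        res = paired_t_contrast(tensor, "b", "w", session=1)
        t_expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        p_expected = 2 * sps.t.sf(abs(t_expected), df=4)
        assert res.t[0] == pytest.approx(t_expected, rel=1e-12)
        assert res.p[0] == pytest.approx(p_expected, rel=1e-12)
        assert res.mean_contrast[0] == pytest.approx(0.06)

    def test_sign_symmetry(self, rng):
        diffs = rng.normal(0.02, 0.01, size=(8, 2, 3))
        pos = paired_t_contrast(make_tensor(diffs), "b", "w")
        neg = paired_t_contrast(make_tensor(-diffs), "b", "w")
        np.testing.assert_allclose(neg.t, -pos.t, rtol=1e-9)
        np.testing.assert_allclose(neg.p, pos.p, rtol=1e-9)

    def test_identical_conditions_flagged_degenerate(self):
        tensor = make_tensor(np.zeros((5, 2, 2)))
        res = paired_t_contrast(tensor, "b", "w")
        assert res.degenerate.all()
        assert np.isnan(res.t).all()
        assert (res.mean_contrast == 0).all()

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            paired_t_contrast(make_tensor(np.zeros((2, 2, 1))), "b", "w")


class TestThreshold:
    def _setup(self, rng, m=50):
        diffs = rng.normal(0, 0.01, size=(10, 2, m))
        pairs = np.column_stack([np.arange(m), np.arange(m) + m])
        coords = rng.uniform(-60, 60, size=(2 * m, 3))
        tensor = make_tensor(diffs, pairs=pairs)
        geometry = make_geometry(coords, parcel_id=np.zeros(2 * m, int))
        return tensor, geometry

    def test_distance_filter_boundary(self):
        # one connection, endpoints 39 mm apart, wildly significant
        diffs = 0.05 + np.random.default_rng(0).normal(0, 1e-4, (6, 2, 1))
        tensor = make_tensor(diffs, pairs=np.array([[0, 1]]))
        near = make_geometry([[0, 0, 0], [39, 0, 0]])
        far = make_geometry([[0, 0, 0], [40, 0, 0]])
        st = paired_t_contrast(tensor, "b", "w")
        assert st.p[0] < 1e-6
        assert len(threshold_connections(st, tensor, near, alpha=1e-3)) == 0
        assert len(threshold_connections(st, tensor, far, alpha=1e-3)) == 1

    def test_stricter_alpha_is_nested(self, rng):
        tensor, geometry = self._setup(rng)
        st = paired_t_contrast(tensor, "b", "w")
        a = set(threshold_connections(st, tensor, geometry, 1e-1, min_endpoint_distance=0))
        b = set(threshold_connections(st, tensor, geometry, 1e-2, min_endpoint_distance=0))
        assert b <= a


class TestBundles:
    def _line_connections(self, n, spacing=5.0, origin=0.0):
        """n parallel connections spaced along x, each 60 mm long in z."""
        a = np.array([[origin + i * spacing, 0.0, 0.0] for i in range(n)])
        b = a + [0.0, 0.0, 60.0]
        coords = np.vstack([a, b])
        pairs = np.column_stack([np.arange(n), np.arange(n) + n])
        return coords, pairs

    def _cluster(self, coords, pairs, **kw):
        tensor = make_tensor(np.zeros((3, 2, len(pairs))), pairs=pairs)
        geometry = make_geometry(coords, parcel_id=np.zeros(len(coords), int))
        return cluster_bundles(np.arange(len(pairs)), tensor, geometry, **kw)

    def test_min_size_boundary(self):
        coords, pairs = self._line_connections(19)
        assert self._cluster(coords, pairs) == []
        coords, pairs = self._line_connections(20)
        bundles = self._cluster(coords, pairs)
        assert len(bundles) == 1 and bundles[0].size == 20

    def test_two_separated_groups(self):
        c1, p1 = self._line_connections(25)
        c2, p2 = self._line_connections(25, origin=500.0)
        coords = np.vstack([c1, c2])
        pairs = np.vstack([p1, p2 + len(c1)])
        bundles = self._cluster(coords, pairs)
        assert len(bundles) == 2
        assert sorted(b.size for b in bundles) == [25, 25]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_transitive_closure(self, seed):
        rng = np.random.default_rng(seed)
        m = 100
        coords = rng.uniform(-40, 40, size=(2 * m, 3))
        pairs = np.column_stack([np.arange(m), np.arange(m) + m])
        tensor = make_tensor(np.zeros((3, 2, m)), pairs=pairs)
        geometry = make_geometry(coords, parcel_id=np.zeros(2 * m, int))
        bundles = cluster_bundles(np.arange(m), tensor, geometry, min_size=1)

        # independent oracle: Warshall transitive closure of the link relation
        d = connection_distance_matrix(coords[:m], coords[m:])
        reach = d <= BUNDLE_MAX_LINK_MM
        for k in range(m):
            reach = reach | (reach[:, [k]] & reach[[k], :])
        oracle_components = set()
        for i in range(m):
            oracle_components.add(frozenset(np.flatnonzero(reach[i])))
        got = {frozenset(b.members) for b in bundles}
        assert got == oracle_components

    def test_connection_distance_is_best_pairing_max(self):
        # c1 = (0,0,0)-(0,0,60); c2 = (0,0,60)-(0,0,0) reversed: distance 0
        coords = np.array([[0, 0, 0], [0, 0, 60], [0, 0, 60.0], [0, 0, 0]])
        d = connection_distance_matrix(coords[[0, 2]], coords[[1, 3]])
        assert d[0, 1] == pytest.approx(0.0)


class TestParcelEdges:
    def _toy(self):
        # 6 points: parcels 0,1 left; 2 right (included), 3 right (excluded)
        coords = [[-50, 0, 0], [-50, 5, 0], [-40, -30, 0], [50, 0, 0], [50, 5, 0], [45, 40, 0]]
        parcel_id = [0, 0, 1, 2, 2, 3]
        geometry = make_geometry(coords, parcel_id)
        parcellation = make_parcellation(
            ["left", "left", "right", "right"], included=[True, True, True, False]
        )
        pairs = np.array([[0, 3], [1, 4], [0, 4], [2, 3], [0, 5], [0, 1], [0, 2]])
        tensor = make_tensor(np.zeros((3, 2, len(pairs))), pairs=pairs)
        return geometry, parcellation, tensor

    def test_single_bundle_single_pair(self):
        geometry, parcellation, tensor = self._toy()
        bundles = [Bundle(members=np.array([0, 1, 2]))]  # all between parcels 0 and 2
        edges = bundles_to_parcel_edges(bundles, tensor, geometry, parcellation, "b", "w")
        assert edges == [ParcelEdge(0, 2, "b", "w")]

    def test_excluded_parcel_and_self_pairs_dropped(self):
        geometry, parcellation, tensor = self._toy()
        bundles = [Bundle(members=np.array([4, 5]))]  # 0-5 touches excluded 3; 0-1 within parcel 0
        edges = bundles_to_parcel_edges(bundles, tensor, geometry, parcellation, "b", "w")
        assert edges == []

    def test_matches_endpoint_enumeration(self, rng):
        m = 60
        parcel_id = rng.integers(0, 5, size=2 * m)
        coords = rng.uniform(-50, 50, size=(2 * m, 3))
        coords[:, 0] = np.abs(coords[:, 0])  # all right hemisphere
        geometry = make_geometry(coords, parcel_id)
        parcellation = make_parcellation(["right"] * 5)
        pairs = np.column_stack([np.arange(m), np.arange(m) + m])
        tensor = make_tensor(np.zeros((3, 2, m)), pairs=pairs)
        members = rng.choice(m, size=30, replace=False)
        edges = bundles_to_parcel_edges([Bundle(members=members)], tensor, geometry,
                                        parcellation, "b", "w")
        expected = set()
        for c in members:
            a, b = parcel_id[pairs[c, 0]], parcel_id[pairs[c, 1]]
            if a != b:
                expected.add((min(a, b), max(a, b)))
        assert {(e.parcel_a, e.parcel_b) for e in edges} == expected


class TestParcelAggregate:
    def _toy(self, diffs):
        coords = [[-50, 0, 0], [-45, 5, 0], [50, 0, 0], [45, 5, 0], [48, -5, 0]]
        parcel_id = [0, 0, 1, 1, 1]
        geometry = make_geometry(coords, parcel_id)
        pairs = np.array([[0, 2], [0, 3], [1, 2], [1, 3], [0, 1], [2, 3], [0, 4]])
        tensor = make_tensor(diffs, pairs=pairs)
        return geometry, tensor

    def test_singleton_sum(self):
        coords = [[-50, 0, 0], [50, 0, 0]]
        geometry = make_geometry(coords, [0, 1])
        tensor = make_tensor(np.full((3, 2, 1), 0.04), pairs=np.array([[0, 1]]))
        series = parcel_aggregate(tensor, geometry, ParcelEdge(0, 1, "b", "w"))
        np.testing.assert_allclose(series, 0.04)

    def test_hand_enumeration_and_linearity(self, rng):
        diffs = rng.normal(0, 0.05, size=(4, 2, 7))
        geometry, tensor = self._toy(diffs)
        series = parcel_aggregate(tensor, geometry, ParcelEdge(0, 1, "b", "w"))
        # grid pairs between parcels 0 and 1: indices 0..3 and 6 (0-4)
        expected = diffs[:, :, [0, 1, 2, 3, 6]].sum(axis=2)
        np.testing.assert_allclose(series, expected, atol=1e-12)
        geometry2, tensor2 = self._toy(2 * diffs)
        series2 = parcel_aggregate(tensor2, geometry2, ParcelEdge(0, 1, "b", "w"))
        np.testing.assert_allclose(series2, 2 * series, atol=1e-12)

    def test_permutation_invariance(self, rng):
        diffs = rng.normal(0, 0.05, size=(4, 2, 7))
        geometry, tensor = self._toy(diffs)
        perm = rng.permutation(7)
        tensor_perm = make_tensor(diffs[:, :, perm], pairs=tensor.pairs[perm])
        s1 = parcel_aggregate(tensor, geometry, ParcelEdge(0, 1, "b", "w"))
        s2 = parcel_aggregate(tensor_perm, geometry, ParcelEdge(0, 1, "b", "w"))
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_missing_pairs_rejected(self):
        coords = [[-50, 0, 0], [50, 0, 0], [50, 5, 0]]
        geometry = make_geometry(coords, [0, 1, 2])
        tensor = make_tensor(np.zeros((3, 2, 1)), pairs=np.array([[0, 1]]))
        with pytest.raises(ValueError, match="no grid pairs"):
            parcel_aggregate(tensor, geometry, ParcelEdge(0, 2, "b", "w"))


class TestDirection:
    def test_all_positive_increase(self):
        assert modulation_direction(np.full((5, 2), 0.1)) == "increase"

    def test_all_negative_decrease(self):
        assert modulation_direction(np.full((5, 2), -0.1)) == "decrease"

    def test_mixed_mean_positive(self):
        series = np.array([[-0.1, 0], [0.3, 0], [0.2, 0]])
        assert modulation_direction(series) == "increase"

    def test_zero_mean_tie_breaks_to_increase(self):
        series = np.array([[-0.1, 0], [0.1, 0], [0.0, 0]])
        assert modulation_direction(series) == "increase"


class TestPowerScreen:
    def _power(self, n_over, n_subjects=10, n_parcels=3):
        """naming power exceeds visual by 30% for n_over subjects in parcel 0."""
        p = np.full((n_subjects, n_parcels, 2), 10.0)
        p[:n_over, 0, 0] = 14.0  # relative diff 4/12 = 33% > 20%
        return p

    def test_more_than_four_subjects_boundary(self):
        assert not power_screen(self._power(4))[0]
        assert power_screen(self._power(5))[0]

    def test_equal_powers_never_flagged(self):
        p = np.full((10, 4, 2), 7.0)
        assert not power_screen(p).any()

    def test_scale_invariance(self):
        p = self._power(6)
        np.testing.assert_array_equal(power_screen(p), power_screen(10 * p))

    def test_zero_power_defined_as_no_difference(self):
        p = np.zeros((10, 2, 2))
        assert not power_screen(p).any()
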