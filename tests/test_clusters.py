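"""Cluster detection against a flood-fill oracle, tier assignment, tiered
Bonferroni thresholds, trend classification, permutation and laterality."""

import itertools

import numpy as np
import pytest

from fagap.clusters import (Cluster, CorrectionRule, assign_tier,
                            classify_significance, corrected_threshold,
                            find_clusters, laterality_compare,
                            permutation_validate)
from fagap.contrast import StatMap
from fagap.core import AOETier, TierConfig

from .conftest import make_volume


# ------------------------------------------------------------- thresholds

class TestCorrectedThreshold:
    @pytest.mark.parametrize("n, k, expected, digits", [
        (418, 9, 0.00108, 5),        # primary search volume
        (9308, 27, 1.4504e-4, 8),    # secondary
        (200000, 81, 2.03e-5, 7),    # whole brain (printed rounding)
    ])
    def test_published_search_volumes(self, n, k, expected, digits):
        assert corrected_threshold(n, k, 0.05) == pytest.approx(
            expected, abs=10.0 ** -digits)

    def test_exact_formula(self):
        assert corrected_threshold(418, 9, 0.05) == 0.05 * 9 / 418

    def test_homogeneity(self):
        base = corrected_threshold(1000, 10, 0.05)
        assert corrected_threshold(1000, 10, 0.10) == pytest.approx(2 * base)
        assert corrected_threshold(2000, 10, 0.05) == pytest.approx(base / 2)
        assert corrected_threshold(1000, 20, 0.05) == pytest.approx(2 * base)

    def test_k_larger_than_search_volume_rejected(self):
        with pytest.raises(ValueError):
            corrected_threshold(5, 9, 0.05)


# ------------------------------------------------------------- detection

def _statmap_from_fields(t_field, p_field, mask=None):
    t_field = np.asarray(t_field, dtype=float)
    p_field = np.asarray(p_field, dtype=float)
    if mask is None:
        mask = np.ones(t_field.shape, dtype=bool)
    return StatMap(t_field=t_field, p_field=p_field, df=42,
                   search_mask=mask, group_sizes=(22, 22), affine=np.eye(4))


_OFFSETS = {}
for conn in (6, 18, 26):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        nz = sum(x != 0 for x in d)
        if nz == 0:
            continue
        if (conn == 6 and nz == 1) or (conn == 18 and nz <= 2) or conn == 26:
            offs.append(d)
    _OFFSETS[conn] = offs


def _flood_fill_components(binary, conn):
    """Independent BFS oracle for connected components."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros(binary.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp, queue = set(), [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.add(v)
            for d in _OFFSETS[conn]:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < binary.shape[i] for i in range(3)) \
                        and binary[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestFindClusters:
    def test_single_voxel(self):
        t = np.zeros((4, 4, 4)); p = np.ones((4, 4, 4))
        t[2, 2, 2], p[2, 2, 2] = 3.0, 0.01
        cl = find_clusters(_statmap_from_fields(t, p), TierConfig())
        assert len(cl) == 1 and cl[0].size == 1 and cl[0].sign == 1
        assert cl[0].peak_index == (2, 2, 2)

    def test_3x3_block(self):
        t = np.zeros((5, 5, 3)); p = np.ones((5, 5, 3))
        t[1:4, 1:4, 1], p[1:4, 1:4, 1] = 2.5, 0.02
        cl = find_clusters(_statmap_from_fields(t, p), TierConfig())
        assert len(cl) == 1 and cl[0].size == 9

    def test_corner_touch_splits(self):
        # voxels sharing only a corner are separate clusters (default 18)
        t = np.zeros((4, 4, 4)); p = np.ones((4, 4, 4))
        for v in [(1, 1, 1), (2, 2, 2)]:
            t[v], p[v] = 3.0, 0.01
        cl = find_clusters(_statmap_from_fields(t, p), TierConfig())
        assert len(cl) == 2
        cl26 = find_clusters(_statmap_from_fields(t, p),
                             TierConfig(connectivity=26))
        assert len(cl26) == 1

    def test_edge_touch_joins(self):
        t = np.zeros((4, 4, 4)); p = np.ones((4, 4, 4))
        for v in [(1, 1, 1), (2, 2, 1)]:  # share an edge
            t[v], p[v] = 3.0, 0.01
        assert len(find_clusters(_statmap_from_fields(t, p), TierConfig())) == 1
        cl6 = find_clusters(_statmap_from_fields(t, p), TierConfig(connectivity=6))
        assert len(cl6) == 2

    def test_opposite_signs_never_merge(self):
        t = np.zeros((4, 4, 4)); p = np.ones((4, 4, 4))
        t[1, 1, 1], p[1, 1, 1] = 3.0, 0.01
        t[1, 1, 2], p[1, 1, 2] = -3.0, 0.01
        cl = find_clusters(_statmap_from_fields(t, p), TierConfig())
        assert len(cl) == 2 and {c.sign for c in cl} == {1, -1}

    def test_peak_is_min_p(self):
        t = np.zeros((4, 4, 4)); p = np.ones((4, 4, 4))
        t[1, 1, 1], p[1, 1, 1] = 2.2, 0.03
        t[1, 1, 2], p[1, 1, 2] = 4.0, 0.001
        cl = find_clusters(_statmap_from_fields(t, p), TierConfig())
        assert cl[0].peak_index == (1, 1, 2)
        assert cl[0].peak_p == pytest.approx(0.001)

    @pytest.mark.parametrize("conn", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, conn):
        """Components on 50 random 16^3 fields equal a BFS oracle."""
        rng = np.random.default_rng(conn)
        cfg = TierConfig(connectivity=conn, voxel_p_threshold=0.05)
        for _ in range(50):
            p = rng.uniform(0, 1, (16, 16, 16))
            t = rng.standard_normal((16, 16, 16))
            sm = _statmap_from_fields(t, p)
            got = {frozenset(map(tuple, c.voxels))
                   for c in find_clusters(sm, cfg)}
            expect = set()
            supra = p < cfg.voxel_p_threshold
            for sgn in (1, -1):
                expect |= _flood_fill_components(
                    supra & ((t > 0) if sgn > 0 else (t < 0)), conn)
            assert got == expect

    def test_partition_property(self):
        rng = np.random.default_rng(99)
        p = rng.uniform(0, 1, (12, 12, 12))
        t = rng.standard_normal((12, 12, 12))
        sm = _statmap_from_fields(t, p)
        cfg = TierConfig()
        cl = find_clusters(sm, cfg)
        all_vox = [tuple(v) for c in cl for v in c.voxels]
        assert len(all_vox) == len(set(all_vox))  # pairwise disjoint
        supra = {tuple(v) for v in
                 np.argwhere((p < cfg.voxel_p_threshold) & (t != 0))}
        assert set(all_vox) == supra                # union covers


# ------------------------------------------------------------- tiers

def _cluster_of(voxels):
    vox = np.array(voxels)
    return Cluster(voxels=vox, sign=1, peak_index=tuple(vox[0]),
                   peak_t=3.0, peak_p=0.001)


class TestAssignTier:
    def _aoes(self, shape=(6, 6, 6)):
        pm = np.zeros(shape, bool); pm[0:2] = True
        sm = np.zeros(shape, bool); sm[3:5] = True
        return [AOETier("prim", pm, "primary"), AOETier("sec", sm, "secondary")]

    def test_fully_inside_primary(self):
        c = _cluster_of([(0, i, 0) for i in range(4)])
        assert assign_tier(c, self._aoes()).tier == "primary"
        assert c.aoe_name == "prim"

    def test_minority_overlap_goes_whole_brain(self):
        # 2 of 5 voxels (40%) inside the only AOE
        c = _cluster_of([(0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0), (2, 2, 0)])
        assert assign_tier(c, self._aoes()).tier == "whole_brain"

    def test_exact_half_is_not_enough(self):
        c = _cluster_of([(1, 0, 0), (1, 1, 0), (2, 0, 0), (2, 1, 0)])
        assert assign_tier(c, self._aoes()).tier == "whole_brain"

    def test_majority_secondary(self):
        c = _cluster_of([(3, 0, 0), (4, 0, 0), (2, 0, 1)])
        out = assign_tier(c, self._aoes())
        assert out.tier == "secondary" and out.aoe_name == "sec"


class TestClassifySignificance:
    # published primary tier: N=418, k=9 -> threshold 0.0010766
    rule = CorrectionRule(n_search=418, k=9, alpha=0.05)

    @pytest.mark.parametrize("size, peak_p, expected", [
        (17, 0.000929, "significant"),   # meets corrected threshold
        (9, 0.00264, "trend"),           # within one order of magnitude
        (17, 0.5, "not_significant"),
        (8, 0.000929, "not_significant"),  # too small regardless of peak
        (9, 0.0109, "not_significant"),    # just past the trend band
    ])
    def test_classification(self, size, peak_p, expected):
        vox = np.zeros((size, 3), dtype=int)
        vox[:, 0] = np.arange(size)
        c = Cluster(voxels=vox, sign=1, peak_index=(0, 0, 0),
                    peak_t=3.5, peak_p=peak_p)
        assert classify_significance(c, self.rule, 10.0) == expected


# ------------------------------------------------------------- permutation

class TestPermutationValidate:
    def test_identical_values_give_p1(self):
        assert permutation_validate([1.0] * 6, [0, 0, 0, 1, 1, 1],
                                    n_perms=1000, seed=0) == 1.0

    def test_exhaustive_3v3_complete_separation(self):
        # 20 assignments; only identity and its mirror reach the observed gap
        p = permutation_validate([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                                 n_perms=20, seed=0)
        assert p == pytest.approx(2 / 20)

    @pytest.mark.parametrize("n_per_group", [3, 4])
    def test_matches_enumeration_oracle(self, n_per_group):
        rng = np.random.default_rng(7)
        values = rng.normal(size=2 * n_per_group)
        labels = [0] * n_per_group + [1] * n_per_group
        # independent oracle: direct enumeration of combinations
        obs = abs(values[:n_per_group].mean() - values[n_per_group:].mean())
        hits = total = 0
        for combo in itertools.combinations(range(2 * n_per_group), n_per_group):
            sel = np.zeros(2 * n_per_group, bool)
            sel[list(combo)] = True
            total += 1
            if abs(values[sel].mean() - values[~sel].mean()) >= obs - 1e-12:
                hits += 1
        p = permutation_validate(values, labels, n_perms=10 ** 6, seed=0)
        assert p == pytest.approx(hits / total)

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=8)
        labels = [0] * 4 + [1] * 4
        exact = permutation_validate(values, labels, n_perms=10 ** 6, seed=0)
        mc = permutation_validate(values, labels, n_perms=10_000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc - exact) <= 2 * se + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            permutation_validate([1, 2, 3, 4], [0, 0, 1, 1], n_perms=0, seed=0)
        with pytest.raises(ValueError):
            permutation_validate([1, 2, 3], [0, 1, 1], n_perms=10, seed=0)


# ------------------------------------------------------------- laterality

class TestLaterality:
    def _masks(self, shape=(6, 6, 6)):
        lm = np.zeros(shape, bool); lm[0:2, 2:4, 2:4] = True
        rm = np.zeros(shape, bool); rm[4:6, 2:4, 2:4] = True
        return (AOETier("left", lm, "primary"), AOETier("right", rm, "primary"))

    def test_symmetric_volumes_all_zero(self):
        left, right = self._masks()
        vols = [make_volume(np.full((6, 6, 6), 0.5), f"s{i}") for i in range(4)]
        res = laterality_compare(vols, vols, left, right)
        assert np.allclose(res["indices_a"], 0)
        assert res["between"]["p"] == 1.0

    def test_doubled_right_gives_one_third(self):
        left, right = self._masks()
        rng = np.random.default_rng(11)

        def grp(double_right, n):
            out = []
            for i in range(n):
                d = np.full((6, 6, 6), 0.3) + rng.normal(0, 1e-3, (6, 6, 6))
                if double_right:
                    d[right.mask] *= 2
                out.append(make_volume(np.clip(d, 0, 1), f"s{i}"))
            return out

        res = laterality_compare(grp(True, 12), grp(False, 12), left, right)
        assert res["indices_a"].mean() == pytest.approx(1 / 3, abs=0.01)
        assert abs(res["indices_b"].mean()) < 0.01
        assert res["between"]["p"] < 1e-6

    def test_swapping_masks_negates_indices(self):
        left, right = self._masks()
        rng = np.random.default_rng(12)
        vols = [make_volume(rng.uniform(0.2, 0.8, (6, 6, 6)), f"s{i}")
                for i in range(5)]
        fwd = laterality_compare(vols, vols, left, right)
        rev = laterality_compare(vols, vols, right, left)
        np.testing.assert_allclose(fwd["indices_a"], -rev["indices_a"])

    def test_empty_mask_rejected(self):
        left, right = self._masks()
        empty = AOETier("e", np.zeros((6, 6, 6), bool), "primary")
        with pytest.raises(ValueError):
            laterality_compare([], [], empty, right)
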