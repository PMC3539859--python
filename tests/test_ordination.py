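import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import dice as scipy_dice, pdist, squareform

from aflpop import (
    DistanceMatrix,
    axis_group_test,
    geographic_distance_matrix,
    haversine_km,
    nei_li_distance,
    pcoa,
)
from aflpop.io import ConfigError, GroupingError
from conftest import make_matrix, random_matrix


def brute_force_nei_li(matrix, i, j):
    n11 = n10 = n01 = 0
    a, b = matrix.band[i], matrix.band[j]
    for x, y in zip(a, b):
        if np.isnan(x) or np.isnan(y):
            continue
        if x == 1 and y == 1:
            n11 += 1
        elif x == 1 and y == 0:
            n10 += 1
        elif x == 0 and y == 1:
            n01 += 1
    denom = 2 * n11 + n10 + n01
    return np.nan if denom == 0 else 1 - 2 * n11 / denom


class TestNeiLiDistance:
    def test_identical_patterns(self):
        m = make_matrix({"a": [1, 0, 1], "b": [1, 0, 1]})
        assert nei_li_distance(m).values[0, 1] == 0.0

    def test_disjoint_band_sets(self):
        m = make_matrix({"a": [1, 1, 0, 0], "b": [0, 0, 1, 1]})
        assert nei_li_distance(m).values[0, 1] == 1.0

    def test_forced_arithmetic(self):
        # n11=2, n10=1, n01=1: S = 4/6, d = 1/3
        m = make_matrix({"a": [1, 1, 1, 0], "b": [1, 1, 0, 1]})
        assert nei_li_distance(m).values[0, 1] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_tallies(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 7, 30, missing=0.1)
        d = nei_li_distance(m).values
        for i in range(7):
            for j in range(i + 1, 7):
                expected = brute_force_nei_li(m, i, j)
                if np.isnan(expected):
                    assert np.isnan(d[i, j])
                else:
                    assert d[i, j] == pytest.approx(expected)

    def test_agrees_with_scipy_dice_on_complete_data(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 6, 40)
        d = nei_li_distance(m).values
        for i in range(6):
            for j in range(i + 1, 6):
                assert d[i, j] == pytest.approx(
                    scipy_dice(m.band[i].astype(bool), m.band[j].astype(bool))
                )

    def test_no_shared_band_pair_is_missing_with_warning(self):
        m = make_matrix({"a": [0, 0, 1], "b": [0, 0, None]})
        with pytest.warns(UserWarning, match="no scored band"):
            d = nei_li_distance(m)
        assert np.isnan(d.values[0, 1])


def _equilateral(n=3, side=1.0):
    pts = np.array([[0, 0], [side, 0], [side / 2, side * np.sqrt(3) / 2]])
    return pts[:n]


class TestPcoa:
    def test_three_equidistant_points_split_variance_evenly(self):
        d = squareform(pdist(_equilateral()))
        res = pcoa(DistanceMatrix(["a", "b", "c"], d, "euclidean"))
        assert res.percent_variance == pytest.approx([50.0, 50.0], abs=1e-8)

    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(list("abcd"), d, "euclidean"))
        assert res.percent_variance[0] == pytest.approx(100.0)
        assert res.coordinates.shape[1] == 1

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 4))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(12)], d, "euclidean"))
        recon = squareform(pdist(res.coordinates))
        assert np.abs(recon - d).max() < 1e-9

    def test_recovers_configuration_up_to_rotation(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        pts -= pts.mean(axis=0)
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d, "euclidean"))
        coords = res.coordinates[:, :3]
        R, _ = orthogonal_procrustes(coords, pts)
        residual = np.abs(coords @ R - pts).max()
        assert residual < 1e-8

    def test_agrees_with_reference_implementation(self):
        import skbio

        rng = np.random.default_rng(13)
        m = random_matrix(rng, 10, 50)
        d = nei_li_distance(m)
        ours = pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, d.ids))
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1]
        # the reference clamps negative eigenvalues; compare the positive part
        k = int((ref_eig > 1e-12).sum())
        np.testing.assert_allclose(ours.eigenvalues[:k], ref_eig[:k], atol=1e-8)

    def test_missing_entries_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ConfigError, match="impute"):
            pcoa(DistanceMatrix(["a", "b"], d, "nei_li"))

    def test_lingoes_correction_removes_negative_eigenvalues(self):
        # non-Euclidean metric distances produce negative eigenvalues
        rng = np.random.default_rng(21)
        m = random_matrix(rng, 12, 20)
        d = nei_li_distance(m)
        plain = pcoa(d)
        fixed = pcoa(d, correction="lingoes")
        assert plain.n_negative > 0
        assert fixed.n_negative == 0


class TestAxisGroupTest:
    def _result(self, coords, ids):
        from aflpop.ordination import PcoaResult

        coords = np.asarray(coords, dtype=float)
        return PcoaResult(
            ids, coords, np.ones(coords.shape[1]),
            np.full(coords.shape[1], 100 / coords.shape[1]), 0,
        )

    def test_complete_separation_extreme_u(self):
        ids = [f"s{i}" for i in range(12)]
        res = self._result([[v] for v in range(12)], ids)
        grouping = {s: ("A" if i < 6 else "B") for i, s in enumerate(ids)}
        t = axis_group_test(res, grouping, axes=(1,))
        assert t["statistic"].iloc[0] in (0.0, 36.0)
        assert t["p_value"].iloc[0] < 0.01

    def test_identical_multisets_p_near_one(self):
        ids = [f"s{i}" for i in range(8)]
        res = self._result([[v] for v in [1, 2, 3, 4, 1, 2, 3, 4]], ids)
        grouping = {s: ("A" if i < 4 else "B") for i, s in enumerate(ids)}
        t = axis_group_test(res, grouping, axes=(1,))
        assert t["p_value"].iloc[0] > 0.9

    def test_u_equals_pair_counting_oracle(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 6.0]
        ids = [f"s{i}" for i in range(7)]
        res = self._result([[v] for v in x + y], ids)
        grouping = {s: ("X" if i < 4 else "Y") for i, s in enumerate(ids)}
        t = axis_group_test(res, grouping, axes=(1,))
        u_oracle = sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y
        )
        assert t["statistic"].iloc[0] in (u_oracle, len(x) * len(y) - u_oracle)

    def test_three_groups_use_kruskal(self):
        ids = [f"s{i}" for i in range(9)]
        res = self._result([[v] for v in range(9)], ids)
        grouping = {s: f"G{i % 3}" for i, s in enumerate(ids)}
        t = axis_group_test(res, grouping, axes=(1,))
        assert t["test"].iloc[0] == "kruskal-wallis"

    def test_normal_approximation_agrees_with_permutation(self):
        rng = np.random.default_rng(17)
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(1.0, 1, 12)])
        ids = [f"s{i}" for i in range(24)]
        res = self._result([[v] for v in vals], ids)
        grouping = {s: ("A" if i < 12 else "B") for i, s in enumerate(ids)}
        p_norm = axis_group_test(res, grouping, axes=(1,))["p_value"].iloc[0]
        from scipy import stats

        obs = stats.mannwhitneyu(vals[:12], vals[12:], alternative="two-sided").statistic
        count = 0
        n_perm = 999
        for _ in range(n_perm):
            perm = rng.permutation(vals)
            u = stats.mannwhitneyu(perm[:12], perm[12:], alternative="two-sided").statistic
            if abs(u - 72) >= abs(obs - 72):  # distance from the null mean n1*n2/2
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_norm - p_perm) < 0.02

    def test_single_group_rejected(self):
        ids = ["a", "b"]
        res = self._result([[0.0], [1.0]], ids)
        with pytest.raises(GroupingError):
            axis_group_test(res, {"a": "G", "b": "G"})


class TestGeographicDistance:
    def test_equator_degree(self):
        # one degree of longitude on the equator is ~111.19 km
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.1)

    def test_matrix_is_symmetric_zero_diagonal(self):
        import pandas as pd

        coords = pd.DataFrame(
            {"latitude": [48.5, 48.7, 42.6], "longitude": [9.0, 10.0, 44.6]},
            index=["a", "b", "c"],
        )
        d = geographic_distance_matrix(coords)
        assert d.values[0, 1] == d.values[1, 0] > 0
        assert np.allclose(np.diag(d.values), 0)
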