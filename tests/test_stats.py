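"""Group statistics: smoothing, TFCE, permutation tests, LI, regressions,
cluster and peak analyses."""

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from speechtrf import (
    GroupDataset,
    SourceMap,
    hemispheric_paired_test,
    language_regression,
    lateralization_index,
    make_grid_space,
    mass_univariate_onesample,
    pairwise_language_ttests,
    peak_analysis,
    roi_summary,
    smooth_map,
    tfce,
    trf_cluster_test,
)
from speechtrf.sourcespace import SourceSpace


def chain_space(n=10):
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return SourceSpace(
        coords=np.arange(n, dtype=float)[:, None],
        edges=edges,
        hemisphere=np.array(["L"] * n),
    )


def tfce_oracle(values, edges, E, H, dh):
    """Independent fine-step integration using scipy connected components."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    out = np.zeros(n)
    for sign in (1.0, -1.0):
        x = np.clip(sign * v, 0.0, None)
        if x.max() <= 0:
            continue
        for h in np.arange(dh, x.max() + dh / 2, dh):
            mask = x >= h
            adj = sparse.lil_matrix((n, n))
            for a, b in edges:
                if mask[a] and mask[b]:
                    adj[a, b] = adj[b, a] = 1
            _, labels = connected_components(adj.tocsr(), directed=False)
            for i in np.flatnonzero(mask):
                extent = np.sum(mask & (labels == labels[i]))
                out[i] += sign * extent**E * h**H * dh
    return out


class TestSmoothing:
    def test_sigma_zero_is_identity(self):
        space = chain_space()
        m = SourceMap(np.random.default_rng(0).standard_normal(10), space)
        out = smooth_map(m, 0.0)
        assert np.array_equal(out.values, m.values)

    def test_constant_map_unchanged(self):
        space = chain_space()
        out = smooth_map(SourceMap(np.full(10, 2.5), space), 1.0)
        assert np.allclose(out.values, 2.5)

    def test_impulse_matches_hand_gaussian_weights(self):
        space = chain_space(7)
        v = np.zeros(7)
        v[3] = 1.0
        sigma = 1.5
        out = smooth_map(SourceMap(v, space), sigma)
        d = np.abs(np.arange(7) - 3)
        w = np.exp(-(np.arange(7)[:, None] - np.arange(7)[None, :]) ** 2 / (2 * sigma**2))
        expected = w[:, 3] / w.sum(axis=1)
        assert np.allclose(out.values, expected)


class TestTFCE:
    def test_isolated_source_integral(self):
        # lone suprathreshold source, t=2: integral of h^2 dh -> 8/3
        space = chain_space(5)
        v = np.array([0.0, 0.0, 2.0, 0.0, 0.0])
        enh = tfce(v, space.edges, E=0.5, H=2.0, dh=0.001)
        assert enh[2] == pytest.approx(8.0 / 3.0, rel=0.01)

    def test_zero_map_zero_output(self):
        space = chain_space(6)
        assert not tfce(np.zeros(6), space.edges).any()

    def test_disconnected_equal_blobs_symmetric(self):
        edges = np.array([[0, 1], [3, 4]])
        v = np.array([1.5, 1.5, 0.0, 1.5, 1.5])
        enh = tfce(v, edges, dh=0.01)
        assert np.allclose(enh[[0, 1]], enh[[3, 4]])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            tfce(np.array([1.0, np.nan]), np.empty((0, 2), dtype=int))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_integration_oracle_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        space = make_grid_space(8, n_rows=2)
        v = rng.standard_normal(space.n_sources) * 2
        enh = tfce(v, space.edges, 0.5, 2.0, 0.05)
        oracle = tfce_oracle(v, space.edges, 0.5, 2.0, 0.05)
        assert np.allclose(enh, oracle, rtol=1e-9, atol=1e-9)


class TestMassUnivariate:
    def test_exhaustive_and_random_flips_agree(self):
        rng = np.random.default_rng(0)
        space = chain_space(12)
        maps = rng.standard_normal((10, 12)) + 0.6
        ds = GroupDataset(maps, ["g"] * 10, space)
        exact = mass_univariate_onesample(ds, sigma=0, n_perm=10_000, seed=1)
        approx = mass_univariate_onesample(
            ds, sigma=0, n_perm=25_000, seed=1, method="random"
        )
        assert exact.exhaustive and not approx.exhaustive
        assert np.all(np.abs(exact.p - approx.p) < 0.01)

    def test_degenerate_equal_maps_guarded(self):
        space = chain_space(6)
        ds = GroupDataset(np.ones((8, 6)), ["g"] * 8, space)
        res = mass_univariate_onesample(ds, sigma=0, n_perm=256, seed=0)
        assert res.p_tmax == min(res.p)  # smallest attainable under the null
        assert np.isfinite(res.t).all()

    def test_injected_effect_detected(self):
        # localized 1-SD effect in 20% of sources, n=12
        space = make_grid_space(10, n_rows=2)
        hits = 0
        runs = 30
        for seed in range(runs):
            rng = np.random.default_rng(400 + seed)
            maps = rng.standard_normal((12, space.n_sources))
            maps[:, :4] += 1.0
            ds = GroupDataset(maps, ["g"] * 12, space)
            res = mass_univariate_onesample(ds, sigma=1.0, n_perm=300, seed=seed)
            hits += res.p.min() <= 0.05
        assert hits / runs >= 0.8


class TestHemisphericTest:
    def test_symmetric_hemispheres_no_effect(self):
        space = make_grid_space(6)
        rng = np.random.default_rng(1)
        half = rng.standard_normal((8, 6))
        maps = np.concatenate([half, half], axis=1)  # right mirrors left
        ds = GroupDataset(maps, ["g"] * 8, space)
        res = hemispheric_paired_test(ds, sigma=0, n_perm=256, seed=0)
        assert np.allclose(res.t, 0.0)
        assert res.p.min() > 0.05

    def test_swapping_hemispheres_negates_t(self):
        space = make_grid_space(6)
        rng = np.random.default_rng(2)
        maps = rng.standard_normal((8, 12))
        ds = GroupDataset(maps, ["g"] * 8, space)
        swapped = GroupDataset(
            np.concatenate([maps[:, 6:], maps[:, :6]], axis=1), ["g"] * 8, space
        )
        r1 = hemispheric_paired_test(ds, sigma=0, n_perm=128, seed=0)
        r2 = hemispheric_paired_test(swapped, sigma=0, n_perm=128, seed=0)
        assert np.allclose(r1.t, -r2.t)

    def test_rightward_effect_detected(self):
        space = make_grid_space(10)
        hits = 0
        runs = 25
        for seed in range(runs):
            rng = np.random.default_rng(500 + seed)
            left = 1.0 + 0.3 * rng.standard_normal((12, 10))
            maps = np.concatenate([left, 2 * left], axis=1)
            ds = GroupDataset(maps, ["g"] * 12, space)
            res = hemispheric_paired_test(ds, sigma=1.0, n_perm=300, seed=seed)
            hits += (res.p.min() <= 0.05) and (res.tmax < 0)
        assert hits / runs >= 0.8

    def test_missing_pairing_rejected(self):
        space = chain_space(4)
        ds = GroupDataset(np.zeros((3, 4)), ["g"] * 3, space)
        with pytest.raises(ValueError, match="pairing"):
            hemispheric_paired_test(ds)


class TestLateralization:
    def test_endpoints(self):
        assert lateralization_index(1.0, 1.0) == 0.5
        assert lateralization_index(0.0, 2.0) == 1.0
        assert lateralization_index(2.0, 0.0) == 0.0

    def test_zero_total_is_missing(self):
        assert np.isnan(lateralization_index(0.0, 0.0))

    @pytest.mark.parametrize("c", [0.1, 1.0, 17.3])
    def test_scale_invariance(self, c):
        L, R = 0.8, 0.3
        assert lateralization_index(c * L, c * R) == pytest.approx(
            lateralization_index(L, R)
        )

    def test_negative_strengths_clipped(self):
        assert lateralization_index(-0.5, 1.0) == 1.0


class TestROISummary:
    def _ds(self, values, labels=None):
        space = chain_space(values.shape[1])
        return GroupDataset(values, labels or ["g"] * len(values), space)

    def test_constant_values_flagged(self):
        ds = self._ds(np.full((5, 4), 0.7))
        with pytest.warns(UserWarning, match="degenerate"):
            table = roi_summary(ds, np.ones(4, dtype=bool))
        row = table[table.group == "all"].iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert np.isnan(row["t"])

    def test_negation_negates_t(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((10, 4)) + 0.5
        t1 = roi_summary(self._ds(v)).iloc[0]["t"]
        t2 = roi_summary(self._ds(-v)).iloc[0]["t"]
        assert t1 == pytest.approx(-t2)

    def test_power_at_strong_effect(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = rng.normal(0.3, 0.1, size=(24, 5))
            table = roi_summary(self._ds(v))
            hits += table[table.group == "all"].iloc[0]["p"] < 0.05
        assert hits >= 95

    def test_empty_roi_rejected(self):
        ds = self._ds(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="ROI"):
            roi_summary(ds, np.zeros(4, dtype=bool))


class TestLanguageRegression:
    def test_two_group_regression_matches_pairwise_t(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.standard_normal(10), rng.standard_normal(10) + 1])
        labels = ["English"] * 10 + ["Mandarin"] * 10
        reg = language_regression(v, labels)
        t_reg = reg[reg.level == "Mandarin"].iloc[0]["t"]
        pair = pairwise_language_ttests(v, labels).iloc[0]
        assert abs(t_reg) == pytest.approx(abs(pair["t"]), abs=1e-9)

    def test_shift_changes_only_intercept(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(18)
        labels = ["English", "Mandarin", "Sinhala"] * 6
        r1 = language_regression(v, labels)
        r2 = language_regression(v + 5.0, labels)
        assert r2.iloc[0]["estimate"] == pytest.approx(r1.iloc[0]["estimate"] + 5.0)
        assert np.allclose(
            r1[r1.term == "language"]["estimate"],
            r2[r2.term == "language"]["estimate"],
        )

    def test_known_offset_recovered_within_2se(self):
        hits = 0
        runs = 100
        delta = 0.8
        for seed in range(runs):
            rng = np.random.default_rng(700 + seed)
            v = np.concatenate(
                [rng.standard_normal(12), rng.standard_normal(12) + delta]
            )
            labels = ["English"] * 12 + ["Mandarin"] * 12
            reg = language_regression(v, labels)
            row = reg[reg.level == "Mandarin"].iloc[0]
            se = abs(row["estimate"] / row["t"]) if row["t"] != 0 else np.inf
            hits += abs(row["estimate"] - delta) <= 2 * se
        assert hits / runs >= 0.93

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            language_regression(np.zeros(5), ["English"] * 5)


class TestPairwiseTTests:
    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(20)
        labels = ["A"] * 10 + ["B"] * 10
        t1 = pairwise_language_ttests(v, labels).iloc[0]["t"]
        # present group B first so the same pair is tested in reverse order
        v2 = np.concatenate([v[10:], v[:10]])
        t2 = pairwise_language_ttests(v2, ["B"] * 10 + ["A"] * 10).iloc[0]["t"]
        assert t1 == pytest.approx(-t2)

    def test_strong_difference_detected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(800 + seed)
            v = np.concatenate([rng.standard_normal(12), rng.standard_normal(12) + 3])
            t = pairwise_language_ttests(v, ["A"] * 12 + ["B"] * 12)
            hits += t.iloc[0]["p"] < 0.01
        assert hits / 50 >= 0.95

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = pairwise_language_ttests(np.arange(4.0), ["A", "A", "A", "B"])
        assert len(out) == 0


class TestClusterTest:
    def _trfs(self, rng, n=12, S=8, T=20, shift=0.0):
        space = make_grid_space(S)[0] if False else chain_space(S)
        base = np.zeros((S, T))
        base[:, 5:9] = 1.0
        trfs = base + 0.3 * rng.standard_normal((2 * n, S, T))
        trfs[n:, :, 5:9] += shift
        return trfs, space

    def test_relabeling_groups_preserves_p(self):
        rng = np.random.default_rng(6)
        trfs, space = self._trfs(rng, shift=0.5)
        r1 = trf_cluster_test(trfs, ["A"] * 12 + ["B"] * 12, space, n_perm=200, seed=3)
        r2 = trf_cluster_test(trfs, ["X"] * 12 + ["Y"] * 12, space, n_perm=200, seed=3)
        assert np.allclose(r1.clusters["p"], r2.clusters["p"])

    def test_injected_difference_localized(self):
        hits = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(900 + seed)
            trfs, space = self._trfs(rng, shift=0.8)
            res = trf_cluster_test(
                trfs, ["A"] * 12 + ["B"] * 12, space, n_perm=200, seed=seed
            )
            sig = res.clusters[res.clusters.p <= 0.05]
            ok = False
            for _, row in sig.iterrows():
                if row.t_start_ms <= 8 and row.t_stop_ms >= 5:
                    ok = True
            hits += ok
        assert hits / runs >= 0.8

    def test_group_count_validated(self):
        rng = np.random.default_rng(7)
        trfs = rng.standard_normal((6, 4, 10))
        with pytest.raises(ValueError, match="two groups"):
            trf_cluster_test(trfs, ["A"] * 6, chain_space(4))


class TestPeakAnalysis:
    def test_single_bump_peak_location_and_size(self):
        lags = np.linspace(0, 500, 51)
        kernel = np.exp(-0.5 * ((lags - 200) / 30) ** 2) * 1.7
        kernels = np.tile(kernel, (8, 1))
        table = peak_analysis(kernels, lags, ["A"] * 4 + ["B"] * 4)
        assert len(table) == 1
        assert table.iloc[0]["mean_latency_ms"] == pytest.approx(200, abs=10)
        assert table.iloc[0]["mean_amplitude"] == pytest.approx(1.7, abs=0.01)

    def test_identical_groups_no_differences(self):
        rng = np.random.default_rng(8)
        lags = np.linspace(0, 500, 51)
        kernel = np.sin(lags / 80.0)
        kernels = kernel + 0.01 * rng.standard_normal((12, 51))
        table = peak_analysis(kernels, lags, ["A"] * 6 + ["B"] * 6)
        assert len(table) > 0
        assert (table["p_amplitude"] > 0.05).all() or len(table) == 0

    def test_latency_shift_detected(self):
        hits = 0
        runs = 25
        lags = np.linspace(0, 500, 101)
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            k = []
            for g, shift in ((0, 0.0), (1, 50.0)):
                for _ in range(12):
                    mu = 200 + shift + 5 * rng.standard_normal()
                    k.append(np.exp(-0.5 * ((lags - mu) / 40) ** 2))
            table = peak_analysis(np.array(k), lags, ["A"] * 12 + ["B"] * 12)
            hits += bool(len(table)) and table.iloc[0]["p_latency"] < 0.05
        assert hits / runs >= 0.8

    def test_flat_kernels_empty_table(self):
        lags = np.linspace(0, 100, 11)
        table = peak_analysis(np.zeros((6, 11)), lags, ["A"] * 3 + ["B"] * 3)
        assert len(table) == 0
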