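"""Hamming basis, standardization, and the boosting estimator."""

import numpy as np
import pytest

from speechtrf import make_basis, standardize
from speechtrf.basis import build_design
from speechtrf.boosting import (
    boost_fit,
    cross_validated_fit,
    make_cv_partition,
    model_improvement,
    predict,
    quality_index,
    FREEZE_VALIDATION,
)
from speechtrf.features import PredictorTrack


def impulse_track(n, fs, rng, rate_hz=10.0, name="x"):
    """Sparse random impulse train with unit-normal magnitudes."""
    v = np.zeros(n)
    idx = rng.random(n) < rate_hz / fs
    v[idx] = rng.standard_normal(idx.sum())
    if not v.any():
        v[0] = 1.0
    return PredictorTrack(name, fs, v, "impulse")


SMALL_BASIS = dict(tmin_ms=0.0, tmax_ms=400.0, width_ms=50.0, stride_ms=20.0)


def simulate_small(rng, n=4000, fs=50.0, n_pred=2, snr=None, peak=(100.0, 1.0)):
    """Impulse predictors convolved with early+late two-peak kernels."""
    basis = make_basis(fs=fs, **SMALL_BASIS)
    tracks = [impulse_track(n, fs, rng, name=f"x{p}") for p in range(n_pred)]
    coef = np.zeros((n_pred, basis.n_elements))
    centers_ms = basis.centers * 1000.0 / fs
    for p in range(n_pred):
        j = int(np.argmin(np.abs(centers_ms - peak[0] * (p + 1))))
        coef[p, j] = peak[1]
        j2 = int(np.argmin(np.abs(centers_ms - (peak[0] * (p + 1) + 140.0))))
        coef[p, j2] = -0.7 * peak[1]
    y = np.zeros(n)
    for p, t in enumerate(tracks):
        xs, _, _ = standardize(t.values)
        y += build_design(xs, basis) @ coef[p]
    if snr is not None:
        noise = rng.standard_normal(n)
        y = y + noise * np.sqrt(y.var() / snr) / noise.std()
    return basis, tracks, coef, y


class TestStandardize:
    def test_already_standard(self):
        out, c, s = standardize(np.array([1.0, -1.0]))
        assert np.allclose(out, [1.0, -1.0]) and c == 0.0 and s == 1.0

    def test_shift_and_scale(self):
        out, c, s = standardize(np.array([2.0, 4.0]))
        assert np.allclose(out, [-1.0, 1.0])
        assert c == 3.0 and s == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_postconditions(self, seed):
        x = np.random.default_rng(seed).standard_normal(500) * 7 + 3
        out, _, _ = standardize(x)
        assert abs(out.mean()) < 1e-9
        assert np.abs(out).mean() == pytest.approx(1.0, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(np.full(10, 3.3))


class TestBasis:
    def test_default_center_count(self):
        basis = make_basis(-100.0, 1000.0, 50.0, 10.0, fs=100.0)
        assert basis.n_elements == 110

    def test_bump_width_in_samples(self):
        basis = make_basis(fs=100.0)
        assert len(basis.window) == 5

    def test_nonoverlapping_elements_tile_the_window(self):
        basis = make_basis(0.0, 200.0, 50.0, 50.0, fs=100.0)
        total = basis.matrix.sum(axis=1)
        # each lag belongs to exactly one bump: profile is the tiled window
        expected = np.tile(basis.window, basis.n_elements)
        assert np.allclose(total[: len(expected)], expected)

    def test_too_coarse_sampling_rejected(self):
        with pytest.raises(ValueError, match="width"):
            make_basis(0.0, 400.0, 50.0, 50.0, fs=20.0)


class TestPredict:
    def test_zero_coefficients_zero_prediction(self):
        rng = np.random.default_rng(0)
        basis, tracks, _, y = simulate_small(rng, n=1000)
        m = boost_fit(tracks, y, (1, 2), 3, basis)
        m.coef[:] = 0.0
        assert not predict(m, tracks).any()

    def test_impulse_reproduces_bump_at_lag(self):
        fs = 50.0
        basis = make_basis(fs=fs, **SMALL_BASIS)
        n = 500
        x = np.zeros(n)
        x[100] = 1.0
        D = build_design(x, basis)
        j = 5
        col = D[:, j]
        c = int(basis.centers[j])
        hw = (len(basis.window) - 1) // 2
        lo = 100 + c - hw
        w = len(basis.window)
        assert np.allclose(col[lo : lo + w], basis.window)
        assert not col[:lo].any() and not col[lo + w :].any()

    def test_linearity(self):
        rng = np.random.default_rng(1)
        basis, tracks, coef, y = simulate_small(rng, n=1500)
        m = boost_fit(tracks, y, (1, 2), 3, basis)
        both = predict(m, tracks)
        single = []
        for p in range(2):
            mp = boost_fit(tracks, y, (1, 2), 3, basis)
            mp.coef[1 - p] = 0.0
            single.append(predict(mp, tracks))
        assert np.allclose(both, single[0] + single[1], atol=1e-9)


class TestBoostFit:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(2)
        basis, tracks, coef, y = simulate_small(rng)
        m = boost_fit(tracks, y, (1, 2), 3, basis)
        for p in range(2):
            r = np.corrcoef(basis.kernel(m.coef[p]), basis.kernel(coef[p]))[0, 1]
            assert r >= 0.95

    def test_pure_noise_yields_null_fit(self):
        rng = np.random.default_rng(3)
        basis, tracks, _, _ = simulate_small(rng)
        y = rng.standard_normal(len(tracks[0]))
        res = cross_validated_fit(tracks, y, 4, 0.005, basis)
        assert res.quality[0] <= 0.02
        assert np.abs(res.mtrf[0].kernels()).max() < 0.5

    def test_sham_predictor_frozen_no_later_than_informative(self):
        # response carries the first predictor's signal only; the sham track
        # is independent of it, so validation freezing should abandon the
        # sham no later than the informative predictor
        wins = 0
        runs = 50
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            basis, tracks, coef, y = simulate_small(rng, n=4000, n_pred=1)
            sham = impulse_track(len(y), 50.0, rng, name="sham")
            m = boost_fit([tracks[0], sham], y, (1, 2), 3, basis)
            if m.freeze_iter[1] <= m.freeze_iter[0]:
                wins += 1
        assert wins / runs >= 0.9

    def test_training_error_nonincreasing(self):
        rng = np.random.default_rng(4)
        basis, tracks, _, y = simulate_small(rng, snr=1.0)
        m = boost_fit(tracks, y, (1, 2), 3, basis)
        assert m.err_trace is not None and len(m.err_trace) > 1
        assert np.all(np.diff(m.err_trace) <= 1e-9)

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(5)
        basis, tracks, _, y = simulate_small(rng, n=2000, snr=1.0)
        m1 = boost_fit(tracks, y, (1, 2), 3, basis)
        m2 = boost_fit(tracks, y, (1, 2), 3, basis)
        assert np.array_equal(m1.coef, m2.coef)
        assert np.array_equal(m1.freeze_iter, m2.freeze_iter)

    def test_validation_freezing_reported(self):
        rng = np.random.default_rng(6)
        basis, tracks, _, y = simulate_small(rng, snr=0.5)
        m = boost_fit(tracks, y, (1, 2), 3, basis)
        assert np.all(m.freeze_iter >= 0)
        assert np.any(m.freeze_reason == FREEZE_VALIDATION)

    @pytest.mark.parametrize("snrs", [(4.0, 0.25)])
    def test_recovery_degrades_with_noise(self, snrs):
        meds = []
        for snr in snrs:
            corrs = []
            for seed in range(12):
                rng = np.random.default_rng(200 + seed)
                basis, tracks, coef, y = simulate_small(
                    rng, n=3000, n_pred=1, snr=snr
                )
                m = boost_fit(tracks, y, (1, 2), 3, basis)
                corrs.append(
                    np.corrcoef(basis.kernel(m.coef[0]), basis.kernel(coef[0]))[0, 1]
                )
            meds.append(np.median(corrs))
        assert meds[0] >= 0.9
        assert meds[0] >= meds[-1] - 0.02


class TestQualityIndex:
    def test_perfect_prediction_is_one(self):
        y = np.random.default_rng(0).standard_normal(100)
        assert quality_index(y, y) == 1.0

    def test_null_prediction_is_zero(self):
        y = np.random.default_rng(1).standard_normal(100)
        assert quality_index(y, np.zeros_like(y)) == 0.0


class TestCrossValidation:
    def test_partition_segments_disjoint_covering(self):
        part = make_cv_partition(1003, 4)
        assert part.bounds[0][0] == 0 and part.bounds[-1][1] == 1003
        for (a, b), (c, d) in zip(part.bounds, part.bounds[1:]):
            assert b == c
        # every non-test segment is validation exactly once per test segment
        for test in range(4):
            vals = [v for _, v in part.rotations(test)]
            assert sorted(vals) == sorted(i for i in range(4) if i != test)

    def test_remainder_goes_to_last_segment(self):
        part = make_cv_partition(103, 4)
        assert part.remainder == 3
        assert part.bounds[-1] == (75, 103)

    def test_model_improvement_identical_sets_is_zero(self):
        rng = np.random.default_rng(7)
        basis, tracks, _, y = simulate_small(rng, n=1200)
        delta = model_improvement(tracks, tracks, y, 4, 0.005, basis)
        assert np.allclose(delta, 0.0)

    def test_model_improvement_requires_subset(self):
        rng = np.random.default_rng(8)
        basis, tracks, _, y = simulate_small(rng, n=1200)
        other = [impulse_track(len(y), 50.0, rng, name="zz")]
        with pytest.raises(ValueError, match="subset"):
            model_improvement(tracks, other, y, 4, 0.005, basis)
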