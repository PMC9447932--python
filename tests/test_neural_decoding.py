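import numpy as np
import pytest

import serialdep as sd
from serialdep.neural_decoding import DEFAULT_CHANNELS


class TestChannelBasis:
    def test_unit_response_at_center_zero_at_orthogonal(self):
        c = sd.channel_basis(np.array([22.5]))[0]
        assert c[1] == pytest.approx(1.0)
        # channel 90 deg away in orientation space is fully rectified
        assert c[5] == pytest.approx(0.0, abs=1e-12)  # center 112.5
        assert (c >= 0).all()

    def test_summed_activation_approximately_constant(self):
        theta = np.linspace(0, 180, 721, endpoint=False)
        s = sd.channel_basis(theta).sum(axis=1)
        assert s.std() / s.mean() < 0.01


class TestTrainDecode:
    def _make_data(self, n=96, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        theta = np.tile(np.arange(n // 2) * 360.0 / n, 2)
        W = rng.normal(size=(8, 20))
        B = sd.channel_basis(theta) @ W
        if noise:
            B = B + rng.normal(0, noise, B.shape)
        return B, theta, W

    def test_exact_weight_recovery(self):
        B, theta, W = self._make_data()
        model = sd.train_iem(B, theta)
        np.testing.assert_allclose(model.weights, W, atol=1e-8)

    def test_trial_order_invariance(self):
        B, theta, _ = self._make_data()
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(theta))
        m1 = sd.train_iem(B, theta)
        m2 = sd.train_iem(B[perm], theta[perm])
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-8)

    def test_rank_conditions(self):
        B, theta, _ = self._make_data()
        with pytest.raises(ValueError, match="training trials"):
            sd.train_iem(B[:5], theta[:5])
        with pytest.raises(ValueError, match="rank deficient"):
            sd.train_iem(B[:20], np.full(20, 30.0))

    def test_one_hot_channel_decodes_to_center(self):
        B, theta, W = self._make_data()
        model = sd.train_iem(B, theta)
        chan = np.zeros(8)
        chan[3] = 1.0
        out = sd.decode_trials(model, chan @ W)
        assert out.theta_hat[0] == pytest.approx(DEFAULT_CHANNELS[3], abs=0.5)
        assert out.certainty[0] > 0.5

    def test_zero_pattern_flagged_undefined(self):
        B, theta, _ = self._make_data()
        model = sd.train_iem(B, theta)
        out = sd.decode_trials(model, np.zeros(20))
        assert np.isnan(out.theta_hat[0])
        assert out.certainty[0] == pytest.approx(0.0, abs=1e-9)

    def test_voxel_count_mismatch(self):
        B, theta, _ = self._make_data()
        model = sd.train_iem(B, theta)
        with pytest.raises(ValueError, match="voxel count"):
            sd.decode_trials(model, np.zeros(7))


class TestCrossval:
    def test_noiseless_round_trip_and_shuffle_null(self, noiseless_voxels):
        ds = noiseless_voxels
        out = sd.crossval_decode(ds.truth_stim_amps, ds.orientations,
                                 fold_size=68)
        assert np.abs(out.errors).max() < 0.1
        assert sd.circ_corr(out.theta_hat, out.theta_true) > 0.999
        rng = np.random.default_rng(0)
        shuf = sd.crossval_decode(ds.truth_stim_amps,
                                  rng.permutation(ds.orientations),
                                  fold_size=68)
        assert abs(sd.circ_corr(shuf.theta_hat, shuf.theta_true)) < 0.2

    def test_determinism_and_fold_structure(self, noiseless_voxels):
        ds = noiseless_voxels
        a = sd.crossval_decode(ds.truth_stim_amps, ds.orientations, 68)
        b = sd.crossval_decode(ds.truth_stim_amps, ds.orientations, 68)
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)
        assert len(np.unique(a.fold)) == len(ds.orientations) // 68

    def test_indivisible_trials_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            sd.crossval_decode(np.zeros((70, 4)), np.zeros(70), fold_size=68)

    def test_wrap_invariance(self, noiseless_voxels):
        ds = noiseless_voxels
        a = sd.crossval_decode(ds.truth_stim_amps, ds.orientations, 68)
        b = sd.crossval_decode(ds.truth_stim_amps, ds.orientations + 180.0,
                               68)
        np.testing.assert_allclose(a.theta_hat, b.theta_hat, atol=1e-6)


class TestCircularSummaries:
    def test_constant_errors(self):
        errs = np.full(20, 5.0)
        assert sd.circ_bias(errs) == pytest.approx(5.0)
        assert sd.circ_sd_errors(errs) == pytest.approx(0.0, abs=1e-6)


class TestDoGErrorsFit:
    def test_sign_conventions(self):
        rng = np.random.default_rng(0)
        delta = rng.uniform(-90, 90, 600)
        attract = sd.dog(delta, 8.0, 0.03) + rng.normal(0, 3, 600)
        fit = sd.dog_fit_errors(attract, delta)
        assert fit.amplitude > 4
        repel = sd.dog(delta, -8.0, 0.03) + rng.normal(0, 3, 600)
        assert sd.dog_fit_errors(repel, delta).amplitude < -4

    def test_zero_mean_noise_amplitude_near_zero(self):
        rng = np.random.default_rng(1)
        delta = rng.uniform(-90, 90, 2000)
        errs = rng.normal(0, 10, 2000)
        # narrow-width spike fits to noise keep the amplitude away from
        # exactly 0; small relative to any real effect (|A| ~ 8-15 deg)
        assert abs(sd.dog_fit_errors(errs, delta).amplitude) < 3.5


class TestVoxelSelection:
    def _localizer(self, seed=0, n_trials=360, n_vox=100):
        rng = np.random.default_rng(seed)
        spatial = np.arange(n_trials) % 2 == 0
        theta = rng.uniform(0, 180, n_trials)
        resp = rng.normal(0, 1.0, (n_trials, n_vox))
        # first half: spatially selective; of those, first 25 orientation tuned
        resp[spatial, :50] += 2.0
        phi = np.linspace(0, 180, 25, endpoint=False)
        tuned = np.exp(2.0 * (np.cos(np.deg2rad(2 * (theta[:, None] - phi)))
                              - 1))
        resp[np.ix_(spatial, np.arange(25))] += \
            3.0 * tuned[spatial]
        return resp, spatial, theta

    def test_two_stage_filter_keeps_quarter_and_prefers_tuned(self):
        resp, spatial, theta = self._localizer()
        keep = sd.select_voxels(resp, spatial, theta)
        assert len(keep) == 25
        assert (keep < 50).all()  # spatial stage removes non-selective half
        assert np.isin(np.arange(25), keep).mean() > 0.8  # tuned voxels win

    def test_deterministic(self):
        resp, spatial, theta = self._localizer(seed=3)
        a = sd.select_voxels(resp, spatial, theta)
        b = sd.select_voxels(resp, spatial, theta)
        np.testing.assert_array_equal(a, b)

    def test_too_few_voxels(self):
        with pytest.raises(ValueError, match="4 voxels"):
            sd.select_voxels(np.zeros((10, 3)), np.zeros(10, bool),
                             np.zeros(10))


class TestPCADimensionality:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(200, 1))
        v = rng.normal(size=(1, 30))
        res = sd.pca_dimensionality(u @ v, rng.uniform(-90, 90, 200), seed=0)
        assert res["n90_close"] == 1 and res["n90_far"] == 1

    def test_isotropic_data_no_difference(self):
        diffs = []
        for s in range(8):
            rng = np.random.default_rng(s)
            B = rng.normal(size=(300, 40))
            res = sd.pca_dimensionality(B, rng.uniform(-90, 90, 300), seed=s)
            diffs.append(res["n90_close"] - res["n90_far"])
        assert abs(np.mean(diffs)) < 1.5

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="far_thresh"):
            sd.pca_dimensionality(np.zeros((10, 4)), np.zeros(10),
                                  close_thresh=60, far_thresh=30)
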