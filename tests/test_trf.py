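"""Ridge deconvolution core: filtering, design matrices, solver, CV, bootstrap."""

import numpy as np
import pytest
from scipy import linalg

from cocktailtrf import RegressorSet
from cocktailtrf.scene import SceneSpec, gen_scene, gen_true_trf
from cocktailtrf.trf import (
    Recording,
    Trial,
    bootstrap_peak_latency,
    build_design,
    estimate_trf,
    lag_axis,
    preprocess_recording,
    ridge_solve,
    select_lambda,
)

SHORT = (-0.1, 0.45)


def sine_recording(freq, fs=1000.0, dur=20.0):
    t = np.arange(0, dur, 1 / fs)
    return Recording(np.sin(2 * np.pi * freq * t)[None, :], fs, ["chL0"])


class TestPreprocess:
    def test_stopband_attenuation_below_passband(self):
        out = preprocess_recording(sine_recording(0.5))
        # steady-state amplitude vs unit input
        amp = np.sqrt(2) * out.data[0, 256:-256].std()
        assert 20 * np.log10(amp) < -20

    def test_passband_nearly_unity(self):
        out = preprocess_recording(sine_recording(10.0))
        amp = np.sqrt(2) * out.data[0, 256:-256].std()
        assert abs(20 * np.log10(amp)) < 1.0

    def test_dc_removed(self):
        rec = Recording(np.full((1, 20000), 5.0), 1000.0, ["chL0"])
        out = preprocess_recording(rec)
        assert np.abs(out.data).mean() < 1e-3 * 5.0

    def test_output_rate_128(self):
        out = preprocess_recording(sine_recording(5.0))
        assert out.rate == 128.0
        assert out.n_samples == pytest.approx(20 * 128, abs=2)

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError):
            preprocess_recording(Recording(np.ones((1, 10)), 1000.0, ["chL0"]))


class TestBuildDesign:
    def test_lag_column_count_193_at_128(self):
        rate = 128.0
        n = int(7 * rate)
        regs = RegressorSet({"a": np.random.default_rng(0).normal(size=n)}, rate)
        X, rows = build_design(regs, (-0.5, 1.0), [Trial(0, 7, "c")], rate)
        assert X.shape[1] == 193 + 1  # lags + intercept
        assert len(lag_axis((-0.5, 1.0), rate)) == 193

    def test_impulse_regressor_produces_shifted_diagonal(self):
        rate = 128.0
        n = 64
        x = np.zeros(n)
        x[10] = 1.0
        regs = RegressorSet({"a": x}, rate)
        X, _ = build_design(regs, (0.0, 0.1), [Trial(0, n / rate, "c")], rate,
                            add_intercept=False)
        # column j holds the impulse delayed by j samples
        for j in range(X.shape[1]):
            expected = np.zeros(n)
            if 10 + j < n:
                expected[10 + j] = 1.0
            assert np.array_equal(X[:, j], expected)

    def test_masking_drops_cue_rows(self):
        rate = 128.0
        n = int(7 * rate)
        regs = RegressorSet({"a": np.ones(n)}, rate)
        mask = np.zeros(n, dtype=bool)
        mask[:128] = True
        X, rows = build_design(regs, SHORT, [Trial(0, 7, "c")], rate, mask=mask)
        assert X.shape[0] == n - 128
        assert rows.min() == 128

    def test_everything_masked_is_an_error(self):
        rate = 128.0
        regs = RegressorSet({"a": np.ones(128)}, rate)
        with pytest.raises(ValueError):
            build_design(regs, SHORT, [Trial(0, 1, "c")], rate,
                         mask=np.ones(128, dtype=bool))


class TestRidgeSolve:
    def toy(self, rng, n=200, p=12):
        X = rng.normal(size=(n, p))
        X = np.concatenate([X, np.ones((n, 1))], axis=1)
        beta = rng.normal(size=p + 1)
        y = X @ beta + 0.1 * rng.normal(size=n)
        return X, y

    def test_lambda_zero_equals_ols(self, rng):
        X, y = self.toy(rng)
        est = ridge_solve(X, y, 0.0)
        ols = linalg.lstsq(X, y)[0]
        coef = np.concatenate([est.kernels[0, 0], [est.intercept[0]]])
        assert np.allclose(coef, ols, atol=1e-8)

    def test_huge_lambda_shrinks_to_zero(self, rng):
        X, y = self.toy(rng)
        est0 = ridge_solve(X, y, 0.0)
        est = ridge_solve(X, y, 1e10)
        assert np.abs(est.kernels).max() < 1e-6 * np.abs(est0.kernels).max()

    def test_matches_dense_normal_equations(self, rng):
        # independent dense solve of (X'X + lam*rbar*D) b = X'y
        X, y = self.toy(rng, n=20, p=3)
        lam = 0.7
        xtx = X.T @ X
        rbar = np.trace(xtx[:-1, :-1]) / 3
        D = np.diag([1.0, 1.0, 1.0, 0.0])
        expected = np.linalg.solve(xtx + lam * rbar * D, X.T @ y)
        est = ridge_solve(X, y, lam)
        got = np.concatenate([est.kernels[0, 0], [est.intercept[0]]])
        assert np.allclose(got, expected, atol=1e-10)

    def test_random_small_systems_match_oracle(self, rng):
        for _ in range(20):
            p = int(rng.integers(2, 50))
            n = int(rng.integers(p + 5, 200))
            X = np.concatenate([rng.normal(size=(n, p)), np.ones((n, 1))], axis=1)
            y = rng.normal(size=n)
            lam = float(10 ** rng.uniform(-4, 4))
            xtx = X.T @ X
            rbar = np.trace(xtx[:-1, :-1]) / p
            D = np.eye(p + 1)
            D[-1, -1] = 0.0
            expected = np.linalg.solve(xtx + lam * rbar * D, X.T @ y)
            got = ridge_solve(X, y, lam)
            coef = np.concatenate([got.kernels[0, 0], [got.intercept[0]]])
            assert np.allclose(coef, expected, rtol=1e-8)

    def test_singular_at_zero_is_an_error(self):
        X = np.ones((10, 3))  # rank 1
        with pytest.raises(linalg.LinAlgError, match="lambda"):
            ridge_solve(X, np.ones(10), 0.0)

    def test_linearity_in_response(self, rng):
        X, y = self.toy(rng)
        a = ridge_solve(X, y, 1.0)
        b = ridge_solve(X, 3.0 * y, 1.0)
        assert np.allclose(b.kernels, 3.0 * a.kernels, rtol=1e-10)


class TestSelectLambda:
    def single_stream(self, snr, seed):
        spec = SceneSpec(
            n_trials=6, single_stream=True, noise_snr_db=snr, seed=seed,
            lag_range=SHORT,
        )
        trf = gen_true_trf(attention=True, lag_range=SHORT)
        rec, _, truth = gen_scene(spec, trf)
        return rec, RegressorSet(dict(truth.regressors), rec.rate)

    def test_noiseless_selects_near_minimum(self):
        rec, regs = self.single_stream(None, 2)
        lam = select_lambda(rec, regs, lag_range=SHORT)
        grid = sorted(10.0**k for k in range(-6, 11))
        assert lam <= grid[1]

    def test_pure_noise_selects_heavy_shrinkage(self):
        rec, regs = self.single_stream(None, 2)
        noise = Recording(
            np.random.default_rng(0).normal(size=rec.data.shape),
            rec.rate, rec.channel_names, rec.trials, rec.exclude,
        )
        assert select_lambda(noise, regs, lag_range=SHORT) >= 1e6

    def test_single_value_grid_returned(self):
        rec, regs = self.single_stream(None, 2)
        assert select_lambda(rec, regs, grid=[0.5], lag_range=SHORT) == 0.5

    def test_empty_grid_is_an_error(self):
        rec, regs = self.single_stream(None, 2)
        with pytest.raises(ValueError):
            select_lambda(rec, regs, grid=[], lag_range=SHORT)


class TestEstimateTRF:
    def test_kernel_recovery_on_noiseless_scene(self, noiseless_scene, noiseless_regs):
        _, rec, _, truth = noiseless_scene
        est = estimate_trf(rec, noiseless_regs, 1e-6, lag_range=SHORT)["mix"]
        for name in ("target_onsets", "masker_onsets"):
            k = est.kernel(name)
            # sensor kernel = mixing @ source kernels
            gt = truth.mixing @ truth.source_kernels[name]
            for ch in range(k.shape[0]):
                if np.abs(gt[ch]).max() < 1e-6:
                    continue
                r = np.corrcoef(k[ch], gt[ch])[0, 1]
                assert r >= 0.95

    def test_unmodeled_word_responses_degrade_recovery(self):
        rs = []
        for seed in range(4):
            spec = SceneSpec(
                n_trials=8, noise_snr_db=None, seed=seed, lag_range=SHORT,
                identity_mixing=True, n_sensors=2, p_hit=1.0, word_kernel_amp=3.0,
            )
            t = gen_true_trf(attention=True, lag_range=SHORT)
            m = gen_true_trf(attention=False, lag_range=SHORT)
            rec, _, truth = gen_scene(spec, t, m)
            full = RegressorSet(dict(truth.regressors), rec.rate)
            ablated = full.subset(["target_onsets", "masker_onsets"])
            gt = truth.source_kernels["target_onsets"][0]
            r_pair = []
            for regs in (full, ablated):
                est = estimate_trf(rec, regs, 1e-6, lag_range=SHORT)["mix"]
                r_pair.append(np.corrcoef(est.kernel("target_onsets")[0], gt)[0, 1])
            rs.append(r_pair)
        rs = np.array(rs)
        assert np.all(rs[:, 1] < rs[:, 0])

    def test_missing_condition_is_an_error(self, noiseless_scene, noiseless_regs):
        _, rec, _, _ = noiseless_scene
        with pytest.raises(ValueError, match="nope"):
            estimate_trf(rec, noiseless_regs, 1e-6, conditions=["nope"], lag_range=SHORT)

    def test_deterministic(self, noiseless_scene, noiseless_regs):
        _, rec, _, _ = noiseless_scene
        a = estimate_trf(rec, noiseless_regs, 1e-3, lag_range=SHORT)["mix"]
        b = estimate_trf(rec, noiseless_regs, 1e-3, lag_range=SHORT)["mix"]
        assert np.array_equal(a.kernels, b.kernels)

    def test_training_mse_nondecreasing_in_lambda(self, noiseless_scene, noiseless_regs):
        _, rec, _, _ = noiseless_scene
        prev = -np.inf
        for lam in (1e-6, 1e-2, 1e2, 1e6):
            est = estimate_trf(rec, noiseless_regs, lam, lag_range=SHORT)["mix"]
            cur = est.residual_var.sum()
            assert cur >= prev - 1e-12
            prev = cur


class TestBootstrapLatency:
    def gaussian_kernels(self, latencies, rate=128.0):
        lags = lag_axis((-0.5, 1.0), rate)
        return lags, np.stack(
            [np.exp(-0.5 * ((lags - lat) / 0.012) ** 2) for lat in latencies]
        )

    def test_identical_kernels_zero_sd(self):
        lags, ks = self.gaussian_kernels([0.09375] * 6)
        est = bootstrap_peak_latency(ks, lags, (0.05, 0.15), n_resamples=500, rng=0)
        assert est.mean == pytest.approx(0.09375, abs=1e-12)
        assert est.sd == 0.0

    def test_polarity_flip_finds_same_latency(self):
        lags, ks = self.gaussian_kernels([0.09375] * 6)
        pos = bootstrap_peak_latency(ks, lags, (0.05, 0.15), polarity=1, rng=0)
        neg = bootstrap_peak_latency(-ks, lags, (0.05, 0.15), polarity=-1, rng=0)
        assert pos.mean == neg.mean

    def test_latency_jitter_bounds_bootstrap_sd(self, rng):
        sds = []
        for _ in range(5):
            lats = rng.normal(0.090, 0.008, size=17)
            lags, ks = self.gaussian_kernels(lats)
            est = bootstrap_peak_latency(ks, lags, (0.05, 0.15), n_resamples=500,
                                         rng=rng)
            sds.append(est.sd)
        assert all(0.001 <= s <= 0.008 for s in sds)

    def test_flat_kernel_is_an_error(self):
        lags = lag_axis((-0.5, 1.0), 128.0)
        with pytest.raises(ValueError):
            bootstrap_peak_latency(np.ones((3, len(lags))), lags, (0.05, 0.15))
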