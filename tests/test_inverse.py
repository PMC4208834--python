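"""Preprocessing, rejection, covariance, inverse operator, seed extraction."""

import numpy as np
import pytest

from cortsync.data_model import EpochSet, Parcel
from cortsync.inverse import (
    RejectionThresholds,
    apply_inverse,
    compute_inverse_operator,
    compute_source_covariance,
    estimate_noise_covariance,
    extract_seed_timecourse,
    filter_resample,
    preprocess,
    reject_artifacts,
)
from cortsync.spectral import taper_fft
from cortsync.synth import NOISE_SD, inject_artifacts


def _chinfo(kinds):
    from cortsync.data_model import ChannelInfo, KIND_UNITS

    return [ChannelInfo(f"CH{i}", k, KIND_UNITS[k], np.zeros(3))
            for i, k in enumerate(kinds)]


class TestPreprocess:
    def test_70hz_amplitude_preserved_within_5pct(self):
        sfreq = 1000.0
        t = np.arange(2000) / sfreq
        x = np.sin(2 * np.pi * 70 * t)
        y = filter_resample(x, sfreq)
        a_in = np.abs(taper_fft(x[None], sfreq, np.array([70.0]), 0.5))[0, 0]
        a_out = np.abs(taper_fft(y[None], 333.0, np.array([70.0]), 0.5))[0, 0]
        # same 0.5-s physical window, different sample counts: normalize
        ratio = (a_out / round(0.5 * 333)) / (a_in / round(0.5 * sfreq))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_slow_drift_attenuated_20db(self):
        sfreq = 1000.0
        t = np.arange(30000) / sfreq  # 30 s: the FIR highpass path
        x = np.sin(2 * np.pi * 0.1 * t)
        y = filter_resample(x, sfreq)
        # compare RMS over the central two thirds (edges see filter warmup)
        n = len(y)
        core = slice(n // 6, -n // 6)
        atten = 20 * np.log10(np.sqrt(np.mean(x**2))
                              / max(np.sqrt(np.mean(y[core] ** 2)), 1e-12))
        assert atten >= 20

    def test_output_sample_count(self):
        x = np.zeros(1500)
        y = filter_resample(x, 1000.0)
        assert len(y) == round(1500 * 333 / 1000)

    def test_infeasible_passband_rejected(self):
        with pytest.raises(ValueError):
            filter_resample(np.zeros(100), 200.0, passband=(0.5, 110.0))

    def test_epochset_metadata_preserved(self, small_subject):
        pre_s, *_ = small_subject
        out = preprocess(pre_s)
        assert out.sfreq == 333.0
        assert out.window == pre_s.window
        np.testing.assert_array_equal(out.trial_ids, pre_s.trial_ids)


class TestRejection:
    def _epochs(self, data, kinds, sfreq=1000.0):
        return EpochSet(data=data, channels=_chinfo(kinds), sfreq=sfreq,
                        window="pre_stimulus", t0=-0.5,
                        trial_ids=np.arange(data.shape[0]))

    def test_eeg_over_100uv_rejected(self):
        data = np.zeros((2, 1, 100))
        data[0, 0, 50] = 120e-6  # ptp 120 uV
        ep = self._epochs(data, ["eeg"])
        kept, rejected = reject_artifacts(ep)
        assert list(rejected) == [0]
        assert list(kept.trial_ids) == [1]

    def test_quiet_epochs_all_accepted(self):
        data = 1e-9 * np.ones((5, 2, 50))
        ep = self._epochs(data, ["eeg", "mag"])
        kept, rejected = reject_artifacts(ep)
        assert kept.n_trials == 5 and len(rejected) == 0

    def test_planted_exceedances_counted_exactly(self, small_subject):
        pre_s, *_ = small_subject
        out, injected = inject_artifacts(pre_s, {"eeg": 3}, seed=2)
        kept, rejected = reject_artifacts(out)
        assert kept.n_trials == pre_s.n_trials - 3
        np.testing.assert_array_equal(np.sort(rejected), injected["eeg"])

    def test_rejection_idempotent(self, small_subject):
        pre_s, *_ = small_subject
        out, _ = inject_artifacts(pre_s, {"grad": 2, "mag": 1}, seed=3)
        once, _ = reject_artifacts(out)
        twice, second_rejects = reject_artifacts(once)
        assert len(second_rejects) == 0
        np.testing.assert_array_equal(once.data, twice.data)

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            RejectionThresholds(eeg_v=-1.0).validate()


class TestNoiseCovariance:
    def test_white_noise_recovers_loaded_diagonal(self):
        rng = np.random.default_rng(0)
        sigma = 3e-6
        data = sigma * rng.standard_normal((60, 4, 500))
        ep = EpochSet(data, _chinfo(["eeg"] * 4), 1000.0, "baseline", -0.8,
                      np.arange(60))
        C = estimate_noise_covariance(ep, lam=0.1)
        np.testing.assert_allclose(np.diag(C), sigma**2 * 1.1, rtol=0.05)
        off = C[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05 * sigma**2)

    def test_duplicated_channels_covary(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 1, 400))
        data = np.concatenate([x, x], axis=1)
        ep = EpochSet(data, _chinfo(["eeg", "eeg"]), 1000.0, "baseline", -0.8,
                      np.arange(30))
        C = estimate_noise_covariance(ep, lam=0.0)
        assert C[0, 1] == pytest.approx(1.0, rel=0.05)

    def test_exact_symmetry(self, small_subject):
        *_, base, _, _ = small_subject
        C = estimate_noise_covariance(base)
        np.testing.assert_array_equal(C, C.T)

    def test_rank_deficiency_requires_regularization(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((2, 10, 3))  # 6 samples < 10 channels
        ep = EpochSet(data, _chinfo(["eeg"] * 10), 1000.0, "baseline", -0.8,
                      np.arange(2))
        with pytest.raises(ValueError, match="regulariz"):
            estimate_noise_covariance(ep, lam=0.0)


class TestSourceCovariance:
    def test_zero_exponent_gives_flat_prior(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((6, 4))
        R = compute_source_covariance(A, depth_exponent=0.0)
        np.testing.assert_allclose(R, R[0])

    def test_depth_weight_ratio(self):
        A = np.zeros((2, 2))
        A[0, 0] = 1.0  # column norm 1
        A[1, 1] = 2.0  # column norm 2
        R = compute_source_covariance(A, depth_exponent=1.0)
        assert R[0] / R[1] == pytest.approx(4.0, rel=1e-12)

    def test_matches_per_column_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((8, 5))
        R = compute_source_covariance(A, depth_exponent=0.8)
        oracle = np.array([np.dot(A[:, j], A[:, j]) ** -0.8 for j in range(5)])
        np.testing.assert_allclose(R, oracle, rtol=1e-12)

    def test_zero_column_rejected(self):
        A = np.ones((4, 3))
        A[:, 1] = 0
        with pytest.raises(ValueError, match="column 1"):
            compute_source_covariance(A)

    def test_snr_scaling_in_whitened_metric(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 9))
        C = np.diag(rng.uniform(0.5, 2.0, 6))
        R = compute_source_covariance(A, 0.8, C=C, snr2=9.0)
        Aw = np.linalg.inv(np.sqrt(C)) @ A
        ratio = np.trace(Aw @ np.diag(R) @ Aw.T) / A.shape[0]
        assert ratio == pytest.approx(9.0, rel=1e-10)


class TestInverseOperator:
    def test_identity_closed_form(self):
        inv = compute_inverse_operator(np.eye(2), np.eye(2), np.ones(2))
        np.testing.assert_allclose(inv.W, 0.5 * np.eye(2), atol=1e-12)

    def test_noiseless_limit_is_matrix_inverse(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        inv = compute_inverse_operator(A, 1e-10 * np.eye(4), np.ones(4))
        assert np.abs(inv.W - np.linalg.inv(A)).max() < 1e-6

    def test_matches_dense_solve_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_ch = rng.integers(4, 21)
            n_src = rng.integers(3, 31)
            A = rng.standard_normal((n_ch, n_src))
            M = rng.standard_normal((n_ch, n_ch))
            C = M @ M.T + n_ch * np.eye(n_ch)
            R = rng.uniform(0.1, 2.0, n_src)
            inv = compute_inverse_operator(A, C, R)
            W_oracle = np.diag(R) @ A.T @ np.linalg.inv(A @ np.diag(R) @ A.T + C)
            scale = np.abs(W_oracle).max()
            assert np.abs(inv.W - W_oracle).max() / scale < 1e-10
            norm_oracle = np.sqrt(np.diag(W_oracle @ C @ W_oracle.T))
            np.testing.assert_allclose(inv.norm_factors, norm_oracle, rtol=1e-8)


class TestApplyInverse:
    @pytest.fixture()
    def inv_small(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((6, 10))
        M = rng.standard_normal((6, 6))
        C = M @ M.T + 6 * np.eye(6)
        R = compute_source_covariance(A, 0.8, C, 9.0)
        return compute_inverse_operator(A, C, R), C

    def _epochs(self, data):
        return EpochSet(data, _chinfo(["eeg"] * data.shape[1]), 1000.0,
                        "pre_stimulus", -0.5, np.arange(data.shape[0]))

    def test_zero_in_zero_out(self, inv_small):
        inv, _ = inv_small
        out = apply_inverse(inv, self._epochs(np.zeros((3, 6, 20))))
        assert np.all(out.data == 0)

    def test_linearity(self, inv_small):
        inv, _ = inv_small
        rng = np.random.default_rng(9)
        x = rng.standard_normal((2, 6, 30))
        y = rng.standard_normal((2, 6, 30))
        a = apply_inverse(inv, self._epochs(x)).data
        b = apply_inverse(inv, self._epochs(y)).data
        ab = apply_inverse(inv, self._epochs(x + y)).data
        np.testing.assert_allclose(ab, a + b, atol=1e-12)

    def test_dspm_unit_variance_on_matched_noise(self, inv_small):
        inv, C = inv_small
        rng = np.random.default_rng(10)
        L = np.linalg.cholesky(C)
        noise = np.einsum("ij,tjn->tin", L,
                          rng.standard_normal((200, 6, 100)))
        out = apply_inverse(inv, self._epochs(noise), noise_normalize=True)
        var = out.data.var()
        assert var == pytest.approx(1.0, rel=0.1)

    def test_channel_mismatch_rejected(self, inv_small):
        inv, _ = inv_small
        with pytest.raises(ValueError, match="channel"):
            apply_inverse(inv, self._epochs(np.zeros((1, 5, 10))))


class TestSeedExtraction:
    def _stc(self, data):
        from cortsync.data_model import SourceEpochs

        return SourceEpochs(data=data, sfreq=1000.0, window="pre_stimulus",
                            trial_ids=np.arange(data.shape[0]))

    def _space(self, normals):
        import dataclasses

        from cortsync.data_model import SourceSpace

        n = len(normals)
        return SourceSpace(
            vertex_positions=np.zeros((n, 3)),
            vertex_normals=np.asarray(normals, dtype=float),
            vertex_area=np.ones(n),
            hemisphere=np.array(["lh"] * n, dtype="U2"),
            triangles=np.zeros((0, 3), dtype=int),
        )

    def test_opposite_normals_do_not_cancel(self):
        w = np.sin(np.linspace(0, 4 * np.pi, 100))
        data = np.stack([np.stack([w, -w])])  # 1 trial, 2 vertices
        src = self._space([[0, 0, 1], [0, 0, -1]])
        parcel = Parcel("p", np.array([0, 1]))
        out = extract_seed_timecourse(self._stc(data), parcel, src)
        np.testing.assert_allclose(np.abs(out[0]), np.abs(w), atol=1e-12)

    def test_identical_normals_identity(self):
        w = np.cos(np.linspace(0, 2 * np.pi, 50))
        data = np.stack([np.stack([w, w, w])])
        src = self._space([[0, 0, 1]] * 3)
        parcel = Parcel("p", np.array([0, 1, 2]))
        out = extract_seed_timecourse(self._stc(data), parcel, src)
        np.testing.assert_allclose(out[0], w, atol=1e-12)

    def test_matches_pca_sign_oracle(self, src162):
        rng = np.random.default_rng(11)
        vids = np.sort(rng.choice(src162.hemi_vertices("rh"), 12, replace=False))
        parcel = Parcel("p", vids)
        data = rng.standard_normal((3, src162.n_vertices, 40))
        out = extract_seed_timecourse(self._stc(data), parcel, src162)
        # independent oracle: principal eigenvector of N N^T via eigh
        N = src162.vertex_normals[vids]
        evals, evecs = np.linalg.eigh(N.T @ N)
        d = evecs[:, -1]
        s = np.sign(N @ d)
        s[np.abs(N @ d) < 1e-6] = 1
        if (s > 0).sum() < (s < 0).sum():
            s = -s
        expect = np.einsum("p,tpn->tn", s, data[:, vids]) / len(s)
        np.testing.assert_allclose(out, expect, atol=1e-10)


def test_point_spread_single_source_lands_on_itself(src162, small_forward):
    """A single active dipole's dSPM peak falls on (or next to) its own
    vertex: own vertex in the top 5% of |map| in >= 95% of 100 placements."""
    gain, channels = small_forward
    rng = np.random.default_rng(12)
    sd = np.array([NOISE_SD[c.kind] for c in channels])
    base = EpochSet(sd[None, :, None] * rng.standard_normal((30, len(channels), 180)),
                    channels, 1000.0, "baseline", -0.8, np.arange(30))
    C = estimate_noise_covariance(base)
    R = compute_source_covariance(gain, 0.8, C, 9.0)
    inv = compute_inverse_operator(gain, C, R)
    gw = gain / sd[:, None]
    hits = 0
    n_top = int(np.ceil(0.05 * src162.n_vertices))
    for _ in range(100):
        j = rng.integers(src162.n_vertices)
        # amplitude set for whitened sensor SNR 9
        amp = 9.0 / np.sqrt(np.mean(gw[:, j] ** 2))
        x = amp * gain[:, j] + sd * rng.standard_normal(len(sd))
        m = np.abs((inv.W @ x) / inv.norm_factors)
        if j in np.argsort(m)[-n_top:]:
            hits += 1
    assert hits >= 95
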