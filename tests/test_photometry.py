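"""ΔF/F preprocessing, QC branching and peri-event dip statistics."""

import numpy as np
import pytest

from oralsa.bouts import Trial
from oralsa.errors import AnalysisError
from oralsa.photometry import (PeriEventMatrix, compute_dff, detrend,
                               dip_statistic, isosbestic_correct,
                               peri_event_matrix, process_session,
                               qc_decision, zscore_session)


def _trial(t_reward, n_rewards=1, liquid="fentanyl"):
    rewards = np.arange(n_rewards) * 3.0 + t_reward
    return Trial(start=t_reward - 0.5, end=rewards[-1] + 0.5, port=1,
                 liquid=liquid, n_rewards=n_rewards, laser=False,
                 lick_times=rewards - 0.1, reward_times=rewards)


class TestDetrend:
    def test_degree5_polynomial_annihilated(self):
        t = np.linspace(0, 100, 5000)
        trace = 3 + 0.5 * t - 1e-3 * t**2 + 1e-5 * t**3 - 1e-8 * t**5
        resid = detrend(trace)
        assert np.abs(resid).max() < 1e-6 * np.abs(trace).max()

    def test_constant_input_zero_residual(self):
        resid = detrend(np.full(100, 7.0))
        assert np.abs(resid).max() < 1e-9

    def test_sinusoid_survives_detrending(self):
        t = np.linspace(0, 500, 10000)
        sine = np.sin(2 * np.pi * t / 2.5)  # 200 cycles across the span
        trace = 100 - 0.01 * t + 1e-6 * t**2 + sine
        resid = detrend(trace)
        rmse = np.sqrt(np.mean((resid - sine) ** 2))
        assert rmse < 0.01  # < 1% of unit amplitude

    def test_too_few_samples(self):
        with pytest.raises(AnalysisError):
            detrend(np.arange(5.0))


class TestQcDecision:
    def test_identical_channels_rejected(self, rng):
        x = rng.normal(size=1000)
        r, status = qc_decision(x, x.copy())
        assert r == pytest.approx(1.0) and status == "rejected"

    def test_anticorrelated_not_subtracted(self, rng):
        x = rng.normal(size=1000)
        r, status = qc_decision(x, -x)
        assert r == pytest.approx(-1.0) and status == "not_subtracted"

    def test_constructed_mid_correlation_subtracted(self, rng):
        # r = w/sqrt(w^2+1) -> w for target r = 0.5 is 1/sqrt(3)
        n = 200000
        shared = rng.normal(size=n)
        w = 1 / np.sqrt(3)
        a = w * shared + rng.normal(size=n)
        b = w * shared + rng.normal(size=n)
        r_direct = np.corrcoef(a, b)[0, 1]
        r, status = qc_decision(a, b)
        assert r == pytest.approx(r_direct)
        assert 0.25 < r <= 0.97 and status == "iso_subtracted"

    def test_zero_variance_errors(self):
        with pytest.raises(AnalysisError):
            qc_decision(np.zeros(10), np.arange(10.0))


class TestIsosbesticCorrect:
    def test_exact_affine_relation_cancels(self, rng):
        iso = rng.normal(size=500)
        sig = 2 * iso + 3
        assert np.abs(isosbestic_correct(sig, iso)).max() < 1e-9

    def test_independent_channels_nearly_untouched(self, rng):
        sig = rng.normal(size=50000)
        iso = rng.normal(size=50000)
        out = isosbestic_correct(sig, iso)
        assert np.corrcoef(out, sig)[0, 1] > 0.99

    def test_residual_orthogonal_to_iso_and_idempotent(self, rng):
        sig = rng.normal(size=2000) + 0.5 * np.arange(2000) / 2000
        iso = rng.normal(size=2000)
        once = isosbestic_correct(sig, iso)
        assert abs(np.corrcoef(once, iso)[0, 1]) < 1e-10
        twice = isosbestic_correct(once, iso)
        assert np.allclose(once, twice, atol=1e-10)


class TestDff:
    def test_linear_ramp_anchor(self):
        trace = np.linspace(0, 100, 101)
        dff, f1 = compute_dff(trace, percentile=1)
        assert f1 == pytest.approx(np.percentile(trace, 1))
        assert dff[-1] == pytest.approx((100 - f1) / f1)
        assert dff[np.argmin(np.abs(trace - f1))] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trace_degenerate(self):
        with pytest.raises(AnalysisError, match="percentile"):
            compute_dff(np.full(100, 5.0))

    def test_gain_invariance(self, rng):
        trace = rng.normal(100, 5, 1000)
        dff1, _ = compute_dff(trace)
        dff2, _ = compute_dff(3.7 * trace)
        assert np.allclose(dff1, dff2, atol=1e-12)


class TestZscore:
    def test_two_point_population_sd(self):
        assert np.allclose(zscore_session(np.array([0.0, 2.0])), [-1.0, 1.0])

    def test_affine_invariance(self, rng):
        x = rng.normal(size=500)
        assert np.allclose(zscore_session(x), zscore_session(5 * x + 2))

    def test_moments(self, rng):
        z = zscore_session(rng.normal(3, 7, 1000))
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9


class TestPeriEvent:
    def test_single_trial_row_shape(self, rng):
        zdff = rng.normal(size=1200)  # 60 s at 20 Hz
        mat = peri_event_matrix(zdff, [_trial(30.0)], fs=20.0)
        assert mat.matrix.shape == (1, 200)
        assert mat.event_index == 100

    def test_edge_trial_excluded(self, rng):
        zdff = rng.normal(size=1200)
        mat = peri_event_matrix(zdff, [_trial(2.0)], fs=20.0)
        assert mat.matrix.shape[0] == 0 and mat.n_excluded == 1

    def test_every_reward_alignment_yields_row_per_reward(self, rng):
        zdff = rng.normal(size=2400)
        mat = peri_event_matrix(zdff, [_trial(30.0, n_rewards=4)],
                                fs=20.0, align="every_reward")
        assert mat.matrix.shape[0] == 4

    def test_bout_rows_dip_below_single_rows(self):
        """Sustained suppression during a bout drives the post-event mean of
        bout rows below that of single rows."""
        fs = 20.0
        t = np.arange(4000) / fs
        from oralsa.simulate import dip_waveform
        single, bout = _trial(50.0, 1), _trial(120.0, 4)
        trace = (dip_waveform(t, 50.0, 50.0, 2.0, 1.2)
                 + dip_waveform(t, 120.0, 129.0, 2.0, 1.2))
        mat = peri_event_matrix(trace, [single, bout], fs=fs)
        post = mat.matrix[:, 100:].mean(axis=1)
        assert post[1] < post[0] < 0


class TestDipStatistic:
    def test_symmetric_row_gives_zero(self):
        row = np.concatenate([np.full(100, 0.7), np.full(100, 0.7)])
        mat = PeriEventMatrix(matrix=row[None, :],
                              labels=[{"liquid": "fentanyl", "bout": False,
                                       "trial_index": 0}],
                              window=(-5.0, 5.0), fs=20.0)
        dip = dip_statistic(mat)
        assert dip.deltas[0] == pytest.approx(0.0)

    def test_step_row_gives_minus_one(self):
        row = np.concatenate([np.zeros(100), -np.ones(100)])
        mat = PeriEventMatrix(matrix=row[None, :],
                              labels=[{"liquid": "fentanyl", "bout": True,
                                       "trial_index": 0}],
                              window=(-5.0, 5.0), fs=20.0)
        assert dip_statistic(mat).deltas[0] == pytest.approx(-1.0)

    def test_injected_dip_recovered_to_analytic_integral(self, rng):
        """Single-reward dips: delta = −(A·tau/T)(1 − e^{−T/tau}) + noise."""
        fs, A, tau, T = 20.0, 2.0, 1.2, 5.0
        from oralsa.simulate import dip_waveform
        t = np.arange(20000) / fs
        trials = [_trial(60.0 + 40 * k) for k in range(20)]
        trace = sum(dip_waveform(t, tr.reward_times[0], tr.reward_times[0],
                                 A, tau) for tr in trials)
        trace = trace + rng.normal(0, 0.05, len(t))
        mat = peri_event_matrix(trace, trials, fs=fs)
        dip = dip_statistic(mat)
        analytic = -(A * tau / T) * (1 - np.exp(-T / tau))
        mean, sem, n = dip.by_label[("fentanyl", False)]
        assert n == 20
        assert mean == pytest.approx(analytic, abs=0.02)

    def test_empty_matrix_errors(self):
        mat = PeriEventMatrix(matrix=np.empty((0, 200)), labels=[],
                              window=(-5.0, 5.0), fs=20.0)
        with pytest.raises(AnalysisError):
            dip_statistic(mat)


class TestPipelineOrder:
    def test_rejected_session_produces_no_zdff(self, rng):
        from oralsa.io import PhotometrySession
        n = 2000
        shared = np.cumsum(rng.normal(size=n))  # dominant common drift texture
        sess = PhotometrySession(fs=20.0, t=np.arange(n) / 20.0,
                                 f_signal=100 + shared,
                                 f_iso=80 + shared)
        proc = process_session(sess)
        assert proc.rejected and proc.zdff is None and proc.dff is None

    def test_accepted_session_zdff_standardized(self, rng):
        from oralsa.io import PhotometrySession
        n = 4000
        sess = PhotometrySession(fs=20.0, t=np.arange(n) / 20.0,
                                 f_signal=rng.normal(100, 3, n),
                                 f_iso=rng.normal(80, 3, n))
        proc = process_session(sess)
        assert not proc.rejected
        assert abs(proc.zdff.mean()) < 1e-9
        assert abs(proc.zdff.std() - 1) < 1e-9
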