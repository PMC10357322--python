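"""Statistical structure and determinism of the synthetic-data generators."""

import numpy as np
import pytest
from scipy.stats import chisquare

from oralsa.bouts import attribute_rewards, parse_trials
from oralsa.errors import ConfigError
from oralsa.io import sessionlog_equal
from oralsa.photometry import detrend, process_session
from oralsa.simulate import (BehaviorSimConfig, BleachSpec, EphysSimConfig,
                             PhotometrySimConfig, draw_bout_sizes,
                             simulate_homecage, simulate_operant_session,
                             simulate_photometry, simulate_spikes)


class TestOperant:
    def test_seed_determinism(self):
        cfg = BehaviorSimConfig(seed=7, n_trials=30, laser_fraction=0.5)
        log1, t1 = simulate_operant_session(cfg)
        log2, t2 = simulate_operant_session(cfg)
        assert sessionlog_equal(log1, log2)
        assert t1.equals(t2)

    def test_p_terminate_one_gives_all_singles(self):
        cfg = BehaviorSimConfig(seed=1, n_trials=40, p_terminate=1.0)
        log, truth = simulate_operant_session(cfg)
        trials = [t for t in parse_trials(log) if t.n_rewards >= 1]
        assert all(t.n_rewards == 1 for t in trials)
        assert len(trials) == 40

    def test_uncapped_geometric_mean_near_inverse_p(self, rng):
        # mean of geometric(p=0.5) is 2; SE of the mean ~ sqrt((1-p)/p^2/n)
        sizes = draw_bout_sizes(0.5, 2000, rng, max_rewards=None)
        se = np.sqrt((1 - 0.5) / 0.5**2 / len(sizes))
        assert abs(sizes.mean() - 2.0) < 3 * se

    def test_bout_sizes_match_geometric_pmf(self, rng):
        """Chi-square goodness of fit of simulated sizes to the geometric pmf."""
        p = 0.4
        sizes = draw_bout_sizes(p, 5000, rng)
        kmax = 12  # pool the tail so expected counts stay comfortable
        obs = np.array([(sizes == k).sum() for k in range(1, kmax)]
                       + [(sizes >= kmax).sum()])
        exp = np.array([(1 - p) ** (k - 1) * p for k in range(1, kmax)]
                       + [(1 - p) ** (kmax - 1)]) * len(sizes)
        assert chisquare(obs, exp).pvalue > 0.01

    def test_impossible_lick_rate_rejected(self):
        with pytest.raises(ConfigError, match="lick_rate"):
            BehaviorSimConfig(lick_rate_hz=0.9)

    def test_laser_trials_have_paired_events(self):
        cfg = BehaviorSimConfig(seed=5, n_trials=40, laser_fraction=1.0)
        log, truth = simulate_operant_session(cfg)
        ons = [e.t for e in log.events if e.kind == "laser_on"]
        offs = [e.t for e in log.events if e.kind == "laser_off"]
        assert len(ons) == len(offs) == 40
        assert np.allclose(np.array(offs) - np.array(ons), 2.0, atol=1e-6)


class TestHomecage:
    def test_attribution_recovers_truth_exactly(self):
        cfg = BehaviorSimConfig(seed=2, schedule=1, p_terminate=0.5,
                                inter_reward_interval_s=3.0)
        logs, truth = simulate_homecage(cfg, ["a", "b", "c", "d"],
                                        visits_per_day=40)
        attributed = attribute_rewards(logs[0])
        trials = [t for t in parse_trials(attributed, post_reward_grace_s=3.0)
                  if t.n_rewards >= 1]
        assert [t.animal for t in trials] == list(truth.animal)
        assert [t.n_rewards for t in trials] == list(truth.n_rewards)

    def test_single_animal_trivial(self):
        cfg = BehaviorSimConfig(seed=3, schedule=1)
        logs, truth = simulate_homecage(cfg, ["solo"], visits_per_day=10)
        attributed = attribute_rewards(logs[0])
        rewards = [e for e in attributed.events if e.kind == "reward"]
        assert all(e.animal == "solo" for e in rewards)

    def test_fentanyl_port_alternates_across_days(self):
        cfg = BehaviorSimConfig(seed=4, schedule=1)
        logs, _ = simulate_homecage(cfg, ["a"], n_days=3, visits_per_day=5)
        fent_ports = [next(p for p, liq in lg.port_map.items()
                           if liq == "fentanyl") for lg in logs]
        assert fent_ports[0] != fent_ports[1]
        assert fent_ports[0] == fent_ports[2]

    def test_empty_animal_list_rejected(self):
        with pytest.raises(ConfigError):
            simulate_homecage(BehaviorSimConfig(), [])

    def test_seed_determinism(self):
        cfg = BehaviorSimConfig(seed=8, schedule=1)
        l1, t1 = simulate_homecage(cfg, ["a", "b"], visits_per_day=15)
        l2, t2 = simulate_homecage(cfg, ["a", "b"], visits_per_day=15)
        assert sessionlog_equal(l1[0], l2[0]) and t1.equals(t2)


class TestPhotometry:
    @pytest.fixture
    def beh_log(self):
        cfg = BehaviorSimConfig(seed=6, n_trials=25, p_terminate=0.4,
                                schedule=1, inter_reward_interval_s=3.0)
        return simulate_operant_session(cfg)[0]

    def test_polynomial_bleach_annihilated_by_detrend(self, beh_log):
        cfg = PhotometrySimConfig(seed=0, noise_sd=0.0, artifact_gain=0.0,
                                  transient_amplitude=0.0, dip_amplitude=0.0)
        phot = simulate_photometry(cfg, beh_log, post_reward_grace_s=3.0)
        resid = detrend(phot.f_signal)
        scale = np.abs(phot.f_signal).max()
        assert np.abs(resid).max() < 1e-6 * scale

    def test_artifact_gain_monotonically_raises_correlation(self, beh_log):
        rs = []
        for gain in (0.0, 1.0, 5.0, 50.0):
            cfg = PhotometrySimConfig(seed=1, artifact_gain=gain)
            phot = simulate_photometry(cfg, beh_log, post_reward_grace_s=3.0)
            rs.append(process_session(phot).pearson_r)
        assert rs == sorted(rs)
        assert rs[0] < 0.25 and rs[-1] > 0.97

    def test_no_rewards_rejected(self):
        from oralsa.io import Event, SessionLog
        log = SessionLog("x", "operant", {1: "water"}, {}, 10.0, 1,
                         [Event(1.0, "lick", 1)])
        with pytest.raises(ConfigError, match="reward"):
            simulate_photometry(PhotometrySimConfig(), log)

    def test_seed_determinism(self, beh_log):
        cfg = PhotometrySimConfig(seed=9)
        a = simulate_photometry(cfg, beh_log, post_reward_grace_s=3.0)
        b = simulate_photometry(cfg, beh_log, post_reward_grace_s=3.0)
        assert np.array_equal(a.f_signal, b.f_signal)
        assert np.array_equal(a.f_iso, b.f_iso)

    def test_true_exponential_bleach_available(self, beh_log):
        cfg = PhotometrySimConfig(
            seed=0, noise_sd=0.0, artifact_gain=0.0, transient_amplitude=0.0,
            dip_amplitude=0.0, bleach_signal=BleachSpec(kind="exp"))
        phot = simulate_photometry(cfg, beh_log, post_reward_grace_s=3.0)
        resid = detrend(phot.f_signal)
        # a true exponential is not exactly a degree-5 polynomial
        assert np.abs(resid).max() > 0


class TestSpikes:
    def test_poisson_count_within_4_sigma(self):
        cfg = EphysSimConfig(seed=0, n_units={"ACC": 1},
                             baseline_rate=("fixed", 5.0),
                             modulation={"control": ("fixed", 1.0)},
                             t_saline=100, t_fentanyl=600, t_end=700)
        units, _ = simulate_spikes(cfg)
        count = np.count_nonzero(units.units[0].spike_times < 600)
        assert abs(count - 3000) < 4 * np.sqrt(3000)

    def test_unmodulated_population_has_mi_centered_at_zero(self):
        from oralsa.ephys import compute_modulation
        cfg = EphysSimConfig(seed=1, n_units={"ACC": 200},
                             baseline_rate=("fixed", 8.0),
                             modulation={"control": ("fixed", 1.0)},
                             t_saline=60, t_fentanyl=1260, t_end=3060)
        units, _ = simulate_spikes(cfg)
        mis = [r.mi for r in compute_modulation(
            units, baseline_window=(60, 1260), fentanyl_window=(1260, 3060))]
        assert abs(np.mean(mis)) < 0.02

    def test_doubled_rate_gives_mean_mi_one_third(self):
        from oralsa.ephys import compute_modulation
        cfg = EphysSimConfig(seed=2, n_units={"ACC": 100},
                             baseline_rate=("fixed", 5.0),
                             modulation={"control": ("fixed", 2.0)},
                             t_saline=60, t_fentanyl=1260, t_end=3060)
        units, _ = simulate_spikes(cfg)
        mis = [r.mi for r in compute_modulation(
            units, baseline_window=(60, 1260), fentanyl_window=(1260, 3060))]
        assert abs(np.mean(mis) - 1 / 3) < 0.02

    def test_seed_determinism_and_truth_table(self):
        cfg = EphysSimConfig(seed=3, n_units={"ACC": 5, "PL": 5},
                             modulation={"control": ("lognormal", 0.0, 0.5)},
                             t_saline=60, t_fentanyl=120, t_end=300)
        u1, t1 = simulate_spikes(cfg)
        u2, t2 = simulate_spikes(cfg)
        assert t1.equals(t2)
        assert all(np.array_equal(a.spike_times, b.spike_times)
                   for a, b in zip(u1.units, u2.units))
        assert set(t1.region) == {"ACC", "PL"}
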