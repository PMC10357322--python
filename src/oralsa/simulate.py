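"""Synthetic event logs, photometry traces and spike trains.

These generators carry the statistical structure the downstream analyses
assume, so every stage is testable without the original recordings:

* operant / home-cage sessions — bouts whose sizes are geometric with a
  per-(port, laser) termination probability, fixed-ratio lick schedules,
  jittered 7 Hz lick trains, post-reward lockouts, optional 2-s laser
  stimulation on half the trials, and serialized RFID-tagged port visits;
* two-channel 20 Hz photometry — slow bleaching (5th-order polynomial or true
  exponential), event-locked negative deflections sustained for the duration
  of a bout, a shared artifact whose gain controls the signal-isosbestic
  correlation, and white sensor noise;
* spike trains — per-unit piecewise-homogeneous Poisson processes whose rate
  is multiplied by a per-unit modulation factor after the fentanyl injection.

Every generator is deterministic under its seed (bit-identical regeneration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bouts as _bouts
from .errors import ConfigError
from .io import Event, PhotometrySession, SessionLog, Unit, UnitSet


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """Study conditions for the operant / home-cage behavior generator.

    ``p_terminate`` may be a float (all conditions), a ``{port: p}`` mapping,
    or a ``{(port, laser): p}`` mapping for the optogenetic contrast.
    Defaults follow the operant procedure: FR5, 7 Hz lick rate with ±30 ms
    jitter, 1-s post-reward lockout, 10-reward cap, laser on 50% of trials
    when enabled, 10 µL rewards of 0.1 mg/mL fentanyl vs quinine.
    """

    schedule: int = 5
    p_terminate: float | dict = 0.5
    laser_fraction: float = 0.0
    lick_rate_hz: float = 7.0
    lick_jitter_s: float = 0.03
    max_rewards_per_trial: Optional[int] = 10
    inter_reward_interval_s: float = 1.0
    inter_trial_gap_min_s: float = 2.0
    inter_trial_gap_mean_s: float = 8.0
    session_duration_s: float = 900.0
    n_trials: Optional[int] = None
    reward_volume_ul: float = 10.0
    port_map: dict = field(default_factory=lambda: {1: "fentanyl", 2: "quinine"})
    dose_mg_per_ml: dict = field(default_factory=lambda: {1: 0.1, 2: 0.0})
    seed: int = 0

    def __post_init__(self):
        for p in self._all_ps():
            if not (0.0 < p <= 1.0):
                raise ConfigError(f"p_terminate must lie in (0, 1], got {p}")
        # within-trial inter-lick gaps must stay below the 1-s rule
        if 1.0 / self.lick_rate_hz + self.lick_jitter_s >= 1.0:
            raise ConfigError(
                "lick_rate_hz too low: within-trial gaps would exceed the 1-s "
                "inter-poke rule and split trials spuriously"
            )
        if self.inter_trial_gap_min_s <= 1.0:
            raise ConfigError("inter-trial gap minimum must exceed the 1-s gap rule")

    def _all_ps(self):
        if isinstance(self.p_terminate, dict):
            return list(self.p_terminate.values())
        return [self.p_terminate]

    def p_for(self, port: int, laser: bool) -> float:
        if isinstance(self.p_terminate, dict):
            if (port, laser) in self.p_terminate:
                return self.p_terminate[(port, laser)]
            if port in self.p_terminate:
                return self.p_terminate[port]
            raise ConfigError(f"no p_terminate entry for port {port}, laser={laser}")
        return self.p_terminate


def draw_bout_sizes(
    p: float, n_trials: int, rng: np.random.Generator,
    max_rewards: Optional[int] = None,
) -> np.ndarray:
    """Geometric bout sizes (support 1, 2, ...), optionally reward-capped."""
    sizes = rng.geometric(p, size=n_trials)
    if max_rewards is not None:
        sizes = np.minimum(sizes, max_rewards)
    return sizes


def _emit_trial(cfg: BehaviorSimConfig, rng, t0: float, port: int,
                laser: bool, size: int, animal: Optional[str] = None):
    """Events of one trial: FR lick trains, rewards 5 ms after the FR-th lick,
    a post-reward lockout before the next train, and optional 2-s laser."""
    events: list[Event] = []
    t = t0
    period = 1.0 / cfg.lick_rate_hz
    for r in range(size):
        for k in range(cfg.schedule):
            if k > 0:
                t += period + rng.uniform(-cfg.lick_jitter_s, cfg.lick_jitter_s)
            events.append(Event(round(t, 6), "lick", port, animal))
        t_reward = round(t + 0.005, 6)
        events.append(Event(t_reward, "reward", port, animal))
        if laser and r == 0:
            events.append(Event(t_reward, "laser_on", port, animal))
            events.append(Event(round(t_reward + 2.0, 6), "laser_off", port, animal))
        t = t_reward + cfg.inter_reward_interval_s  # lockout, licks resume after
    return events, t


def simulate_operant_session(
    cfg: BehaviorSimConfig, session_id: str = "sim-operant",
) -> tuple[SessionLog, pd.DataFrame]:
    """Generate an operant session; returns the log and a ground-truth table.

    The truth table has one row per trial: ``trial, t_start, port, liquid,
    laser, n_rewards`` — the reference for parser and fit-recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    ports = sorted(cfg.port_map)
    events: list[Event] = []
    truth_rows = []
    t = 5.0  # settle-in before first trial
    i = 0
    while True:
        if cfg.n_trials is not None and i >= cfg.n_trials:
            break
        if cfg.n_trials is None and t >= cfg.session_duration_s:
            break
        port = int(rng.choice(ports))
        laser = bool(rng.random() < cfg.laser_fraction)
        p = cfg.p_for(port, laser)
        size = int(draw_bout_sizes(p, 1, rng, cfg.max_rewards_per_trial)[0])
        ev, t_end = _emit_trial(cfg, rng, t, port, laser, size)
        events.extend(ev)
        truth_rows.append({
            "trial": i, "t_start": t, "port": port,
            "liquid": cfg.port_map[port], "laser": laser, "n_rewards": size,
        })
        gap = cfg.inter_trial_gap_min_s + rng.exponential(
            max(cfg.inter_trial_gap_mean_s - cfg.inter_trial_gap_min_s, 1e-9))
        t = t_end + gap
        i += 1
    events.sort(key=lambda e: (e.t, e.kind != "lick"))
    log = SessionLog(
        session_id=session_id, setup="operant",
        port_map=dict(cfg.port_map), dose_mg_per_ml=dict(cfg.dose_mg_per_ml),
        reward_volume_ul=cfg.reward_volume_ul, schedule=cfg.schedule,
        events=events,
    )
    return log, pd.DataFrame(truth_rows)


def simulate_homecage(
    cfg: BehaviorSimConfig,
    animals: Sequence[str],
    n_days: int = 1,
    visits_per_day: int = 40,
) -> tuple[list[SessionLog], pd.DataFrame]:
    """Home-cage epochs with serialized RFID-tagged port visits.

    One log per simulated day; the fentanyl port alternates daily (the
    procedure swaps port identity between days).  Visits never interleave
    (the access tube admits one mouse), and every visit is preceded by an
    ``rfid_read`` for the visiting animal.  Returns the logs and a ground
    truth table (day, visit, animal, port, liquid, n_rewards).
    """
    if not animals:
        raise ConfigError("at least one animal id is required")
    rng = np.random.default_rng(cfg.seed)
    logs: list[SessionLog] = []
    truth_rows = []
    for day in range(n_days):
        if day % 2 == 0:
            port_map = dict(cfg.port_map)
            doses = dict(cfg.dose_mg_per_ml)
        else:  # swap liquids between the two ports
            ports = sorted(cfg.port_map)
            port_map = {ports[0]: cfg.port_map[ports[1]],
                        ports[1]: cfg.port_map[ports[0]]}
            doses = {ports[0]: cfg.dose_mg_per_ml[ports[1]],
                     ports[1]: cfg.dose_mg_per_ml[ports[0]]}
        events: list[Event] = []
        t = 5.0
        for v in range(visits_per_day):
            animal = str(rng.choice(list(animals)))
            port = int(rng.choice(sorted(port_map)))
            events.append(Event(round(t, 6), "rfid_read", None, animal))
            p = cfg.p_for(port, False)
            size = int(draw_bout_sizes(p, 1, rng, cfg.max_rewards_per_trial)[0])
            ev, t_end = _emit_trial(cfg, rng, t + 0.5, port, False, size, animal)
            events.extend(ev)
            truth_rows.append({
                "day": day, "visit": v, "animal": animal, "port": port,
                "liquid": port_map[port], "n_rewards": size,
            })
            gap = cfg.inter_trial_gap_min_s + rng.exponential(
                max(cfg.inter_trial_gap_mean_s - cfg.inter_trial_gap_min_s, 1e-9))
            t = t_end + gap
        events.sort(key=lambda e: (e.t, e.kind != "lick"))
        logs.append(SessionLog(
            session_id=f"sim-homecage-day{day}", setup="homecage",
            port_map=port_map, dose_mg_per_ml=doses,
            reward_volume_ul=cfg.reward_volume_ul, schedule=cfg.schedule,
            events=events,
        ))
    return logs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

@dataclass
class BleachSpec:
    """Slow drift of one channel.

    ``kind='taylor_exp'`` evaluates the 5th-order Taylor polynomial of
    ``amplitude * exp(-t/tau) + offset`` (exactly annihilated by degree-5
    polynomial detrending); ``kind='exp'`` is the true exponential (to probe
    detrending robustness); ``kind='poly'`` takes raw coefficients.
    """

    kind: str = "taylor_exp"
    amplitude: float = 20.0
    tau_s: float = 1200.0
    offset: float = 100.0
    coeffs: Optional[Sequence[float]] = None  # c0..c5 for kind='poly'

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "poly":
            c = np.asarray(self.coeffs if self.coeffs is not None else [0.0])
            return np.polynomial.polynomial.polyval(t, c)
        if self.kind == "exp":
            return self.amplitude * np.exp(-t / self.tau_s) + self.offset
        if self.kind == "taylor_exp":
            x = -t / self.tau_s
            taylor = sum(x ** k / math.factorial(k) for k in range(6))
            return self.amplitude * taylor + self.offset
        raise ConfigError(f"unknown bleach kind {self.kind!r}")


@dataclass
class PhotometrySimConfig:
    """Study conditions for the two-channel trace generator.

    The reward-locked dip is a sustained suppression of ``dip_amplitude``
    from the first to the last reward of a bout, recovering exponentially
    with ``dip_recovery_tau_s`` afterwards (singles recover within 5 s).
    ``artifact_gain`` scales a shared smooth artifact added to both channels;
    increasing it monotonically increases the detrended-channel Pearson r.
    """

    fs: float = 20.0
    bleach_signal: BleachSpec = field(default_factory=BleachSpec)
    bleach_iso: BleachSpec = field(
        default_factory=lambda: BleachSpec(amplitude=10.0, offset=80.0))
    transient_amplitude: float = 1.0   # lick-approach elevation at trial start
    transient_tau_s: float = 1.0
    dip_amplitude: float = 2.0
    dip_recovery_tau_s: float = 1.2
    noise_sd: float = 0.3
    artifact_gain: float = 1.0
    artifact_smooth_s: float = 1.0
    pad_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def dip_waveform(
    t: np.ndarray, t_first: float, t_last: float,
    amplitude: float, recovery_tau_s: float,
) -> np.ndarray:
    """The injected suppression for one bout: -A on [t_first, t_last), then
    exponential recovery.  Exposed so tests can integrate it analytically."""
    out = np.zeros_like(t)
    during = (t >= t_first) & (t < t_last)
    after = t >= t_last
    out[during] = -amplitude
    out[after] = -amplitude * np.exp(-(t[after] - t_last) / recovery_tau_s)
    return out


def _shared_artifact(n: int, fs: float, smooth_s: float, rng) -> np.ndarray:
    """Unit-variance smooth noise common to both channels."""
    white = rng.standard_normal(n)
    win = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(win) / win
    smooth = np.convolve(white, kernel, mode="same")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def simulate_photometry(
    cfg: PhotometrySimConfig, log: SessionLog,
    gap_s: float = 1.0, post_reward_grace_s: Optional[float] = None,
) -> PhotometrySession:
    """Two-channel trace with bout-locked dips derived from the event log."""
    rng = np.random.default_rng(cfg.seed)
    reward_times = [ev.t for ev in log.events if ev.kind == "reward"]
    if not reward_times:
        raise ConfigError("log has no reward events to lock dips to")
    duration = max(ev.t for ev in log.events) + cfg.pad_s
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    grace = post_reward_grace_s
    if grace is None:
        grace = 3.0 if log.setup == "homecage" else 1.0
    trials = _bouts.parse_trials(log, gap_s=gap_s, post_reward_grace_s=grace)

    deflect = np.zeros(n)
    for tr in trials:
        if tr.n_rewards < 1:
            continue
        deflect += dip_waveform(
            t, tr.reward_times[0], tr.reward_times[-1],
            cfg.dip_amplitude, cfg.dip_recovery_tau_s,
        )
        if cfg.transient_amplitude:
            pre = (t >= tr.start - 1.0) & (t < tr.reward_times[0])
            deflect[pre] += cfg.transient_amplitude

    shared = _shared_artifact(n, cfg.fs, cfg.artifact_smooth_s, rng)
    f_signal = (
        cfg.bleach_signal.evaluate(t) + deflect
        + cfg.artifact_gain * shared
        + cfg.noise_sd * rng.standard_normal(n)
    )
    f_iso = (
        cfg.bleach_iso.evaluate(t)
        + cfg.artifact_gain * shared
        + cfg.noise_sd * rng.standard_normal(n)
    )
    return PhotometrySession(
        fs=cfg.fs, t=t, f_signal=f_signal, f_iso=f_iso,
        events=list(log.events), session_id=log.session_id,
    )


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

@dataclass
class EphysSimConfig:
    """Study conditions for the Poisson spike-train generator.

    Epoch times follow the recording procedure: data acquisition starts
    20 min before the saline injection, fentanyl comes 20 min after saline,
    and the recording lasts 30 min after fentanyl.  ``modulation`` maps a
    group label to a per-unit modulation-factor distribution, one of
    ``("fixed", m)``, ``("uniform", a, b)``, ``("lognormal", mu, sigma)`` or
    ``("choice", values, probs)``.
    """

    n_units: dict = field(default_factory=lambda: {"ACC": 30, "PL": 10,
                                                   "IL": 10, "OFC": 10})
    baseline_rate: tuple = ("loguniform", 1.0, 10.0)
    modulation: dict = field(default_factory=lambda: {"control": ("fixed", 1.0)})
    transient_gain: float = 0.0      # extra rate multiplier just after fentanyl
    transient_duration_s: float = 180.0
    t_saline: float = 1200.0
    t_fentanyl: float = 2400.0
    t_end: float = 4200.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.t_saline < self.t_fentanyl < self.t_end):
            raise ConfigError("epochs must satisfy 0 <= t_saline < t_fentanyl < t_end")


def _draw(dist: tuple, rng) -> float:
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(dist[1]), np.log(dist[2]))))
    if kind == "lognormal":
        return float(rng.lognormal(dist[1], dist[2]))
    if kind == "choice":
        values, probs = dist[1], dist[2]
        return float(rng.choice(values, p=probs))
    raise ConfigError(f"unknown distribution kind {kind!r}")


def _poisson_segment(rate: float, t0: float, t1: float, rng) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    count = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=count))


def simulate_spikes(cfg: EphysSimConfig) -> tuple[UnitSet, pd.DataFrame]:
    """Piecewise-homogeneous Poisson spike trains across the injection epochs.

    Rate is ``baseline`` before the fentanyl injection and
    ``baseline x modulation_factor`` after (negative factor draws are clipped
    at 0).  Returns the UnitSet and a ground-truth table with each unit's
    baseline rate and modulation factor.
    """
    rng = np.random.default_rng(cfg.seed)
    units: list[Unit] = []
    truth_rows = []
    for group in sorted(cfg.modulation):
        mod_dist = cfg.modulation[group]
        for region in sorted(cfg.n_units):
            for i in range(cfg.n_units[region]):
                base = max(_draw(cfg.baseline_rate, rng), 0.0)
                factor = max(_draw(mod_dist, rng), 0.0)
                uid = f"{group}-{region}-{i:03d}"
                pre = _poisson_segment(base, 0.0, cfg.t_fentanyl, rng)
                if cfg.transient_gain > 0:
                    t_tr = min(cfg.t_fentanyl + cfg.transient_duration_s, cfg.t_end)
                    seg1 = _poisson_segment(
                        base * factor * (1 + cfg.transient_gain),
                        cfg.t_fentanyl, t_tr, rng)
                    seg2 = _poisson_segment(base * factor, t_tr, cfg.t_end, rng)
                    post = np.concatenate([seg1, seg2])
                else:
                    post = _poisson_segment(
                        base * factor, cfg.t_fentanyl, cfg.t_end, rng)
                units.append(Unit(
                    uid, region, np.concatenate([pre, post]), group=group))
                truth_rows.append({
                    "unit_id": uid, "group": group, "region": region,
                    "baseline_rate": base, "modulation_factor": factor,
                })
    unit_set = UnitSet(units=units, t_saline=cfg.t_saline,
                       t_fentanyl=cfg.t_fentanyl, t_end=cfg.t_end)
    return unit_set, pd.DataFrame(truth_rows)


__all__ = [
    "BehaviorSimConfig", "PhotometrySimConfig", "EphysSimConfig", "BleachSpec",
    "draw_bout_sizes", "dip_waveform",
    "simulate_operant_session", "simulate_homecage", "simulate_photometry",
    "simulate_spikes",
]
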