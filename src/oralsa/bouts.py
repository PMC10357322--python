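"""Trial/bout parsing of lick-reward event streams and consumption summaries.

A *trial* (equivalently a *bout* once it contains >=1 reward) is a maximal run
of same-port licks in which no inter-lick gap exceeds ``gap_s`` (default 1 s,
the inter-poke rule of the operant procedure).  Two refinements mirror the
task logic:

* after a reward, a ``post_reward_grace_s`` interval is instated before the
  gap clock restarts (the task does not count pokes during this lockout), so
  a lick is late only if it arrives after
  ``max(last_lick, last_reward + grace) + gap_s``;
* an optional ``max_rewards`` cap closes the trial at the capping reward.

Home-cage logs have no enforced trial structure; the same gap rule is applied
after RFID attribution, with the grace parameter set to the procedure's
inter-reward lockout (3 s for the photometry-style schedule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import AnalysisError, ValidationError
from .io import Event, SessionLog

logger = logging.getLogger(__name__)


@dataclass
class Trial:
    """A contiguous same-port lick run with its rewards."""

    start: float
    end: float
    port: int
    liquid: str
    n_rewards: int
    laser: bool
    lick_times: np.ndarray
    reward_times: np.ndarray
    animal: Optional[str] = None

    @property
    def rewarded(self) -> bool:
        return self.n_rewards >= 1


@dataclass
class BoutDistribution:
    """Empirical distribution of bout sizes (number of rewards per trial)."""

    counts: dict[int, int]
    n_trials: int
    liquid: Optional[str] = None
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(k < 1 for k in self.counts):
            raise ValidationError("bout sizes must be >= 1")
        if sum(self.counts.values()) != self.n_trials:
            raise ValidationError("counts must sum to n_trials")

    @property
    def sizes(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=int)

    @property
    def n_rewards(self) -> int:
        return sum(n * c for n, c in self.counts.items())

    @property
    def mean_size(self) -> float:
        return self.n_rewards / self.n_trials

    def expand(self) -> np.ndarray:
        """Individual bout sizes, one entry per trial."""
        return np.repeat(self.sizes, [self.counts[s] for s in self.sizes])


@dataclass
class ConsumptionSummary:
    """Per-liquid volume and drug-mass totals, split singles vs bouts."""

    liquid: str
    n_rewards: int
    volume_ml: float
    volume_single_ml: float
    volume_bouts_ml: float
    mass_ug: Optional[float] = None


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_trials(
    log: SessionLog,
    gap_s: float = 1.0,
    max_rewards: Optional[int] = None,
    post_reward_grace_s: float = 1.0,
) -> list[Trial]:
    """Segment an event log into trials by the inter-lick gap rule.

    Returns trials in time order, including unrewarded runs (``n_rewards=0``),
    which downstream bout statistics ignore.  Orphan rewards (no open run) are
    attached to a run that ended within 0.5 s, else dropped with a log message.
    """
    log.validate()
    trials: list[Trial] = []
    cur_licks: list[float] = []
    cur_rewards: list[float] = []
    cur_port: Optional[int] = None
    cur_animal: Optional[str] = None
    last_reward: float = -np.inf
    capped = False

    def close_run():
        nonlocal cur_licks, cur_rewards, cur_port, cur_animal, last_reward, capped
        if cur_port is not None and cur_licks:
            end = max(cur_licks[-1], cur_rewards[-1] if cur_rewards else -np.inf)
            trials.append(Trial(
                start=cur_licks[0],
                end=end,
                port=cur_port,
                liquid=log.port_map.get(cur_port, "water"),
                n_rewards=len(cur_rewards),
                laser=False,
                lick_times=np.array(cur_licks),
                reward_times=np.array(cur_rewards),
                animal=cur_animal,
            ))
        cur_licks, cur_rewards = [], []
        cur_port, cur_animal = None, None
        last_reward = -np.inf
        capped = False

    for ev in log.events:
        if ev.kind == "lick":
            if cur_port is not None:
                deadline = max(cur_licks[-1], last_reward + post_reward_grace_s) + gap_s
                if ev.port != cur_port or ev.animal != cur_animal or ev.t > deadline or capped:
                    close_run()
            if cur_port is None:
                cur_port, cur_animal = ev.port, ev.animal
            cur_licks.append(ev.t)
        elif ev.kind == "reward":
            deadline = (
                max(cur_licks[-1], last_reward + post_reward_grace_s) + gap_s
                if cur_port is not None else -np.inf
            )
            if cur_port is None or ev.port != cur_port or ev.t > deadline or capped:
                # orphan: try the most recent closed run on this port
                if (trials and trials[-1].port == ev.port
                        and 0 <= ev.t - trials[-1].end <= 0.5):
                    prev = trials[-1]
                    prev.reward_times = np.append(prev.reward_times, ev.t)
                    prev.n_rewards += 1
                    prev.end = max(prev.end, ev.t)
                    logger.warning(
                        "orphan reward at t=%.3f attached to preceding run", ev.t)
                else:
                    logger.warning("orphan reward at t=%.3f dropped", ev.t)
                continue
            cur_rewards.append(ev.t)
            last_reward = ev.t
            if max_rewards is not None and len(cur_rewards) >= max_rewards:
                capped = True
    close_run()

    # laser flag: laser_on event within [start, end] of a trial
    laser_times = [ev.t for ev in log.events if ev.kind == "laser_on"]
    for t_laser in laser_times:
        hit = False
        for tr in trials:
            if tr.start <= t_laser <= tr.end:
                tr.laser = True
                hit = True
                break
        if not hit:
            logger.warning("laser_on at t=%.3f outside any trial; ignored", t_laser)
    return trials


def attribute_rewards(log: SessionLog) -> SessionLog:
    """Fill each lick/reward's animal from the most recent RFID read.

    Events preceding the first read stay unassigned (``animal=None``) and are
    excluded from per-animal summaries downstream.
    """
    if log.setup != "homecage":
        raise AnalysisError("RFID attribution applies to home-cage logs only")
    if not any(ev.kind == "rfid_read" for ev in log.events):
        raise AnalysisError("log contains no rfid_read events; cannot attribute")
    current: Optional[str] = None
    out = []
    for ev in log.events:
        if ev.kind == "rfid_read":
            current = ev.animal
            out.append(ev)
        elif ev.kind in ("lick", "reward"):
            out.append(Event(ev.t, ev.kind, ev.port, current))
        else:
            out.append(ev)
    return SessionLog(
        session_id=log.session_id,
        setup=log.setup,
        port_map=dict(log.port_map),
        dose_mg_per_ml=dict(log.dose_mg_per_ml),
        reward_volume_ul=log.reward_volume_ul,
        schedule=log.schedule,
        events=out,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _filter(trials, liquid=None, laser=None, animal=None, rewarded=True):
    out = []
    for tr in trials:
        if rewarded and tr.n_rewards < 1:
            continue
        if liquid is not None and tr.liquid != liquid:
            continue
        if laser is not None and tr.laser != laser:
            continue
        if animal is not None and tr.animal != animal:
            continue
        out.append(tr)
    return out


def bout_size_distribution(
    trials: list[Trial],
    liquid: Optional[str] = None,
    laser: Optional[bool] = None,
    animal: Optional[str] = None,
) -> BoutDistribution:
    sel = _filter(trials, liquid, laser, animal)
    if not sel:
        raise AnalysisError("no rewarded trials left after filtering")
    counts: dict[int, int] = {}
    for tr in sel:
        counts[tr.n_rewards] = counts.get(tr.n_rewards, 0) + 1
    return BoutDistribution(
        counts=counts, n_trials=len(sel), liquid=liquid,
        condition={"laser": laser, "animal": animal},
    )


def fraction_in_bouts(trials: list[Trial], liquid: Optional[str] = None) -> float:
    """Percentage of rewards consumed in trials of >= 2 rewards."""
    dist = bout_size_distribution(trials, liquid=liquid)
    total = dist.n_rewards
    if total == 0:
        raise AnalysisError("zero rewards; bouts fraction undefined")
    in_bouts = sum(n * c for n, c in dist.counts.items() if n >= 2)
    return 100.0 * in_bouts / total


def prob_single(trials: list[Trial], liquid: Optional[str] = None,
                laser: Optional[bool] = None) -> float:
    """Probability that a rewarded trial terminates after exactly one reward."""
    dist = bout_size_distribution(trials, liquid=liquid, laser=laser)
    return dist.counts.get(1, 0) / dist.n_trials


def cumulative_consumption_curve(
    trials: list[Trial], liquid: Optional[str] = None
) -> dict[int, float]:
    """Cumulative fraction of total volume consumed in bouts of size <= n.

    With constant reward volume this is reward-weighted; returns a
    nondecreasing mapping reaching 1.0 at the maximum observed bout size.
    """
    dist = bout_size_distribution(trials, liquid=liquid)
    total = dist.n_rewards
    if total == 0:
        raise AnalysisError("zero rewards; consumption curve undefined")
    curve = {}
    acc = 0
    for n in sorted(dist.counts):
        acc += n * dist.counts[n]
        curve[n] = acc / total
    return curve


def consumption_summary(
    trials: list[Trial],
    log: SessionLog,
    liquid: str,
) -> ConsumptionSummary:
    """Volume (mL) and drug mass (µg) for one liquid, split singles vs bouts.

    volume_mL = n_rewards x reward_volume_ul / 1000;
    mass_µg   = volume_mL x dose_mg_per_mL x 1000.
    """
    sel = _filter(trials, liquid=liquid)
    n_single = sum(tr.n_rewards for tr in sel if tr.n_rewards == 1)
    n_bouts = sum(tr.n_rewards for tr in sel if tr.n_rewards >= 2)
    n_total = n_single + n_bouts
    vol = n_total * log.reward_volume_ul / 1000.0
    vol_single = n_single * log.reward_volume_ul / 1000.0
    vol_bouts = n_bouts * log.reward_volume_ul / 1000.0
    ports = [p for p, liq in log.port_map.items() if liq == liquid]
    doses = {log.dose_mg_per_ml[p] for p in ports if p in log.dose_mg_per_ml}
    mass = None
    if len(doses) == 1:
        mass = vol * doses.pop() * 1000.0
    return ConsumptionSummary(
        liquid=liquid, n_rewards=n_total, volume_ml=vol,
        volume_single_ml=vol_single, volume_bouts_ml=vol_bouts, mass_ug=mass,
    )


__all__ = [
    "Trial", "BoutDistribution", "ConsumptionSummary",
    "parse_trials", "attribute_rewards", "bout_size_distribution",
    "fraction_in_bouts", "prob_single", "cumulative_consumption_curve",
    "consumption_summary",
]
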