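"""Firing-rate modulation analysis of units around saline/fentanyl injections.

The fentanyl modulation index of a unit is

    MI = (fr_fent − fr_base) / (fr_fent + fr_base)

with fr_base the mean rate in a post-saline baseline epoch and fr_fent the
mean rate in a fentanyl epoch.  |MI| = 1/3 corresponds exactly to a 2-fold
rate change, which sets the classification cutoff (up if MI > 1/3, down if
MI < −1/3).  Epoch defaults: baseline [t_saline + 60 s, t_fentanyl] (so acute
injection effects are shared by both injections), fentanyl epoch
[t_fentanyl + 300 s, t_fentanyl + 1500 s]; both configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import AnalysisError
from .io import UnitSet

logger = logging.getLogger(__name__)

MI_THRESHOLD = 1.0 / 3.0


@dataclass
class FiringRateMatrix:
    rates: np.ndarray          # units x bins, Hz
    bin_s: float
    unit_ids: list[str]
    regions: list[str]
    groups: list[Optional[str]]
    t_saline: float
    t_fentanyl: float

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.rates.shape[1]) + 0.5) * self.bin_s


@dataclass
class ModulationResult:
    unit_id: str
    region: str
    fr_base: float
    fr_fent: float
    mi: float
    klass: str = "unmodulated"
    group: Optional[str] = None


def bin_firing_rates(units: UnitSet, bin_s: float = 10.0) -> FiringRateMatrix:
    """Spike counts / bin_s on bins tiling [0, t_end]; a trailing partial bin
    is dropped."""
    if bin_s <= 0:
        raise AnalysisError("bin_s must be positive")
    n_bins = int(units.t_end // bin_s)
    edges = np.arange(n_bins + 1) * bin_s
    rates = np.empty((len(units.units), n_bins))
    for i, u in enumerate(units.units):
        counts, _ = np.histogram(u.spike_times, bins=edges)
        rates[i] = counts / bin_s
    return FiringRateMatrix(
        rates=rates, bin_s=bin_s,
        unit_ids=[u.unit_id for u in units.units],
        regions=[u.region for u in units.units],
        groups=[u.group for u in units.units],
        t_saline=units.t_saline, t_fentanyl=units.t_fentanyl,
    )


def normalize_rates(
    mat: FiringRateMatrix, baseline_end: Optional[float] = None,
) -> tuple[FiringRateMatrix, list[str]]:
    """Per-unit z-scoring against the pre-saline baseline window.

    Units with zero baseline SD are excluded; their ids are returned.
    """
    if baseline_end is None:
        baseline_end = mat.t_saline
    n_base = int(baseline_end // mat.bin_s)
    if n_base < 2:
        raise AnalysisError("baseline window must contain at least 2 bins")
    base = mat.rates[:, :n_base]
    mu = base.mean(axis=1)
    sd = base.std(axis=1)
    keep = sd > 0
    excluded = [uid for uid, k in zip(mat.unit_ids, keep) if not k]
    if not np.any(keep):
        raise AnalysisError("all units have zero baseline SD")
    if excluded:
        logger.warning("excluded %d zero-baseline-SD units", len(excluded))
    norm = (mat.rates[keep] - mu[keep, None]) / sd[keep, None]
    out = FiringRateMatrix(
        rates=norm, bin_s=mat.bin_s,
        unit_ids=[u for u, k in zip(mat.unit_ids, keep) if k],
        regions=[r for r, k in zip(mat.regions, keep) if k],
        groups=[g for g, k in zip(mat.groups, keep) if k],
        t_saline=mat.t_saline, t_fentanyl=mat.t_fentanyl,
    )
    return out, excluded


def modulation_index(fr_base: float, fr_fent: float) -> float:
    """(fent − base)/(fent + base); antisymmetric in its arguments, |MI| <= 1."""
    if fr_base < 0 or fr_fent < 0:
        raise AnalysisError("firing rates must be non-negative")
    total = fr_base + fr_fent
    if total == 0:
        raise AnalysisError("both epoch rates are zero: MI undefined")
    return (fr_fent - fr_base) / total


def _epoch_rate(spikes: np.ndarray, t0: float, t1: float) -> float:
    if t1 <= t0:
        raise AnalysisError("epoch window is empty")
    return float(np.count_nonzero((spikes >= t0) & (spikes < t1)) / (t1 - t0))


def compute_modulation(
    units: UnitSet,
    baseline_window: Optional[tuple[float, float]] = None,
    fentanyl_window: Optional[tuple[float, float]] = None,
    threshold: float = MI_THRESHOLD,
) -> list[ModulationResult]:
    """Epoch rates, MI and up/down class per unit.

    Units silent in both epochs are excluded (logged).
    """
    if baseline_window is None:
        baseline_window = (units.t_saline + 60.0, units.t_fentanyl)
    if fentanyl_window is None:
        fentanyl_window = (units.t_fentanyl + 300.0,
                           min(units.t_fentanyl + 1500.0, units.t_end))
    results = []
    n_excluded = 0
    for u in units.units:
        fr_base = _epoch_rate(u.spike_times, *baseline_window)
        fr_fent = _epoch_rate(u.spike_times, *fentanyl_window)
        if fr_base + fr_fent == 0:
            n_excluded += 1
            continue
        mi = modulation_index(fr_base, fr_fent)
        results.append(ModulationResult(
            unit_id=u.unit_id, region=u.region, fr_base=fr_base,
            fr_fent=fr_fent, mi=mi, group=u.group,
        ))
    if n_excluded:
        logger.warning("excluded %d units silent in both epochs", n_excluded)
    return classify_units(results, threshold)


def classify_units(
    results: list[ModulationResult], threshold: float = MI_THRESHOLD,
) -> list[ModulationResult]:
    """Strict-inequality classification: up if MI > threshold, down if
    MI < −threshold, else unmodulated."""
    for r in results:
        if r.mi > threshold:
            r.klass = "up"
        elif r.mi < -threshold:
            r.klass = "down"
        else:
            r.klass = "unmodulated"
    return results


def region_proportions(
    results: list[ModulationResult],
    regions: Optional[list[str]] = None,
    group: Optional[str] = None,
) -> dict[str, dict]:
    """Per-region counts of up/down units: {region: {up: k, down: k, n: n}}."""
    if group is not None:
        results = [r for r in results if r.group == group]
    if regions is None:
        regions = sorted({r.region for r in results})
    out = {}
    for region in regions:
        sel = [r for r in results if r.region == region]
        if not sel:
            logger.warning("region %s has no units; omitted", region)
            continue
        out[region] = {
            "up": sum(r.klass == "up" for r in sel),
            "down": sum(r.klass == "down" for r in sel),
            "n": len(sel),
        }
    return out


def modulation_timecourse(
    norm_mat: FiringRateMatrix, window_s: float = 60.0,
    group: Optional[str] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Population mean normalized rate in consecutive windows of ``window_s``.

    Returns (window centers, mean curve); curve length = floor(duration/window).
    """
    rates = norm_mat.rates
    if group is not None:
        sel = np.array([g == group for g in norm_mat.groups])
        rates = rates[sel]
    bins_per_win = max(int(round(window_s / norm_mat.bin_s)), 1)
    n_win = rates.shape[1] // bins_per_win
    trimmed = rates[:, :n_win * bins_per_win]
    curve = trimmed.reshape(rates.shape[0], n_win, bins_per_win).mean(axis=(0, 2))
    centers = (np.arange(n_win) + 0.5) * bins_per_win * norm_mat.bin_s
    return centers, curve


__all__ = [
    "FiringRateMatrix", "ModulationResult", "MI_THRESHOLD",
    "bin_firing_rates", "normalize_rates", "modulation_index",
    "compute_modulation", "classify_units", "region_proportions",
    "modulation_timecourse",
]
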