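"""Single-parameter geometric model of bout termination.

Each reward ends the bout with probability ``p_terminate``, so the bout-size
pmf is P(n) = (1 - p)^(n-1) * p for n >= 1.  The headline fit minimizes the
unweighted sum of squared residuals between the observed relative frequencies
and the pmf over support 1..max observed size (unobserved interior sizes enter
as zero frequencies).  The closed-form maximum-likelihood estimate
p = 1/mean(bout size) is provided as a cross-check, and an optional
censored-top-bin pmf handles reward-capped sessions (a cap accumulates the
geometric tail at the cap size rather than removing it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .bouts import BoutDistribution, Trial, bout_size_distribution
from .errors import AnalysisError

P_MIN = 1e-6


@dataclass
class GeometricFit:
    p_terminate: float
    method: str
    n_bouts: int
    sse: float = 0.0
    converged: bool = True
    low_n: bool = False

    @property
    def mean_bout_size(self) -> float:
        return 1.0 / self.p_terminate


def geom_pmf(p: float, n) -> np.ndarray | float:
    """P(bout of size n) = (1-p)^(n-1) * p, for integer n >= 1."""
    n_arr = np.asarray(n)
    if not (P_MIN / 10 < p <= 1):
        raise AnalysisError(f"p must lie in (0, 1], got {p}")
    if np.any(n_arr < 1) or np.any(n_arr != np.floor(n_arr)):
        raise AnalysisError("bout size n must be an integer >= 1")
    out = (1.0 - p) ** (n_arr - 1) * p
    return out if out.ndim else float(out)


def _capped_pmf(p, n, n_max):
    """Geometric pmf with a right-censored top bin: a reward cap at n_max
    piles the entire tail mass (1-p)^(n_max-1) onto size n_max."""
    n = np.asarray(n)
    out = geom_pmf(p, n)
    return np.where(n == n_max, (1.0 - p) ** (n_max - 1), out)


def _objective_frequencies(dist: BoutDistribution):
    n_max = int(dist.sizes.max())
    support = np.arange(1, n_max + 1)
    freqs = np.array([dist.counts.get(int(n), 0) / dist.n_trials for n in support])
    return support, freqs


def sse_at(p: float, dist: BoutDistribution, capped: bool = False) -> float:
    """The least-squares objective at a given p (used by the grid oracle)."""
    support, freqs = _objective_frequencies(dist)
    model = _capped_pmf(p, support, support[-1]) if capped \
        else geom_pmf(p, support)
    return float(np.sum((freqs - model) ** 2))


def fit_geometric_ls(dist: BoutDistribution, capped: bool = False) -> GeometricFit:
    """Least-squares fit of the geometric pmf to relative bout-size frequencies.

    With ``capped=True`` the top observed size is modeled as right-censored
    (a reward cap accumulates the geometric tail there).
    """
    if dist.n_trials < 1:
        raise AnalysisError("empty bout distribution")
    support, freqs = _objective_frequencies(dist)
    n_max = support[-1]
    if capped:
        def model(n, p):
            return _capped_pmf(p, n, n_max)
    else:
        def model(n, p):
            return geom_pmf(p, n)
    p0 = min(1.0, max(P_MIN, 1.0 / dist.mean_size))
    converged = True
    try:
        popt, _ = curve_fit(
            model, support.astype(float), freqs,
            p0=[p0], bounds=(P_MIN, 1.0), maxfev=10000,
        )
        p_hat = float(popt[0])
    except RuntimeError:
        converged = False
        grid = np.linspace(P_MIN, 1.0, 10001)
        sses = [sse_at(p, dist, capped) for p in grid]
        p_hat = float(grid[int(np.argmin(sses))])
    return GeometricFit(
        p_terminate=p_hat, method="least_squares", n_bouts=dist.n_trials,
        sse=sse_at(p_hat, dist, capped), converged=converged,
    )


def fit_geometric_mle(dist: BoutDistribution) -> GeometricFit:
    """Closed-form maximum-likelihood estimate p = 1/mean(bout size)."""
    if dist.n_trials < 1:
        raise AnalysisError("empty bout distribution")
    p_hat = 1.0 / dist.mean_size
    return GeometricFit(p_terminate=p_hat, method="mle", n_bouts=dist.n_trials)


def fit_by_condition(
    trials: list[Trial],
    by_animal: bool = True,
    by_liquid: bool = True,
    by_laser: bool = True,
    method: str = "least_squares",
    min_bouts: int = 10,
    capped: bool = False,
) -> dict[tuple, GeometricFit]:
    """One fit per (animal, liquid, laser) cell of rewarded trials.

    Cells with fewer than ``min_bouts`` bouts are fitted but flagged
    ``low_n``; empty cells are skipped.
    """
    cells: dict[tuple, list[Trial]] = {}
    for tr in trials:
        if tr.n_rewards < 1:
            continue
        key = (
            tr.animal if by_animal else None,
            tr.liquid if by_liquid else None,
            tr.laser if by_laser else None,
        )
        cells.setdefault(key, []).append(tr)
    fits = {}
    for key, cell in sorted(cells.items(), key=lambda kv: str(kv[0])):
        dist = bout_size_distribution(cell)
        if method == "mle":
            fit = fit_geometric_mle(dist)
        else:
            fit = fit_geometric_ls(dist, capped=capped)
        fit.low_n = dist.n_trials < min_bouts
        fits[key] = fit
    return fits


__all__ = [
    "GeometricFit", "geom_pmf", "sse_at",
    "fit_geometric_ls", "fit_geometric_mle", "fit_by_condition",
]
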