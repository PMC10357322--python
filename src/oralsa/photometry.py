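"""Fiber-photometry preprocessing and peri-event analysis.

The pipeline order is fixed:

1. detrend both channels with a least-squares 5th-degree polynomial in time
   (photobleaching removal);
2. compute the Pearson correlation of the detrended channels and branch:
   r > 0.97 → session rejected (unreliable signal); 0.25 < r <= 0.97 →
   isosbestic scaled (OLS) and subtracted; r <= 0.25 → no subtraction (the
   subtraction would only add noise);
3. subtract the trace minimum (non-negativity), anchor F1 at a low percentile
   (default the 1st) and form ΔF/F = (F − F1)/F1;
4. z-score ΔF/F over the session (population SD).

Peri-event analysis aligns z(ΔF/F) to the first (or every) reward of a trial
on the half-open grid [−5, +5) s and summarizes each trial by the dip
statistic: mean over [0, +5) minus mean over [−5, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import pearsonr

from .bouts import Trial
from .errors import AnalysisError
from .io import PhotometrySession

QC_HIGH_DEFAULT = 0.97
QC_LOW_DEFAULT = 0.25


@dataclass
class ProcessedTrace:
    """Output of the per-session preprocessing pipeline."""

    pearson_r: float
    qc_status: str  # rejected | iso_subtracted | not_subtracted
    dff: Optional[np.ndarray] = None
    zdff: Optional[np.ndarray] = None
    f1: Optional[float] = None
    fs: float = 20.0
    session_id: str = ""

    @property
    def rejected(self) -> bool:
        return self.qc_status == "rejected"


@dataclass
class PeriEventMatrix:
    """Trials x samples of z(ΔF/F) aligned to a per-trial reward."""

    matrix: np.ndarray
    labels: list[dict]                 # per-row {liquid, bout, trial_index}
    window: tuple[float, float]
    fs: float
    n_excluded: int = 0

    @property
    def event_index(self) -> int:
        return int(round(-self.window[0] * self.fs))


@dataclass
class DipResult:
    """Per-trial post-minus-pre deltas and per-label aggregates."""

    deltas: np.ndarray
    labels: list[dict]
    by_label: dict = field(default_factory=dict)  # (liquid, bout) -> (mean, sem, n)


def detrend(trace: np.ndarray, degree: int = 5) -> np.ndarray:
    """Subtract the least-squares polynomial of the given degree in time.

    The time axis is rescaled to [−1, 1] for conditioning; the subtracted
    values equal the naive-basis fit in exact arithmetic.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 2 * (degree + 1):
        raise AnalysisError(
            f"need at least {2 * (degree + 1)} samples for degree-{degree} detrend")
    x = np.linspace(-1.0, 1.0, len(trace))
    coefs = np.polynomial.polynomial.polyfit(x, trace, degree)
    return trace - np.polynomial.polynomial.polyval(x, coefs)


def qc_decision(
    sig_adj: np.ndarray, iso_adj: np.ndarray,
    qc_high: float = QC_HIGH_DEFAULT, qc_low: float = QC_LOW_DEFAULT,
) -> tuple[float, str]:
    """Pearson r of the detrended channels and the resulting QC branch."""
    sig_adj = np.asarray(sig_adj, float)
    iso_adj = np.asarray(iso_adj, float)
    if len(sig_adj) != len(iso_adj) or len(sig_adj) < 3:
        raise AnalysisError("channels must have equal length >= 3")
    if sig_adj.std() == 0 or iso_adj.std() == 0:
        raise AnalysisError("zero-variance channel: correlation undefined")
    r = float(pearsonr(sig_adj, iso_adj).statistic)
    if r > qc_high:
        status = "rejected"
    elif r > qc_low:
        status = "iso_subtracted"
    else:
        status = "not_subtracted"
    return r, status


def isosbestic_correct(sig_adj: np.ndarray, iso_adj: np.ndarray) -> np.ndarray:
    """Scale the isosbestic to the signal (OLS with intercept) and subtract.

    The residual is analytically uncorrelated with the isosbestic trace.
    """
    iso_adj = np.asarray(iso_adj, float)
    sig_adj = np.asarray(sig_adj, float)
    var = iso_adj.var()
    if var == 0:
        raise AnalysisError("zero-variance isosbestic: cannot scale")
    slope = np.cov(sig_adj, iso_adj, bias=True)[0, 1] / var
    intercept = sig_adj.mean() - slope * iso_adj.mean()
    return sig_adj - (slope * iso_adj + intercept)


def compute_dff(trace: np.ndarray, percentile: float = 1.0
                ) -> tuple[np.ndarray, float]:
    """Min-subtract, anchor F1 at a low percentile, return ((F−F1)/F1, F1)."""
    trace = np.asarray(trace, float)
    shifted = trace - trace.min()
    f1 = float(np.percentile(shifted, percentile))
    if f1 <= 0:
        raise AnalysisError(
            "degenerate ΔF/F scale: the percentile anchor equals the minimum; "
            "raise the percentile"
        )
    return (shifted - f1) / f1, f1


def zscore_session(dff: np.ndarray) -> np.ndarray:
    """Session z-score with population (n-denominator) SD."""
    dff = np.asarray(dff, float)
    sd = dff.std()
    if sd == 0:
        raise AnalysisError("zero-variance trace: z-score undefined")
    return (dff - dff.mean()) / sd


def process_session(
    session: PhotometrySession,
    percentile: float = 1.0,
    qc_high: float = QC_HIGH_DEFAULT,
    qc_low: float = QC_LOW_DEFAULT,
) -> ProcessedTrace:
    """Run the full preprocessing pipeline on one session."""
    sig_adj = detrend(session.f_signal)
    iso_adj = detrend(session.f_iso)
    r, status = qc_decision(sig_adj, iso_adj, qc_high, qc_low)
    if status == "rejected":
        return ProcessedTrace(pearson_r=r, qc_status=status, fs=session.fs,
                              session_id=session.session_id)
    corrected = isosbestic_correct(sig_adj, iso_adj) \
        if status == "iso_subtracted" else sig_adj
    dff, f1 = compute_dff(corrected, percentile)
    zdff = zscore_session(dff)
    return ProcessedTrace(
        pearson_r=r, qc_status=status, dff=dff, zdff=zdff, f1=f1,
        fs=session.fs, session_id=session.session_id,
    )


def peri_event_matrix(
    zdff: np.ndarray,
    trials: list[Trial],
    fs: float = 20.0,
    window: tuple[float, float] = (-5.0, 5.0),
    align: str = "first_reward",
) -> PeriEventMatrix:
    """Align z(ΔF/F) to per-trial rewards on the half-open grid [lo, hi).

    ``align='first_reward'`` yields one row per rewarded trial;
    ``align='every_reward'`` yields one row per reward (per-reward recovery
    analysis).  Rows whose window leaves the session are excluded and
    counted in ``n_excluded``.
    """
    zdff = np.asarray(zdff, float)
    lo, hi = window
    n_samples = int(round((hi - lo) * fs))
    rows, labels = [], []
    n_excluded = 0
    for i, tr in enumerate(trials):
        if tr.n_rewards < 1:
            continue
        if align == "first_reward":
            align_times = [tr.reward_times[0]]
        elif align == "every_reward":
            align_times = list(tr.reward_times)
        else:
            raise AnalysisError(f"unknown alignment {align!r}")
        for t0 in align_times:
            start = int(round((t0 + lo) * fs))
            stop = start + n_samples
            if start < 0 or stop > len(zdff):
                n_excluded += 1
                continue
            rows.append(zdff[start:stop])
            labels.append({
                "liquid": tr.liquid,
                "bout": tr.n_rewards >= 2,
                "trial_index": i,
            })
    matrix = np.vstack(rows) if rows else np.empty((0, n_samples))
    return PeriEventMatrix(matrix=matrix, labels=labels, window=window,
                           fs=fs, n_excluded=n_excluded)


def dip_statistic(mat: PeriEventMatrix) -> DipResult:
    """Per-row mean over [0, +5) minus mean over [−5, 0), aggregated by label."""
    if mat.matrix.shape[0] == 0:
        raise AnalysisError("empty peri-event matrix")
    idx0 = mat.event_index
    pre = mat.matrix[:, :idx0].mean(axis=1)
    post = mat.matrix[:, idx0:].mean(axis=1)
    deltas = post - pre
    by_label: dict = {}
    for key in sorted({(lab["liquid"], lab["bout"]) for lab in mat.labels}):
        sel = np.array([
            (lab["liquid"], lab["bout"]) == key for lab in mat.labels])
        d = deltas[sel]
        sem = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.nan
        by_label[key] = (float(d.mean()), float(sem), int(len(d)))
    return DipResult(deltas=deltas, labels=mat.labels, by_label=by_label)


__all__ = [
    "ProcessedTrace", "PeriEventMatrix", "DipResult",
    "detrend", "qc_decision", "isosbestic_correct", "compute_dff",
    "zscore_session", "process_session", "peri_event_matrix", "dip_statistic",
]
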