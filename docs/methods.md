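# Methods

This note documents the models implemented by `oralsa`, the defaults and
numerical choices behind them, and what the synthetic-data generators do and
do not emulate.

## Behavioral event model and bout parsing

Events are timestamped licks, rewards, laser on/off TTLs and RFID reads, in
seconds from session start. The trial (= bout) parser follows the operant
task logic: a trial is a maximal run of same-port licks in which every
inter-lick gap is at most `gap_s` (default 1 s). Two refinements mirror the
task controller:

- after each reward a `post_reward_grace_s` lockout is instated before the
  gap clock restarts, so a lick is late only after
  `max(last_lick, last_reward + grace) + gap_s`. The grace defaults to 1 s
  (operant/optogenetic schedule) and should be set to 3 s for the
  photometry-style and home-cage schedules, whose pumps enforce a 3-s
  inter-reward interval;
- an optional `max_rewards` cap (10 in the optogenetic schedule) closes the
  trial at the capping reward.

Home-cage streams have no hardware-enforced trial structure; after RFID
attribution (each lick/reward is assigned to the most recent tag read, and
events before the first read are left unassigned) the same gap rule is
applied. This reuse of the operant rule for home-cage segmentation is an
analysis choice, surfaced as parameters rather than hard-coded.

Unrewarded lick runs are retained as 0-reward trials but excluded from all
bout statistics, so `prob_single` denominators count rewarded trials only.
Consumption accounting is exact: volume = rewards × reward volume (10 µL by
default), drug mass = volume × concentration, and the single/bout split
always sums to the total.

## Geometric bout-termination model

If every reward independently terminates the bout with probability `p`, bout
sizes are geometric, `P(n) = (1−p)^(n−1) p`. The headline estimator
minimizes the unweighted sum of squared differences between this pmf and the
observed relative frequencies over support 1..max observed size, with
unobserved interior sizes entering as zero frequencies; optimization uses
`scipy.optimize.curve_fit` with `p` constrained to (1e-6, 1] and initial
value 1/mean(size). The closed-form MLE `p = 1/mean(size)` is provided as a
diagnostic cross-check; both are consistent and agree within 0.02 on 10,000
geometric draws. Fits are performed per (animal, liquid, laser) cell, with
cells under 10 bouts flagged `low_n`.

A reward cap *censors* the distribution — all tail mass accumulates at the
cap size — rather than truncating it. The optional `capped=True` fit
therefore models the top bin as `P(cap) = (1−p)^(cap−1)`; the
renormalized-truncated alternative was tested and cannot recover `p` from
capped draws (it attributes the cap spike to a heavy geometric tail). The
flag is off by default, matching the plain fit used for uncapped sessions.

## Photometry pipeline

Order is fixed: detrend → QC → (isosbestic subtraction) → min-subtract →
ΔF/F → z-score.

- **Detrend.** Least-squares 5th-degree polynomial in time, fitted on a
  time axis rescaled to [−1, 1] for conditioning (identical subtraction in
  exact arithmetic). At least 12 samples are required.
- **QC.** Pearson r of the two detrended channels: r > 0.97 rejects the
  session (signal dominated by a shared artifact); 0.25 < r ≤ 0.97 triggers
  isosbestic subtraction; r ≤ 0.25 skips it (subtraction would only add
  isosbestic noise). Thresholds are parameters.
- **Isosbestic subtraction.** OLS of signal on isosbestic *with intercept*;
  the residual is analytically uncorrelated with the isosbestic, making the
  operation idempotent. Whether the original scaling included an intercept
  is not documented; OLS-with-intercept is the standard choice.
- **ΔF/F.** The minimum is subtracted first (non-negativity), then
  F₁ = 1st percentile of the shifted trace (linear-interpolation percentile)
  anchors ΔF/F = (F − F₁)/F₁. "Lowest percentile" is read as percentile
  index 1; the percentile is a parameter. A constant trace makes F₁ = 0 and
  raises a descriptive error. ΔF/F is invariant to any positive gain on the
  raw trace.
- **z-score.** Population (n-denominator) SD over the session; the
  convention is fixed so exact assertions are possible.

Peri-event rows are sampled on the half-open grid [−5, +5) s at the session
rate (200 samples at 20 Hz, event at index 100), aligned to the first reward
of each trial (or to every reward, for per-reward recovery analyses); rows
whose window leaves the session are excluded and counted. The dip statistic
is the mean over [0, +5) minus the mean over [−5, 0) per row, aggregated by
(liquid, single/bout) label. The [−5, 0) baseline is taken literally and
includes the pre-reward licking period. Hemispheres are processed
independently; no pooling is applied.

## Spike modulation

Rates are binned at 10 s (heatmap normalization z-scores each unit against
its pre-saline baseline bins; zero-SD units are excluded and reported).
Epoch rates use configurable windows; the defaults are
baseline = [t_saline + 60 s, t_fentanyl] — post-saline so acute injection
effects are common to both epochs — and fentanyl = [t_fentanyl + 300 s,
t_fentanyl + 1500 s], within a recording that lasts 30 min after the
fentanyl injection. Neither window nor the bin width is externally
specified; these are the package's defaults and all are parameters.

MI = (fent − base)/(fent + base) is the unique symmetric index for which a
2-fold rate change gives |MI| = 1/3, matching the stated cutoff;
classification uses strict inequalities (MI exactly 1/3 is unmodulated).
Units silent in both epochs are excluded and reported.

## Inferential tests

The two-proportion z-test uses the pooled variance, no continuity
correction, and is signed as (group 2 − group 1) so that a smaller
experimental fraction yields a negative statistic; this convention, with
normal two-sided p-values, reproduces published per-region statistics from
their count pairs to three decimals. z² is identically the 2×2 Pearson
chi-square (scipy, `correction=False`), kept as a separate route for
cross-checking. Paired t (sample SD, df = n−1) and tie-corrected
Kruskal-Wallis delegate to scipy. Linear mixed models are out of scope; the
pipeline emits tidy per-animal tables suitable for external LMM tooling.

## Synthetic-data generators

All generators are deterministic under their seed (bit-identical output).

**Behavior.** Trials draw a geometric bout size at the configured
`p_terminate` (per port, or per port × laser state), emit FR-schedule lick
trains as jittered regular trains at 7 Hz (±30 ms) — fast enough that the
1-s gap rule never splits a trial from within — deliver the reward 5 ms
after the FR-th lick, pause for the inter-reward lockout, and separate
trials by a shifted-exponential gap with a 2-s minimum so the parser always
separates them. Laser trials (a configurable fraction, 50% in the
optogenetic design) receive `laser_on` at the first reward and `laser_off`
2 s later. The home-cage generator serializes visits of tagged animals
(one mouse fits the access tube), precedes each visit with an RFID read, and
swaps the fentanyl port daily. Lick-rate and inter-trial-gap distributions
are not documented for the original task; the defaults here are plausible
for mouse licking (~7 Hz) and are configurable. Each generator returns a
ground-truth table (bout sizes, laser flags, visiting animal) against which
the parser and the fits are tested — on these logs parsing recovers the
truth exactly.

**Photometry.** f_signal = bleach + event-locked deflections + shared
artifact × gain + white noise; f_iso = bleach + shared artifact × gain +
noise. Bleaching defaults to the 5th-order Taylor polynomial of a decaying
exponential (annihilated exactly by the degree-5 detrend), toggleable to a
true exponential to probe detrending robustness. The bout dip is a
sustained −A suppression from first to last reward with exponential recovery
(τ = 1.2 s, so single rewards recover within 5 s); its waveform is exposed
(`dip_waveform`) so tests can compare recovered dip statistics against the
analytic window average of the injected kernel. The shared artifact is
unit-variance smoothed noise; its gain monotonically raises the detrended
channel correlation, and the regimes gain = 0 / 1 / 50 land in the
not-subtracted / subtracted / rejected QC branches (1.0 is the default —
real recordings share motion and hemodynamic components, which is the reason
the isosbestic branch exists). The generator does not model calcium
indicator kinetics, hemodynamics, or movement artifacts with realistic
spectra — passing tests demonstrate correctness of the pipeline's
operations, not biological fidelity of any particular trace.

**Spikes.** Per-unit piecewise-homogeneous Poisson processes: baseline rate
(log-uniform 1–10 Hz by default) before the fentanyl injection, baseline ×
modulation factor after, with factor distributions configurable per group
and negative draws clipped at zero. An optional transient gain in the first
minutes after injection supports timecourse analyses. Epoch defaults
(saline at 20 min, fentanyl at 40 min, 30 min of post-fentanyl recording)
follow the recording procedure. Real units are not Poisson (refractoriness,
bursting, non-stationarity), so recovered modulation indices validate the
estimator, not spike-train realism.

## Problem sizes

The test suite and examples use sizes chosen to make statistical assertions
sharp while keeping runs fast: 10,000 bouts for fit-recovery checks (SE of
p̂ ≈ 0.005), 2,000–10,000 trials for closed-form behavioral checks,
10–30-minute equivalent photometry traces, and 40–200 units at 5–10 Hz for
modulation checks. The full suite completes in well under a minute.

## Known limitations

- Concurrent home-cage visits (two mice in the tube) are out of scope; the
  generator never produces them and attribution assumes serialized visits.
- The bout-grouping rule for home-cage/photometry sessions reuses the
  operant 1-s rule with a 3-s grace; this is an assumption exposed as
  parameters, not a documented property of the original procedures.
- No hemodynamic or motion regression beyond the isosbestic procedure; no
  spike sorting or waveform QC (region labels and spike times are inputs).
- The least-squares pmf fit weights all sizes equally; for heavily skewed
  distributions the MLE is the more efficient estimator and should be used
  as a sanity check.
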