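"""Bout microstructure of a simulated operant session.

Simulates an FR5 fentanyl-vs-quinine session in which the fentanyl port has a
lower bout-termination probability than the quinine port, parses the lick
stream into trials with the 1-s inter-poke rule, and fits the geometric
bout-termination model per liquid.  The recovered p_terminate values should
track the generator's (0.35 for fentanyl, 0.65 for quinine), and the share of
rewards consumed in bouts of 2+ should be larger for fentanyl.
"""

from oralsa import (BehaviorSimConfig, consumption_summary, fit_by_condition,
                    fraction_in_bouts, parse_trials, simulate_operant_session)

cfg = BehaviorSimConfig(
    seed=7, n_trials=2000, schedule=5,
    p_terminate={1: 0.35, 2: 0.65},   # port 1 = fentanyl, port 2 = quinine
    max_rewards_per_trial=None,
)
log, truth = simulate_operant_session(cfg)
trials = parse_trials(log)

for liquid in ("fentanyl", "quinine"):
    summ = consumption_summary(trials, log, liquid)
    pct = fraction_in_bouts(trials, liquid=liquid)
    print(f"{liquid:9s} {summ.n_rewards:5d} rewards  "
          f"{summ.volume_ml:6.2f} mL  {pct:5.1f}% in bouts of 2+")

fits = fit_by_condition(trials, by_animal=False, by_laser=False)
for (_, liquid, _), fit in fits.items():
    print(f"{liquid:9s} p_terminate = {fit.p_terminate:.3f} "
          f"({fit.n_bouts} bouts, method {fit.method})")
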