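"""Fentanyl modulation of frontal-cortex units and group contrasts.

Simulates Poisson spike trains across saline/fentanyl injection epochs for a
control group (mixed up/down modulation) and an experimental group shifted
toward excitation, computes each unit's modulation index
MI = (fent − base)/(fent + base), classifies units with the 2-fold cutoff
(|MI| > 1/3), and contrasts per-region up/down proportions between groups
with the pooled two-proportion z-test.
"""

from oralsa import (EphysSimConfig, compute_modulation, region_proportions,
                    simulate_spikes, two_proportion_z)

cfg = EphysSimConfig(
    seed=5,
    n_units={"ACC": 120, "IL": 40, "PL": 40, "OFC": 40},
    baseline_rate=("loguniform", 1.0, 10.0),
    modulation={
        # control: mostly suppressed by fentanyl; experimental: excited
        "control": ("choice", [0.3, 1.0, 2.5], [0.40, 0.48, 0.12]),
        "kir": ("choice", [0.3, 1.0, 2.5], [0.15, 0.55, 0.30]),
    },
    t_saline=1200.0, t_fentanyl=2400.0, t_end=4200.0,
)
units, truth = simulate_spikes(cfg)
results = compute_modulation(units)

for group in ("control", "kir"):
    mis = [r.mi for r in results if r.group == group]
    print(f"{group:8s} mean MI = {sum(mis)/len(mis):+.2f} (n={len(mis)})")

pc = region_proportions(results, group="control")
pk = region_proportions(results, group="kir")
for region in ("ACC", "IL", "PL", "OFC"):
    for direction in ("down", "up"):
        res = two_proportion_z(pc[region][direction], pc[region]["n"],
                               pk[region][direction], pk[region]["n"])
        print(f"{region}-{direction}: control {res.k1}/{res.n1} vs "
              f"kir {res.k2}/{res.n2}  z = {res.z:+.2f}  p = {res.p:.4f}")
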