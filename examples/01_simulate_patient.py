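"""Simulate one lymph-node aspirate and inspect its ground truth.

Draws one NSCLC patient from the default cohort priors, simulates the
identification tube, and prints the true population mixture next to the raw
event counts.  The percentages are fractions of viable (non-debris,
live) events — the same denominator the gating stage reports.
"""

import collections

from lnaspire import (default_cohort_config, draw_patient_truth,
                      identification_panel, simulate_sample)

config = default_cohort_config("NSCLC", master_seed=11)
truth = draw_patient_truth(config, index=0)
table, labels = simulate_sample(identification_panel(), truth, 20_000,
                                doublet_fraction=0.03)

print(f"patient {truth.patient_id}: {table.n_events} events, "
      f"{len(table.panel.channels)} channels")
print(f"{'population':>12} {'true % viable':>14} {'events':>8}")
counts = collections.Counter(labels.population)
for pop, frac in sorted(truth.viable_composition().items(),
                        key=lambda kv: -kv[1]):
    print(f"{pop:>12} {100 * frac:>13.2f}% {counts[pop]:>8}")
print(f"{'debris':>12} {'':>14} {counts['debris']:>8}")
print(f"{'dead':>12} {'':>14} {counts['dead']:>8}")
print(f"{'doublet':>12} {'':>14} {counts['doublet']:>8}")
# The event counts follow a multinomial in the truth fractions; doublets
# replace merged pairs, so totals come out slightly below 20,000.
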