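"""The pre-label/washout design and the uptake-mechanism classifier.

Shows the body-water and pool enrichment dynamics (7-week label, 2-week
washout: fast liver pools empty, slow adipose pools retain label), then
simulates the three candidate mechanisms of hepatic lipid accrual and
classifies each from its tissue/moiety enrichment pattern.
"""

import numpy as np

from midaflux import redistribution as rd
from midaflux import simulate

protocol = rd.LabelingProtocol.prelabel_washout()
grid = np.linspace(0, protocol.total_days, 300)
p_t = rd.body_water_timecourse(protocol, grid)
print(f"body water: plateau {p_t[150]:.3f} during labeling, "
      f"{p_t[-1]:.4f} at the end of washout")

for name, k in (("liver TG", 0.7), ("adipose TG", 0.02)):
    pool = rd.pool_enrichment_dynamics(k, p_t, c=0.5, grid=grid)
    print(f"{name:10s} (k={k}/day): final excess enrichment {pool.final:.4f}")
print("-> washout empties the fast liver pool; adipose keeps its label,")
print("   so label reappearing in liver must have come from adipose.\n")

for scenario in simulate.SCENARIOS:
    table, truth = simulate.simulate_prelabel_study(scenario, seed=3)
    streams, _ = simulate.comparisons_from_table(table, "tunicamycin", "control")
    call = rd.classify_uptake(
        **streams,
        source_glycerol_palmitate_ratio=truth["source_glycerol_palmitate_ratio"],
    )
    s = call.statistics
    print(f"{scenario:20s} -> {call.classification}")
    print(f"    liver palmitate delta {s['liver_palmitate_delta']:+.4f} "
          f"(p={s['liver_palmitate_p']:.1e}), "
          f"liver glycerol delta {s['liver_glycerol_delta']:+.4f}")
print("\nlabeled palmitate arriving without labeled glycerol = free-fatty-acid")
print("uptake; both moieties arriving in the source ratio = intact transfer;")
print("both diluted = dietary influx.")
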