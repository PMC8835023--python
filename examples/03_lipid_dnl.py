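"""De novo lipogenesis from GC-MS palmitate isotopomers.

Simulates the suppressed-lipogenesis design (control f_DNL ~ 0.30, treated
falling to 0.05 by 48 h), applies the unenriched-standard baseline
correction and the MIDA combinatorial model, and prints group statistics.
"""

from midaflux import lipids, simulate

spec = simulate.LipidSpec(animals_per_group=5).with_default_design()
table, truth = simulate.simulate_lipids(spec, seed=2)
print(f"simulated {len(table)} GC-MS measurements "
      f"({table['analyte'].nunique()} analytes, matched standards included)")

results = lipids.dnl_table(table, p=spec.p)
stats = lipids.dnl_group_stats(results, spec.treated_label, spec.control_label)

palm_tg = stats[(stats["analyte"] == "palmitate") & (stats["fraction"] == "TG")]
print("\npalmitate in triglycerides, fraction from de novo lipogenesis:")
print(f"{'time_h':>7} {'control':>9} {'treated':>9} {'p':>10}")
for row in palm_tg.itertuples(index=False):
    print(f"{row.time_h:7.0f} {row.mean_control:9.3f} {row.mean_treated:9.3f} "
          f"{row.p_value:10.2e}")
print("\ntreated DNL declines from 0.25 at 12 h and collapses to ~0.05 by 48 h;")
print("small p-values mark the suppressed time points. Absolute synthesis in")
print("grams is f times the measured pool mass (lipids.absolute_dnl).")
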