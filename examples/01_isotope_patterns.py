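"""Isotope patterns and the MIDA precursor-product ratio for one peptide.

Builds the natural-abundance M0-M3 pattern of a tryptic peptide, the
pattern of a molecule synthesized at 5% body-water deuterium, and shows how
a 40% old / 60% new mixture inverts back to the fraction newly synthesized.
"""

import numpy as np

from midaflux import mida

SEQ = "GASPVTLCK"
P = 0.05  # body-water deuterium enrichment

comp = mida.composition_from_peptide(SEQ)
n_sites = mida.label_site_count(SEQ)
lp = mida.LabelParameters(p=P, n=n_sites)

baseline = mida.natural_isotope_distribution(comp, 4)
enriched = mida.enriched_distribution(comp, lp, 4)

print(f"peptide {SEQ}: {comp.formula()}, mass {comp.monoisotopic_mass:.4f} Da")
print(f"effective deuterium sites n = {n_sites:.2f}")
print(f"natural  M0-M3: {np.round(baseline.abundances, 5)}")
print(f"enriched M0-M3: {np.round(enriched.abundances, 5)}  (100% new at p={P})")

em_max = mida.theoretical_max_em(comp, lp, channel=0)
print(f"EMmax(M0) = {em_max:.5f}  "
      "(maximum M0 depletion a fully renewed pool can show)")

# a pool in which 60% of molecules were made during labeling
measured = baseline.mix(enriched, 0.6)
em = mida.excess_enrichment(measured, baseline, channel=0)
est = mida.fractional_synthesis(em, em_max)
print(f"measured EM(M0) = {em:.5f} -> fractional synthesis f = {est.f:.3f}")

k = mida.rate_constant(est.f, t=1.0)
print(f"over a 1-day label that is a replacement rate constant k = {k:.3f}/day")
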