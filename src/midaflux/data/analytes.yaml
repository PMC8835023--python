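# GC-MS analyte configuration for de novo synthesis calculations.
#
# Each analyte carries the elemental composition used for the natural-
# abundance baseline, the effective number of deuterium-incorporation sites
# (n) under the combinatorial polymerization model, and the number of
# reported mass-isotopomer channels (M0..M[channels-1]).
#
# n values are literature-derived MIDA conventions for body-water labeling:
#   palmitate  22   (C16 fatty acid synthesized from acetyl-CoA)
#   cholesterol 26  (C27 sterol)
#   glycerol    4.0 (effective; glycerol-3-phosphate from glycolysis)
# Compositions are the underivatized analytes; the monitored GC-MS fragment
# m/z sets map onto these channel windows.
palmitate:
  composition: {C: 16, H: 32, O: 2}
  n_sites: 22
  channels: 3
cholesterol:
  composition: {C: 27, H: 46, O: 1}
  n_sites: 26
  channels: 3
glycerol:
  composition: {C: 3, H: 8, O: 3}
  n_sites: 4.0
  channels: 3
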