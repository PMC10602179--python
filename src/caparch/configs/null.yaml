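# Shared-architecture null: identical effects and frequencies in all
# three regions.  Cohort sizes are matched (the study-wide totals split
# evenly) because ANOSIM is sensitive to dispersion differences, and
# unequal cohort sizes change cloud spread even when the architectures
# are identical.
scenario: "null"
m_variants: 90
f_drift: 0.0
seed: 11
region_sizes:
  West: [1321, 1170]
  East: [1321, 1170]
  South: [1321, 1170]
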