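# Region-specific effect sizes at 10 of 90 variants (log-OR shifted by
# +/- 0.2 in East/South), shared allele frequencies.
scenario: heterogeneous_beta
m_variants: 90
n_hetero: 10
delta_beta: 0.2
f_drift: 0.0
seed: 11
region_sizes:
  West: [1780, 1739]
  East: [835, 667]
  South: [1348, 1103]
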