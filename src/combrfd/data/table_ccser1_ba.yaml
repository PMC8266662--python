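# Two-zone fork-travel kinetics inputs for the beta-actin-promoter-activated
# CCSER1 allele (DT40 cells): rightward forks from the 5' IZ and leftward
# forks from the 3' IZ converge inside the 621-kb allele.
doubling_time_min: 744
s_fraction_percent: 62.5
locus_len_kb: 621
right_iz:                      # 5' IZ, source of rightward forks
  velocity_kb_min: 1.9         # vRF (median)
  timing_unit: percent
  timing: [26.3, 53.2, 17.6, 2.9]    # fS1..fS4
left_iz:                       # 3' IZ, source of leftward forks
  velocity_kb_min: 1.8         # vLF (median)
  timing_unit: percent
  timing: [5.7, 20.1, 41.0, 33.2]    # fS1'..fS4'
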