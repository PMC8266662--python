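# Fork-travel kinetics inputs for rightward forks emanating from the highly
# efficient initiation zone at the 5' end of the Tet-activated DMD allele
# (DT40 cells).  Timing values are the percentage of BrdU-labelled DNA per
# S-phase quarter at the IZ position.
doubling_time_min: 552
s_fraction_percent: 69.4
iz:
  velocity_kb_min: 2.1        # median velocity of rightward forks
  timing_unit: percent
  timing: [2.2, 6.2, 26.2, 65.4]   # fS1..fS4
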