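# combrfd

Replication fork directionality (RFD) profiling from single combed DNA
molecules, for researchers studying where eukaryotic replication starts,
ends, and how fast forks travel across megabase loci.

In dual-pulse DNA combing experiments, cells are labelled with two
consecutive thymidine-analog pulses (IdU then CldU, 20 min each), their DNA
is stretched on glass, and each fibre is mapped to the genome by FISH. The
order of the two analogs along a fibre reveals local fork direction:
IdU followed by CldU is a rightward-moving fork, the reverse a leftward
one; diverging pairs mark initiation events and converging pairs mark
terminations, each positioned at the midpoint between the two forks. This
package turns tables of such annotated tracks into:

- **oriented replicated-DNA segments** per fibre (the Fig-1-style grammar:
  fork/initiation/termination patterns, midpoint rules, broken-end
  handling);
- **RFD profiles**, `RFD = (R − L)/(R + L)` per bin, where `R` and `L` are
  the rightward- and leftward-replicated coverages, with the **origin
  efficiency metric** `OEM(i) = L/(R+L)|_i − L/(R+L)|_{i+1}` and the
  initiation-minus-termination event density, plus a threshold-based
  initiation-/termination-zone caller;
- **per-fork velocities** from track lengths and pulse durations,
  `v = (d_IdU + d_CldU)/(2·t_pulse)` for intact forks;
- **population RFD from OK-seq-style strand-oriented reads**, with random
  subsampling to single-molecule depth and binned Spearman comparison;
- **closed-form fork-travel kinetics**: S-phase duration
  `T_S = f_S · T_doubling`, quarter travel distances
  `d(q) = (1 − (q−1)/4) · T_S · v`, timing-weighted mean travel
  `Σ_q d(q)·f(q)`, the converging-fork meeting point
  `d₁/(d₁+d₂) · L`, and locus-traversal percentages `f_S1 · f_S4′ · 100`;
- a **stochastic locus simulator** (initiation zones with quarter-resolved
  firing-time distributions plus dispersed Poisson origins, constant fork
  velocities, passive suppression, dual-pulse labelling, fibre
  fragmentation and read emission) so that every analysis step can be
  validated against a known ground truth.

## Worked example

Fork-travel kinetics of a 621-kb locus flanked by an early-firing 5′
initiation zone (median rightward fork velocity 1.9 kb/min, firing-quarter
fractions 26.3/53.2/17.6/2.9 %) and a late-firing 3′ zone (1.8 kb/min,
5.7/20.1/41.0/33.2 %), in cells doubling every 744 min with 62.5 % of
cells in S phase:

```bash
$ python examples/05_kinetics_tables.py
two-zone analysis (beta-actin-activated CCSER1, 621 kb):
Estimated S-phase duration      465 min
Average rightward travel (dIZ1) 669 kb
Average leftward travel (dIZ2)  415 kb
Average meeting point           383 kb
Rightward forks reaching the far IZ  8.7 %   (distance feasible: True)
Leftward forks reaching the far IZ   0.17 %  (distance feasible: True)
```

Rightward forks from the early zone travel 669 kb on average versus 415 kb
for the late zone, so converging forks meet about 383 kb (two-thirds of the
way) into the locus — and fewer than 9 % of rightward forks (essentially no
leftward forks) can traverse the whole locus before the far zone fires.
This is the quantitative signature of a "crenelated N-shaped" RFD domain.

The simulator round trip (`examples/02_rfd_profile.py`) shows the
single-molecule chain end to end: 500 simulated labelled fibres give 306
oriented segments whose binned RFD correlates with the model's analytic
expectation at Spearman ρ = 0.974, and the two called initiation zones land
within a few kb of the true zone centres (90 kb and 710 kb).

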