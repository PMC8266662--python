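"""Replication fork directionality profile of a simulated two-zone locus.

Simulates pulse-labelled fibres from the default model (two fully efficient
initiation zones 620 kb apart, late-firing 3' zone), aggregates the
oriented tracks into a binned RFD profile and compares it with the model's
analytic expectation.
"""

import numpy as np

from combrfd import (
    analytic_profile,
    binned_spearman,
    call_zones,
    coverage,
    default_two_iz_model,
    emit_fibers,
    oem,
    orient_all,
)

model = default_two_iz_model()
rng = np.random.default_rng(11)

fibers, _truth = emit_fibers(model, 500, rng, resolution=10)
segments, events = orient_all(fibers)
profile = coverage(segments, model.locus, bin_size=10_000)
truth = analytic_profile(model)

rho = binned_spearman(profile, truth)
print(f"{len(fibers)} labelled fibres -> {len(segments)} oriented segments, "
      f"{len(events)} events")
print(f"binned Spearman rho vs analytic RFD: {rho:.3f}")

oem_profile = oem(profile)
izs = [z for z in call_zones(oem_profile, threshold=0.25) if z.kind == "IZ"]
print("called initiation zones (threshold 0.25):")
for z in izs:
    print(f"  IZ {z.start}-{z.end}, centre {z.center} bp")
# The two IZ centres should land near the true zones at 90 kb and 710 kb;
# rho above ~0.9 shows the single-molecule profile reproduces the
# population-average directionality.
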