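"""Closed-form fork-travel kinetics from the packaged parameter tables.

S-phase duration = doubling time x fraction of cells in S; quarter travel
distances d(q) = (1 - (q-1)/4) x S x v; the firing-quarter fractions weight
them into mean travel distances, meeting points and locus-traversal
percentages.
"""

import importlib.resources as resources

from combrfd import kinetics

tables = resources.files("combrfd") / "data"

print("single-zone analysis (Tet-activated DMD, 5' IZ):")
print(kinetics.format_single_iz_report(
    kinetics.load_single_iz(tables / "table_dmd_tet.yaml")))
print()
print("two-zone analysis (beta-actin-activated CCSER1, 621 kb):")
print(kinetics.format_two_iz_report(
    kinetics.load_two_iz(tables / "table_ccser1_ba.yaml")))
# Rightward forks from the early 5' zone travel 669 kb on average versus
# 415 kb for the late 3' zone, so converging forks meet ~383 kb into the
# locus, and under 9% of rightward forks can traverse it before the far
# zone fires.
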