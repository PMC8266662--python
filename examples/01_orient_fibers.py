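"""Orient the replication tracks of two hand-built combed fibres.

The IdU→CldU analog order gives fork direction; diverging/converging pairs
mark initiation/termination events whose positions are the midpoints
between the forks.  Direction is assigned from the leading-gap midpoint to
the trailing-gap midpoint of each fibre.
"""

from combrfd import Analog, Fiber, LabelTrack, classify_structures, orient_fiber

fibers = [
    # one rightward elongating fork
    Fiber("elongating", "chr1", 0, 40_000, (
        LabelTrack(Analog.IDU, 10_000, 20_000),
        LabelTrack(Analog.CLDU, 20_000, 30_000),
    )),
    # an origin that fired during the first pulse: CldU-IdU-CldU
    Fiber("origin", "chr1", 0, 28_000, (
        LabelTrack(Analog.CLDU, 0, 8_000),
        LabelTrack(Analog.IDU, 8_000, 20_000),
        LabelTrack(Analog.CLDU, 20_000, 28_000),
    )),
]

for fiber in fibers:
    structures = classify_structures(fiber)
    segments, events = orient_fiber(fiber, structures)
    print(f"fibre {fiber.fiber_id!r} ({fiber.start}-{fiber.end} bp)")
    for s in structures:
        print(f"  structure: {s.kind.value}" + (f" anchored at {s.anchor}" if s.anchor else ""))
    for seg in segments:
        print(f"  {seg.direction.value} replicated DNA {seg.start}-{seg.end}")
    for e in events:
        print(f"  {e.kind.value} event at {e.position} bp")
    print()

# The elongating fork yields one rightward segment from 5 kb (midpoint of
# the 0-10 kb leading gap) to 35 kb; the origin fibre splits at the IdU
# centre (14 kb) into leftward and rightward halves with one initiation.
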