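"""Shared test helpers: a grammar-level random fibre builder.

Fibres are composed of well-separated fork structures (inter-structure gaps
larger than the adjacency tolerance, intra-structure gaps within it) so the
track grammar has a unique reading.  All coordinates are even so that the
integer midpoint rule is exact under reflection.
"""

from __future__ import annotations

import numpy as np
import pytest

from combrfd.fibers import (
    Analog,
    Fiber,
    LabelTrack,
    DEFAULT_MAX_EVENT_GAP,
    DEFAULT_MAX_FORK_GAP,
)

_I, _C = Analog.IDU, Analog.CLDU

# analog layout per structure kind; None marks an internal unlabelled gap
STRUCT_LAYOUTS = {
    "right_fork": (_I, _C),
    "left_fork": (_C, _I),
    "initiation3": (_C, _I, _C),
    "initiation4": (_C, _I, None, _I, _C),
    "termination3": (_I, _C, _I),
    "termination4": (_I, _C, None, _C, _I),
    "lone_cldu": (_C,),
}

def _even(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo // 2, hi // 2 + 1)) * 2


def random_fiber(
    rng: np.random.Generator,
    kinds: list[str] | None = None,
    max_structures: int = 4,
    fiber_id: str = "rand",
) -> tuple[Fiber, list[str]]:
    """A random fibre built from unambiguous, well-separated structures.

    Returns the fibre and the ordered list of structure kinds laid down
    (the expected classification, with initiation3/4 collapsing to
    initiation etc.).
    """
    kinds = kinds or list(STRUCT_LAYOUTS)
    n = int(rng.integers(1, max_structures + 1))
    chosen = [kinds[rng.integers(len(kinds))] for _ in range(n)]
    pos = _even(rng, 0, 10_000)  # leading gap after fibre start
    start = 0
    tracks: list[LabelTrack] = []
    for kind in chosen:
        first = True
        forced_gap: int | None = None
        for sym in STRUCT_LAYOUTS[kind]:
            if sym is None:  # marks a mandatory inter-fork (event) gap
                forced_gap = _even(rng, 2, DEFAULT_MAX_EVENT_GAP - 2)
                continue
            if not first:
                gap = forced_gap if forced_gap is not None else _even(
                    rng, 0, DEFAULT_MAX_FORK_GAP
                )
                pos += gap
                forced_gap = None
            first = False
            length = _even(rng, 4_000, 40_000)
            tracks.append(LabelTrack(sym, pos, pos + length))
            pos = pos + length
        pos += _even(rng, DEFAULT_MAX_EVENT_GAP + 2, 30_000)  # separator
    end = pos + _even(rng, 0, 10_000)
    fiber = Fiber(fiber_id, "chrT", start, end, tuple(tracks))
    expected = [k.rstrip("34").replace("lone_cldu", "initiation") for k in chosen]
    return fiber, expected


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
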