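"""Per-fork velocity estimates from dual-pulse track lengths.

Each analog pulse lasts ``pulse_min`` minutes (default 20), so an elongating
fork with both tracks intact travelled (IdU + CldU length) over two pulses:
v = (d_IdU + d_CldU) / (2 · pulse).  When one track is interrupted by a
physical fibre break, only the intact track is informative and the speed is
its length over one pulse.  Fork position follows the same convention: the
centre of the combined IdU+CldU span when both tracks are intact, otherwise
the centre of the intact track.  Forks with both tracks broken yield no
measurement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .fibers import (
    Analog,
    Direction,
    Fiber,
    ForkStructure,
    StructureKind,
    classify_structures,
)

__all__ = ["IntactPattern", "ForkMeasurement", "fork_speed", "measure_forks",
           "write_measurements"]

BP_PER_KB = 1_000
DEFAULT_PULSE_MIN = 20.0


class IntactPattern(str, enum.Enum):
    BOTH_INTACT = "both_intact"
    IDU_INTACT_CLDU_BROKEN = "idu_intact_cldu_broken"
    CLDU_INTACT_IDU_BROKEN = "cldu_intact_idu_broken"


@dataclass(frozen=True)
class ForkMeasurement:
    fiber_id: str
    chrom: str
    direction: Direction
    position: int  # bp
    speed: float  # kb/min
    idu_len: int | None  # bp, None when the track is broken
    cldu_len: int | None
    pattern: IntactPattern


def fork_speed(
    fiber: Fiber,
    fork: ForkStructure,
    pulse_min: float = DEFAULT_PULSE_MIN,
) -> ForkMeasurement | None:
    """Speed and position of one elongating fork; None when unmeasurable."""
    if fork.kind not in (StructureKind.RIGHT_FORK, StructureKind.LEFT_FORK):
        raise ValueError("fork_speed expects an elongating fork structure")
    if pulse_min <= 0:
        raise ValueError("pulse_min must be positive")
    a, b = (fiber.tracks[i] for i in fork.member_tracks)
    idu, cldu = (a, b) if a.analog is Analog.IDU else (b, a)
    direction = (
        Direction.R if fork.kind is StructureKind.RIGHT_FORK else Direction.L
    )
    if idu.intact and cldu.intact:
        speed = (idu.length + cldu.length) / BP_PER_KB / (2 * pulse_min)
        span_start = min(a.start, b.start)
        span_end = max(a.end, b.end)
        return ForkMeasurement(
            fiber.fiber_id, fiber.chrom, direction, (span_start + span_end) // 2,
            speed, idu.length, cldu.length, IntactPattern.BOTH_INTACT,
        )
    if idu.intact:
        speed = idu.length / BP_PER_KB / pulse_min
        return ForkMeasurement(
            fiber.fiber_id, fiber.chrom, direction, idu.center,
            speed, idu.length, None, IntactPattern.IDU_INTACT_CLDU_BROKEN,
        )
    if cldu.intact:
        speed = cldu.length / BP_PER_KB / pulse_min
        return ForkMeasurement(
            fiber.fiber_id, fiber.chrom, direction, cldu.center,
            speed, None, cldu.length, IntactPattern.CLDU_INTACT_IDU_BROKEN,
        )
    return None  # both tracks broken: no usable length


def measure_forks(
    fibers: Iterable[Fiber],
    pulse_min: float = DEFAULT_PULSE_MIN,
    max_fork_gap: int | None = None,
) -> list[ForkMeasurement]:
    """All measurable elongating-fork speeds in a fibre collection."""
    from .fibers import DEFAULT_MAX_FORK_GAP

    gap = DEFAULT_MAX_FORK_GAP if max_fork_gap is None else max_fork_gap
    out: list[ForkMeasurement] = []
    for f in fibers:
        for s in classify_structures(f, gap):
            if s.kind in (StructureKind.RIGHT_FORK, StructureKind.LEFT_FORK):
                m = fork_speed(f, s, pulse_min)
                if m is not None:
                    out.append(m)
    return out


def write_measurements(
    measurements: Sequence[ForkMeasurement], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "fiber_id": m.fiber_id,
                "direction": m.direction.value,
                "chrom": m.chrom,
                "position": m.position,
                "speed_kb_min": m.speed,
                "pattern": m.pattern.value,
            }
            for m in measurements
        ]
    ).to_csv(path, sep="\t", index=False)
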