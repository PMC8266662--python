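"""Single-molecule replication fibres and their track grammar.

A combed DNA fibre mapped to the reference genome carries an ordered set of
labelled replication tracks (IdU from the first analog pulse, CldU from the
second).  The order of the two analogs along the fibre encodes local fork
direction: IdU immediately followed by CldU is a rightward-moving fork,
CldU followed by IdU a leftward one.  Diverging fork pairs mark initiation
events, converging pairs mark terminations; event positions are estimated as
the midpoint between the two forks.  This module parses fibre tables,
classifies tracks into fork structures, and converts each fibre into
direction-assigned (oriented) segments plus discrete initiation/termination
events.

Coordinates are 0-based half-open (BED convention) throughout; midpoints are
rounded down to integer bp.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Analog",
    "Direction",
    "StructureKind",
    "EventKind",
    "LabelTrack",
    "Fiber",
    "ForkStructure",
    "OrientedSegment",
    "ReplicationEvent",
    "FiberError",
    "parse_fibers",
    "write_fibers",
    "classify_structures",
    "orient_fiber",
    "orient_all",
    "assignable_span",
    "write_segments_bed",
    "write_events_bed",
    "DEFAULT_MAX_FORK_GAP",
]

#: maximum unlabelled gap (bp) between the two tracks of one fork (a
#: labelling/microscopy artifact); larger gaps separate structures.
DEFAULT_MAX_FORK_GAP = 3_000

#: maximum gap (bp) between the facing same-analog tracks of a diverging or
#: converging fork pair.  This DNA is genuinely unlabelled (replicated before
#: the first pulse, or not yet replicated by the end of the second), so the
#: tolerance is wider than within a fork.
DEFAULT_MAX_EVENT_GAP = 10_000


class FiberError(ValueError):
    """Raised for malformed fibre tables or invariant violations."""


class Analog(str, enum.Enum):
    IDU = "IdU"
    CLDU = "CldU"


class Direction(str, enum.Enum):
    R = "R"
    L = "L"


class StructureKind(str, enum.Enum):
    RIGHT_FORK = "right_fork"
    LEFT_FORK = "left_fork"
    INITIATION = "initiation"
    TERMINATION = "termination"
    UNORIENTED = "unoriented"


class EventKind(str, enum.Enum):
    INITIATION = "initiation"
    TERMINATION = "termination"


@dataclass(frozen=True)
class LabelTrack:
    """One analog-labelled track on a fibre.

    ``left_intact``/``right_intact`` are False when the signal is interrupted
    by a physical fibre break on that side; a broken end must coincide with
    the fibre boundary.
    """

    analog: Analog
    start: int
    end: int
    left_intact: bool = True
    right_intact: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FiberError(f"track start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def intact(self) -> bool:
        return self.left_intact and self.right_intact


@dataclass(frozen=True)
class Fiber:
    """One combed DNA molecule mapped to reference coordinates."""

    fiber_id: str
    chrom: str
    start: int
    end: int
    tracks: tuple[LabelTrack, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FiberError(f"fibre {self.fiber_id}: start >= end")
        tracks = tuple(sorted(self.tracks, key=lambda t: t.start))
        object.__setattr__(self, "tracks", tracks)
        prev_end = self.start
        for t in tracks:
            if t.start < self.start or t.end > self.end:
                raise FiberError(
                    f"fibre {self.fiber_id}: track {t.start}-{t.end} outside "
                    f"fibre span {self.start}-{self.end}"
                )
            if t.start < prev_end:
                raise FiberError(
                    f"fibre {self.fiber_id}: track {t.start}-{t.end} overlaps "
                    f"a preceding track"
                )
            prev_end = t.end
            if not t.left_intact and t.start != self.start:
                raise FiberError(
                    f"fibre {self.fiber_id}: broken left end of track at "
                    f"{t.start} does not abut the fibre boundary"
                )
            if not t.right_intact and t.end != self.end:
                raise FiberError(
                    f"fibre {self.fiber_id}: broken right end of track at "
                    f"{t.end} does not abut the fibre boundary"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def reflected(self) -> "Fiber":
        """Mirror image of the fibre around its own span (for symmetry checks)."""
        pivot = self.start + self.end
        tracks = tuple(
            LabelTrack(
                analog=t.analog,
                start=pivot - t.end,
                end=pivot - t.start,
                left_intact=t.right_intact,
                right_intact=t.left_intact,
            )
            for t in reversed(self.tracks)
        )
        return Fiber(self.fiber_id, self.chrom, self.start, self.end, tracks)


@dataclass(frozen=True)
class ForkStructure:
    """A group of adjacent tracks read as one replication structure."""

    kind: StructureKind
    member_tracks: tuple[int, ...]
    anchor: int | None = None  # event position for initiation/termination


@dataclass(frozen=True)
class OrientedSegment:
    chrom: str
    start: int
    end: int
    direction: Direction
    fiber_id: str


@dataclass(frozen=True)
class ReplicationEvent:
    kind: EventKind
    chrom: str
    position: int
    fiber_id: str


# ---------------------------------------------------------------------------
# fibre table I/O

FIBER_TSV_COLUMNS = [
    "fiber_id",
    "chrom",
    "fiber_start",
    "fiber_end",
    "analog",
    "track_start",
    "track_end",
    "left_intact",
    "right_intact",
]


def parse_fibers(table_path: str | Path) -> list[Fiber]:
    """Read a fibre track table (one TSV row per labelled track).

    Rows sharing a ``fiber_id`` describe one fibre; tracks are sorted by
    start.  Invariant violations (overlapping tracks, tracks outside the
    fibre span, unknown analog names) raise :class:`FiberError` naming the
    offending fibre.
    """
    table_path = Path(table_path)
    df = pd.read_csv(table_path, sep="\t", dtype={"fiber_id": str, "chrom": str})
    missing = [c for c in FIBER_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FiberError(f"{table_path}: missing columns {missing}")
    fibers: list[Fiber] = []
    for fid, grp in df.groupby("fiber_id", sort=False):
        chroms = grp["chrom"].unique()
        starts = grp["fiber_start"].unique()
        ends = grp["fiber_end"].unique()
        if len(chroms) != 1 or len(starts) != 1 or len(ends) != 1:
            raise FiberError(f"fibre {fid}: inconsistent fibre coordinates across rows")
        tracks = []
        for _, row in grp.iterrows():
            try:
                analog = Analog(row["analog"])
            except ValueError:
                raise FiberError(
                    f"fibre {fid}: unknown analog label {row['analog']!r}"
                ) from None
            tracks.append(
                LabelTrack(
                    analog=analog,
                    start=int(row["track_start"]),
                    end=int(row["track_end"]),
                    left_intact=bool(int(row["left_intact"])),
                    right_intact=bool(int(row["right_intact"])),
                )
            )
        fibers.append(
            Fiber(str(fid), str(chroms[0]), int(starts[0]), int(ends[0]), tuple(tracks))
        )
    return fibers


def write_fibers(fibers: Iterable[Fiber], table_path: str | Path) -> None:
    """Write fibres back to the TSV dialect read by :func:`parse_fibers`."""
    rows = []
    for f in fibers:
        for t in f.tracks:
            rows.append(
                {
                    "fiber_id": f.fiber_id,
                    "chrom": f.chrom,
                    "fiber_start": f.start,
                    "fiber_end": f.end,
                    "analog": t.analog.value,
                    "track_start": t.start,
                    "track_end": t.end,
                    "left_intact": int(t.left_intact),
                    "right_intact": int(t.right_intact),
                }
            )
    pd.DataFrame(rows, columns=FIBER_TSV_COLUMNS).to_csv(
        table_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# track grammar

_I = Analog.IDU
_C = Analog.CLDU

# Patterns tried greedily left-to-right, longest (event) readings first, so a
# diverging/converging fork pair is preferred over two independent forks.
# Each entry: (analog sequence, structure kind, per-junction gap classes);
# "fork" junctions use max_fork_gap, "event" junctions max_event_gap.
_PATTERNS: list[tuple[tuple[Analog, ...], StructureKind, tuple[str, ...]]] = [
    # origin fired before pulse 1: the inter-IdU DNA was replicated earlier
    ((_C, _I, _I, _C), StructureKind.INITIATION, ("fork", "event", "fork")),
    # forks not merged by the end of pulse 2: inter-CldU DNA still unreplicated
    ((_I, _C, _C, _I), StructureKind.TERMINATION, ("fork", "event", "fork")),
    ((_C, _I, _C), StructureKind.INITIATION, ("fork", "fork")),   # fired during IdU
    ((_I, _C, _I), StructureKind.TERMINATION, ("fork", "fork")),  # merged during CldU
    ((_I, _C), StructureKind.RIGHT_FORK, ("fork",)),
    ((_C, _I), StructureKind.LEFT_FORK, ("fork",)),
]


def _anchor(kind: StructureKind, tracks: Sequence[LabelTrack]) -> int | None:
    if kind is StructureKind.INITIATION:
        if len(tracks) == 4:  # centre of the gap between the diverging IdU tracks
            return (tracks[1].end + tracks[2].start) // 2
        if len(tracks) == 3:  # centre of the shared IdU track
            return tracks[1].center
        return tracks[0].center  # lone CldU: origin fired during pulse 2
    if kind is StructureKind.TERMINATION:
        if len(tracks) == 4:  # centre of the gap between the converging CldU tracks
            return (tracks[1].end + tracks[2].start) // 2
        return tracks[1].center  # centre of the shared CldU track
    return None


def classify_structures(
    fiber: Fiber,
    max_fork_gap: int = DEFAULT_MAX_FORK_GAP,
    max_event_gap: int = DEFAULT_MAX_EVENT_GAP,
) -> list[ForkStructure]:
    """Group a fibre's tracks into fork structures.

    Tracks are scanned left to right; consecutive tracks belong to the same
    fork when separated by at most ``max_fork_gap`` bp, and the facing
    same-analog tracks of a diverging/converging pair may be separated by up
    to ``max_event_gap`` bp.  Event readings take precedence over pairs of
    independent forks.  An intact lone CldU track is an initiation during
    the second pulse; a lone IdU track (or a broken lone CldU) has ambiguous
    direction and is returned as unoriented.
    """
    tracks = fiber.tracks
    n = len(tracks)
    gap_limit = {"fork": max_fork_gap, "event": max_event_gap}

    def adjacent(i: int, j: int, kind: str) -> bool:
        return tracks[j].start - tracks[i].end <= gap_limit[kind]

    structures: list[ForkStructure] = []
    i = 0
    while i < n:
        matched = False
        for pattern, kind, junctions in _PATTERNS:
            k = len(pattern)
            if i + k > n:
                continue
            window = tracks[i : i + k]
            if tuple(t.analog for t in window) != pattern:
                continue
            if not all(
                adjacent(i + m, i + m + 1, junctions[m]) for m in range(k - 1)
            ):
                continue
            structures.append(
                ForkStructure(kind, tuple(range(i, i + k)), _anchor(kind, window))
            )
            i += k
            matched = True
            break
        if not matched:
            t = tracks[i]
            if t.analog is _C and t.intact:
                # lone intact CldU: origin fired during the CldU pulse; its
                # centre estimates the origin position.  A broken lone CldU
                # is a truncated passing fork, not an origin: unoriented.
                structures.append(
                    ForkStructure(
                        StructureKind.INITIATION,
                        (i,),
                        _anchor(StructureKind.INITIATION, [t]),
                    )
                )
            else:  # lone IdU or truncated lone CldU: direction ambiguous
                structures.append(ForkStructure(StructureKind.UNORIENTED, (i,), None))
            i += 1
    return structures


# direction carried by the left/right edge of each oriented structure kind
_EDGE_DIRS: dict[StructureKind, tuple[Direction | None, Direction | None]] = {
    StructureKind.RIGHT_FORK: (Direction.R, Direction.R),
    StructureKind.LEFT_FORK: (Direction.L, Direction.L),
    StructureKind.INITIATION: (Direction.L, Direction.R),
    StructureKind.TERMINATION: (Direction.R, Direction.L),
    StructureKind.UNORIENTED: (None, None),
}


def assignable_span(fiber: Fiber) -> tuple[int, int] | None:
    """Span over which replication direction can in principle be assigned.

    Direction is only defined from the midpoint of the leading unlabelled
    gap to the midpoint of the trailing one (DNA beyond those midpoints may
    have been replicated by forks from outside the observed molecule).
    Returns None for a fibre without tracks.
    """
    if not fiber.tracks:
        return None
    lead_mid = (fiber.start + fiber.tracks[0].start) // 2
    trail_mid = (fiber.tracks[-1].end + fiber.end) // 2
    return lead_mid, trail_mid


def orient_fiber(
    fiber: Fiber, structures: Sequence[ForkStructure]
) -> tuple[list[OrientedSegment], list[ReplicationEvent]]:
    """Assign replication direction along one fibre.

    Labelled structures carry the direction of their forks (the shared track
    of a contiguous initiation or termination is split at the event anchor).
    Each unlabelled interval is split at its midpoint, each half inheriting
    the direction of the adjacent fork; the outer half of a fibre-end gap and
    intervals adjacent only to unoriented structures get no assignment.
    """
    pieces: list[tuple[int, int, Direction]] = []
    events: list[ReplicationEvent] = []

    spans = []  # (span_start, span_end, left_dir, right_dir) per structure
    for s in structures:
        first = fiber.tracks[s.member_tracks[0]]
        last = fiber.tracks[s.member_tracks[-1]]
        left_dir, right_dir = _EDGE_DIRS[s.kind]
        spans.append((first.start, last.end, left_dir, right_dir))
        if s.kind is StructureKind.INITIATION:
            events.append(
                ReplicationEvent(EventKind.INITIATION, fiber.chrom, s.anchor, fiber.fiber_id)
            )
            pieces.append((first.start, s.anchor, Direction.L))
            pieces.append((s.anchor, last.end, Direction.R))
        elif s.kind is StructureKind.TERMINATION:
            events.append(
                ReplicationEvent(EventKind.TERMINATION, fiber.chrom, s.anchor, fiber.fiber_id)
            )
            pieces.append((first.start, s.anchor, Direction.R))
            pieces.append((s.anchor, last.end, Direction.L))
        elif s.kind is StructureKind.RIGHT_FORK:
            pieces.append((first.start, last.end, Direction.R))
        elif s.kind is StructureKind.LEFT_FORK:
            pieces.append((first.start, last.end, Direction.L))
        # unoriented: no assignment

    # unlabelled intervals between structures and at the fibre ends
    for idx in range(len(spans) + 1):
        gap_start = fiber.start if idx == 0 else spans[idx - 1][1]
        gap_end = fiber.end if idx == len(spans) else spans[idx][0]
        if gap_end <= gap_start:
            continue
        left_dir = spans[idx - 1][3] if idx > 0 else None
        right_dir = spans[idx][2] if idx < len(spans) else None
        mid = (gap_start + gap_end) // 2
        if idx == 0:
            # leading end gap: only the inner half is assignable
            if right_dir is not None:
                pieces.append((mid, gap_end, right_dir))
        elif idx == len(spans):
            if left_dir is not None:
                pieces.append((gap_start, mid, left_dir))
        else:
            if left_dir is not None:
                pieces.append((gap_start, mid, left_dir))
            if right_dir is not None:
                pieces.append((mid, gap_end, right_dir))

    # merge touching same-direction pieces into maximal segments
    pieces = [p for p in pieces if p[1] > p[0]]
    pieces.sort()
    segments: list[OrientedSegment] = []
    for start, end, direction in pieces:
        if (
            segments
            and segments[-1].end == start
            and segments[-1].direction == direction
        ):
            segments[-1] = replace(segments[-1], end=end)
        else:
            segments.append(
                OrientedSegment(fiber.chrom, start, end, direction, fiber.fiber_id)
            )
    return segments, events


def orient_all(
    fibers: Iterable[Fiber], max_fork_gap: int = DEFAULT_MAX_FORK_GAP
) -> tuple[list[OrientedSegment], list[ReplicationEvent]]:
    """Classify and orient a collection of fibres."""
    segments: list[OrientedSegment] = []
    events: list[ReplicationEvent] = []
    for f in fibers:
        seg, ev = orient_fiber(f, classify_structures(f, max_fork_gap))
        segments.extend(seg)
        events.extend(ev)
    return segments, events


# ---------------------------------------------------------------------------
# BED export

def write_segments_bed(segments: Iterable[OrientedSegment], path: str | Path) -> None:
    """Oriented segments as BED6 (strand + for rightward, − for leftward)."""
    with open(path, "w") as fh:
        for s in segments:
            strand = "+" if s.direction is Direction.R else "-"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.fiber_id}\t0\t{strand}\n")


def write_events_bed(events: Iterable[ReplicationEvent], path: str | Path) -> None:
    """Events as 1-bp BED6 named initiation/termination."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(
                f"{e.chrom}\t{e.position}\t{e.position + 1}\t{e.kind.value}\t0\t.\n"
            )
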