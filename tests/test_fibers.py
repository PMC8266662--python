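"""Fibre parsing, the track grammar, and direction assignment."""

import numpy as np
import pytest

from combrfd.fibers import (
    Analog,
    Direction,
    EventKind,
    Fiber,
    FiberError,
    LabelTrack,
    StructureKind,
    assignable_span,
    classify_structures,
    orient_fiber,
    parse_fibers,
    write_fibers,
)
from conftest import random_fiber

I, C = Analog.IDU, Analog.CLDU


def _fiber(tracks, start=0, end=None, fid="F1"):
    end = end if end is not None else max(t.end for t in tracks) + 10_000
    return Fiber(fid, "chr1", start, end, tuple(tracks))


def _write(tmp_path, rows):
    path = tmp_path / "fibers.tsv"
    header = (
        "fiber_id\tchrom\tfiber_start\tfiber_end\tanalog\ttrack_start"
        "\ttrack_end\tleft_intact\tright_intact\n"
    )
    path.write_text(header + "".join(r + "\n" for r in rows))
    return path


class TestParse:
    def test_header_only_gives_empty_list(self, tmp_path):
        assert parse_fibers(_write(tmp_path, [])) == []

    def test_minimal_two_track_fiber(self, tmp_path):
        path = _write(
            tmp_path,
            [
                "F1\tchr1\t0\t40000\tIdU\t10000\t20000\t1\t1",
                "F1\tchr1\t0\t40000\tCldU\t20000\t30000\t1\t1",
            ],
        )
        (fiber,) = parse_fibers(path)
        assert fiber.fiber_id == "F1" and len(fiber.tracks) == 2
        assert fiber.tracks[0].analog is I and fiber.tracks[1].analog is C

    @pytest.mark.parametrize(
        "bad_row, match",
        [
            ("F1\tchr1\t0\t40000\tCldU\t15000\t25000\t1\t1", "overlap"),
            ("F1\tchr1\t0\t40000\tCldU\t35000\t45000\t1\t1", "outside"),
            ("F1\tchr1\t0\t40000\tEdU\t1000\t2000\t1\t1", "analog"),
            ("F1\tchr1\t0\t40000\tCldU\t25000\t30000\t0\t1", "boundary"),
        ],
    )
    def test_invalid_rows_rejected_naming_fiber(self, tmp_path, bad_row, match):
        path = _write(
            tmp_path, ["F1\tchr1\t0\t40000\tIdU\t10000\t20000\t1\t1", bad_row]
        )
        with pytest.raises(FiberError, match=match):
            parse_fibers(path)
        with pytest.raises(FiberError, match="F1"):
            parse_fibers(path)

    def test_parse_write_parse_is_identity(self, tmp_path, rng):
        fibers = [random_fiber(rng, fiber_id=f"F{i}")[0] for i in range(25)]
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        write_fibers(fibers, p1)
        round1 = parse_fibers(p1)
        write_fibers(round1, p2)
        assert round1 == parse_fibers(p2) == fibers


class TestGrammar:
    def test_idu_then_cldu_is_rightward_fork(self):
        f = _fiber([LabelTrack(I, 10_000, 20_000), LabelTrack(C, 20_000, 30_000)])
        (s,) = classify_structures(f)
        assert s.kind is StructureKind.RIGHT_FORK

    def test_cldu_idu_cldu_is_initiation_anchored_at_idu_centre(self):
        f = _fiber(
            [
                LabelTrack(C, 0, 8_000, left_intact=True),
                LabelTrack(I, 8_000, 20_000),
                LabelTrack(C, 20_000, 28_000),
            ],
            end=28_000,
        )
        (s,) = classify_structures(f)
        assert s.kind is StructureKind.INITIATION and s.anchor == 14_000

    def test_converging_cldu_pair_is_termination_anchored_in_gap(self):
        f = _fiber(
            [
                LabelTrack(I, 0, 10_000),
                LabelTrack(C, 10_000, 18_000),
                LabelTrack(C, 22_000, 30_000),
                LabelTrack(I, 30_000, 40_000),
            ],
            end=40_000,
        )
        (s,) = classify_structures(f)
        assert s.kind is StructureKind.TERMINATION and s.anchor == 20_000

    def test_separated_diverging_idu_pair_is_initiation(self):
        f = _fiber(
            [
                LabelTrack(C, 0, 8_000),
                LabelTrack(I, 8_000, 18_000),
                LabelTrack(I, 20_000, 30_000),
                LabelTrack(C, 30_000, 38_000),
            ]
        )
        (s,) = classify_structures(f)
        assert s.kind is StructureKind.INITIATION and s.anchor == 19_000

    def test_lone_tracks(self):
        (s,) = classify_structures(_fiber([LabelTrack(C, 10_000, 20_000)]))
        assert s.kind is StructureKind.INITIATION and s.anchor == 15_000
        (s,) = classify_structures(_fiber([LabelTrack(I, 10_000, 20_000)]))
        assert s.kind is StructureKind.UNORIENTED

    def test_broken_lone_cldu_is_unoriented(self):
        # a truncated passing fork, not a second-pulse origin
        f = _fiber([LabelTrack(C, 0, 20_000, left_intact=False)], end=30_000)
        (s,) = classify_structures(f)
        assert s.kind is StructureKind.UNORIENTED

    def test_large_gap_separates_structures(self):
        f = _fiber([LabelTrack(I, 0, 10_000), LabelTrack(C, 15_000, 25_000)])
        kinds = [s.kind for s in classify_structures(f)]
        assert kinds == [StructureKind.UNORIENTED, StructureKind.INITIATION]

    def test_event_reading_preferred_over_two_forks(self):
        # IdU-CldU-IdU-CldU admits (right fork, right fork); the greedy
        # event-first scan reads termination + lone-CldU initiation
        f = _fiber(
            [
                LabelTrack(I, 0, 10_000),
                LabelTrack(C, 10_000, 20_000),
                LabelTrack(I, 20_000, 30_000),
                LabelTrack(C, 30_000, 40_000),
            ]
        )
        kinds = [s.kind for s in classify_structures(f)]
        assert kinds == [StructureKind.TERMINATION, StructureKind.INITIATION]

    def test_every_track_in_exactly_one_structure(self, rng):
        for _ in range(100):
            f, expected = random_fiber(rng)
            structs = classify_structures(f)
            members = [i for s in structs for i in s.member_tracks]
            assert sorted(members) == list(range(len(f.tracks)))
            assert [s.kind.value for s in structs] == expected


class TestOrientation:
    def test_right_fork_extends_to_end_gap_midpoints(self):
        f = _fiber(
            [LabelTrack(I, 10_000, 20_000), LabelTrack(C, 20_000, 30_000)],
            end=40_000,
        )
        segments, events = orient_fiber(f, classify_structures(f))
        assert [(s.start, s.end, s.direction) for s in segments] == [
            (5_000, 35_000, Direction.R)
        ]
        assert events == []

    def test_initiation_splits_fiber_at_anchor(self):
        f = _fiber(
            [
                LabelTrack(C, 0, 8_000),
                LabelTrack(I, 8_000, 20_000),
                LabelTrack(C, 20_000, 28_000),
            ],
            end=28_000,
        )
        segments, events = orient_fiber(f, classify_structures(f))
        assert [(s.start, s.end, s.direction) for s in segments] == [
            (0, 14_000, Direction.L),
            (14_000, 28_000, Direction.R),
        ]
        (e,) = events
        assert e.kind is EventKind.INITIATION and e.position == 14_000

    def test_unoriented_lone_idu_yields_nothing(self):
        f = _fiber([LabelTrack(I, 10_000, 20_000)], end=40_000)
        segments, events = orient_fiber(f, classify_structures(f))
        assert segments == [] and events == []

    def test_broken_end_stops_segment_at_break(self):
        # leftward break: no midpoint extension on that side
        f = _fiber(
            [
                LabelTrack(I, 0, 10_000, left_intact=False),
                LabelTrack(C, 10_000, 20_000),
            ],
            end=30_000,
        )
        (seg,), _ = orient_fiber(f, classify_structures(f))
        assert (seg.start, seg.end, seg.direction) == (0, 25_000, Direction.R)

    def test_partition_of_assignable_span(self, rng):
        """Oriented segments tile the assignable span exactly once."""
        for _ in range(200):
            f, _ = random_fiber(rng)
            segments, _ = orient_fiber(f, classify_structures(f))
            span = assignable_span(f)
            segments = sorted(segments, key=lambda s: s.start)
            assert segments[0].start == span[0]
            assert segments[-1].end == span[1]
            for a, b in zip(segments[:-1], segments[1:]):
                assert a.end == b.start

    def test_mirror_symmetry(self, rng):
        """Reflection swaps R and L and reflects event positions."""
        for _ in range(200):
            f, _ = random_fiber(rng)
            pivot = f.start + f.end
            seg, ev = orient_fiber(f, classify_structures(f))
            mseg, mev = orient_fiber(f.reflected(), classify_structures(f.reflected()))
            flipped = sorted(
                (pivot - s.end, pivot - s.start,
                 Direction.L if s.direction is Direction.R else Direction.R)
                for s in seg
            )
            got = sorted((s.start, s.end, s.direction) for s in mseg)
            assert got == flipped
            assert sorted(pivot - e.position for e in ev) == sorted(
                e.position for e in mev
            )

    def test_event_anchors_sit_on_direction_transitions(self, rng):
        for _ in range(100):
            f, _ = random_fiber(rng)
            segments, events = orient_fiber(f, classify_structures(f))
            bounds = {
                (a.end, a.direction, b.direction)
                for a, b in zip(segments[:-1], segments[1:])
                if a.end == b.start
            }
            for e in events:
                if e.kind is EventKind.INITIATION:
                    assert (e.position, Direction.L, Direction.R) in bounds
                else:
                    assert (e.position, Direction.R, Direction.L) in bounds
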