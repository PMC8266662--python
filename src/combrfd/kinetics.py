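"""Closed-form fork-travel kinetics for an asynchronously cycling population.

The S-phase duration of an exponentially growing culture is estimated as the
fraction of cells in S times the doubling time.  A replication origin firing
in quarter q of S phase (q = 1..4) leaves a fork at most
d(q) = (1 − (q − 1)/4) · S · v  kb of travel before S ends (the fork is
credited the full remaining time from the quarter's start; velocity v is
assumed constant).  Weighting the quarter distances by the origin's
firing-quarter distribution f(q) gives the average potential travel
distance.  For a locus flanked by two initiation zones, the average meeting
point of the converging forks is taken proportional to the two average
travel distances, and the fraction of forks from one zone able to reach the
other is the probability that the source fires in the first quarter while
the target does not fire until the last.

All intermediate quantities are kept unrounded; rounding (half-up, to the
precision used in reports) happens only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "round_half_up",
    "s_phase_duration",
    "quarter_distances",
    "mean_travel",
    "meeting_point",
    "reach_fraction",
    "IZKinetics",
    "SingleIZResult",
    "TwoIZResult",
    "single_iz_analysis",
    "two_iz_analysis",
    "load_single_iz",
    "load_two_iz",
    "format_single_iz_report",
    "format_two_iz_report",
]

QUARTERS = (1, 2, 3, 4)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding: halves away from zero (presentation only)."""
    factor = 10.0 ** ndigits
    r = math.floor(abs(x) * factor + 0.5) / factor
    r = math.copysign(r, x)
    return r if ndigits > 0 else float(int(r))


def _as_proportions(values: Sequence[float], unit: str) -> tuple[float, ...]:
    if unit == "percent":
        out = tuple(v / 100.0 for v in values)
    elif unit == "proportion":
        out = tuple(float(v) for v in values)
    else:
        raise ValueError(f"unknown unit {unit!r} (use 'percent' or 'proportion')")
    if len(out) != 4:
        raise ValueError("exactly four quarter fractions are required")
    if any(v < 0 for v in out):
        raise ValueError("quarter fractions must be non-negative")
    if abs(sum(out) - 1.0) > 0.01:
        raise ValueError(f"quarter fractions sum to {sum(out):.4f}, expected ~1")
    return out


def s_phase_duration(doubling_time_min: float, s_fraction: float) -> float:
    """Estimated S-phase duration (min) = fraction of cells in S × doubling time."""
    if doubling_time_min <= 0:
        raise ValueError("doubling time must be positive")
    if not 0 < s_fraction <= 1:
        raise ValueError("s_fraction must be in (0, 1]")
    return doubling_time_min * s_fraction


def quarter_distances(s_duration_min: float, velocity_kb_min: float) -> tuple[float, ...]:
    """d(q) = (1 − (q − 1)/4) · S · v for q = 1..4, in kb (unrounded)."""
    if s_duration_min <= 0 or velocity_kb_min < 0:
        raise ValueError("s_duration must be positive and velocity non-negative")
    return tuple(
        (1 - (q - 1) / 4) * s_duration_min * velocity_kb_min for q in QUARTERS
    )


def mean_travel(distances: Sequence[float], fractions: Sequence[float]) -> float:
    """Timing-weighted average travel distance Σ_q d(q)·f(q), in kb."""
    if len(distances) != 4 or len(fractions) != 4:
        raise ValueError("four quarters expected")
    if abs(sum(fractions) - 1.0) > 0.01:
        raise ValueError("quarter fractions must sum to ~1")
    return sum(d * f for d, f in zip(distances, fractions))


def meeting_point(d_left: float, d_right: float, locus_len_kb: float) -> float:
    """Average meeting point (kb from the left IZ): d1/(d1+d2) × locus length."""
    if d_left <= 0 or d_right <= 0:
        raise ValueError("travel distances must be positive")
    return d_left / (d_left + d_right) * locus_len_kb


def reach_fraction(f_source_s1: float, f_target_s4: float) -> float:
    """Percent of forks able to traverse the locus: fS1(source) × fS4(target) × 100.

    A fork can only cross before the far zone fires if it starts at the very
    beginning of S (source fires in S1) and the far zone fires only in the
    last quarter (target fires in S4).
    """
    for v in (f_source_s1, f_target_s4):
        if not 0 <= v <= 1:
            raise ValueError("fractions must be in [0, 1]")
    return f_source_s1 * f_target_s4 * 100.0


# ---------------------------------------------------------------------------
# table-level pipelines


@dataclass(frozen=True)
class IZKinetics:
    """Per-initiation-zone inputs: fork velocity and firing-quarter fractions."""

    velocity_kb_min: float
    timing: tuple[float, float, float, float]  # proportions summing to ~1


@dataclass(frozen=True)
class SingleIZResult:
    s_duration_min: float
    distances_kb: tuple[float, ...]
    mean_travel_kb: float


@dataclass(frozen=True)
class TwoIZResult:
    s_duration_min: float
    right: SingleIZResult  # rightward forks from the 5' IZ
    left: SingleIZResult   # leftward forks from the 3' IZ
    locus_len_kb: float
    meeting_point_kb: float
    reach_right_pct: float  # 5' forks reaching the 3' IZ
    reach_left_pct: float
    # distance-feasibility diagnostics: could an S1-starting fork physically
    # cross the locus by the end of S3 (i.e. d(2) ≥ locus length)?
    reach_right_feasible: bool
    reach_left_feasible: bool


def single_iz_analysis(
    doubling_time_min: float, s_fraction: float, iz: IZKinetics
) -> SingleIZResult:
    s = s_phase_duration(doubling_time_min, s_fraction)
    d = quarter_distances(s, iz.velocity_kb_min)
    return SingleIZResult(s, d, mean_travel(d, iz.timing))


def two_iz_analysis(
    doubling_time_min: float,
    s_fraction: float,
    right_iz: IZKinetics,
    left_iz: IZKinetics,
    locus_len_kb: float,
) -> TwoIZResult:
    """Full two-zone locus analysis: travel distances, meeting point, reach."""
    right = single_iz_analysis(doubling_time_min, s_fraction, right_iz)
    left = single_iz_analysis(doubling_time_min, s_fraction, left_iz)
    mp = meeting_point(right.mean_travel_kb, left.mean_travel_kb, locus_len_kb)
    return TwoIZResult(
        s_duration_min=right.s_duration_min,
        right=right,
        left=left,
        locus_len_kb=locus_len_kb,
        meeting_point_kb=mp,
        reach_right_pct=reach_fraction(right_iz.timing[0], left_iz.timing[3]),
        reach_left_pct=reach_fraction(left_iz.timing[0], right_iz.timing[3]),
        reach_right_feasible=right.distances_kb[1] >= locus_len_kb,
        reach_left_feasible=left.distances_kb[1] >= locus_len_kb,
    )


# ---------------------------------------------------------------------------
# YAML parameter tables


def _load_iz(node: dict) -> IZKinetics:
    unit = node.get("timing_unit", "percent")
    return IZKinetics(
        velocity_kb_min=float(node["velocity_kb_min"]),
        timing=_as_proportions(node["timing"], unit),
    )


def load_single_iz(path: str | Path) -> SingleIZResult:
    """Run the single-zone pipeline from a YAML parameter file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return single_iz_analysis(
        float(cfg["doubling_time_min"]),
        float(cfg["s_fraction_percent"]) / 100.0,
        _load_iz(cfg["iz"]),
    )


def load_two_iz(path: str | Path) -> TwoIZResult:
    """Run the two-zone pipeline from a YAML parameter file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return two_iz_analysis(
        float(cfg["doubling_time_min"]),
        float(cfg["s_fraction_percent"]) / 100.0,
        _load_iz(cfg["right_iz"]),
        _load_iz(cfg["left_iz"]),
        float(cfg["locus_len_kb"]),
    )


def format_single_iz_report(res: SingleIZResult) -> str:
    lines = [
        f"Estimated S-phase duration\t{round_half_up(res.s_duration_min):.0f} min",
    ]
    for q, d in zip(QUARTERS, res.distances_kb):
        lines.append(f"Distance for forks starting in S{q}\t{round_half_up(d):.0f} kb")
    lines.append(f"Average travel distance\t{round_half_up(res.mean_travel_kb):.0f} kb")
    return "\n".join(lines)


def format_two_iz_report(res: TwoIZResult) -> str:
    lines = [
        f"Estimated S-phase duration\t{round_half_up(res.s_duration_min):.0f} min",
        f"Average rightward travel (dIZ1)\t{round_half_up(res.right.mean_travel_kb):.0f} kb",
        f"Average leftward travel (dIZ2)\t{round_half_up(res.left.mean_travel_kb):.0f} kb",
        f"Average meeting point\t{round_half_up(res.meeting_point_kb):.0f} kb",
        f"Rightward forks reaching the far IZ\t{round_half_up(res.reach_right_pct, 1):.1f} %"
        f"\t(distance feasible: {res.reach_right_feasible})",
        f"Leftward forks reaching the far IZ\t{round_half_up(res.reach_left_pct, 2):.2f} %"
        f"\t(distance feasible: {res.reach_left_feasible})",
    ]
    return "\n".join(lines)
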