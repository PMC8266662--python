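"""Strand-resolved coverage, RFD, OEM and (I − T) profiles over a locus.

Replication fork directionality at a position is RFD = (R − L)/(R + L),
where R and L are the amounts of DNA replicated by rightward- and
leftward-moving forks.  Profiles are stored binned; binned RFD is the ratio
of summed coverages within the bin, and bins with zero total coverage are
undefined (NaN), never zero.

The origin efficiency metric (OEM) at the boundary between two adjacent
windows is the drop in the normalised leftward coverage fraction,
OEM(i) = L/(R+L)|window i − L/(R+L)|window i+1, equivalently
(RFD(i+1) − RFD(i))/2.  Positive OEM marks efficient initiation, negative
OEM predominant termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .fibers import Direction, OrientedSegment, ReplicationEvent, EventKind

__all__ = [
    "Locus",
    "RFDProfile",
    "OEMProfile",
    "ITProfile",
    "Zone",
    "coverage",
    "binned_bp_overlap",
    "oem",
    "it_density",
    "call_zones",
    "write_bedgraph",
    "read_bedgraph",
    "write_bigwig",
]


@dataclass(frozen=True)
class Locus:
    """A half-open genomic interval with a bin size."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("locus start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    def n_bins(self, bin_size: int) -> int:
        return -(-self.length // bin_size)  # ceil

    def bin_edges(self, bin_size: int) -> np.ndarray:
        edges = np.arange(self.start, self.end + bin_size, bin_size)
        edges[-1] = min(edges[-1], self.end)
        return edges[: self.n_bins(bin_size) + 1]


def binned_bp_overlap(
    starts: np.ndarray, ends: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Total interval-bp overlapping each bin of ``edges`` (vectorised).

    Uses the cumulative overlap function F(x) = sum_i clip(x − s_i, 0, len_i);
    per-bin bp is the difference of F at consecutive edges.
    """
    if len(starts) == 0:
        return np.zeros(len(edges) - 1)
    starts = np.asarray(starts, dtype=float)
    lengths = np.asarray(ends, dtype=float) - starts
    # F at every edge: (n_edges,) after summing over intervals
    f = np.clip(edges[:, None] - starts[None, :], 0.0, lengths[None, :]).sum(axis=1)
    return np.diff(f)


@dataclass
class RFDProfile:
    """Binned rightward/leftward coverage and their directionality ratio."""

    locus: Locus
    bin_size: int
    r_cov: np.ndarray
    l_cov: np.ndarray

    def __post_init__(self) -> None:
        self.r_cov = np.asarray(self.r_cov, dtype=float)
        self.l_cov = np.asarray(self.l_cov, dtype=float)
        n = self.locus.n_bins(self.bin_size)
        if len(self.r_cov) != n or len(self.l_cov) != n:
            raise ValueError("coverage arrays do not match locus binning")
        if (self.r_cov < 0).any() or (self.l_cov < 0).any():
            raise ValueError("coverage must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.r_cov)

    @property
    def total(self) -> np.ndarray:
        return self.r_cov + self.l_cov

    @property
    def rfd(self) -> np.ndarray:
        """(R − L)/(R + L); NaN where no coverage."""
        total = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (self.r_cov - self.l_cov) / total
        out[total == 0] = np.nan
        return out

    @property
    def defined(self) -> np.ndarray:
        return self.total > 0

    @property
    def bin_starts(self) -> np.ndarray:
        return self.locus.bin_edges(self.bin_size)[:-1].astype(int)


def coverage(
    segments: Iterable[OrientedSegment], locus: Locus, bin_size: int
) -> RFDProfile:
    """Bin oriented-segment bp into rightward and leftward coverage.

    Segment overlap is clipped to the locus; bp are apportioned to bins by
    exact overlap, so the ratio within a bin is a ratio of summed coverages.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    edges = locus.bin_edges(bin_size).astype(float)
    by_dir: dict[Direction, list[tuple[int, int]]] = {Direction.R: [], Direction.L: []}
    for s in segments:
        if s.chrom != locus.chrom:
            continue
        start, end = max(s.start, locus.start), min(s.end, locus.end)
        if start < end:
            by_dir[s.direction].append((start, end))
    covs = {}
    for d, ivals in by_dir.items():
        if ivals:
            arr = np.array(ivals, dtype=float)
            covs[d] = binned_bp_overlap(arr[:, 0], arr[:, 1], edges)
        else:
            covs[d] = np.zeros(len(edges) - 1)
    return RFDProfile(locus, bin_size, covs[Direction.R], covs[Direction.L])


@dataclass
class OEMProfile:
    """OEM at each interior boundary between adjacent windows."""

    locus: Locus
    window: int
    values: np.ndarray  # length n_bins − 1, NaN where a flanking window is undefined

    @property
    def boundary_positions(self) -> np.ndarray:
        return self.locus.bin_edges(self.window)[1:-1].astype(int)


def oem(profile: RFDProfile) -> OEMProfile:
    """Origin efficiency metric from a binned RFD profile.

    OEM(i) = Lfrac(i) − Lfrac(i+1) with Lfrac = L/(R+L); boundaries with an
    undefined flanking window are NaN.  With fewer than two windows the
    profile is empty.
    """
    total = profile.total
    with np.errstate(invalid="ignore", divide="ignore"):
        lfrac = profile.l_cov / total
    lfrac[total == 0] = np.nan
    values = lfrac[:-1] - lfrac[1:] if profile.n_bins >= 2 else np.empty(0)
    return OEMProfile(profile.locus, profile.bin_size, values)


@dataclass
class ITProfile:
    """Initiation-minus-termination event counts per non-overlapping bin."""

    locus: Locus
    bin_size: int
    values: np.ndarray  # int per bin

    @property
    def bin_starts(self) -> np.ndarray:
        return self.locus.bin_edges(self.bin_size)[:-1].astype(int)


def it_density(
    events: Iterable[ReplicationEvent], locus: Locus, bin_size: int
) -> ITProfile:
    """Count initiation minus termination events in non-overlapping bins."""
    edges = locus.bin_edges(bin_size)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for e in events:
        if e.chrom != locus.chrom or not (locus.start <= e.position < locus.end):
            continue
        b = min((e.position - locus.start) // bin_size, len(counts) - 1)
        counts[b] += 1 if e.kind is EventKind.INITIATION else -1
    return ITProfile(locus, bin_size, counts)


@dataclass(frozen=True)
class Zone:
    """A called initiation (IZ) or termination (TZ) zone."""

    kind: str  # "IZ" | "TZ"
    chrom: str
    start: int
    end: int
    center: int  # |OEM|-weighted centre of the member boundaries

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def call_zones(
    oem_profile: OEMProfile,
    threshold: float = 0.1,
    min_run: int = 1,
    merge_within: int = 0,
) -> list[Zone]:
    """Threshold-based initiation/termination zone caller.

    Maximal runs of at least ``min_run`` consecutive boundaries with
    OEM ≥ threshold become IZs; runs at or below −threshold become TZs.
    Runs of the same kind separated by at most ``merge_within`` boundaries
    are merged (useful for broad, noisy zones; off by default).  A zone spans
    from half a window left of its first boundary to half a window right of
    its last; its centre is the |OEM|-weighted mean boundary position.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = oem_profile.values
    positions = oem_profile.boundary_positions
    half = oem_profile.window // 2
    zones: list[Zone] = []
    for kind, mask in (
        ("IZ", values >= threshold),
        ("TZ", values <= -threshold),
    ):
        mask = mask & ~np.isnan(values)
        runs = _runs(mask)
        if merge_within > 0:
            runs = _merge_runs(runs, merge_within)
        for i0, i1 in runs:  # half-open index run
            if i1 - i0 < min_run:
                continue
            w = np.abs(values[i0:i1])
            w = np.where(np.isnan(w), 0.0, w)
            center = (
                int(np.round(np.average(positions[i0:i1], weights=w)))
                if w.sum() > 0
                else int(positions[i0:i1].mean())
            )
            zones.append(
                Zone(
                    kind,
                    oem_profile.locus.chrom,
                    int(positions[i0] - half),
                    int(positions[i1 - 1] + half),
                    center,
                )
            )
    zones.sort(key=lambda z: z.start)
    return zones


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)
    return merged


# ---------------------------------------------------------------------------
# bedGraph / bigWig export

def write_bedgraph(
    path: str | Path,
    chrom: str,
    starts: Sequence[int],
    ends: Sequence[int],
    values: Sequence[float],
) -> None:
    """4-column bedGraph; rows with NaN values are omitted (undefined bins)."""
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split("\t")
            rows.append((chrom, int(s), int(e), float(v)))
    return rows


def write_bigwig(
    path: str | Path,
    chrom: str,
    starts: Sequence[int],
    ends: Sequence[int],
    values: Sequence[float],
    chrom_sizes: dict[str, int],
) -> None:
    """Optional bigWig export; requires pyBigWig and a chrom-sizes mapping."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - capability check
        raise RuntimeError("bigWig export requires the pyBigWig package") from exc
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader(sorted(chrom_sizes.items()))
    keep = [i for i, v in enumerate(values) if not np.isnan(v)]
    bw.addEntries(
        [chrom] * len(keep),
        [int(starts[i]) for i in keep],
        ends=[int(ends[i]) for i in keep],
        values=[float(values[i]) for i in keep],
    )
    bw.close()
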