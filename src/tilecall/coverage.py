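"""Per-base read-coverage tracks and per-tile mean coverage.

The pipeline consumes mapped-read intervals (BED) or ready-made coverage
(bedGraph); read mapping itself is upstream provenance. Depth at a base
is the number of read intervals covering it. A tile's "no coverage"
predicate — every base of its 25 bp interval at depth 0, equivalently a
zero mean — is the sequencing half of the deletion-calling criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .probe_map import ProbeMap


@dataclass
class CoverageTrack:
    """chrom -> dense vector of non-negative integer depth, one per base."""

    depth: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, vec in self.depth.items():
            vec = np.asarray(vec)
            if (vec < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self.depth[chrom] = vec

    def total(self) -> int:
        """Sum of depth over all bases (== total aligned bases)."""
        return int(sum(v.sum() for v in self.depth.values()))


@dataclass
class TileCoverage:
    """probe_id -> mean depth over the tile's genomic interval."""

    mean_depth: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mean_depth)

    def __getitem__(self, probe_id: str) -> float:
        return self.mean_depth[probe_id]

    def zero_coverage_ids(self) -> set[str]:
        return {pid for pid, d in self.mean_depth.items() if d == 0}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("probe_id\tmean_depth\n")
            for pid, d in self.mean_depth.items():
                fh.write(f"{pid}\t{d:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TileCoverage":
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
        return cls(dict(zip(df["probe_id"], df["mean_depth"].astype(float))))


def coverage_from_alignments(
    intervals: Iterable[tuple[str, int, int]],
    genome_lengths: Mapping[str, int],
) -> CoverageTrack:
    """Accumulate per-base depth from half-open mapped-read intervals.

    Uses a difference array per chromosome: +1 at each interval start,
    -1 at each end, then a cumulative sum.
    """
    diffs = {c: np.zeros(l + 1, dtype=np.int64) for c, l in genome_lengths.items()}
    for lineno, (chrom, start, end) in enumerate(intervals, start=1):
        if chrom not in diffs:
            raise ValueError(f"interval {lineno}: unknown chromosome {chrom!r}")
        if start < 0 or end > genome_lengths[chrom] or start >= end:
            raise ValueError(
                f"interval {lineno}: [{start}, {end}) out of bounds on {chrom}"
            )
        diffs[chrom][start] += 1
        diffs[chrom][end] -= 1
    return CoverageTrack(
        {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    )


def read_sam_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Reference spans of aligned reads from SAM/BAM (convenience path).

    Each mapped read contributes its aligned blocks (soft/hard-clipped
    bases excluded; deletions in the read's CIGAR split the span), so
    depth accumulation matches samtools-style per-base coverage. BED /
    bedGraph remain the canonical inputs.
    """
    import pysam

    out: list[tuple[str, int, int]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            for start, end in read.get_blocks():
                out.append((read.reference_name, start, end))
    return out


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read 3+-column BED into (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def read_bedgraph(
    path: str | Path, genome_lengths: Mapping[str, int]
) -> CoverageTrack:
    """Read a 0-based half-open bedGraph into a dense track.

    Positions not covered by any bedGraph line are depth 0. Overlapping
    intervals are rejected (a bedGraph is a partition, not a pile-up).
    """
    depth = {c: np.zeros(l, dtype=np.int64) for c, l in genome_lengths.items()}
    covered = {c: np.zeros(l, dtype=bool) for c, l in genome_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start_s, end_s, value_s = line.split("\t")
            if chrom not in depth:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            start, end = int(start_s), int(end_s)
            if start < 0 or end > len(depth[chrom]) or start >= end:
                raise ValueError(f"{path}: line {lineno}: bad interval [{start}, {end})")
            if covered[chrom][start:end].any():
                raise ValueError(f"{path}: line {lineno}: overlapping bedGraph intervals")
            covered[chrom][start:end] = True
            depth[chrom][start:end] = int(float(value_s))
    return CoverageTrack(depth)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write the track as a minimal run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in track.depth:
            vec = track.depth[chrom]
            if len(vec) == 0:
                continue
            breaks = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(vec)]))
            for s, e in zip(starts, ends):
                v = int(vec[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def tile_mean_coverage(track: CoverageTrack, probes: ProbeMap) -> TileCoverage:
    """Mean depth over each tile's [start, start+length) interval.

    The zero-coverage predicate (mean == 0) is exactly "no read covers any
    of the tile's bases", since depth is non-negative.
    """
    means: dict[str, float] = {}
    for p in probes:
        if p.chrom not in track.depth:
            raise ValueError(
                f"probe {p.probe_id!r} is on chromosome {p.chrom!r}, "
                "absent from the coverage track"
            )
        vec = track.depth[p.chrom]
        if p.end > len(vec):
            raise ValueError(
                f"probe {p.probe_id!r} extends past the end of {p.chrom}"
            )
        means[p.probe_id] = float(vec[p.start : p.end].mean())
    return TileCoverage(means)
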