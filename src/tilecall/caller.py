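"""Deletion calling: intersect signal ratio with tile coverage, then merge.

A tile is a deletion candidate when the two independent lines of evidence
agree: its log2 signal ratio falls strictly below the threshold (default
-1.0; -1.5 for a stringent screen) AND no short read covers any of its
bases. Candidate tiles are chained left-to-right: a tile joins the
current chain when the gap between the previous tile's end and its start
is at most ``max_gap`` (39 bp — tiles are typically spaced 10 bp apart,
always under 40). Chains spanning at least ``min_span`` bp (100 bp; 300 bp
for major deletions) become deletion calls.

The intersection of the two weak criteria is what gives the method its
specificity: polymorphism-dense regions lose read coverage but retain a
near-neutral hybridization signal, and noisy low-signal tiles are still
covered by reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .array_signal import SignalRatioTrack
from .coverage import TileCoverage
from .probe_map import Probe, ProbeMap

DEFAULT_RATIO_THRESHOLD = -1.0
STRINGENT_RATIO_THRESHOLD = -1.5
DEFAULT_MAX_GAP = 39
DEFAULT_MIN_SPAN = 100
MAJOR_DELETION_MIN_SPAN = 300


@dataclass(frozen=True)
class TileRecord:
    """One tile's joint evidence: array signal ratio and mean read depth."""

    probe: Probe
    ratio: float
    mean_depth: float


@dataclass(frozen=True)
class CallerConfig:
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    max_gap: int = DEFAULT_MAX_GAP
    min_span: int = DEFAULT_MIN_SPAN

    def __post_init__(self) -> None:
        if self.ratio_threshold >= 0:
            raise ValueError("ratio_threshold must be negative")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class DeletionCall:
    """A maximal chain of flagged tiles: chrom, [start, end), tile count."""

    chrom: str
    start: int
    end: int
    n_tiles: int
    mean_ratio: float = float("nan")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class CallSummary:
    """Stage counts: tiles considered, each single criterion, their intersection."""

    n_tiles: int = 0
    n_ratio_flagged: int = 0
    n_zero_coverage: int = 0
    n_intersection: int = 0
    n_chains: int = 0
    n_chains_dropped: int = 0
    n_calls: int = 0
    n_missing_either_side: int = 0


def _check_sorted(records: Sequence[TileRecord]) -> None:
    keys = [(r.probe.chrom, r.probe.start) for r in records]
    if keys != sorted(keys):
        raise ValueError("tile records must be sorted by (chrom, start)")


def flag_tiles(
    records: Sequence[TileRecord], cfg: CallerConfig
) -> list[TileRecord]:
    """Tiles with ratio strictly below threshold AND zero coverage over all bases."""
    _check_sorted(records)
    return [
        r
        for r in records
        if r.ratio < cfg.ratio_threshold and r.mean_depth == 0
    ]


def merge_flagged(
    flagged: Sequence[TileRecord], cfg: CallerConfig
) -> tuple[list[DeletionCall], int]:
    """Chain flagged tiles under the gap rule; keep chains spanning >= min_span.

    Greedy left-to-right: a tile extends the current chain iff
    (tile.start - previous tile.end) <= max_gap and it is on the same
    chromosome. Each maximal chain whose total span (last end - first
    start) reaches min_span becomes one call; shorter chains are dropped
    and counted. Returns (calls, n_dropped_chains).
    """
    _check_sorted(flagged)
    calls: list[DeletionCall] = []
    dropped = 0
    chain: list[TileRecord] = []

    def close_chain() -> None:
        nonlocal dropped
        if not chain:
            return
        start = chain[0].probe.start
        end = chain[-1].probe.end
        if end - start >= cfg.min_span:
            calls.append(
                DeletionCall(
                    chrom=chain[0].probe.chrom,
                    start=start,
                    end=end,
                    n_tiles=len(chain),
                    mean_ratio=float(np.mean([t.ratio for t in chain])),
                )
            )
        else:
            dropped += 1

    for rec in flagged:
        if (
            chain
            and rec.probe.chrom == chain[-1].probe.chrom
            and rec.probe.start - chain[-1].probe.end <= cfg.max_gap
        ):
            chain.append(rec)
        else:
            close_chain()
            chain = [rec]
    close_chain()
    return calls, dropped


def build_tile_records(
    ratios: SignalRatioTrack, cov: TileCoverage, probes: ProbeMap
) -> tuple[list[TileRecord], int]:
    """Join ratio and coverage evidence per probe; count probes missing a side.

    Probes absent from either track are invisible to chaining: they
    neither extend nor break a chain beyond the inter-tile distance they
    leave behind.
    """
    records: list[TileRecord] = []
    missing = 0
    for p in probes:
        if p.probe_id in ratios.ratios and p.probe_id in cov.mean_depth:
            records.append(
                TileRecord(p, ratios[p.probe_id], cov[p.probe_id])
            )
        else:
            missing += 1
    return records, missing


def call_deletions(
    ratios: SignalRatioTrack,
    cov: TileCoverage,
    probes: ProbeMap,
    cfg: CallerConfig = CallerConfig(),
) -> tuple[list[DeletionCall], CallSummary]:
    """Run the full intersection caller and report per-stage counts."""
    records, missing = build_tile_records(ratios, cov, probes)
    if not records:
        raise ValueError("no probes shared between the signal and coverage tracks")
    summary = CallSummary(
        n_tiles=len(records),
        n_missing_either_side=missing,
        n_ratio_flagged=sum(r.ratio < cfg.ratio_threshold for r in records),
        n_zero_coverage=sum(r.mean_depth == 0 for r in records),
    )
    flagged = flag_tiles(records, cfg)
    summary.n_intersection = len(flagged)
    calls, dropped = merge_flagged(flagged, cfg)
    summary.n_calls = len(calls)
    summary.n_chains_dropped = dropped
    summary.n_chains = len(calls) + dropped
    return calls, summary


def write_calls_bed(calls: Iterable[DeletionCall], path: str | Path) -> None:
    """BED6: name = call id, score = number of merged tiles, strand '.'."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls, start=1):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tdel_{i}\t{c.n_tiles}\t.\n"
            )


def write_calls_tsv(calls: Iterable[DeletionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tspan\tn_tiles\tmean_ratio\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.span}\t{c.n_tiles}\t"
                f"{c.mean_ratio:.4f}\n"
            )


def read_calls_bed(path: str | Path) -> list[DeletionCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            calls.append(
                DeletionCall(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    n_tiles=int(fields[4]) if len(fields) > 4 else 1,
                )
            )
    return calls
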