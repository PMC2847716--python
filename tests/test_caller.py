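"""Tile flagging, gap-constrained chain merging and the composed caller."""

import math

import numpy as np
import pytest

from tilecall import (
    CallerConfig,
    ProbeMap,
    TileCoverage,
    TileRecord,
    call_deletions,
    flag_tiles,
    merge_flagged,
)
from tilecall.array_signal import SignalRatioTrack
from tilecall.caller import merge_flagged as _merge
from tilecall.probe_map import Probe

CFG = CallerConfig()


def rec(start, ratio=-2.0, depth=0.0, chrom="c"):
    return TileRecord(Probe(f"{chrom}_{start}", chrom, start), ratio, depth)


@pytest.mark.parametrize(
    "ratio, depth, flagged",
    [
        (-1.2, 0.0, True),  # both criteria met
        (-1.0, 0.0, False),  # threshold is strict
        (-2.5, 0.04, False),  # covered tile
        (-0.9, 0.0, False),
    ],
)
def test_flagging_rules(ratio, depth, flagged):
    out = flag_tiles([rec(0, ratio, depth)], CFG)
    assert (len(out) == 1) == flagged


def test_canonical_grid_merges_to_one_call():
    tiles = [rec(s) for s in (0, 35, 70, 105)]  # 25 bp tiles, 10 bp gaps
    calls, dropped = merge_flagged(tiles, CFG)
    assert dropped == 0
    (call,) = calls
    assert (call.start, call.end, call.n_tiles, call.span) == (0, 130, 4, 130)


def test_large_gap_breaks_chain_and_short_chains_drop():
    calls, dropped = merge_flagged([rec(0), rec(100)], CFG)  # gap 75 > 39
    assert calls == [] and dropped == 2


def oracle_chains(tiles, cfg):
    """Independent chain enumeration: break vector + group scan."""
    out = []
    if not tiles:
        return out
    groups = [[tiles[0]]]
    for prev, cur in zip(tiles, tiles[1:]):
        same = cur.probe.chrom == prev.probe.chrom
        if same and cur.probe.start - prev.probe.end <= cfg.max_gap:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    for g in groups:
        span = g[-1].probe.end - g[0].probe.start
        if span >= cfg.min_span:
            out.append((g[0].probe.chrom, g[0].probe.start, g[-1].probe.end, len(g)))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_merging_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    tiles = []
    for chrom in ("c1", "c2"):
        starts = np.unique(rng.integers(0, 8000, size=100))
        tiles.extend(rec(int(s), chrom=chrom) for s in starts)
    calls, _ = merge_flagged(tiles, CFG)
    assert [(c.chrom, c.start, c.end, c.n_tiles) for c in calls] == oracle_chains(
        tiles, CFG
    )


def test_unsorted_input_rejected():
    with pytest.raises(ValueError, match="sorted"):
        merge_flagged([rec(100), rec(0)], CFG)
    with pytest.raises(ValueError, match="sorted"):
        flag_tiles([rec(100), rec(0)], CFG)


def _call_inputs(flag_mask, n=30):
    """Grid of n tiles; tiles where flag_mask is true get (-2, 0) evidence."""
    probes = ProbeMap([Probe(f"p{i}", "c", 35 * i) for i in range(n)])
    ratios = SignalRatioTrack(
        {f"p{i}": (-2.0 if flag_mask[i] else 0.0) for i in range(n)}
    )
    cov = TileCoverage({f"p{i}": (0.0 if flag_mask[i] else 5.0) for i in range(n)})
    return ratios, cov, probes


def test_no_evidence_means_no_calls():
    ratios, cov, probes = _call_inputs([False] * 30)
    calls, summary = call_deletions(ratios, cov, probes)
    assert calls == [] and summary.n_intersection == 0


def test_no_shared_probes_is_an_error():
    probes = ProbeMap([Probe("p", "c", 0)])
    with pytest.raises(ValueError, match="shared"):
        call_deletions(SignalRatioTrack({"x": -2.0}), TileCoverage({"y": 0.0}), probes)


def test_min_span_monotonicity():
    mask = [False] * 30
    mask[3:8] = [True] * 5
    mask[15:25] = [True] * 10
    ratios, cov, probes = _call_inputs(mask)
    calls_100, _ = call_deletions(ratios, cov, probes, CallerConfig(min_span=100))
    calls_300, _ = call_deletions(ratios, cov, probes, CallerConfig(min_span=300))
    assert set(calls_300).issubset(set(calls_100))
    assert len(calls_100) == 2 and len(calls_300) == 1


def test_threshold_monotonicity():
    n = 30
    probes = ProbeMap([Probe(f"p{i}", "c", 35 * i) for i in range(n)])
    rng = np.random.default_rng(4)
    ratios = SignalRatioTrack({f"p{i}": float(-rng.uniform(0, 3)) for i in range(n)})
    cov = TileCoverage({f"p{i}": 0.0 for i in range(n)})
    loose, _ = call_deletions(ratios, cov, probes, CallerConfig(ratio_threshold=-1.0))
    strict, _ = call_deletions(ratios, cov, probes, CallerConfig(ratio_threshold=-1.5))
    loose_bp = {(c.chrom, b) for c in loose for b in range(c.start, c.end)}
    strict_bp = {(c.chrom, b) for c in strict for b in range(c.start, c.end)}
    assert strict_bp.issubset(loose_bp)


def test_summary_counts_and_tile_lower_bound():
    mask = [False] * 40
    mask[2:12] = [True] * 10
    mask[20] = True  # isolated: chain of one tile, dropped at min_span
    ratios, cov, probes = _call_inputs(mask, n=40)
    calls, summary = call_deletions(ratios, cov, probes)
    assert summary.n_intersection <= min(summary.n_ratio_flagged, summary.n_zero_coverage)
    assert summary.n_calls + summary.n_chains_dropped == summary.n_chains
    for c in calls:
        lower = math.ceil(CFG.min_span / (25 + CFG.max_gap))
        assert c.n_tiles >= lower


def test_missing_tiles_are_invisible_to_chaining():
    """A probe absent from one side neither extends nor breaks a chain
    beyond the inter-tile distance it leaves behind."""
    probes = ProbeMap([Probe(f"p{i}", "c", 35 * i) for i in range(5)])
    # p2 has no ratio entry: distance p1.end -> p3.start = 45 > 39 splits
    ratios = SignalRatioTrack({f"p{i}": -2.0 for i in range(5) if i != 2})
    cov = TileCoverage({f"p{i}": 0.0 for i in range(5)})
    calls, summary = call_deletions(ratios, cov, probes, CallerConfig(min_span=25))
    assert summary.n_missing_either_side == 1
    assert [(c.start, c.end) for c in calls] == [(0, 60), (105, 165)]
    # with a laxer gap the hole is bridged by distance alone
    bridged, _ = call_deletions(ratios, cov, probes, CallerConfig(min_span=25, max_gap=45))
    assert [(c.start, c.end, c.n_tiles) for c in bridged] == [(0, 165, 4)]
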