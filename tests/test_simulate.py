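"""Synthetic-data generator: determinism, noise structure, truth scoring."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from tilecall import DeletionCall, read_bedgraph, read_genome_fasta, read_probe_map
from tilecall.simulate import PackingError, SimConfig, score_calls, simulate_dataset

from conftest import run_accession


def _dir_hash(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
        if p.is_file()
    }


def test_same_seed_gives_byte_identical_output(tmp_path):
    cfg = SimConfig(genome_length=60_000, n_chromosomes=1, n_accessions=1,
                    n_deletions=5, seed=5)
    simulate_dataset(cfg, tmp_path / "a")
    simulate_dataset(cfg, tmp_path / "b")
    assert _dir_hash(tmp_path / "a") == _dir_hash(tmp_path / "b")


def test_coverage_mean_and_zero_depth_structure(small_sim):
    cfg, truth, outdir = small_sim
    lengths = {c: len(s) for c, s in read_genome_fasta(outdir / "genome.fa").items()}
    label = truth.accessions[0]
    track = read_bedgraph(outdir / f"{label}.coverage.bedgraph", lengths)
    masked = {c: np.ones(l, dtype=bool) for c, l in lengths.items()}
    for c, s, e in truth.deletions[label] + truth.hotspots[label]:
        masked[c][s:e] = False
    outside = np.concatenate([track.depth[c][masked[c]] for c in lengths])
    assert abs(outside.mean() - cfg.coverage_mean) / cfg.coverage_mean < 0.1
    # deleted bases have exactly zero depth
    for c, s, e in truth.deletions[label]:
        assert (track.depth[c][s:e] == 0).all()


def test_signal_ratio_distribution(tmp_path):
    """Intact unique tiles are centered at 0 and fully deleted tiles fall
    below the -1.0 threshold in at least 90% of cases, at a realistic
    (low) deleted fraction of the genome. Joint quantile normalization
    shifts intact ratios upward in proportion to the deleted fraction, so
    centering is a property of the sparse-deletion regime."""
    from tilecall import IntensityTable, quantile_normalize, signal_ratio
    from tilecall.annotate import intersect_length

    cfg = SimConfig(genome_length=120_000, n_chromosomes=1, n_accessions=1,
                    n_deletions=3, deletion_min_len=500, deletion_max_len=1500,
                    seed=6)
    truth = simulate_dataset(cfg, tmp_path)
    outdir = tmp_path
    label = truth.accessions[0]
    pm = read_probe_map(outdir / "probes.tsv")
    table = IntensityTable.from_tsvs(
        [outdir / f"{label}.test{i}.tsv" for i in (1, 2)],
        [outdir / f"{label}.ref{i}.tsv" for i in (1, 2)],
    )
    ratios = signal_ratio(quantile_normalize(table))
    dels = {c: [(s, e) for cc, s, e in truth.deletions[label] if cc == c]
            for c in {d[0] for d in truth.deletions[label]}}
    hots = {c: [(s, e) for cc, s, e in truth.hotspots[label] if cc == c]
            for c in {h[0] for h in truth.hotspots[label]}}
    deleted, intact = [], []
    for p in pm:
        r = ratios[p.probe_id]
        dfrac = intersect_length([(p.start, p.end)], dels.get(p.chrom, [])) / 25
        hfrac = intersect_length([(p.start, p.end)], hots.get(p.chrom, [])) / 25
        if dfrac == 1.0:
            deleted.append(r)
        elif dfrac == 0.0 and hfrac == 0.0:
            intact.append(r)
    assert abs(np.median(intact)) < 0.1
    assert np.mean(np.array(deleted) < -1.0) >= 0.9


def test_polymorphic_tiles_mildly_attenuated_not_called(tmp_path):
    """Hotspot tiles lose coverage but keep a mild (~ -0.2) signal ratio,
    so pure polymorphism produces no deletion calls."""
    cfg = SimConfig(genome_length=150_000, n_chromosomes=1, n_accessions=1,
                    n_deletions=0, snp_hotspot_rate=1e-4, seed=8)
    truth = simulate_dataset(cfg, tmp_path)
    assert len(truth.hotspots["acc01"]) > 5
    calls, summary = run_accession(tmp_path, "acc01")
    assert calls == []
    assert summary.n_zero_coverage > 0  # the hotspots did lose coverage


def test_noise_free_single_deletion_recovered(tmp_path):
    cfg = SimConfig(genome_length=50_000, n_chromosomes=1, n_accessions=1,
                    n_deletions=1, deletion_min_len=1000, deletion_max_len=1000,
                    intensity_sd_log2=1e-6, snp_hotspot_rate=0.0, seed=9)
    truth = simulate_dataset(cfg, tmp_path)
    calls, _ = run_accession(tmp_path, "acc01")
    res = score_calls(calls, truth.deletions["acc01"], min_jaccard=0.9)
    assert res.n_calls == 1
    assert res.recall == 1.0 and res.precision == 1.0
    # boundaries within one tile + gap of truth
    assert max(res.boundary_errors_bp) <= 35


def test_truth_json_round_trips(tmp_path):
    cfg = SimConfig(genome_length=60_000, n_chromosomes=1, n_accessions=2,
                    n_deletions=4, seed=12)
    truth = simulate_dataset(cfg, tmp_path)
    on_disk = json.loads((tmp_path / "truth.json").read_text())
    for label in truth.accessions:
        assert [list(t) for t in truth.deletions[label]] == on_disk["deletions"][label]
        assert sorted(truth.deleted_genes[label]) == on_disk["deleted_genes"][label]


def test_infeasible_packing_rejected(tmp_path):
    cfg = SimConfig(genome_length=30_000, n_chromosomes=1, n_deletions=200, seed=1)
    with pytest.raises(PackingError):
        simulate_dataset(cfg, tmp_path / "never")


def test_deletion_placement_respects_separation(small_sim):
    cfg, truth, _ = small_sim
    for label in truth.accessions:
        by_chrom = {}
        for c, s, e in truth.deletions[label]:
            by_chrom.setdefault(c, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 - e1 >= cfg.min_deletion_separation


def test_score_calls_identity_and_edge_cases():
    truth = [("c", 100, 1100), ("c", 5000, 6000)]
    exact = [DeletionCall("c", s, e, 1) for _, s, e in truth]
    res = score_calls(exact, truth)
    assert res.recall == 1.0 and res.precision == 1.0
    assert res.boundary_errors_bp == [0, 0]

    none = score_calls([], truth)
    assert none.recall == 0.0 and none.precision is None

    jittered = [DeletionCall("c", s + 30, e - 30, 1) for _, s, e in truth]
    res_j = score_calls(jittered, truth, min_jaccard=0.5)
    assert res_j.recall == 1.0
    assert res_j.boundary_within(64) == 1.0
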