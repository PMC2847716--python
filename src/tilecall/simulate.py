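"""Synthetic benchmark data with the statistical structure the caller assumes.

The generator emits the full input ecosystem — random genome FASTA, tile
grid (probe map), GFF3 gene models, per-accession read-coverage bedGraph
and array-intensity TSVs — together with ground truth for scoring:

* planted deletions (>= 100 bp, non-overlapping, >= 200 bp apart so two
  truths can never legitimately merge at the default 39 bp gap rule),
  preferentially placed in transposable-element genes;
* per-base coverage drawn negative-binomially, forced to zero over
  deletions and (mapping dropout) over SNP-hotspot intervals;
* log-normal intensities: test arrays fall to the background
  distribution over deleted tiles but are only mildly attenuated
  (~ -0.21 log2) over polymorphic tiles — the confound the intersection
  criterion is designed to reject.

One global seed drives every draw; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import TE_BIOTYPE, PROTEIN_CODING, Interval, intersect_length
from .caller import DeletionCall
from .probe_map import Probe, ProbeMap, write_probe_map
from .coverage import CoverageTrack, write_bedgraph


@dataclass
class SimConfig:
    """Generator parameters; defaults are the benchmark's study conditions."""

    genome_length: int = 500_000
    n_chromosomes: int = 2
    tile_length: int = 25
    tile_gap: int = 10
    n_accessions: int = 4
    n_deletions: int = 50
    deletion_min_len: int = 100
    deletion_max_len: int = 5000
    min_deletion_separation: int = 200
    gene_deletion_fraction: float = 0.8  # rest is intergenic
    shared_deletion_fraction: float = 0.5  # planted in every accession
    gene_length: int = 2000
    intergenic_length: int = 1000
    cds_margin: int = 200  # CDS = gene span minus this margin on each side
    te_gene_fraction: float = 0.12
    deletion_te_bias: float = 4.0  # target fold over-representation of TE genes
    coverage_mean: float = 10.0
    coverage_dispersion: float = 5.0  # negative-binomial size parameter
    snp_hotspot_rate: float = 2e-5  # expected hotspots per bp per accession
    hotspot_len_min: int = 50
    hotspot_len_max: int = 200
    hotspot_dropout_prob: float = 1.0
    intensity_fg_log2: float = 10.0
    intensity_bg_log2: float = 7.0
    intensity_sd_log2: float = 0.25  # replicate (array-to-array) noise
    probe_affinity_sd_log2: float = 2.0  # per-probe sequence affinity, shared by all arrays
    polymorphic_attenuation: float = -0.21  # log2, over hotspot tiles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deletion_min_len < self.tile_length:
            raise ValueError("deletion_min_len must be >= tile_length")
        for name in (
            "te_gene_fraction", "gene_deletion_fraction",
            "shared_deletion_fraction", "hotspot_dropout_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def tile_step(self) -> int:
        return self.tile_length + self.tile_gap


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    start: int
    end: int
    biotype: str


@dataclass
class SimTruth:
    """Ground truth: planted intervals per accession, gene status, hotspots."""

    accessions: list[str]
    deletions: dict[str, list[tuple[str, int, int]]]
    hotspots: dict[str, list[tuple[str, int, int]]]
    genes: list[SimGene]
    deleted_genes: dict[str, set] = field(default_factory=dict)


class PackingError(ValueError):
    """Requested deletions cannot be placed on the genome."""


def _chrom_lengths(cfg: SimConfig) -> dict[str, int]:
    per = cfg.genome_length // cfg.n_chromosomes
    return {f"chr{i + 1}": per for i in range(cfg.n_chromosomes)}


def _layout_genes(cfg: SimConfig, chrom_lengths: dict[str, int], rng) -> list[SimGene]:
    genes = []
    i = 1
    for chrom, length in chrom_lengths.items():
        pos = cfg.intergenic_length
        while pos + cfg.gene_length + cfg.intergenic_length <= length:
            biotype = TE_BIOTYPE if rng.random() < cfg.te_gene_fraction else PROTEIN_CODING
            genes.append(SimGene(f"G{i:05d}", chrom, pos, pos + cfg.gene_length, biotype))
            i += 1
            pos += cfg.gene_length + cfg.intergenic_length
    return genes


def _far_enough(
    placed: dict[str, list[Interval]], chrom: str, start: int, end: int, sep: int
) -> bool:
    for s, e in placed.get(chrom, []):
        if start < e + sep and s < end + sep:
            return False
    return True


def _plant_deletions(
    cfg: SimConfig,
    chrom_lengths: dict[str, int],
    genes: list[SimGene],
    rng,
) -> tuple[list[tuple[str, int, int]], dict[str, list[tuple[str, int, int]]]]:
    """Place the shared pool and per-accession private deletions.

    Gene-targeted deletions choose a transposable-element gene with
    probability min(bias * te_fraction, 1), which makes the expected fold
    over-representation of TE genes among deleted genes equal the bias.
    Genes host at most one deletion per accession set; intergenic
    deletions land between genes. Raises PackingError before any file is
    written if placement is impossible.
    """
    te_genes = [g for g in genes if g.biotype == TE_BIOTYPE]
    pc_genes = [g for g in genes if g.biotype != TE_BIOTYPE]
    p_te = min(cfg.deletion_te_bias * cfg.te_gene_fraction, 1.0)

    n_shared = int(round(cfg.n_deletions * cfg.shared_deletion_fraction))
    n_private = cfg.n_deletions - n_shared
    n_gene_targets_needed = cfg.n_deletions  # upper bound per accession
    if n_gene_targets_needed > len(genes):
        raise PackingError(
            f"{cfg.n_deletions} deletions requested but only {len(genes)} genes fit "
            f"on a {cfg.genome_length} bp genome"
        )

    taken_genes: set[str] = set()

    def draw_one(placed: dict[str, list[Interval]]) -> tuple[str, int, int]:
        for _ in range(200):
            if rng.random() < cfg.gene_deletion_fraction:
                pool = te_genes if (rng.random() < p_te and te_genes) else pc_genes
                candidates = [g for g in pool if g.gene_id not in taken_genes]
                if not candidates:
                    continue
                g = candidates[rng.integers(len(candidates))]
                max_len = min(cfg.deletion_max_len, g.end - g.start)
                length = int(rng.integers(cfg.deletion_min_len, max_len + 1))
                start = int(g.start + rng.integers(g.end - g.start - length + 1))
                if _far_enough(placed, g.chrom, start, start + length,
                               cfg.min_deletion_separation):
                    taken_genes.add(g.gene_id)
                    return (g.chrom, start, start + length)
            else:
                chrom = list(chrom_lengths)[rng.integers(len(chrom_lengths))]
                length = int(
                    rng.integers(cfg.deletion_min_len,
                                 min(cfg.deletion_max_len, cfg.intergenic_length) + 1)
                )
                # pick an intergenic block
                blocks = _intergenic_blocks(cfg, chrom_lengths, genes, chrom)
                blocks = [b for b in blocks if b[1] - b[0] >= length]
                if not blocks:
                    continue
                s, e = blocks[rng.integers(len(blocks))]
                start = int(s + rng.integers(e - s - length + 1))
                if _far_enough(placed, chrom, start, start + length,
                               cfg.min_deletion_separation):
                    return (chrom, start, start + length)
        raise PackingError(
            "could not place a deletion after 200 attempts: genome too crowded"
        )

    shared_placed: dict[str, list[Interval]] = {}
    shared: list[tuple[str, int, int]] = []
    for _ in range(n_shared):
        d = draw_one(shared_placed)
        shared.append(d)
        shared_placed.setdefault(d[0], []).append((d[1], d[2]))

    private: dict[str, list[tuple[str, int, int]]] = {}
    for a in range(cfg.n_accessions):
        label = f"acc{a + 1:02d}"
        placed = {c: list(v) for c, v in shared_placed.items()}
        mine: list[tuple[str, int, int]] = []
        for _ in range(n_private):
            d = draw_one(placed)
            mine.append(d)
            placed.setdefault(d[0], []).append((d[1], d[2]))
        private[label] = mine
    return shared, private


def _intergenic_blocks(cfg, chrom_lengths, genes, chrom) -> list[Interval]:
    gene_ivs = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
    blocks, pos = [], 0
    for s, e in gene_ivs:
        if s > pos:
            blocks.append((pos, s))
        pos = e
    if chrom_lengths[chrom] > pos:
        blocks.append((pos, chrom_lengths[chrom]))
    return blocks


def _place_hotspots(
    cfg: SimConfig,
    chrom_lengths: dict[str, int],
    deletions: Sequence[tuple[str, int, int]],
    rng,
) -> list[tuple[str, int, int]]:
    """Polymorphism-dense intervals, kept clear of planted deletions."""
    n = rng.poisson(cfg.snp_hotspot_rate * cfg.genome_length)
    placed: dict[str, list[Interval]] = {}
    for c, s, e in deletions:
        placed.setdefault(c, []).append((s, e))
    hotspots = []
    for _ in range(n):
        for _ in range(100):
            chrom = list(chrom_lengths)[rng.integers(len(chrom_lengths))]
            length = int(rng.integers(cfg.hotspot_len_min, cfg.hotspot_len_max + 1))
            start = int(rng.integers(chrom_lengths[chrom] - length))
            if _far_enough(placed, chrom, start, start + length, 100):
                hotspots.append((chrom, start, start + length))
                placed.setdefault(chrom, []).append((start, start + length))
                break
    return hotspots


def make_probe_grid(cfg: SimConfig, chrom_lengths: dict[str, int]) -> ProbeMap:
    """Regular tile grid: 25 bp tiles every tile_length + tile_gap bp."""
    probes = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length - cfg.tile_length + 1, cfg.tile_step):
            probes.append(Probe(f"{chrom}_{start:08d}", chrom, start, cfg.tile_length))
    return ProbeMap(probes, genome_id="synthetic")


def _simulate_coverage(
    cfg: SimConfig,
    chrom_lengths: dict[str, int],
    deletions: Sequence[tuple[str, int, int]],
    hotspots: Sequence[tuple[str, int, int]],
    rng,
) -> CoverageTrack:
    p = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)
    depth = {
        c: rng.negative_binomial(cfg.coverage_dispersion, p, size=l).astype(np.int64)
        for c, l in chrom_lengths.items()
    }
    for c, s, e in deletions:
        depth[c][s:e] = 0
    for c, s, e in hotspots:
        if rng.random() < cfg.hotspot_dropout_prob:
            depth[c][s:e] = 0
    return CoverageTrack(depth)


def _tile_overlap_fracs(
    probes: ProbeMap, intervals: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    by_chrom: dict[str, list[Interval]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    fracs = np.zeros(len(probes))
    for i, p in enumerate(probes):
        ivs = by_chrom.get(p.chrom)
        if ivs:
            fracs[i] = intersect_length([(p.start, p.end)], ivs) / p.length
    return fracs


def _simulate_intensities(
    cfg: SimConfig,
    probes: ProbeMap,
    deletions: Sequence[tuple[str, int, int]],
    hotspots: Sequence[tuple[str, int, int]],
    affinity: np.ndarray,
    rng,
    n_test: int = 2,
    n_ref: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """(test, reference) raw intensity matrices, one row per probe.

    Test-array log2 means slide from foreground to background in
    proportion to the tile's deleted fraction; hotspot overlap adds the
    mild polymorphic attenuation. Reference arrays see the intact genome.
    The per-probe sequence-affinity offset is common to every array —
    a dim probe is dim everywhere — which gives each array the wide
    marginal intensity distribution real tiling arrays show.
    """
    del_frac = _tile_overlap_fracs(probes, deletions)
    hot_frac = _tile_overlap_fracs(probes, hotspots)
    fg, bg = cfg.intensity_fg_log2, cfg.intensity_bg_log2
    test_mu = fg + affinity + del_frac * (bg - fg) + hot_frac * cfg.polymorphic_attenuation
    ref_mu = fg + affinity
    n = len(probes)
    test = 2.0 ** (test_mu[:, None] + rng.normal(0, cfg.intensity_sd_log2, (n, n_test)))
    ref = 2.0 ** (ref_mu[:, None] + rng.normal(0, cfg.intensity_sd_log2, (n, n_ref)))
    return test, ref


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gff3(genes: Sequence[SimGene], cfg: SimConfig, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start1, end1 = g.start + 1, g.end  # 1-based inclusive
            ftype = TE_BIOTYPE if g.biotype == TE_BIOTYPE else "gene"
            fh.write(
                f"{g.chrom}\tsim\t{ftype}\t{start1}\t{end1}\t.\t+\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{start1}\t{end1}\t.\t+\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            cs, ce = g.start + cfg.cds_margin + 1, g.end - cfg.cds_margin
            if ce > cs:
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t+\t0\t"
                    f"ID={g.gene_id}.1.cds;Parent={g.gene_id}.1\n"
                )


def _write_intervals_bed(intervals, path: Path) -> None:
    with open(path, "w") as fh:
        for c, s, e in sorted(intervals):
            fh.write(f"{c}\t{s}\t{e}\n")


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> SimTruth:
    """Generate the complete synthetic input set plus ground truth on disk.

    Writes genome.fa, probes.tsv, genes.gff3 and, per accession,
    `<acc>.coverage.bedgraph`, `<acc>.{test1,test2,ref1,ref2}.tsv`,
    `<acc>.truth.bed` and `<acc>.hotspots.bed`, plus truth.json.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(cfg.seed)
    chrom_lengths = _chrom_lengths(cfg)
    genes = _layout_genes(cfg, chrom_lengths, rng)
    shared, private = _plant_deletions(cfg, chrom_lengths, genes, rng)

    outdir.mkdir(parents=True, exist_ok=True)
    seqs = {
        c: "".join(rng.choice(list("ACGT"), size=l))
        for c, l in chrom_lengths.items()
    }
    _write_fasta(seqs, outdir / "genome.fa")
    probes = make_probe_grid(cfg, chrom_lengths)
    write_probe_map(probes, outdir / "probes.tsv")
    _write_gff3(genes, cfg, outdir / "genes.gff3")

    accessions = [f"acc{a + 1:02d}" for a in range(cfg.n_accessions)]
    truth = SimTruth(accessions=accessions, deletions={}, hotspots={}, genes=genes)
    affinity = rng.normal(0, cfg.probe_affinity_sd_log2, len(probes))
    for label in accessions:
        dels = sorted(shared + private[label])
        hots = _place_hotspots(cfg, chrom_lengths, dels, rng)
        truth.deletions[label] = dels
        truth.hotspots[label] = hots
        truth.deleted_genes[label] = {
            g.gene_id
            for g in genes
            if intersect_length(
                [(g.start, g.end)],
                [(s, e) for c, s, e in dels if c == g.chrom],
            ) > 0
        }
        track = _simulate_coverage(cfg, chrom_lengths, dels, hots, rng)
        write_bedgraph(track, outdir / f"{label}.coverage.bedgraph")
        test, ref = _simulate_intensities(cfg, probes, dels, hots, affinity, rng)
        for j in range(test.shape[1]):
            _write_intensity_tsv(probes, test[:, j], outdir / f"{label}.test{j + 1}.tsv")
        for j in range(ref.shape[1]):
            _write_intensity_tsv(probes, ref[:, j], outdir / f"{label}.ref{j + 1}.tsv")
        _write_intervals_bed(dels, outdir / f"{label}.truth.bed")
        _write_intervals_bed(hots, outdir / f"{label}.hotspots.bed")

    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "config": asdict(cfg),
                "accessions": accessions,
                "deletions": {a: truth.deletions[a] for a in accessions},
                "hotspots": {a: truth.hotspots[a] for a in accessions},
                "deleted_genes": {a: sorted(truth.deleted_genes[a]) for a in accessions},
                "gene_biotypes": {g.gene_id: g.biotype for g in genes},
            },
            fh,
            indent=1,
        )
    return truth


def _write_intensity_tsv(probes: ProbeMap, values: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tintensity\n")
        for p, v in zip(probes, values):
            fh.write(f"{p.probe_id}\t{v:.6f}\n")


def _jaccard(a: Interval, b: Interval) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union


@dataclass
class ScoreResult:
    recall: float
    precision: float | None  # None when there are no calls
    boundary_errors_bp: list[int]
    n_truth: int
    n_calls: int

    def boundary_within(self, limit_bp: int) -> float:
        """Fraction of recovered deletions with both boundaries within limit_bp."""
        if not self.boundary_errors_bp:
            return float("nan")
        return float(np.mean([e <= limit_bp for e in self.boundary_errors_bp]))


def score_calls(
    calls: Sequence[DeletionCall],
    truth_intervals: Sequence[tuple[str, int, int]],
    min_jaccard: float = 0.5,
) -> ScoreResult:
    """Score calls against planted deletions by interval Jaccard overlap.

    A planted deletion is recovered when some call on its chromosome
    reaches the Jaccard threshold. A call matches the truth — counts
    toward precision — when the planted intervals cover at least
    ``min_jaccard`` of the call's own span, so a call lying inside a
    larger true deletion is not a false positive even though its Jaccard
    with the full truth interval is low. The boundary error of a
    recovered deletion is the larger absolute offset of its best call's
    two endpoints.
    """
    truth_by_chrom: dict[str, list[Interval]] = {}
    for c, s, e in truth_intervals:
        truth_by_chrom.setdefault(c, []).append((s, e))
    recovered = 0
    boundary_errors = []
    for c, s, e in truth_intervals:
        best, best_call = 0.0, None
        for call in calls:
            if call.chrom != c:
                continue
            jac = _jaccard((s, e), (call.start, call.end))
            if jac > best:
                best, best_call = jac, call
        if best >= min_jaccard:
            recovered += 1
            boundary_errors.append(
                max(abs(best_call.start - s), abs(best_call.end - e))
            )
    tp_calls = sum(
        1
        for call in calls
        if call.span > 0
        and intersect_length(
            [(call.start, call.end)], truth_by_chrom.get(call.chrom, [])
        ) / call.span >= min_jaccard
    )
    n_truth = len(truth_intervals)
    return ScoreResult(
        recall=recovered / n_truth if n_truth else float("nan"),
        precision=tp_calls / len(calls) if calls else None,
        boundary_errors_bp=boundary_errors,
        n_truth=n_truth,
        n_calls=len(calls),
    )
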