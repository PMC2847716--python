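import numpy as np
import pytest

from tilecall import (
    IntensityTable,
    call_deletions,
    quantile_normalize,
    read_bedgraph,
    read_genome_fasta,
    read_probe_map,
    signal_ratio,
    tile_mean_coverage,
)
from tilecall.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated dataset shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("smallsim")
    cfg = SimConfig(
        genome_length=120_000,
        n_chromosomes=2,
        n_accessions=2,
        n_deletions=12,
        seed=42,
    )
    truth = simulate_dataset(cfg, outdir)
    return cfg, truth, outdir


def run_accession(datadir, label, caller_cfg=None):
    """Run normalize -> coverage -> call for one accession of a sim dataset."""
    pm = read_probe_map(datadir / "probes.tsv")
    lengths = {c: len(s) for c, s in read_genome_fasta(datadir / "genome.fa").items()}
    table = IntensityTable.from_tsvs(
        [datadir / f"{label}.test{i}.tsv" for i in (1, 2)],
        [datadir / f"{label}.ref{i}.tsv" for i in (1, 2)],
    )
    ratios = signal_ratio(quantile_normalize(table))
    cov = tile_mean_coverage(
        read_bedgraph(datadir / f"{label}.coverage.bedgraph", lengths), pm
    )
    if caller_cfg is None:
        return call_deletions(ratios, cov, pm)
    return call_deletions(ratios, cov, pm, caller_cfg)


def random_genome(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
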