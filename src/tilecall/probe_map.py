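"""Tile-to-genome mapping with a single-perfect-match uniqueness filter.

A tiling array interrogates the reference genome with short (25 bp by
default) oligonucleotide probes laid down at near-regular intervals.
Before any signal is interpreted, probes must be anchored to the genome:
only probes whose sequence occurs exactly once are kept, so that a low
hybridization signal can be attributed to absence of the one locus the
probe targets rather than to cross-hybridization among repeats.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_TILE_LENGTH = 25

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Probe:
    """A single tile: an exact-match oligo anchored at one genomic position."""

    probe_id: str
    chrom: str
    start: int  # 0-based inclusive
    length: int = DEFAULT_TILE_LENGTH
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"probe {self.probe_id}: negative start {self.start}")
        if self.length <= 0:
            raise ValueError(f"probe {self.probe_id}: non-positive length {self.length}")

    @property
    def end(self) -> int:
        """Exclusive end coordinate."""
        return self.start + self.length


@dataclass
class ProbeMap:
    """Ordered collection of uniquely mapped probes, sorted by (chrom, start)."""

    probes: list[Probe] = field(default_factory=list)
    genome_id: str = ""

    def __post_init__(self) -> None:
        self.probes = sorted(self.probes, key=lambda p: (p.chrom, p.start))
        seen_ids: set[str] = set()
        seen_pos: set[tuple[str, int, int]] = set()
        for p in self.probes:
            if p.probe_id in seen_ids:
                raise ValueError(f"duplicate probe_id {p.probe_id!r}")
            seen_ids.add(p.probe_id)
            key = (p.chrom, p.start, p.length)
            if key in seen_pos:
                raise ValueError(f"duplicate probe position {key} in ProbeMap")
            seen_pos.add(key)

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return self.probes == other.probes and self.genome_id == other.genome_id

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def by_id(self) -> dict[str, Probe]:
        return {p.probe_id: p for p in self.probes}


@dataclass
class MappingSummary:
    """Disposition of every input probe; retained + excluded partitions the input."""

    n_input: int = 0
    n_retained: int = 0
    n_multi_hit: int = 0
    n_zero_hit: int = 0
    n_unmappable: int = 0  # ambiguous bases

    @property
    def n_excluded(self) -> int:
        return self.n_multi_hit + self.n_zero_hit + self.n_unmappable


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-record, possibly line-wrapped) FASTA into {name: sequence}."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _kmer_index(genome: Mapping[str, str], k: int) -> tuple[Counter, dict[str, list[tuple[str, int]]]]:
    """Count every forward-strand k-mer and remember positions of the rare ones.

    Positions are stored only while a k-mer is still a uniqueness candidate
    (≤ 2 sightings) to keep memory proportional to the genome, not to the
    occurrence multiset.
    """
    counts: Counter = Counter()
    positions: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] += 1
            if counts[kmer] <= 2:
                positions.setdefault(kmer, []).append((chrom, i))
    return counts, positions


def map_probe_sequences(
    probe_seqs: Iterable[tuple[str, str]],
    genome: Mapping[str, str],
    check_reverse_complement: bool = True,
    tile_length: int = DEFAULT_TILE_LENGTH,
    genome_id: str = "",
) -> tuple[ProbeMap, MappingSummary]:
    """Anchor probe sequences on the genome, retaining single-perfect-match probes.

    A probe is retained iff its sequence has exactly one perfect-match
    occurrence in the genome. With ``check_reverse_complement`` (default),
    occurrences on either strand count toward the total; a palindromic
    probe matching both strands at the same position counts once there.
    Probes containing ambiguous bases cannot perfectly match and are
    counted as unmappable.

    Returns the ProbeMap of retained probes (positioned on the forward
    strand) and a summary partitioning the input.
    """
    probe_list = list(probe_seqs)
    genome = {c: s.upper() for c, s in genome.items()}
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("genome is empty")
    for pid, seq in probe_list:
        if len(seq) != tile_length:
            raise ValueError(
                f"probe {pid!r} has length {len(seq)}, expected {tile_length}"
            )

    counts, positions = _kmer_index(genome, tile_length)
    summary = MappingSummary(n_input=len(probe_list))
    retained: list[Probe] = []
    for pid, seq in probe_list:
        seq = seq.upper()
        if not _VALID_BASES.issuperset(seq):
            summary.n_unmappable += 1
            continue
        rc = _revcomp(seq)
        if check_reverse_complement and rc != seq:
            n_occ = counts[seq] + counts[rc]
        else:
            # palindromes: a forward hit and its reverse-complement hit are
            # the same position, counted once
            n_occ = counts[seq]
        if n_occ == 0:
            summary.n_zero_hit += 1
        elif n_occ > 1:
            summary.n_multi_hit += 1
        else:
            if counts[seq] == 1:
                chrom, pos = positions[seq][0]
            else:
                chrom, pos = positions[rc][0]
            retained.append(Probe(pid, chrom, pos, tile_length, sequence=seq))
            summary.n_retained += 1
    return ProbeMap(retained, genome_id=genome_id), summary


_TSV_COLUMNS = ["probe_id", "chrom", "start", "length"]


def write_probe_map(pm: ProbeMap, path: str | Path) -> None:
    """Write the canonical probe-map TSV (0-based starts, header line)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for p in pm:
            fh.write(f"{p.probe_id}\t{p.chrom}\t{p.start}\t{p.length}\n")


def read_probe_map(path: str | Path, genome_id: str = "") -> ProbeMap:
    """Read a probe-map TSV, validating header, integer starts and id uniqueness."""
    probes: list[Probe] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected header {_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_TSV_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            pid, chrom, start_s, length_s = fields
            try:
                start, length = int(start_s), int(length_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer start/length"
                ) from None
            if pid in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate probe_id {pid!r}"
                )
            seen.add(pid)
            probes.append(Probe(pid, chrom, start, length))
    return ProbeMap(probes, genome_id=genome_id)
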