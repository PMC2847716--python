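"""Deletion sharing across accessions at the gene level.

Sharing is defined on gene identity: the same gene reported as deleted in
two or more accessions counts as a shared deletion, matching the
gene-based Venn view of presence/absence variation. Coordinate-level
co-localization of call boundaries is deliberately not assessed.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

AccessionGeneSets = Mapping[str, set]


def _validate(sets: AccessionGeneSets, min_n: int, max_n: int = 6) -> None:
    if not (min_n <= len(sets) <= max_n):
        raise ValueError(
            f"need between {min_n} and {max_n} accessions, got {len(sets)}"
        )


def venn_partition(sets: AccessionGeneSets) -> dict[frozenset, int]:
    """Exclusive region counts for every non-empty accession subset.

    Each gene in the union is assigned to exactly the region of the
    accessions that contain it, so region counts sum to |union|.
    """
    _validate(sets, min_n=2)
    labels = list(sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions[frozenset(combo)] = 0
    union = set().union(*sets.values())
    for gene in union:
        members = frozenset(l for l in labels if gene in sets[l])
        regions[members] += 1
    return regions


def sharing_summary(sets: AccessionGeneSets) -> dict[str, dict]:
    """Per-accession sharing statistics.

    For each accession with a non-empty deleted-gene set:
      - unique_fraction: fraction of its genes found in no other accession
      - in_ge3_fraction: fraction found in at least 3 accessions in total
        (including itself)
      - in_all_count: genes present in every accession's set
    Empty accessions are reported with None fractions.
    """
    _validate(sets, min_n=2)
    labels = list(sets)
    in_all = set.intersection(*[set(s) for s in sets.values()])
    out: dict[str, dict] = {}
    for label in labels:
        genes = sets[label]
        if not genes:
            out[label] = {
                "unique_fraction": None,
                "in_ge3_fraction": None,
                "in_all_count": len(in_all),
            }
            continue
        n = len(genes)
        n_unique = sum(
            1
            for g in genes
            if not any(g in sets[o] for o in labels if o != label)
        )
        n_ge3 = sum(
            1 for g in genes if sum(g in sets[o] for o in labels) >= 3
        )
        out[label] = {
            "unique_fraction": n_unique / n,
            "in_ge3_fraction": n_ge3 / n,
            "in_all_count": len(in_all),
        }
    return out


def write_venn_tsv(regions: dict[frozenset, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accessions\tcount\n")
        for region in sorted(regions, key=lambda r: (len(r), sorted(r))):
            fh.write(f"{'+'.join(sorted(region))}\t{regions[region]}\n")


def format_sharing_summary(summary: dict[str, dict]) -> str:
    lines = ["accession\tunique_fraction\tin_ge3_fraction\tin_all_count"]
    for label, stats in summary.items():
        uf = stats["unique_fraction"]
        gf = stats["in_ge3_fraction"]
        lines.append(
            f"{label}\t{'NA' if uf is None else f'{uf:.3f}'}\t"
            f"{'NA' if gf is None else f'{gf:.3f}'}\t{stats['in_all_count']}"
        )
    return "\n".join(lines)
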