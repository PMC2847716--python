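"""Gene-level impact of deletion calls.

Deletion calls are projected onto gene models (GFF3 mRNA/CDS features):
per gene, the deleted base-pair total and proportion of the gene span,
whether coding sequence is hit, and the gene's biotype (transposable
element vs. protein coding). A chi-square test on the 2x2 table
{deleted, not} x {TE, not} quantifies over-representation of TE genes
among the deleted set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import logging

import gffutils
from scipy.stats import chi2_contingency

from .caller import DeletionCall

log = logging.getLogger(__name__)

TE_BIOTYPE = "transposable_element_gene"
PROTEIN_CODING = "protein_coding"

Interval = tuple[int, int]  # 0-based half-open


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted, non-overlapping list."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intersect_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Total bp shared between two interval sets (each merged first)."""
    a, b = merge_intervals(a), merge_intervals(b)
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class GeneModel:
    """One gene: mRNA span (union over isoforms), CDS union, biotype."""

    gene_id: str
    chrom: str
    strand: str
    mrna_span: Interval
    cds_intervals: list[Interval] = field(default_factory=list)
    biotype: str = PROTEIN_CODING

    @property
    def length(self) -> int:
        return self.mrna_span[1] - self.mrna_span[0]

    @property
    def is_te(self) -> bool:
        return self.biotype == TE_BIOTYPE


@dataclass
class GeneDeletionReport:
    """Per-gene deletion summary for one accession."""

    gene_id: str
    accession: str
    biotype: str
    deleted_bp: int
    deleted_fraction: float
    cds_hit: bool


def load_gff(
    path: str | Path,
    biotype_attribute: str = "biotype",
) -> list[GeneModel]:
    """Parse GFF3 gene models into 0-based half-open GeneModels.

    The gene span is the union of the gene's mRNA features (falling back
    to the gene feature itself when no mRNA child exists); CDS intervals
    are unioned over isoforms. A gene is classed as a transposable-element
    gene when its feature type is ``transposable_element_gene`` or its
    ``biotype_attribute`` says so. CDS features without a resolvable gene
    parent are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    gene_types = [
        t for t in ("gene", TE_BIOTYPE, "pseudogene") if t in set(db.featuretypes())
    ]
    n_orphan_cds = 0
    for gtype in gene_types:
        for g in db.features_of_type(gtype, order_by=("seqid", "start")):
            mrna_ivs: list[Interval] = []
            cds_ivs: list[Interval] = []
            for m in db.children(g, featuretype="mRNA"):
                mrna_ivs.append((m.start - 1, m.end))
            for c in db.children(g, featuretype="CDS"):
                cds_ivs.append((c.start - 1, c.end))
            if not mrna_ivs:
                mrna_ivs = [(g.start - 1, g.end)]
            merged_mrna = merge_intervals(mrna_ivs)
            span = (merged_mrna[0][0], merged_mrna[-1][1])
            if gtype == TE_BIOTYPE:
                biotype = TE_BIOTYPE
            else:
                biotype = g.attributes.get(biotype_attribute, [PROTEIN_CODING])[0]
            genes.append(
                GeneModel(
                    gene_id=g.id,
                    chrom=g.seqid,
                    strand=g.strand,
                    mrna_span=span,
                    cds_intervals=merge_intervals(cds_ivs),
                    biotype=biotype,
                )
            )
    # orphan CDS: no ancestor resolves to a known gene
    known = {g.gene_id for g in genes}
    if "CDS" in set(db.featuretypes()):
        for c in db.features_of_type("CDS"):
            ancestors = {p.id for p in db.parents(c)}
            if not (ancestors & known):
                n_orphan_cds += 1
    if n_orphan_cds:
        log.warning("skipped %d CDS features without a resolvable gene parent",
                    n_orphan_cds)
    genes.sort(key=lambda g: (g.chrom, g.mrna_span[0]))
    return genes


def genes_with_deletions(
    calls: Sequence[DeletionCall],
    genes: Sequence[GeneModel],
    accession: str = "",
    min_deleted_bp: int = 100,
    require_overlap_bp: int = 1,
) -> list[GeneDeletionReport]:
    """Report genes whose span overlaps merged deletion calls.

    ``deleted_bp`` is the length of the intersection between the gene's
    mRNA span and the union of calls on its chromosome. A gene is
    reported when either the intersection reaches ``min_deleted_bp`` or
    some single overlapping call spans at least ``min_deleted_bp`` and the
    overlap reaches ``require_overlap_bp`` — a gene clipped by the edge of
    a long deletion is still affected. ``cds_hit`` is true when any call
    overlaps any CDS interval by at least 1 bp.
    """
    calls_by_chrom: dict[str, list[Interval]] = {}
    for c in calls:
        calls_by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    reports: list[GeneDeletionReport] = []
    for gene in genes:
        chrom_calls = calls_by_chrom.get(gene.chrom, [])
        if not chrom_calls:
            continue
        deleted_bp = intersect_length([gene.mrna_span], chrom_calls)
        if deleted_bp == 0:
            continue
        long_call_overlap = any(
            e - s >= min_deleted_bp
            and intersect_length([gene.mrna_span], [(s, e)]) >= require_overlap_bp
            for s, e in chrom_calls
        )
        if deleted_bp < min_deleted_bp and not long_call_overlap:
            continue
        cds_hit = intersect_length(gene.cds_intervals, chrom_calls) > 0
        reports.append(
            GeneDeletionReport(
                gene_id=gene.gene_id,
                accession=accession,
                biotype=gene.biotype,
                deleted_bp=deleted_bp,
                deleted_fraction=deleted_bp / gene.length,
                cds_hit=cds_hit,
            )
        )
    return reports


def write_gene_reports(
    reports: Iterable[GeneDeletionReport], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\taccession\tbiotype\tdeleted_bp\tdeleted_fraction\tcds_hit\n")
        for r in reports:
            fh.write(
                f"{r.gene_id}\t{r.accession}\t{r.biotype}\t{r.deleted_bp}\t"
                f"{r.deleted_fraction:.4f}\t{int(r.cds_hit)}\n"
            )


def read_gene_reports(path: str | Path) -> list[GeneDeletionReport]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "accession": str})
    return [
        GeneDeletionReport(
            gene_id=row.gene_id,
            accession=str(row.accession),
            biotype=row.biotype,
            deleted_bp=int(row.deleted_bp),
            deleted_fraction=float(row.deleted_fraction),
            cds_hit=bool(row.cds_hit),
        )
        for row in df.itertuples()
    ]


def biotype_enrichment(
    reports: Sequence[GeneDeletionReport],
    all_genes: Sequence[GeneModel],
    continuity_correction: bool = False,
) -> dict[str, float]:
    """TE over-representation among deleted genes.

    fold = (TE fraction among deleted genes) / (TE fraction among all
    genes); the chi-square statistic comes from the 2x2 table
    {deleted, not deleted} x {TE, non-TE} with 1 df, without Yates
    continuity correction unless requested.
    """
    if not reports:
        raise ValueError("empty report set: no deleted genes to test")
    deleted_ids = {r.gene_id for r in reports}
    n_genes = len(all_genes)
    n_te = sum(g.is_te for g in all_genes)
    obs_te = sum(g.is_te for g in all_genes if g.gene_id in deleted_ids)
    n_del = len(deleted_ids)
    te_frac_all = n_te / n_genes
    te_frac_del = obs_te / n_del
    fold = te_frac_del / te_frac_all if te_frac_all > 0 else float("nan")
    table = [
        [obs_te, n_del - obs_te],
        [n_te - obs_te, (n_genes - n_del) - (n_te - obs_te)],
    ]
    chi2, p, _, _ = chi2_contingency(table, correction=continuity_correction)
    return {
        "observed_te": float(obs_te),
        "expected_te": te_frac_all * n_del,
        "fold": float(fold),
        "chi2_statistic": float(chi2),
        "p_value": float(p),
    }
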