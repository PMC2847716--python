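# Methods

## The model

`tilecall` infers deletions in a divergent strain relative to a reference
genome from two independent observations per 25 bp tile:

* the **array signal ratio** *r* = log₂(mean test intensity / mean
  reference intensity), computed after quantile-normalizing the two test
  and two reference hybridizations together, and
* the **mean short-read depth** over the tile's genomic interval.

A tile supports a deletion when *r* < θ (strictly) **and** every base of
the tile has depth 0. Supporting tiles are chained greedily left-to-right;
a tile extends the chain when the gap between the previous tile's end and
its own start is at most `max_gap`. Maximal chains whose total span
(last end − first start) reaches `min_span` are reported as deletion
calls. Neither criterion is reliable alone: zero coverage also arises at
polymorphism hotspots where reads fail to map, and low signal ratios arise
from hybridization noise; their intersection is the method's specificity
mechanism.

The underlying assumptions: probes report only their single perfect-match
locus (enforced by the uniqueness filter, counting both strands by
default); a deleted target drops the probe to the array's background
level; read depth within a deletion is exactly zero (reads are mapped to
the reference, so a deleted locus can attract none); and breakpoints are
not resolvable below tile granularity, so call boundaries are the first
and last supporting tile — accurate to about one tile plus one gap
(35 bp on the canonical 25 + 10 bp grid) per side.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ratio_threshold` | −1.0 (log₂) | strict upper bound on the signal ratio; −1.5 for a stringent screen |
| `max_gap` | 39 bp | maximum inter-tile gap inside a chain; tolerates the array's typical 10 bp spacing but not a missing tile |
| `min_span` | 100 bp | minimum chain span; 300 bp selects only major deletions |
| `min_deleted_bp` | 100 bp | gene-report threshold; a gene clipped by <100 bp of a ≥100 bp call is still reported (flag `--require-overlap-bp` tightens this) |

Lowering `ratio_threshold` or raising `min_span` can only remove calls
(tested monotonicity). The threshold comparison is strict (`<`), so a tile
at exactly −1.0 is not flagged. On the default grid a deletion must be
≥130 bp for four fully-contained tiles (span 130 ≥ 100) to be guaranteed;
deletions of 100–129 bp are structurally uncallable at `min_span` 100.

## Quantile normalization

All four arrays of an accession are normalized in one pass: each column's
values are replaced by the across-column mean of the order statistics at
the same rank. Ties within a column receive the mean of the quantiles
spanned by their tied ranks (the behavior of `limma::normalizeQuantiles`
with `ties=TRUE`, against which the implementation is cross-checked).
Consequences worth knowing:

* The output columns share one sorted multiset exactly when no column has
  internal ties; ties perturb the multiset by less than the local
  quantile gap.
* Normalizing test and reference together makes the transform
  deletion-aware in an undesirable but unavoidable way: the deleted mass
  occupies the bottom ranks of the test columns, so the common
  distribution's low quantiles are pulled up by the intact reference
  columns. Deleted-tile ratios are therefore compressed toward the
  threshold, and intact-tile ratios shift slightly positive, in
  proportion to the deleted fraction of the genome. With a few percent
  of tiles deleted (the realistic regime) the intact median stays within
  ±0.1 of zero; at ~10% deleted it can shift by ~+0.2. The calling
  threshold is unaffected in practice because deleted tiles still sit
  2–3 log₂ units below intact ones.

## The synthetic benchmark generator

`tilecall.simulate` emulates the input ecosystem end to end. Defaults are
the benchmark's study conditions; all draws flow from one `numpy`
generator seeded by `SimConfig.seed`, and identical configs produce
byte-identical files.

* **Genome and annotation**: uniform-random nucleotide sequence
  (default 500 kb over 2 chromosomes); genes of 2 kb separated by 1 kb
  intergenic spacers, ~12% annotated as transposable-element genes
  (matching the TE share of a plant gene complement); CDS is the gene
  span minus 200 bp margins.
* **Tiles**: 25 bp probes every 35 bp (10 bp gaps), written as the
  probe-map TSV the pipeline consumes.
* **Deletions**: 50 per accession, lengths uniform on 100–5,000 bp
  (clipped to the host gene for gene-targeted placements), at least
  200 bp apart so two planted deletions can never merge under the 39 bp
  gap rule; half are shared by all accessions, the rest are private; 80%
  are placed inside genes. The TE bias parameter (default 4) is the
  target fold over-representation of TE genes among deleted genes: a TE
  gene is chosen as host with probability `bias × te_fraction`, so the
  measured fold recovers the bias in expectation. (Interpreting the bias
  as a raw per-gene rate ratio would saturate the observable fold at
  `bias / (1 + (bias−1)·te_fraction)` ≈ 2.9 — the fraction-among-deleted,
  not the rate, is what the enrichment statistic measures.)
* **Coverage**: per-base negative binomial (mean 10, dispersion 5) —
  deliberately over-dispersed relative to Poisson, since real short-read
  coverage follows neither Poisson nor gamma — zeroed over deletions and,
  with probability 1 per hotspot, over SNP hotspots.
* **Intensities**: log₂-normal. Each probe carries a sequence-affinity
  offset (sd 2.0 log₂) common to *all* arrays — a dim probe is dim
  everywhere — which reproduces the several-log₂-unit marginal intensity
  spread of real tiling arrays and is what keeps deleted-tile ratios well
  separated after joint quantile normalization. On top of that, each
  array adds independent replicate noise (sd 0.25 log₂). Test-array
  means slide from foreground (2¹⁰) to background (2⁷) in proportion to
  the tile's deleted fraction; hotspot overlap adds a mild −0.21 log₂
  attenuation, the average ratio depression measured over heavily
  polymorphic (5–10 SNPs / 25 bp) but present sequence.
* **Hotspots**: Poisson-placed (default 2×10⁻⁵ per bp), 50–200 bp long,
  kept ≥100 bp from planted deletions.

What the generator does **not** emulate: real probe GC/sequence effects
(affinity is i.i.d. normal), spatial array artifacts, mappability
structure, organelle contamination, segmental duplications, or read-level
errors. Passing benchmarks therefore demonstrate the intersection logic
and its noise rejection, not performance on any particular array design
or read mapper.

A known, quantified limitation that the benchmark *does* expose: probes
whose intact signal is indistinguishable from the array floor
(affinity ≲ −5 sd, ~0.3% of tiles) cannot report a deletion. Each such
"blind" tile inside a deletion breaks the chain (one missing tile creates
a 45 bp gap > 39 bp), splitting the call. This is the dominant cause of
boundary errors > 64 bp and of sub-threshold call fragments in the
benchmark, and mirrors the behavior expected on real arrays.

## Scoring

`score_calls` matches calls to planted deletions by interval Jaccard
(default ≥ 0.5) for **recall**; for **precision** a call counts as a true
positive when the planted intervals cover at least that fraction of the
*call's own* span — a fragment lying wholly inside a larger true deletion
claims no false sequence and is not a false positive, even though its
Jaccard against the full truth interval is small. Boundary error is the
larger endpoint offset of the best matching call.

## Benchmark problem sizes

The shipped acceptance checks use: 4 accessions × 50 deletions on 500 kb
(recovery); 20 single-accession 200 kb replicates with hotspots only
(false-positive rejection); and one 3 Mb, ~1,000-gene accession with 240
gene-targeted deletions under a 4× TE bias (enrichment recovery; ~225
deleted genes). These sizes give stable statistics (binomial sd ≲ 2
percentage points on the recovery rates) at desk-scale runtimes.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere internally; GFF3's
  1-based inclusive convention is converted at the I/O boundary.
* Intensities must be strictly positive and finite; zeros are an input
  error, not floored.
* Quantile normalization is idempotent to 1e-9 and order-preserving
  within columns; fractional (tied) ranks interpolate linearly between
  adjacent reference quantiles.
* A probe absent from either evidence track is invisible to chaining: it
  neither extends nor breaks a chain except through the inter-tile
  distance it leaves (the gap rule handles holes uniformly).
* Empty chains, empty call sets and header-only TSVs are valid inputs
  downstream; an accession with no deleted genes is reported with
  missing (None/NA) sharing fractions rather than NaNs.
* The χ² enrichment test uses 1 df without Yates continuity correction
  by default (counts in the hundreds); a flag enables the correction.
* Deletion placement raises a `PackingError` before writing any file
  when the requested deletions cannot fit (more gene targets than genes,
  or repeated placement failure under the separation constraint).
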