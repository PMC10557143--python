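# Methods

## Coordinate and overlap conventions

All coordinates are 0-based half-open (BED convention) everywhere in the
package.  The overlap primitive is record-level with a 1 bp minimum:
interval *a* overlaps interval *b* iff they share a chromosome and
`a.start < b.end and b.start < a.end`.  Abutting intervals do not overlap;
zero-length intervals are rejected at construction rather than handled
specially in queries.  `intersect_report_a(A, B)` reports each record of
A at most once, in A's input order, iff it overlaps at least one record of
B — the semantics of `bedtools intersect -wa -u` with its default minimum
overlap.  Duplicate identical records in A are independent records and are
reported independently; peak sets are never deduplicated, and this is a
documented choice rather than an oversight (public IDR-thresholded peak
sets are already non-redundant, and deduplication would silently change
the denominator of the screen statistic).

Interval queries are served by per-chromosome interval trees (the
`intervaltree` library); the test suite checks the tree-backed engine
against an independent all-pairs brute-force scan on large batches of
random instances.

Chromosome names are matched as exact strings.  There is no silent
"chr"-prefix normalization — aliasing would produce false zero overlaps —
but the `validate` command flags disjoint chromosome-name sets between
input files and specifically calls out likely prefix mismatches.

## The screen

For each protein the overlap percentage against a structure set is
`100 * n_overlap / n_peaks`, computed with exact rational arithmetic
(`fractions.Fraction`) before the final float conversion, so planted
integer counts map to exact percentages.  Three-way co-occupancy counts
(R-loop, G4, both) are derived from two independent record-level
memberships.  Proteins with zero peaks are skipped and recorded — the
statistic is undefined for them and is never imputed.

The cross-protein correlation is the Pearson product-moment `r` of the
(pct_G4, pct_R-loop) pairs, computed via `scipy.stats.pearsonr` and
declared undefined (never NaN) below 3 records or at zero variance.
Candidate ranking filters proteins with both percentages above a threshold
and orders them by `min(pct_rloop, pct_g4)` descending, ties broken by
name.  The ranking statistic is a package choice — any scalar summary of
"high against both" would serve — and the threshold is exposed
(`--min-pct`).

## Promoter windows and classification

A promoter window is `[tx_start - upstream, tx_start + downstream)` for a
+ strand gene and `[tx_end - downstream, tx_end + upstream)` for a −
strand gene, clipped to chromosome bounds.  The default −1000/+500 bp is
a common convention; published promoter-localization fractions depend
heavily on the window definition and annotation build, which are often
unstated, so the default is explicitly configurable and reported fractions
should always be read together with the window used.  Classification
precedence is promoter > genic > intergenic; membership is existential
(≥ 1 bp of the full peak span, or the summit point with `--by-summit`),
so overlapping windows from different genes are kept unmerged — merging
cannot change any label, and unmerged windows keep gene attribution.

## Profiles

Bin values are always **length-weighted means** of the coverage step
function, never sums.  This makes a constant track produce an exactly
constant profile at any bin size and makes every profile linear in the
track.  Aggregation profiles tile `[center − window, center + window)`
with equal bins (defaults 2,000 bp / 50 bp, the conventions of the usual
profiling tools); anchors whose window would cross a chromosome end are
dropped entirely and counted, never zero-padded, which would bias the mean
toward zero at the edges.

Metagene profiles use fixed-length flanks (2,000 bp in 50 bp bins) and a
gene body scaled to 100 equal slices.  Slice boundaries are exact
rationals (`fractions.Fraction`) and per-bin integrals are accumulated
with `math.fsum`, so the computation is invariant under coordinate
reflection: a gene and its mirror image on a mirrored track produce
bitwise-identical curves, which the tests assert literally.  − strand
genes are traversed 3'→5' in genomic coordinates and reversed, putting
every gene on a TSS→TES axis.  Genes shorter than the number of body bins
or with out-of-bounds flanks are dropped and counted.

Region density is `(Σ signal over region) / (length in kb) /
(total_signal / 1e6)` — a signal-domain analogue of the usual read-count
density.  RPKM binning counts reads overlapping each fixed genomic bin and
normalizes by bin length (a truncated final bin uses its actual length)
and by total read count.

## Exclusion ratios

`exclusion / (inclusion + exclusion)` per event and replicate; a 0/0 ratio
is reported as missing, never as 0.  Replicate ratios are averaged per
condition (ratio-of-each-replicate, matching per-lane gel quantification,
not pooled counts) with SEM = sd(ddof=1)/√n; a single replicate has a
missing SEM, and identical replicates are reported with exactly zero SEM.
The ratio is scale-invariant, so upstream normalization of band
intensities does not affect it.  Group-comparison testing is deliberately
out of scope: the table emits means ± SEM, to which any standard test can
be applied externally.

## The synthetic generator

The generator emulates the structure of a real screen's inputs — many TF
peak sets with heterogeneous, mutually correlated overlap fractions
against two promoter-enriched structure peak sets, plus coverage tracks
with bumps at peak centers and promoter/body plateaus — under fixed
default conditions: 2 × 5 Mb chromosomes; 500 non-overlapping genes of
4–8 kb (≥ 2.5 kb apart, ≥ 6 kb from chromosome ends so no anchor or flank
is ever dropped); 1,000 structure peaks per set with discretized lognormal
widths (median 300 bp, a plausible peak scale); 70% of structure peaks in
promoter windows; 50% of G4 peaks centered inside an R-loop peak; 50
proteins × 500 peaks with per-protein R-loop fraction `U(0.05, 0.9)` and
G4 fraction `clamp(0.8·f_R + 0.05 + N(0, 0.05))`; Gaussian signal bumps of
amplitude 10 and σ = 150 bp on background 2 with truncated-normal noise
(sd 1, clipped at 0); RNAPII-like plateaus at 3 (promoter) vs 1 (body).

Three design choices make the ledger *exact* rather than statistical:

1. **Exact-count planting.**  Overlap structure is planted as
   `round(n · f)` memberships, not per-peak Bernoulli draws, so the
   screen's planted counts carry no sampling error.
2. **Exclusion masks.**  Placement works on a four-way segment
   decomposition of the genome (R∩G4, R-only, G4-only, neither; promoter
   windows handled analogously), and every "background" peak is placed
   fully inside a segment of the complement — it cannot accidentally
   overlap a structure or promoter.  The R-loop set's promoter fraction is
   therefore exactly the planted value; the G4 set's is approximate (its
   co-occurring peaks inherit the R-loop set's promoter enrichment), and
   the ledger records the realized value.
3. **Self-verification.**  Before returning, the generator re-derives
   every planted count from the finished peak sets with the package's own
   interval engine and raises on any mismatch.

The plateau track is emitted as an exact step function cut at region
boundaries (not rasterized), so planted promoter:body ratios are exact.
The bump track is discretized to 50 bp bins (bump value at the bin
midpoint); its ground truth is the noiseless track, and the ledger stores
the aggregation curve of that noiseless track over the same anchors, so
recovery is checked against exactly what was planted even when anchor
windows overlap neighboring bumps.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequence content and motif structure, read-level
noise and mappability artifacts, peak-width/signal correlation,
within-set peak non-overlap, chromatin-state heterogeneity, and any
biological correlation structure beyond the single planted linear
relation.  Recovery results on this generator validate the *computations*,
not the biology.

One `numpy.random.Generator` seeded from a single integer drives every
draw in a fixed order, and all file formatting is deterministic, so one
seed fixes every byte of every emitted file; the end-to-end tests assert
byte-identity of repeated runs.

## Numerical choices

- Percentages and fractions that are ratios of integers go through exact
  rational arithmetic before the final float.
- Metagene arithmetic uses rational bin edges and exactly rounded sums
  (`fsum`) as described above; aggregation uses vectorized cumulative
  integrals of the step function (float64 throughout).
- Peak center is the summit when defined, else the floor midpoint
  `⌊(start+end)/2⌋` (explicit tie-break for odd lengths).
- `round(n·f)` uses Python's banker's rounding; with the default
  conditions no planted quantity sits on a .5 boundary by construction,
  and any rounding choice would remain self-consistent between ledger and
  pipeline.
- Problem sizes in tests and the acceptance script (1,000 oracle
  instances, 50 × 500 screens, 200–1,000 anchors, 500 genes) were chosen
  as the package's default study conditions — large enough that sampling
  tolerances (e.g. 3·sd/√n for profile recovery, 10% for plateau-ratio
  recovery) are comfortably informative.

## Known limitations

- The CLI reads whole files into memory; it is sized for peak sets and
  binned tracks (up to a few hundred thousand records), not for
  base-resolution whole-genome coverage of large genomes.
- bigWig input is not supported; convert to bedGraph first.
- Overlap significance testing (permutation/shuffling null models) is out
  of scope: the screen reports descriptive percentages and their
  correlation only.
- Peak calling, read alignment and visualization are upstream/downstream
  of this package and intentionally absent.
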