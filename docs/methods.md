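# Methods

This note records the exact conventions the package implements, the choices
made where the standard definitions are ambiguous, what the synthetic
generator does and does not emulate, and the known limitations.

## Taxonomy model

The evaluation iterates over eight major ranks, by default

```
superkingdom, kingdom, phylum, class, order, family, genus, species
```

ordered most general first. The list is configurable
(`TaxonomyDB.major_ranks`), but its length fixes the geometry of the
weighted UniFrac metric: with unit branch lengths and the tree root joining
the superkingdoms, a fully annotated species sits 8 edges below the root,
so the worst case — all mass in one species versus all mass in a species
under a different superkingdom — is exactly 16. Sub-species nodes (rank
`strain`, `no rank`, …) are never metric keys; they are only reached
through `project_to_rank`, which walks the parent chain to the first node
at the requested rank and returns none when a lineage lacks that rank.

Merged-taxon tables (`merged.dmp`) are resolved before any lookup, with
chains of merges followed. Taxon IDs present in neither table are, by
default, dropped from predictions with a logged warning; `strict=True`
turns this into an error. Real NCBI lineages frequently lack intermediate
ranks (most bacteria have no `kingdom` node); projection simply skips such
ranks, which shortens UniFrac paths accordingly — a property of the
taxonomy, not of the implementation.

## Genome binning

All counts are base pairs, taken from the gold standard's sequence lengths;
the evaluator never touches sequence data. Each bin maps to its most
abundant genome (ties broken by lexicographic genome ID — purity is
tie-invariant, completeness bookkeeping is not, so the tie-break is fixed
for determinism). Average completeness divides by |B| + |X| where X is the
set of gold genomes that are the majority genome of no bin; a bin's
completeness denominator is the genome's *total* gold size, including
unbinned base pairs. The F1 column is the harmonic mean of average purity
and average completeness (not the average of per-bin F1 scores).

The ARI uses the pair-counting closed form on the bp-weighted contingency
restricted to assigned sequences. Values near zero may be slightly
negative and are reported as computed. Two caveats are inherent to the
bp-weighted formulation: it must be read together with the binned fraction
(an evaluator scoring only 1 % of the data can still have ARI 1), and when
bins contain few, heavily size-skewed contigs the chance-level ARI is
biased upward because contigs are atomic — base pairs of one contig can
never be split across bins, which the chance correction does not model.

Quality-tier counting uses strict inequalities (completeness strictly
above, contamination = 1 − purity strictly below the thresholds), with the
conventional tiers (0.5, 0.10) for "moderate or higher" and (0.9, 0.05)
for high quality.

## Taxonomic binning

Gold and predicted labels are both projected to the evaluation rank.
Sequences whose *gold* lineage has no node at the rank are excluded from
the gold set GS and from the accuracy denominator n (otherwise an accuracy
of 1 would be unreachable); predictions that do not project contribute no
bin. A prediction is a true positive for its projected taxon when the
sequence's projected gold taxon matches, otherwise the base pairs count as
false positives of that bin — including sequences with no gold annotation
at the rank. Unfiltered average purity therefore includes predicted taxa
absent from the sample, which is exactly why the unfiltered purity of real
submissions tends to be low and why the small-bin filter exists.

The 1 % filter sorts predicted bins by increasing size — size is defined as
the *predicted* bp in the bin (TP + FP), the only size known before truth
matching — and removes bins while the cumulative size stays ≤ 1 % of the
summed size of all bins. GS and n are left untouched, so filtered
completeness and accuracy can only decrease (asserted as a property test);
filtered purity usually increases. On the worked sizes [1, 1, 98] exactly
the first bin is removed (cumulative 1 ≤ 1, then 2 > 1).

## Taxonomic profiling

Abundances are fractions in [0, 1] everywhere inside the package; the
0–100 percentage scale of the exchange format exists only at I/O
boundaries. L1 and Bray–Curtis run over the union of taxa at a rank, so
taxa absent from one profile contribute their full abundance — this is
what makes the documented upper bounds (2 and 1) attainable, and makes
Bray–Curtis equal to L1/2 exactly when both profiles sum to 1.

The Shannon equitability index is implemented in its standard non-negative
form, (−Σ x ln x)/ln m over the m taxa with positive abundance, defined as
0 for m = 1 and compared between prediction and gold as an absolute
difference.

Weighted UniFrac is the earth-mover's distance between the two profiles'
mass distributions on the taxonomic tree with unit branch lengths. On a
tree the EMD has a closed form — for every edge, the absolute net mass
imbalance of the subtree below it — computed here in one bottom-up pass
and verified in the tests against a linear-programming transport oracle.
Mass placement: each profile's mass sits at its most specific annotated
taxon. Profiles typically repeat a lineage's abundance at every rank, so
for every entry the mass already explained by more specific entries
beneath it is subtracted and only the residual stays at that node;
duplicating the full mass at all eight ranks would change the metric's
scale. Taxa that do not resolve in the taxonomy are dropped from UniFrac
with re-normalization (toggleable via `renormalize=False`) and a warning,
while the ID-based presence metrics keep them as false positives.

## Assembly

Strain thresholds use strict inequalities. The mismatch cap accepts either
mismatches per 100 kb or a percentage of aligned bases (0.5 % ≡ 500 per
100 kb). Two named presets ship: `marine` (genome fraction > 90 %,
mismatches < 0.5 %) and `strain-madness` (> 75 %, < 0.5 %). The marine
mismatch cap is a package default chosen for symmetry with the
strain-madness preset, not an externally fixed constant; both presets are
overridable. Genomes absent from a report count as unrecovered for recall;
strain precision is *undefined* (not 0) when no assembly clears the
genome-fraction threshold. Cross-genome NGA50 averaging substitutes 0 for
genomes below 50 % genome fraction or with undefined NGA50 before taking
the mean; other columns average over the genomes where they are defined.
Per-partition columns (e.g. unique/common strains) are produced when a
genome → partition map is supplied; computing the partition (an ANI
question) is out of scope.

## Ranking

Metric values are averaged over a dataset's samples first and ranked
second (average-then-rank); undefined per-sample values are excluded from
the mean. Tools are scored per metric — and per taxonomic rank for
rank-resolved metrics, summing the per-rank scores — with 0 for first
place and ties sharing the better (minimum) score, which makes the totals
independent of processing order. A tool missing a metric entirely receives
the worst score (n − 1) rather than being excluded, keeping totals
comparable; this is logged. Optional per-metric weights (default 1) scale
each metric's contribution.

## Synthetic communities and the error model

`CommunitySpec` defaults describe a small but structurally faithful
benchmark: log-normal genome abundances (σ = 2, the long-tailed shape
typical of simulated communities), 20 contigs per genome with log-normal
lengths of ~5 kb and a 500 bp minimum — so bp-weighted and
sequence-counted results genuinely differ and count-versus-bp bugs
surface — and full 8-rank lineages with at least two lineages alive at
every rank. `n_common_pairs` genome pairs share a species node, the
bookkeeping analogue of closely related strains. Gold profiles are the
bp-weighted genome shares projected to every rank, so they sum to 1 per
rank by construction. One integer seed drives a named substream per
generator, making all fixtures reproducible.

The corruption operators model tool error minimally but not uniformly
randomly:

- `corrupt_binning` leaves each sequence unassigned with one rate and
  otherwise reassigns it to a uniformly chosen wrong bin with another;
  both rates at 0 reproduce the gold standard exactly.
- `corrupt_profile` resamples abundances from a Dirichlet centered on the
  gold proportions (concentration → ∞ disables the noise), then drops or
  relabels taxa. Both failure probabilities scale with taxon rarity
  (rate × (1 − x_t)): detection and classification failures hit taxa with
  little evidence, not the dominant community members — under uniform
  per-taxon failure a single drop of the head of the long-tailed abundance
  distribution dominates every abundance metric, which no real profiler
  exhibits. Relabeling moves mass to a sibling species under the same
  genus where one exists (species-level confusion leaves higher ranks
  intact), falling back to a random species.
- `generate_assembly_report` draws per-genome genome fraction and mismatch
  rates from a pluggable quality generator; `assembly_quality_level(i)`
  provides coherent quality tiers in which genome fraction falls while
  mismatches, misassemblies and duplication rise together.

What the generator does **not** emulate: sequence content and read error
profiles, assembly fragmentation structure, chimeric contigs, reference-
database incompleteness, or ANI-based strain relationships beyond the
shared-species bookkeeping. Tests passing on these fixtures demonstrate
that the *metrics and their aggregation* behave correctly, not that any
particular tool performs well on real data.

## Statistical test conditions

The ordering-recovery check (four synthetic tools at strictly increasing
corruption, ranked by the summary statistic) runs on a 40-genome,
10-sample community with metrics averaged over samples before ranking,
mirroring the multi-sample protocol of real benchmarks; recovery of a
known quality ordering is a statistical property and needs enough taxa and
samples that rates, not single random drop events, dominate the metric
differences. Monte-Carlo expectations (ARI under full mis-binning, binned
fraction under dropout, L1 versus Dirichlet concentration) use ≥ 20 seeds
each. The chance-level ARI check uses a fine-grained community (80
contigs per genome, σ = 0.3) because of the atomic-contig bias described
above.

## Numerical choices and degenerate inputs

- Profile rank sums are validated to 1 + 1e−6; UniFrac mass assignments are
  normalized to 1 and residual masses below 1e−12 are treated as zero.
- ARI requires ≥ 2 binned bp; the degenerate case where both partitions
  are single clusters returns 1 (the partitions agree).
- Empty bins, empty gold sets at a rank, zero-mass profiles and a missing
  high-genome-fraction set all raise `UndefinedMetricError` rather than
  returning a sentinel; `run_evaluation` records such values as missing,
  and the ranking assigns the worst score.
- Duplicate sequence rows keep the first occurrence (logged); unassigned
  sequences are absent from the assignment map, never a sentinel bin.
- Readers round-trip their writers' output up to row order and ≥ 6
  significant digits of float formatting.

## Known limitations

- The evaluator is alignment-free: assembly metrics are consumed from
  per-genome report tables, not recomputed from sequences.
- Unweighted UniFrac, rarefaction and ordination analyses are out of
  scope, as are BIOM I/O and read-level formats.
- Taxonomies are inputs; no version pinning or downloading is provided.
- The bp-weighted ARI inherits the atomic-contig bias discussed above;
  comparisons across datasets with very different contig size
  distributions should lean on the other metrics as well.
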