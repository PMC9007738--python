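# metaeval

Benchmark metrics for metagenome interpretation tools: score metagenome
**assembly**, **genome binning**, **taxonomic binning** and **taxonomic
profiling** submissions against gold standards, and aggregate the results
into an overall per-tool ranking. A synthetic fixture generator produces
complete toy benchmarks (taxonomy dumps, gold standards, corrupted
submissions), so every metric is testable without external data.

It is written for method developers and benchmark organizers who need the
community-standard evaluation conventions as a tested, scriptable library
rather than a pipeline: bioboxes-format I/O, base-pair-weighted scoring, and
the exact per-metric definitions used in collaborative benchmarking
challenges.

## Metrics

**Genome binning** is scored on a bp-weighted genome × bin contingency
table. For each predicted bin *b* with majority genome *g*:

- purity_b = TP_b / (TP_b + FP_b), where TP_b is the bp of *g* inside *b*;
- completeness_b = TP_b / (size of *g*), and the average completeness
  divides the summed per-bin completeness by |B| + |X|, with *X* the gold
  genomes that are the majority genome of no bin;
- the **adjusted Rand index** (ARI) over the binned base pairs only, via the
  standard pair-counting closed form, reported together with the binned bp
  fraction;
- counts of bins above quality tiers (moderate: >50 % completeness,
  <10 % contamination; high: >90 %, <5 %).

**Taxonomic binning** computes purity, completeness (denominator |GS|, the
gold taxa at the rank) and accuracy (Σ TP_b / n) at each of the eight major
ranks, plus the same metrics after removing the smallest predicted bins
whose cumulative size is ≤ 1 % of all binned bp.

**Taxonomic profiling** scores presence/absence (purity, completeness, F1
over detected taxa), abundance error (L1 norm ∈ [0, 2], Bray–Curtis
∈ [0, 1]), alpha-diversity error (Shannon equitability,
(−Σ x ln x)/ln m ∈ [0, 1]) and the rank-independent **weighted UniFrac
error**: the earth-mover's distance between the two profiles' masses placed
on the taxonomic tree with unit branch lengths, range 0–16 (eight ranks up
plus eight down in the worst case).

**Assembly** summaries consume per-genome report tables (genome fraction,
mismatches/100 kb, NGA50 with the 0-substitution below 50 % genome
fraction, misassemblies, duplication) and add **strain recall** (fraction of
ground-truth genomes assembled with genome fraction > threshold and
mismatches < threshold) and **strain precision** (low-mismatch share among
high-genome-fraction assemblies).

**Ranking**: metric values are averaged over a dataset's samples, tools are
scored 0 (best) to n−1 per metric — per taxonomic rank for rank-resolved
metrics, with ties sharing the better score — and the summed placement
score is the overall summary statistic (lower is better).

## Worked example

Generate a toy benchmark (8 genomes, 2 samples, 3 submissions at increasing
corruption) and score the genome binnings:

```bash
metaeval fixtures --out-dir demo --seed 42 --n-genomes 8 --n-samples 2
metaeval genome-binning \
  --gold demo/gold/sample_0.tsv --gold demo/gold/sample_1.tsv \
  --pred tool_0=demo/submissions/tool_0/sample_0.genome_binning.tsv \
  --pred tool_0=demo/submissions/tool_0/sample_1.genome_binning.tsv \
  --pred tool_1=demo/submissions/tool_1/sample_0.genome_binning.tsv \
  --pred tool_1=demo/submissions/tool_1/sample_1.genome_binning.tsv \
  --pred tool_2=demo/submissions/tool_2/sample_0.genome_binning.tsv \
  --pred tool_2=demo/submissions/tool_2/sample_1.genome_binning.tsv \
  --out-dir demo/eval
```

prints

```
overall ranking (lower is better):
  tool_0        0
  tool_1        7
  tool_2        14
tables written to demo/eval
```

`tool_0` is the uncorrupted submission: it places first (score 0) in every
metric. `demo/eval/per_tool_metrics.tsv` holds the sample-averaged values —
for instance the ARI column reads 1.0, 0.781 and 0.507 for the three tools,
showing the bp-weighted partition agreement decaying with the mis-binning
rate, while `ranking_scores.tsv` lists the per-metric placements that sum
to the totals above.

The same works for `tax-binning` (add `--taxonomy-dir demo/taxonomy`),
`profiling` (`--gold-profile demo/gold/profile.tsv`) and `assembly`
(per-genome report tables), or through a YAML config with `metaeval rank
--config config.yaml`.

## Layout

- `src/metaeval/taxonomy.py` — NCBI-style dump parsing, merged-ID
  resolution, projection onto the eight major ranks
- `src/metaeval/cami_io.py` — bioboxes binning/profiling formats, gold
  standards, assembly report tables
- `src/metaeval/genome_binning.py`, `taxonomic_binning.py`,
  `profiling.py`, `assembly.py` — the four metric categories
- `src/metaeval/ranking.py`, `report.py` — aggregation, placement scores,
  end-to-end runs
- `src/metaeval/synthetic.py` — fixture generator and corruption operators
- `src/metaeval/cli.py` — the `metaeval` command

See `docs/methods.md` for the full metric conventions, the synthetic error
model and the numerical choices.
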