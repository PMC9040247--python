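# phylodiscord

Toolkit for dissecting gene-tree/species-tree discordance into its sources —
incomplete lineage sorting, introgression and lineage rate heterogeneity —
driven by a multispecies-coalescent simulator with introgression pulses in
place of raw sequencing data.

## What it does

- **treekit** — rooted tree model, Newick I/O (parsing via dendropy),
  bipartitions, canonical topology IDs, exhaustive rooted-topology
  enumeration ((2k−3)!!), Robinson–Foulds distances, root-to-tip path sums.
- **msc_sim** — gene trees under the multispecies coalescent with
  instantaneous introgression pulses (inheritance probability γ), clade rate
  multipliers, JC69/HKY sequence simulation, outgroup-polarized biallelic
  site-pattern extraction, and closed-form topology-frequency expectations
  for tests.
- **topo_spectrum** — classify gene trees into canonical topologies and build
  rank-ordered frequency spectra over the full topology universe.
- **concordance** — quartet scores (q1/q2/q3), gene and site concordance
  factors, the quartet-based polytomy χ² test, PhyParts-style reference
  mapping with ICA, and an exhaustive quartet-score species-tree search for
  ≤7 ingroup taxa.
- **dstat** — ABBA-BABA D-statistics with delete-one block jackknife
  Z-scores, full triplet scans, pairwise mean |D| matrices.
- **quibl** — QuIBL-style exponential vs exponential+shifted-exponential
  mixture test on triplet internal branch lengths (EM profiled over the
  shift, BIC comparison, dBIC < −10 introgression calls).
- **clockrates** — clock-constrained likelihoods (Felsenstein pruning) with
  clade-local rate multipliers, M0..Mk model ladders, AICc / LRT / Bonferroni
  arithmetic, p-distances and clade rate summaries.
- **treespace** — all-pairs RF matrices and classical PCoA embedding.
- **pipeline** — end-to-end orchestration with deterministic seeding, TSV
  reports and a run log.

## CLI

```sh
# full pipeline on the built-in 5-taxon + outgroup scenario (2608 loci)
phylodiscord run --seed 1 --out out/

# individual stages
phylodiscord simulate --out sim/ --seed 1 --loci 500
phylodiscord spectrum  --trees sim/gene_trees_subs.nwk --outgroup OUT --out spectrum.tsv
phylodiscord concord   --trees sim/gene_trees_subs.nwk --outgroup OUT \
                       --alignment sim/alignment_concat.fasta --out concord.tsv
phylodiscord dstat     --alignment sim/alignment_concat.fasta --loci-table sim/loci.tsv \
                       --outgroup OUT --out dstat.tsv
phylodiscord quibl     --trees sim/gene_trees_subs.nwk --outgroup OUT --out quibl.tsv
phylodiscord treespace --trees sim/gene_trees_subs.nwk --out ts
```

Scenarios are plain YAML (species tree with branch durations, pulses, clade
rate multipliers, mutation rate, coalescent scaling, locus count/length,
seed); see `phylodiscord.msc_sim.tribe_level_scenario()` for the defaults and
`save_scenario`/`load_scenario` for the format. All outputs are tab-separated
text with header rows; missing values are `NA`.

## Reproducibility notes

- Every stochastic routine takes a seed; per-locus RNG streams are split so
  locus *i* is invariant to the total locus count, and re-running a pipeline
  config reproduces byte-identical TSVs.
- `tests/test_acceptance.py` holds the acceptance criteria: printed-table
  AICc/LRT arithmetic, analytic combinatorics, simulator-vs-closed-form
  checks, D-statistic type-I/power, mixture-test oracle equivalence and
  parameter recovery, clock-multiplier recovery, and RF/PCoA oracle
  round-trips. Simulation sizes are scaled to run on one CPU in a few
  minutes; the thresholds themselves are not relaxed.
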