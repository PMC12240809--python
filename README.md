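# coexmod

Pseudobulk co-expression and consensus-NMF module discovery for
multiplexed-perturbation single-cell experiments.

## The problem

Finding the genes of a specialized metabolic pathway in a large,
enzyme-rich plant genome by co-expression is hard: the pathway is active
only in rare cell states under particular elicitation conditions, and
dozens of unrelated biosynthetic branches respond to the same stimuli.
Bulk RNA-seq compendia see only the shared sample-level on/off response
and dilute rare states away.  A multiplexed perturbation x single-nucleus
(mpXsn) design — hundreds of (condition, stage, time point) samples pooled
into one snRNA-seq library — samples enough transcriptional states to
separate the branches cell by cell.

`coexmod` implements that analysis as a tested library plus numbered
analysis scripts:

1. **synthetic data** (`coexmod.sim`) — a generator for multiplexed
   elicitation designs: factorial samples, additive gene programs with
   Dirichlet per-cell usage, condition-gated rare programs, planted bait
   genes, negative-binomial counts.  It stands in for the deposited data
   and provides ground truth for every downstream claim.
2. **QC** (`coexmod.qc`) — keep cells with `pct_counts_top20 < 25` and
   read depths within 5 MADs of the median; drop genes expressed in < 50
   cells.
3. **pseudobulk** (`coexmod.pseudobulk`) — log-CP10K, PCA, kNN + Leiden
   into ~10-cell states (resolution auto-tuned), raw counts pooled per
   state.
4. **co-expression** (`coexmod.coexpression`) — gene–gene Pearson
   correlation across states, bait rankings, and the mutual-rank network
   `mr_ij = sqrt(rank_ij * rank_ji)` with edges at `mr < 20`.
5. **factorization** (`coexmod.factorization`) — consensus NMF of the
   cell x HVG matrix: multiplicative updates, density-filtered restart
   spectra, k-means consensus, NNLS usage refit, full-genome gene scores;
   plus a k scan.
6. **prioritization** (`coexmod.prioritization`) — bait x module rank
   tables, bait-dominated module detection, enzyme-family counts in module
   tops, ranked candidate lists.
7. **orchestration** (`coexmod.pipeline`, `coexmod.io`) — 10x-style
   MatrixMarket I/O and an end-to-end runner with a checksummed manifest.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
data, writing tables under `results/` (large matrices are regenerated by
the scripts and only the summary tables are kept in the repository; run
the scripts in order):

```sh
python analysis/01_simulate_dataset.py
python analysis/02_quality_control.py
python analysis/03_pseudobulk_states.py
python analysis/04_coexpression_network.py
python analysis/05_discover_modules.py
python analysis/06_prioritize_candidates.py
```

Output (abridged):

```
wrote 1200 genes x 1920 cells (96 samples) to results/data
bait-program activity fractions: [0.083, 0.083, 0.083] (rare, condition-gated states)
cells: 1920 -> 1893 (27 removed: 27 concentrated, 0 depth outliers)
genes: 1200 -> 1066 (expressed in fewer than 50 cells removed)
1893 cells -> 231 cell states (mean size 8.2, min 2, max 20); totals conserved: True
ranks by PCC to g00012: baits of its own program [1, 3, 6, 20], baits of the
  other two programs median 922 of 1065 — the pathway splits into separately
  regulated co-expression groups
mutual-rank network (mr < 20): 10149 edges, 1066 genes; 14/14 baits linked
bulk-comparison study: 15/15 pathway genes rank better under pseudobulk states
  (median improvement 10.6x)
consensus NMF k=12: objective 6.538e+05, mean module stability 0.99
bait-dominated modules across the k scan (>=3 of 14 baits in a module's top
  100): {12: 3, 16: 3, 24: 3} — stable at three
bait-dominated modules (>=3 baits in top 100): ['module2', 'module5', 'module4']
candidate list: 223 genes; precision@20 against the planted pathway programs: 1.00
```

Reading: one bait gene correlates tightly only with the baits of its own
program — the pathway occupies three separately regulated modules, which
simple anchor correlation cannot capture but the factorization finds at
every k scanned.  Pseudobulk cell states beat a coarse in-silico bulk
compendium for every planted pathway gene, with a 10.6x median rank
improvement, and the top of the bait modules is free of false candidates.

The model and all parameter choices are documented in
[docs/methods.md](docs/methods.md).

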