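# Methods

## The model

`ppimod` operationalizes the network-medicine view of a transcriptomic
perturbation: genes whose products interact tend to participate in the
same biological process, so a perturbation that hits a real process should
leave its differentially expressed (DE) genes *clustered* on the
protein–protein interactome rather than scattered. The module statistic is
deliberately minimal — the size S of the largest connected component (LCC)
of the subgraph induced by the seed genes — and all inferential weight is
carried by the null model.

### Seed genes

Counts are normalized with median-of-ratios size factors: per sample j,
`s_j = median_g( c_gj / geomean(c_g·) )` over the genes with positive
counts in every sample, rescaled so the factors have geometric mean 1 (a
pure convention; only ratios matter downstream). Technical replicates are
averaged within each (donor, phenotype, treatment, timepoint) cell before
testing, so the donor is the unit of analysis. Per gene the linear fold
change is `(mean_a + pc) / (mean_b + pc)` with pseudocount pc = 0.5
(guards against zero means; configurable), and the p-value comes from

* **unpaired contrasts** — Mann–Whitney U on log₂(normalized + pc) values;
  exact p from the full rank-sum null distribution (Gaussian-binomial
  recursion) when n+m ≤ 12 and the pooled data are tie-free, else the
  normal approximation with midrank tie correction and 0.5 continuity
  correction;
* **paired contrasts** — Wilcoxon matched-pairs signed-rank on donor-wise
  log₂ differences; exact p from the sign-flip generating function
  (conditional on the observed midranks, so tied magnitudes are handled
  exactly) for ≤ 15 nonzero pairs, else the normal approximation. Zero
  differences are dropped; a gene whose differences are all zero gets
  p = 1 rather than an error, since "no evidence" is the right verdict
  inside a genome-wide scan.

Seeds are the genes with p ≤ 0.05 and FC ≥ c or FC ≤ 1/c. The cut-offs are
symmetric on the linear scale; the defaults c = 1.87 (early timepoint) and
c = 1.67 (late timepoint) with raw p ≤ 0.05 follow the convention of the
kind of study the package targets. No multiple-testing correction is
applied at seed selection — the module null, not the per-gene test,
provides the family-level control — but a precomputed DE table (e.g.
DESeq2 output with FDR-adjusted p) can be supplied instead, in which case
whatever column it carries is thresholded as-is.

A deliberate scope decision: the DE stage is the nonparametric route
(size factors + rank tests), not a negative-binomial GLM. The NB-GLM
machinery with dispersion shrinkage is a project of its own and exists in
mature packages; the external-table hook is the intended integration
point.

### Module significance

The observed module is the LCC of the seed-induced subgraph (ties between
equal-size components break toward the component containing the
lexicographically smallest gene, for determinism). The null randomizes
both of the things that could manufacture apparent connectivity:

* **network** — degree-preserving double-edge swaps: edges (a,b), (c,d)
  and an orientation are drawn uniformly and rewired to (a,d), (c,b)
  unless a self-loop or duplicate would result. The proposal is symmetric,
  so the chain's stationary distribution is uniform over simple graphs
  with the observed degree sequence. The chain runs continuously with a
  burn-in of 10×|E| attempted swaps and 10×|E| further attempts between
  consecutive samples (one chain, not a restart per sample — the
  stationary distribution is identical and the cost halves);
* **seed placement** — a fresh uniform node set of the mapped seed count
  per sample.

A configuration switch (`randomize_network=False`) restricts the null to
random seeds on the fixed network. Reported are
`z = (S − mean₀)/sd₀` (sample sd, ddof = 1; flagged undefined when
sd₀ = 0) and the add-one empirical `p = (#{null ≥ S} + 1)/(n + 1)` with
n = 1000 samples by default, so the smallest attainable p is 1/1001.
Unmapped seeds are excluded from both the observed statistic and the null
seed count, keeping the two comparable, and are reported separately.

The swap chain and the per-sample LCC evaluation run in a numba-compiled
kernel over edge-endpoint arrays with a packed adjacency bitset
(N²/64 uint64 words) for O(1) duplicate checks and a union–find over the
sampled seeds; degree preservation is verified against the pre-run degree
sequence after sampling. At the default study size (2000 nodes, ~6000
edges) one 1000-sample null takes a few seconds on one CPU.

### Enrichment and overlap

Over-representation uses the exact hypergeometric upper tail
`P(X ≥ q)` for overlap q between a size-k query and a size-m set in a
universe of N genes (scipy's hypergeom survival function; the test suite
checks it exhaustively against integer PMF summation for all tables with
N ≤ 30). Correction is Bonferroni over the number of sets actually
tested — the convention of the reports this mirrors — with
Benjamini-Hochberg intentionally left out of the default path. The
default universe is the measured genes that the collection annotates,
overridable by file; GO cellular-component collections are handled by the
same flat machinery (no ontology propagation). Overlap between two
signatures uses the same tail with the interactome genes as the default
universe; the percent overlap is reported relative to each set, and the
p-value is symmetric under swapping the sets.

## The synthetic study

The generator emulates the statistical skeleton of a small paired design:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | interactome size and gene universe |
| `attachment_m` | 3 | preferential-attachment edges per node (scale-free background) |
| `planted_module_size` | 30 | genes of the planted connected module |
| `extra_module_edges` | 30 | intra-module edges beyond the random spanning tree |
| `planted_log2fc` | 2.0 | treatment effect on planted genes (log₂) |
| `nb_dispersion` | 0.1 | NB dispersion α; Var = μ + αμ² |
| `base_mean_log_range` | (1, 3) | log₁₀ range of per-gene base means (10–1000 counts) |
| `n_donors` | 8 | 4 non-asthmatic + 4 asthmatic, each with paired control/treated samples |
| `replicates_per_condition` | 2 | technical replicates, averaged by the pipeline |
| `donor_sigma` | 0.2 | lognormal sd of the per-donor multiplier |
| depth multipliers | log-uniform in [0.5, 2] | per-sample sequencing depth |
| `n_pathways`, sizes | 50, 10–60 | random sets plus one planted set |
| `planted_pathway_fraction` | 0.8 | fraction of the planted set drawn from module genes |

The planted module is made connected by construction (random recursive
tree plus extra intra-module edges), so end-to-end recovery is a
well-defined target. Donor multipliers exercise the size-factor stage;
the paired design cancels them in the signed-rank differences. Truth
labels (planted genes, planted pathway, per-gene true fold change) are
always written and never read by the pipeline.

What the generator does *not* emulate: transcript-level quantification,
GC/length bias, batch effects, correlated co-expression modules beyond
the planted one, or any real disease biology. Passing the recovery tests
therefore shows the machinery is correct and calibrated under its own
assumptions — not that the thresholds are optimal for real data.

## Numerical and design choices

* **Determinism** — every stochastic stage derives a substream from
  (global seed, stage label) via `SeedSequence`; outputs use fixed
  formatting (6-significant-digit scientific notation in TSVs, sorted
  JSON keys), so a config+seed reproduces byte-identical files and the
  pipeline manifest's SHA-256 checksums are stable.
* **Empirical p discreteness** — with small seed sets the LCC statistic
  takes few values and the add-one empirical p is superuniform
  (conservative), not uniform; the calibration test for approximate
  uniformity therefore uses seed sets large enough (≈80 on a 500-node
  graph) for the statistic to have wide support. Interpreting very small
  modules should lean on the empirical p, never the z-score.
* **Exact-test conservatism** — at 8 donor pairs the exact two-sided
  signed-rank test can reject at most 10/256 ≈ 3.9% of nulls at the 0.05
  level; this is a property of the test, not a bug. The type-I
  calibration experiment consequently uses 20 donor pairs, where the
  attainable level is ≈ 0.05 and a band centred on the nominal level is
  meaningful.
* **Problem sizes** — the shipped experiments use the 2000-gene default
  study (20 generator seeds for recovery, 1000-sample nulls) and
  scaled-down variants (300 genes) for I/O and orchestration tests; these
  sizes give stable verdicts for every property tested while keeping a
  full run in minutes on one CPU.
* **Degenerate inputs** — self-loops are always removed (module
  statistics are defined on simple graphs); genes absent from the
  interactome are reported, not errors; a null with sd = 0 flags the
  z-score undefined and falls back on the empirical p; an all-zero sample
  or an empty contrast group is a hard error naming the offender.

## Known limitations

* The module definition is the induced LCC of the seeds; connector-gene
  expansion (DIAMOnD-style growth) and inter-module proximity measures
  are out of scope.
* Gene identity is the canonical uppercase symbol; no bundled alias or
  Entrez resolution (an optional user-supplied alias map is honored, and
  mapping losses are logged).
* The swap-chain null assumes the interactome fits a dense adjacency
  bitset (~50 MB at 20k nodes); far larger graphs would need a sparse
  membership structure.
* Bonferroni across pathway sets ignores their overlap structure, as do
  all flat over-representation analyses.
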