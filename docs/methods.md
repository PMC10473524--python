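# Methods

Statistical methods, model definitions and numerical conventions used by
ystrkit. Notation: n males, L loci, alleles are repeat counts (possibly
fractional microvariants), p_i are frequencies by the counting method.

## Data conventions

- An allele cell is a float (single-copy locus), `None` (missing), or a
  tuple of two floats — either the unphased DYS385 a/b pair (stored sorted)
  or a duplicated-allele record at a single-copy locus.
- Missing-data sentinels on input: `99`, `99.0`, empty, `NA`, `nan`, `?`.
- Microvariants keep one decimal with fractional part in {.1, .2, .3}.
  Wherever integer repeat arithmetic is required (distances, networks,
  simulation round trips) microvariants are rounded half-away-from-zero.
- DYS389II.I recoding: DYS389II is typed as the combined repeat count of
  both DYS389 stretches; the recoded value is DYS389II − DYS389I.
  `DYS389II < DYS389I` is rejected as an impossible encoding; a panel flag
  guards against double recoding.
- Duplicated-allele filtering removes every haplotype with a two-allele
  record at any single-copy locus; DYS385 pairs are never grounds for
  removal. The filter reports input/removed/retained counts and the
  removed sample IDs.

## Forensic parameters

- Gene diversity: GD = 1 − Σp²; unbiased variant n·GD/(n − 1) on request.
- Polymorphism information content:
  PIC = 1 − Σp² − (Σp²)² + Σp⁴.
- Locus match probability: Σp².
- Haplotype diversity (Nei, unbiased): HD = n(1 − Σp²)/(n − 1) with p the
  haplotype frequencies; match probability MP = Σp²; discrimination
  capacity DC = h/n (h = number of distinct haplotypes); haplotype match
  probability HMP = 1 − HD. Haplotype-level statistics use complete
  profiles only; excluded rows are counted and logged.
- DYS385 contributes two allele observations per male to its frequency
  spectrum.

## Population distances and AMOVA/Rst

- Pairwise haplotype distance δ under the stepwise mutation model: sum of
  squared repeat-step differences across loci (a `step_count` metric, sum
  of absolute differences, is also available). Microvariants are rounded
  first; DYS385 is excluded from distance computations by default (no
  phase, no step interpretation of an unordered pair).
- One-level distance-based AMOVA with N samples in P populations:
  SSD_total = Σ_{i<j} δ_ij / N, SSD_within = Σ_p Σ_{i<j∈p} δ_ij / n_p,
  σ²_w = SSD_within/(N − P),
  n̄ = (N − Σ n_p²/N)/(P − 1),
  σ²_a = (SSD_among/(P − 1) − σ²_w)/n̄,
  Rst = σ²_a/(σ²_a + σ²_w). Negative estimates are retained (finite-sample
  behaviour near Rst = 0; duplicating a population yields exactly
  −1/(n − 1)). N ≤ P is rejected (no within-population degrees of
  freedom).
- Permutation test: sample labels are permuted; the p-value uses the +1
  correction, p = (1 + #{Rst* ≥ Rst_obs})/(B + 1), with a 1e-12 tie
  tolerance. A seed is mandatory whenever permutations are requested.
- Nei's corrected average pairwise difference between populations X and Y:
  PiXY − (PiX + PiY)/2; may legitimately be negative; the self-distance is
  exactly zero by construction.
- Classical (Torgerson) MDS: B = −½ J (D∘D) J with J the centring matrix;
  eigendecomposition; coordinates from the top-k non-negative eigenvalues;
  negative input distances are clipped to zero beforehand; the report
  includes the positive-eigenvalue mass captured.
- Hierarchical clustering: scipy linkage on the condensed distance matrix,
  `upgma` (average) or `ward`; cluster assignments by `fcluster` at k
  groups; Newick export from the linkage matrix.

## Haplogroup prediction

Bayesian classifier over per-haplogroup allele-frequency tables
(long-format CSV `haplogroup,locus,allele,frequency`; priors uniform or
user-supplied):

- score_g = prior_g · Π_l f_{g,l}(x_l), computed in log space over the
  loci shared by the haplotype and the table; DYS533 and DYS543 are
  excluded by default, as are multi-copy and missing loci.
- Smoothing: each distribution is renormalised to sum/(sum + s) with
  pseudo-frequency s = 0.001 assigned to unseen alleles; a microvariant
  falls back to its rounded integer allele when absent.
- Probability = 100 · softmax over haplogroups; fitness =
  100 · (Π_l f_{g,l}/max_l f_{g,l-modal})^(1/L), a scale-free geometric
  mean relative to the modal haplotype of the best group.
- A call is made only when probability > 85 and fitness > 15 (both
  configurable); otherwise the outcome is `UNPREDICTED`.
- A small fully synthetic frequency table (5 haplogroups × 15 Y23 loci)
  ships with the package for demonstrations and tests; it encodes no real
  population frequencies.

## Median-joining networks

- Input preparation: single-copy loci only, microvariants rounded, rows
  with missing values excluded (with a manifest), identical haplotypes
  collapsed with size counts and optional majority annotation.
- Distance: L1 step distance on integer repeat vectors, optional locus
  weights.
- ε-relaxed minimum spanning network: edge (u,v) is kept iff
  d(u,v) ≤ minimax(u,v) + ε, where minimax is the largest edge on the
  minimum-spanning-tree path between u and v; at ε = 0 this is the union
  of all minimum spanning trees.
- Median addition: for each connected triple in the current network, the
  per-locus median vector is a candidate; candidates are added greedily
  while they reduce the minimum-spanning-tree cost of the node set, with
  lexicographic tie-breaking for bit-reproducibility. Median vectors whose
  removal does not increase the cost are pruned.
- On homoplasy-free data in which every intermediate haplotype is sampled,
  the network equals the (unique) minimum spanning tree with no medians.

## Coalescent simulator

Structured coalescent in mutational time units (mutation rate 1 per locus,
time in 1/μ units), Gillespie event loop:

- Within deme i with k lineages, coalescence occurs at total rate
  k(k − 1)/Θ_i; for n = 2 this gives E[TMRCA] = Θ/2 and expected mean
  pairwise allele-size difference E[(x − y)²] = Θ per locus under the
  single-step model.
- Backward migration: a lineage in deme i jumps to deme j at rate M[i][j].
- Models: `panmixia` (all samples in one deme with Θ = theta[0]);
  `divergence_only` (isolated demes merging into one ancestral deme at
  time τ, with `ancestral_theta` or the mean Θ); `divergence_plus_migration`
  (migration until τ, then merge); `unidirectional_flow` (arbitrary
  constant migration matrix, no merge — configurations whose demes cannot
  reach a common deme are rejected up front).
- All loci share one genealogy (the Y chromosome does not recombine);
  mutation counts per branch are Poisson(branch length) and each mutation
  steps the repeat count ±1 with probability ½; repeat counts reflect at 1.
- Everything is seeded: dataset simulation, replicate streams, and the
  corruption operators (missing cells, microvariants, duplicated-allele
  records). Identical configurations with identical seeds produce
  byte-identical exports.
- Bayes-factor ranking: models/routes are ordered by log marginal
  likelihood; log Bayes factor of model i is logml_best − logml_i; ties
  break alphabetically; non-finite inputs and fewer than two models are
  rejected.

## Problem sizes and verification

Test and script problem sizes are chosen for desk-scale runtimes while
keeping Monte-Carlo assertions well-powered:

- ASD/Θ recovery: one deme, 2 lineages, 2 loci, 10,000 replicates;
  asserted within 3 standard errors.
- Rst versus migration: two demes of 6, 4 loci, symmetric M ∈
  {0.1, 1, 10, 100}, 2,000 replicates per point; asserted strictly
  monotone decreasing.
- AMOVA is fuzz-tested (≥220 random instances, N ≤ 12) against an
  independent brute-force variance decomposition written as literal
  double loops.
- Permutation p-values are checked for approximate uniformity under the
  null (200 datasets, 99 permutations each, Kolmogorov–Smirnov at
  α = 0.01).
- MDS must reconstruct genuine Euclidean configurations to 1e-9.

## Limitations

- The 379-male Qatari PowerPlex Y23 table (YHRD accession YA004657) and
  the multi-population comparative datasets are third-party data and are
  not bundled; the acceptance tests covering the published forensic
  parameters and haplogroup tallies require the user to supply
  `data/qatari_s1_table.csv` and fail with instructions otherwise.
- The simulator models a constant-size structured coalescent with at most
  one divergence event; no growth, bottlenecks, or recombination.
- Marginal-likelihood *estimation* for gene-flow models (e.g. MIGRATE-N
  thermodynamic integration) is out of scope; the toolkit ranks models
  from user-supplied log marginal likelihoods.
- No plotting: MDS coordinates, dendrograms (Newick) and networks
  (GraphML/DOT) are exported for external visualisation.
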