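# Methods

## The inference problem

Given a taxa × samples OTU count table, a rooted phylogeny covering the
taxa, and per-sample environmental metadata grouped into sites, the package
estimates how much of the between-sample community turnover is attributable
to deterministic processes (environmental selection) versus stochastic ones
(dispersal and drift). The estimates are built from three null models and a
threshold classification, described below, followed by environment-linkage
statistics and co-occurrence network summaries.

## Null models

### Richness/abundance-preserving Bray–Curtis null

Each sample is re-assembled under the null as follows: (i) draw the
sample's observed richness of distinct taxa without replacement with
probability proportional to each taxon's occurrence frequency across the
samples handed to the call; (ii) give every drawn taxon one individual;
(iii) distribute the remaining individuals (observed total − richness)
multinomially with probability proportional to the taxa's mean relative
abundances. Each null assembly therefore preserves the sample's richness
and total count exactly (asserted on every replicate). The weighted draw
without replacement is implemented with exponential keys
(Efraimidis–Spirakis), which is distributionally identical to sequential
weighted sampling; a test checks the inclusion probabilities against the
exact sequential enumeration on a 3-taxon pool.

Per replicate, every sample is re-assembled once and all pairwise
Bray–Curtis values are computed on that replicate's assembly. This shares
the null assemblies across pairs within a replicate — marginally identical
to re-assembling per pair, and cheaper by a factor of the number of
samples. Two statistics consume this distribution:

- **Null deviation**: observed BC − mean null BC, and the relative form
  (obs − mean) / mean. Both are reported; the relative form is the default
  site-level summary. The null-model pool for a site-level summary is that
  site's own samples (per-site calls).
- **RC_bray**: the fraction of null values below the observation, ties
  half-weighted, rescaled as 2·(frac − 0.5) ∈ [−1, +1].

The default replicate count is 999. Monte-Carlo error shrinks as 1/√reps
(checked empirically); 199 replicates are used in the shipped validation
runs to keep them inside a few minutes on one CPU — a package default for
the synthetic studies, with 999 retained for real analyses.

### Phylogenetic null (βMNTD → βNTI)

βMNTD is abundance-weighted: for each taxon present in one community, the
cophenetic distance to its nearest taxon in the other community (zero if
the taxon is itself present there), averaged with relative-abundance
weights and symmetrized. The null shuffles taxon identities across the
tips — implemented as a joint row/column permutation of the cophenetic
matrix restricted to the taxa of the loaded table — once per replicate,
shared by all pairs (independent per-pair shuffles are available behind a
flag). βNTI is the z-score of the observed βMNTD. Because a z-score is
scale-free, multiplying all branch lengths by c > 0 multiplies βMNTD by c
and leaves βNTI unchanged (tested).

When the shuffle cannot change βMNTD (an equal-branch star tree, or two
samples with identical supports — shared taxa keep distance zero under
every permutation), the null standard deviation is 0 and the pair is
flagged undefined rather than silently scored; undefined pairs are
excluded from process fractions with a reported count.

The shuffle pool is the table handed to the call. Within-site statistics
are taken from a full-table run: restricting the shuffle to one site's taxa
would randomize only within the environmentally filtered subtree and
systematically shrink the null's reach (this is visible in simulation as a
sign flip of the homogeneous-selection signal).

### Classification

Each pair with defined statistics receives exactly one label:
βNTI > +2 → variable selection; βNTI < −2 → homogeneous selection;
otherwise RC_bray > +0.95 → dispersal limitation; RC_bray < −0.95 →
homogenizing dispersal; else undominated. Boundary values fall to
undominated (the rules are strict inequalities). The residual category is
reported explicitly so the fractions always form a complete partition.

## Environment linkage

The Mantel test correlates the condensed upper triangles of two
sample × sample matrices; the permutation null jointly permutes the rows
and columns of one matrix, with p = (1 + #{r_perm ≥ r_obs}) / (1 + perms),
one-sided by default (999 permutations). Pairwise regression fits OLS of a
pairwise statistic (e.g. βNTI) on pairwise environmental differences
|v_i − v_j|; because pairs sharing a sample are not independent, the
reported p-value uses the same Mantel-style label permutation (two-sided on
r), and the parametric OLS p-value is additionally returned labelled
*naive*. Both routines take explicit seeds so that runs are bit-reproducible
— the reason they are implemented here rather than delegated (library
Mantel implementations are used as cross-checks in the test suite, not as
the implementation). Regressing on pairwise differences (rather than raw
per-plot values) is the only form commensurate with a pairwise response.

## Co-occurrence networks

Networks are built per site. Taxa present in fewer than 5 samples are
dropped (rank correlations on near-constant vectors are degenerate; the
filter is configurable down to 1 = none). Spearman ρ (midranks for ties)
is computed on per-sample relative abundances for all remaining pairs;
p-values are Benjamini–Hochberg adjusted over all tested pairs; kept edges
satisfy |ρ| > 0.6 *and* adjusted p < 0.05, with the sign retained. The
threshold is applied to |ρ| so that mutual-exclusion (negative) edges are
representable. Correlating relative abundances carries the usual
compositional caveat; no CLR transform is applied by default.

Modules come from greedy modularity maximization on the unweighted graph
(module ids relabelled deterministically by size then lexicographic
smallest member), with Q = Σ_m (e_m/E − (d_m/2E)²). Topology: average
degree 2E/N; average local clustering with degree-<2 nodes contributing 0;
average path length over connected pairs only; betweenness normalized by
(N−1)(N−2)/2; Freeman centralization Σ(b_max − b_i)/(N−1). Node roles use
the within-module degree z-score Zi (0 when a module's within-degree
spread is 0) and participation coefficient Pi = 1 − Σ_m (k_im/k_i)², with
the conventional thresholds Zi = 2.5 and Pi = 0.62.

## α-diversity conventions

Shannon is natural-log by default (a base flag exists); Simpson defaults to
the Gini–Simpson form 1 − Σp² ("higher = more diverse"), with the dominance
form selectable. Chao1 is bias-corrected: S + F1(F1−1)/(2(F2+1)). ACE uses
a rare/abundant threshold of 10 and falls back to Chao1 with a warning when
every rare taxon is a singleton (coverage 0). Faith's PD is root-inclusive
(the stem path from the community to the root is counted), matching
QIIME-style implementations; users comparing against root-exclusive tools
should expect an offset. Good's coverage is 1 − F1/N and is computed on
whatever table it is given — computing it before or after rarefaction is a
choice the caller makes; the pipeline computes it after.

Rarefaction subsamples without replacement (multivariate hypergeometric);
samples below the depth are dropped with a warning, never padded. The
shipped default depth is 4020.

## Synthetic study generator

The generator emulates a three-site soil 16S survey in which plots within
each site are laid out along an environmental (altitudinal) gradient. Its
components:

- **Phylogeny**: pure-birth (Yule) tree, scaled to unit root height.
- **Niches**: Brownian-motion environmental optima evolved along the tree
  (rate `trait_signal`, default 1.0 per unit branch length), giving
  phylogenetically conserved habitat preferences — the assumption that
  makes βNTI informative. The phylogenetic signal is built in by
  construction, not tested.
- **Regional abundances**: log-normal (sdlog 0.5), yielding realistic
  rank-abundance curves with rare taxa.
- **Communities**: multinomial draws of 5000 reads with taxon weights
  `regional × exp(−(optimum − env)²/(2σ²)) × drift`, where drift is
  per-sample log-normal noise (sdlog 0.3) standing in for demographic
  stochasticity.
- **Environment**: per-site windows of width 2 centered at −1, 0, +1 on
  the trait axis; SOC = 40 + 15·env + N(0, 2) (mg g⁻¹ scale) and a weakly
  anti-correlated pH, so environment-linked turnover is recoverable by
  Mantel/regression.

Regime mapping — each scenario isolates one dominant process:

- *Variable selection*: sample environments spread across the site window;
  niche breadth σ = 0.45.
- *Homogeneous selection*: one constant environment per site, σ = 0.22,
  plus a per-sample recruitment lottery (each sample can recruit only a
  random 40% of the pool). The lottery is essential, not cosmetic: βMNTD
  is presence-driven, so identical filters applied to identical pools
  produce identical supports and a degenerate null — homogeneous selection
  is only *visible* when ecologically equivalent close relatives replace
  one another across samples.
- *Neutral dispersal*: the niche kernel is removed; all samples draw from
  the shared pool and differ only by drift and sampling.
- *Dispersal limitation*: no selection, and each sample draws from its own
  disjoint-leaning block (25% of a site-wise permuted pool), so observed
  turnover exceeds the occupancy-based null.

Parameter choices were calibrated once, power-analysis style, so that each
regime's defining signature is statistically detectable at the study's
sample sizes (3 × 8 samples): the 800-taxon pool keeps per-sample richness
a minority of the tree (nearest-taxon distances saturate otherwise), the
evenness setting prevents a few dominant non-shared taxa from dominating
the abundance-weighted βMNTD shuffle variance, and the drift level keeps
the neutral scenario's null deviation below the selection scenarios'.
Weakening any of these (exposed as `ScenarioConfig` fields) degrades the
classifier in the expected direction, which is itself a useful exercise.

### What the generator does and does not emulate

It produces count tables with realistic richness, evenness, rare taxa and
site structure, under exactly known assembly processes. It does not
simulate sequencing error, chimeras, taxonomy, spatial autocorrelation
within sites, temporal dynamics, or species interactions; its niche model
is unimodal Gaussian on a single axis. Passing the regime-recovery tests
therefore shows the inference chain is consistent under the model's own
assumptions — it does not certify performance on real data, where
phylogenetic signal in niches may be weak and multiple gradients overlap.

## Reproducibility and numerics

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from one master seed by fixed offsets (simulate +0, rarefy
+101, null deviation +202, βNTI +303, RC_bray +404, Mantel +505,
regression +606), so stages can be re-run in isolation and a full pipeline
run is byte-identical under a fixed seed (tested). Bray–Curtis tie
comparisons in RC_bray use a 1e-10 tolerance (BC on integer counts is
rational, so exact ties are common). Distance matrices are validated
symmetric and hollow; newick branches without lengths are assigned 0 with
a warning (a strict mode rejects them); tip/taxon matching is exact string
equality after whitespace stripping.

Default problem sizes in the shipped validation runs (tests and
`scripts/acceptance.py`) are 3 sites × 8 samples, 800 taxa, 5000 reads
rarefied to 4020, 199 null replicates — sized to complete the full
four-regime battery in a few minutes on a single CPU while leaving the
regime signatures well clear of their thresholds.

## Known limitations

- βNTI pairs with degenerate nulls are excluded (flagged), so process
  fractions on pathological trees (e.g. stars) can rest on few pairs.
- Matrices containing undefined βNTI values cannot be fed to the Mantel
  test; filter those samples first.
- The co-occurrence screen tests all retained pairs; at small sample sizes
  (n < ~6) Spearman p-values are coarse and FDR control is conservative —
  per-site networks on few samples are exploratory summaries, not
  inference.
- Greedy modularity is one of many partition heuristics; printed Q values
  from other tools (e.g. simulated annealing) will differ slightly.
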