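# assemblyscope

Null-model inference of microbial community assembly processes from OTU
count tables.

Soil (and other environmental) bacterial communities are structured by a
mixture of deterministic processes (environmental selection) and stochastic
processes (dispersal, ecological drift). `assemblyscope` implements the
standard null-model toolkit ecologists use to quantify that balance from a
taxa × samples count table, a rooted phylogeny, and per-sample environmental
metadata:

- **β-diversity null deviation** — the (relative) difference between
  observed Bray–Curtis dissimilarity and its expectation under a null model
  that re-assembles each sample while preserving its richness and total
  abundance (999 iterations by default). Values near zero indicate chance
  assembly; large magnitudes indicate deterministic structuring.
- **βMNTD / βNTI** — abundance-weighted between-community mean
  nearest-taxon distance, and its z-score against a null that shuffles
  taxon identities across the tips of the phylogeny:
  βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null.
  βNTI > +2 indicates variable selection, βNTI < −2 homogeneous selection.
- **RC_bray** — abundance-weighted Raup–Crick: the observed Bray–Curtis
  value ranked within its null distribution and rescaled to [−1, +1]
  (ties half-weighted).
- **Process classification** — each sample pair gets exactly one label:
  variable selection (βNTI > +2), homogeneous selection (βNTI < −2),
  dispersal limitation (|βNTI| < 2, RC_bray > +0.95), homogenizing
  dispersal (|βNTI| < 2, RC_bray < −0.95), or undominated. Per-site label
  fractions estimate the relative influence of each process.
- **Environment linkage** — Mantel tests and pairwise
  (distance-on-distance) regression of βNTI against environmental
  difference matrices, with permutation p-values.
- **Co-occurrence networks** — Spearman correlations of relative
  abundances screened at |ρ| > 0.6 with Benjamini–Hochberg FDR < 0.05,
  greedy-modularity module detection, the usual topology block (average
  degree, clustering, path length, betweenness centralization, modularity),
  and Zi–Pi node roles (peripherals / module hubs / connectors / network
  hubs).
- **α-diversity** — sobs, bias-corrected Chao1, ACE, Shannon (nats),
  Gini–Simpson, Faith's PD (root-inclusive), Good's coverage, plus
  rarefaction by subsampling without replacement.

Because studies of this kind rarely deposit re-analyzable tables, the
package ships a first-class **synthetic study generator**: a Yule phylogeny
with Brownian-motion environmental optima (phylogenetically conserved
niches), log-normal regional abundances, and multinomial sampling under
four assembly regimes (variable selection, homogeneous selection, neutral
dispersal, dispersal limitation), with site-structured environmental
covariates (SOC, pH) correlated with community turnover. Every inference
stage is validated by recovering the regime that generated the data.

## Worked example

```python
import assemblyscope as asc
from assemblyscope import NullModelConfig, ScenarioConfig

cfg = ScenarioConfig(regime="variable_selection", n_taxa=200,
                     n_samples_per_site=4, reads_per_sample=2000, seed=42)
table, tree, meta = asc.simulate_study(cfg)
table = asc.rarefy(table, 1500, seed=42).drop_empty_taxa()

bnti = asc.beta_nti(table, tree, NullModelConfig(reps=199, seed=1))
rc = asc.rc_bray(table, NullModelConfig(reps=199, seed=2))
classified = asc.classify_pairs(bnti, rc)
print(asc.process_fractions(classified, meta).round(3).to_string(index=False))

r, p = asc.mantel(asc.bnti_matrix(classified),
                  asc.env_difference_matrix(meta, "SOC"),
                  permutations=999, seed=3)
print(f"Mantel betaNTI~SOC: r = {r:.3f}, p = {p:.3f}")
```

prints

```
group  n_pairs  n_undefined  variable_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated
site1        6            0               0.667                    0.0                 0.167                   0.000        0.167
site2        6            0               0.667                    0.0                 0.167                   0.167        0.000
site3        6            0               0.667                    0.0                 0.167                   0.000        0.167
Mantel betaNTI~SOC: r = 0.727, p = 0.001
```

Two thirds of within-site pairs exceed βNTI = +2 — the variable-selection
signature of the regime that generated the data — and phylogenetic turnover
tracks the SOC gradient (Mantel p = 0.001).

## Command line

Each stage is also a subcommand of the `assemblyscope` CLI:

```bash
assemblyscope simulate --regime variable_selection --seed 1 --outdir demo/
assemblyscope rarefy  --table demo/table.tsv --depth 4020 --seed 1 --out demo/rare.tsv
assemblyscope alpha   --table demo/rare.tsv --tree demo/tree.nwk --out demo/alpha.tsv
assemblyscope bnti    --table demo/rare.tsv --tree demo/tree.nwk --reps 999 --seed 1 --out demo/bnti.tsv
assemblyscope rcbray  --table demo/rare.tsv --reps 999 --seed 1 --out demo/rc.tsv
assemblyscope classify --bnti demo/bnti.tsv --rc demo/rc.tsv --metadata demo/metadata.tsv --out demo/processes.tsv
assemblyscope network --table demo/rare.tsv --out demo/net.graphml --edges demo/edges.tsv
assemblyscope pipeline --regime variable_selection --seed 1 --reps 999 --outdir demo/run/
```

## Layout

- `src/assemblyscope/io.py` — data model (OtuTable), readers/writers, rarefaction
- `src/assemblyscope/alpha.py` — α-diversity estimators
- `src/assemblyscope/beta.py` — Bray–Curtis, the richness/abundance-preserving null, null deviation
- `src/assemblyscope/phylo.py` — cophenetic distances, βMNTD, βNTI
- `src/assemblyscope/raupcrick.py` — RC_bray
- `src/assemblyscope/processes.py` — classification, Mantel, pairwise regression
- `src/assemblyscope/network.py` — co-occurrence networks, modularity, Zi–Pi roles
- `src/assemblyscope/simulate.py` — synthetic study generator
- `src/assemblyscope/pipeline.py` — end-to-end pipeline
- `docs/methods.md` — model details, parameter choices, limitations
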