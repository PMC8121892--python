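# riverdiv

Catchment-scale analysis of freshwater fish communities from eDNA
metabarcoding read tables: contamination-aware cleaning, α/β-diversity
patterns along a river network, and validated biogeographical clustering
of sites into candidate conservation units.

The package is aimed at ecologists who already have per-sample
taxon×read-count tables (one per PCR assay, e.g. two 12S primer sets)
plus sample metadata and a river-network edge list, and who want the
downstream community analysis to be scripted, seeded and testable. It
deliberately starts *after* taxonomic assignment — no FASTQ or
bioinformatic clean-up is handled here.

## What it computes

Given count tables with replicates and negative controls:

1. **Cleaning** — per-sample low-frequency filter (counts < 0.1% of the
   sample's total are zeroed), subtraction of each taxon's maximum
   negative-control count, replicate merging per site, and cross-assay
   merging by per-cell maxima over the union taxon set.
2. **α-diversity** — local richness S_i; distance decay from the outlet
   by Poisson GLM, log μ = β0 + β1·d (d = along-network km); exact
   species-accumulation curves E[S(k)] = S_obs − Σ_i C(N−n_i,k)/C(N,k)
   with permutation SDs; PCA of site environmental variables.
3. **β-diversity** — pairwise Jaccard dissimilarity additively
   partitioned (Baselga) into turnover β_jtu = 2min(b,c)/(a+2min(b,c))
   and nestedness β_jne = β_jac − β_jtu; Mantel permutation tests of
   each component against the fluvial distance matrix.
4. **Clustering** — Canberra distances on the merged count matrix;
   hierarchical (ward.D2), k-means, PAM and DIANA over k = 2..10;
   Hopkins clustering tendency; seven validation measures
   (connectivity, Dunn, silhouette; APN, AD, ADM, FOM under
   leave-one-taxon-out reclustering) with per-measure optimal
   (method, k); cluster labels projected back onto the network with a
   spatial-coherence summary.

A seeded synthetic-data generator (`riverdiv.synthetic_data`) produces
dendritic networks, planted communities (null / distance-decay /
two-zone / four-zone scenarios), and two-assay read tables with
replicate structure, reference-coverage gaps and contamination, plus
the ground truth needed to score recovery. See `docs/methods.md` for
models, parameter defaults and limitations.

## Worked example

Simulate a four-zone catchment (4 rivers × 10 sites, 250 taxa, six
replicates/site, two assays) and run every stage from one config:

```yaml
# config.yaml
seed: 7
scenario: four_zone
```

```bash
riverdiv all --config config.yaml --out run
```

prints (abridged):

```
[clean] taxa union=250 shared=242 (97%) kelly-only=2 (1%) mifish-only=6 (2%)
[alpha] richness 24-51; GLM slope=-0.00020/km z=-2.06 AIC=255.11
[beta] jaccard:    Mantel r=0.6075 p=0.0010
[beta] turnover:   Mantel r=0.5924 p=0.0010
[beta] nestedness: Mantel r=-0.2709 p=1.0000
[cluster] Hopkins statistic: 0.719
measure              type        method   k
connectivity     Internal  hierarchical   2
dunn             Internal  hierarchical   9
silhouette       Internal  hierarchical   4
APN             Stability           pam   2
ADM             Stability           pam   2
[cluster] k=4: same-cluster adjacent pairs per cluster {1: 9, 2: 9, 3: 9, 4: 9}
```

Reading the output: richness spans 24–51 taxa and falls with distance
from the outlet (negative GLM slope); community dissimilarity increases
with river distance and the signal sits in the turnover component, not
nestedness (its Mantel r is negative and non-significant) — i.e. sites
replace taxa along the network rather than being nested subsets. The
Hopkins statistic (≈0.72) says the site×taxon matrix is genuinely
clusterable, the validation measures mostly support small k, and at
k = 4 the cut recovers the four planted river zones perfectly: every
cluster is spatially contiguous (9 adjacent same-cluster pairs = all 9
within-river neighbour pairs). `run/manifest.json` records every
parameter, seed, output checksum and stage timing.

Each stage is also available separately (`riverdiv simulate | clean |
alpha | beta | cluster`, see `--help`), reading/writing plain TSV/CSV,
Newick and JSON files.

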