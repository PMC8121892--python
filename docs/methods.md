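# Methods

`riverdiv` analyses catchment-scale fish-community composition derived
from eDNA metabarcoding: per-sample taxon read-count tables from two 12S
assays, taken as six replicate water samples per site along a river
network, are cleaned, merged, and summarised into alpha-diversity,
beta-diversity and biogeographical-clustering results. This note records
the models, the parameter choices, and the reasoning behind the open
design decisions.

## Cleaning model

Contamination is controlled by two incidence filters, applied per assay
before any merging:

1. **Low-frequency filter.** Within each sample, a taxon whose count is
   *strictly below* `fraction x (sample's total reads)` is zeroed, with
   `fraction = 0.001` by default. The threshold uses the pre-filter
   total and is applied in a single pass: iterating the filter would
   make the result depend on the iteration order and has no biological
   rationale. The per-sample (rather than per-run) total matches the
   view that index-hopping and low-level carry-over scale with a
   sample's own sequencing depth.
2. **Negative-control subtraction.** For each taxon, the maximum count
   observed in any filtration blank is subtracted from every real
   sample (floored at zero), and the blanks are dropped. The global
   maximum over all blanks is used because no blank-to-batch pairing is
   assumed; this is the more stringent choice.

The default order is filter → subtraction; the reverse order is
supported (`negatives_first`) because the choice is not forced by any
principle — with typical blank counts (tens of reads) versus sample
thresholds (tens of reads at ~20k depth), the two orders rarely differ.

Replicates are merged per site either as a presence union or as
per-taxon maxima; the two assays are merged by the per-cell maximum
over the union taxon universe (absent columns are explicit zeros). The
max-merge is robust to one assay failing to amplify a taxon that the
other detects reliably, at the cost of adopting the noisier assay's
counts where both amplify. Identities that hold by construction —
commutativity, idempotence, and presence∘max-merge = union-of-presences
— are asserted in the test-suite.

## Spatial model

The river network is an undirected weighted graph (a tree for dendritic
catchments) with edge lengths in km and one designated outlet. All
spatial covariates are along-channel shortest-path lengths (Dijkstra);
"distance" never means Euclidean map distance. On trees the matrix
satisfies d(i,j) = d(i,outlet) + d(j,outlet) − 2·d(lca,outlet), which
the tests verify against exhaustive path enumeration.

## Alpha diversity

Local richness is the row sum of the presence matrix. Its decay with
distance-to-outlet is fitted as a Poisson GLM with log link,
log μ = β0 + β1·d (d in km), by IRLS to relative tolerance 1e-8
(statsmodels backend; an independent Newton–Raphson maximiser is the
test oracle). The Wald z of β1 is the headline statistic. No
overdispersion correction is applied (scale fixed at 1), matching the
ordinary Poisson `glm()` convention.

Species accumulation curves use the exact hypergeometric expectation
E[S(k)] = S_obs − Σ_i C(N−n_i, k)/C(N, k), evaluated through log-gamma.
The standard deviation is always estimated from seeded site-order
permutations (default 1000) even when the mean is exact, since the
curves are reported as mean ± SD and the exact variance adds little.

Environmental variables (altitude m, width m, pH, conductivity µS/cm,
TDS mg/L) mix units, so the PCA operates on the correlation matrix;
loadings' signs are fixed by making each component's largest-magnitude
loading positive so runs are bit-reproducible.

## Beta diversity

Pairwise Jaccard dissimilarity is additively partitioned into turnover
and nestedness-resultant components (Baselga's incidence-based scheme):
β_jac=(b+c)/(a+b+c), β_jtu=2min(b,c)/(a+2min(b,c)), β_jne=β_jac−β_jtu.
A pair of empty communities is defined as dissimilarity 0 (the 0/0 case
must be fixed by convention; "identical, both empty" is the least
surprising reading) and is warned about upstream by the cleaning stage
when a site loses all taxa.

The Mantel test correlates strictly-lower-triangle entries and builds
its null by simultaneously permuting rows/columns of the second matrix.
Defaults: 999 permutations, one-tailed "greater" (the ecological
convention for distance decay), add-one p-correction so p is never 0.
Both the statistic and the p-value are cross-checked against scikit-bio
and vegan in the tests; small-n p-values are checked against the exact
distribution over all n! permutations.

## Clustering and validation

The clustering input is the cross-assay max-count site×taxon matrix,
untransformed, with Canberra distance — counts act as a relative signal
proxy, and Canberra's per-variable normalisation keeps high-count taxa
from dominating. Zero-in-both variables contribute 0 and the sum is
*not* rescaled by the number of contributing terms (a documented dialect
difference from R's `dist`, which rescales; the tests therefore compare
against R on all-positive data where the dialects agree).

Methods: agglomerative hierarchical clustering with the ward.D2
Lance–Williams update (authored here so tie-breaking — smallest
original-index pair — is explicit; merge heights are verified against
scipy's ward and R's `hclust(..., "ward.D2")`), Lloyd k-means (best of
25 random starts), PAM (BUILD + steepest-descent SWAP, exactly the
classical algorithm; see the caveat in the tests that single-swap
descent can stop in a local optimum, as R's `cluster::pam` does on the
same instances), and DIANA (Macnaughton-Smith divisive splitting of the
largest-diameter cluster). A SOTA-style method is deliberately not
included; the method registry accepts additional callables.

Validation follows the clValid measure set. Internal: connectivity
(neighbourhood L = 10, capped at n−1), Dunn index, mean silhouette
(singletons score 0). Stability: APN, AD, ADM and FOM under
leave-one-taxon-column-out reclustering with the same method, k and
seed, so the perturbation is isolated to the column deletion. All four
are recomputed in the tests by an independent plain-loop reference.
Optima per measure use each measure's direction with ties resolved to
the smallest k, then method order. Clustering tendency is quantified by
the Hopkins statistic (m = max(2, ⌊0.1n⌋) sampled rows vs uniform
pseudo-points in the min–max box) — ≈0.5 for spatial randomness, →1 for
clustered data.

Cluster labels are projected back onto the network as a site→cluster
table plus, per cluster, the count of network-adjacent same-cluster
pairs (adjacency contracts junction-only paths), a simple spatial-
coherence summary of the biogeographical units.

## Synthetic data

The generator emulates the assumed study design, not sequencing
chemistry (no reads/FASTQ, chimeras or misassignment). Defaults define
the study conditions and are sized to a realistic single-campaign
catchment survey:

- **Network**: 4 rivers × 10 sites (40 sites; one river is the
  mainstem), lognormal edge lengths (median 60 km, σ_log 0.45) giving
  ~16–180 km between neighbours; tributaries join the mainstem at evenly
  spread junction sites. Environmental covariates follow the river
  continuum (altitude rises upstream, width/conductivity fall) with
  Gaussian noise.
- **Communities**: 250-taxon pool. Cosmopolitan taxa get a niche
  optimum uniform along the catchment with a Gaussian occupancy kernel
  (σ = 250 km) and baseline occupancy 0.55·exp(−0.0008·d) decaying
  upstream, producing local richness of roughly 20–55 downstream-to-
  upstream. Zone-private taxa (fraction = `zone_effect`, default 0.6)
  are modelled as zone specialists: flat occupancy 0.5 inside their
  zone's rivers, zero outside — a planted, recoverable biogeographic
  signal. Scenarios: `null` (no structure), `distance_decay`
  (σ = 150 km, no zones), `two_zone`, `four_zone`.
- **Reads**: per replicate, depth ~ lognormal(10, 0.4) (~22k reads)
  allocated multinomially over the site's present taxa with site-level
  lognormal relative abundances scaled by per-taxon Beta(8,2)
  amplification efficiencies; 6 of 250 taxa are absent from the kelly
  assay's reference and 2 from the mifish reference (zero efficiency).
  Each sample gains ~Poisson(2) random contaminant taxa at relative
  weight 8e-4 (≈18 reads), restricted to taxa the assay can amplify
  (contamination precedes PCR); negatives carry only contamination
  (~Poisson(60) total reads).

Passing recovery tests on these data shows the pipeline's statistics
behave correctly *under this generative model*; real eDNA data add
overdispersion beyond multinomial, taxon misassignment, spatially
correlated contamination and eDNA transport between sites, none of
which are modelled. The lognormal-multinomial read model is a stated
assumption, not an inference from data.

## Problem sizes and numerical choices

The test-suite and the acceptance script run the recovery analyses at
the generator's default scale (40 sites, 250 taxa): 10 seeds for
zone-recovery ARI and GLM sign recovery, 200 simulations for Mantel
type-I calibration (199 permutations each), one full validation grid
(4 methods × k = 2..10 × 7 measures with leave-one-column-out
stability) on the two-zone scenario. Oracle-equivalence checks run at
n ≤ 20 where exhaustive enumeration is feasible.

Floating-point conventions: partition additivity is exact to 1e-12;
ward.D2 under-sqrt values are clamped at 0; distance matrices are
symmetrised after Dijkstra to remove summation-order noise; all
stochastic stages take explicit seeds and derive per-stage substreams
from fixed offsets.

## Known limitations

- PAM's SWAP is the classical steepest descent; on a small fraction of
  instances it terminates in a swap-local optimum (verified to match R's
  reference implementation on such instances).
- DIANA's flat clustering is obtained by successive largest-diameter
  splits (equivalent to cutting the divisive hierarchy at the k−1
  largest division diameters).
- The exact Hopkins variant (sampling fraction, distance exponent) is a
  convention; the implemented one uses the min–max bounding box and
  Euclidean nearest neighbours, m = ⌊0.1n⌋.
- Negative-control subtraction assumes blanks bound contamination for
  *all* samples; day-paired designs would need the (unimplemented)
  per-batch variant.
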