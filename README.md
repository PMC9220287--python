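# betageo

Biogeographical analysis of regional presence/absence faunas: β-diversity
partitioning, spatially aware correlation and permutation inference, AICc
multimodel averaging, and non-metric multidimensional scaling (NMDS) with
geographic RGB mapping.

The package is aimed at macroecologists working with coarse regional
checklists — a binary species × region incidence table plus per-region
centroids, area and climate — who want to ask: is species richness driven
by climate or by isolation (peninsula effect)? Is compositional turnover
between regions explained by climatic differences, by geographic distance,
or by a residual historical signal that neither explains? A synthetic-data
generator emulating a 17-region peninsular system with an 88-species fauna
of two suborders (weak and strong dispersers) makes every stage testable
without any external data.

## The statistics at its core

For two regional faunas with `a` shared species and `b`, `c` exclusive
species, total dissimilarity is partitioned into spatial turnover and
nestedness-resultant components:

    βsor  = (b + c) / (2a + b + c)         (1 − Sørensen similarity)
    βsim  = min(b,c) / (a + min(b,c))      (1 − Simpson similarity)
    βnest = βsor − βsim

These matrices are compared to geographic (great-circle, between centroids)
and climatic (Euclidean on z-scored variables) distance matrices with
Mantel and partial Mantel permutation tests (add-one p-value estimator,
999 permutations by default). Richness models use all-subsets OLS ranked by
AICc = −2 logL + 2k + 2k(k+1)/(n−k−1), with full-model averaging of the
ΔAICc ≤ 2 set (zero substitution, Burnham–Anderson unconditional SE).
Richness and similarity gradients are tested with Pearson correlations,
pre-screened for spatial autocorrelation with Moran's I and corrected with
Dutilleul's modified t-test (effective sample size from distance-class
autocovariances) when the pre-test fires. Biogeographical structure is
drawn with restart NMDS (Kruskal stress-1, Procrustes agreement between
restarts) and a four-corner blue/green/yellow/red bilinear colour map.
The Smith–Bermingham random-split test splits the species pool in two at
random and partial-Mantel-tests the two halves' dissimilarity matrices
against each other controlling geography or climate: a significant residual
association is a historical signal.

## Worked example

```python
import betageo

regions, occ, areas = betageo.scenario("climate_only", seed=3)
triplet = betageo.dissimilarity_matrices(occ)
geo = betageo.geographic_distance_matrix(regions)
clim = betageo.climate_distance_matrix(regions)

m = betageo.mantel_test(triplet.beta_sor, clim, n_permutations=199, seed=1)
print(f"Mantel r(beta_sor, climate) = {m.statistic_r:.3f}, p = {m.p_value}")

res = betageo.nmds(triplet.beta_sor, n_restarts=20, seed=1)
print(f"NMDS stress-1 = {res.stress:.3f} after {res.n_restarts_used} restarts")
```

prints

```
Mantel r(beta_sor, climate) = 0.803, p = 0.005
NMDS stress-1 = 0.122 after 20 restarts
```

meaning compositional dissimilarity between regions tracks their climatic
distance (r = 0.803, the smallest attainable p at 199 permutations), and the
two-dimensional NMDS map summarises the 17 × 17 dissimilarity structure
with a stress of 0.122 — a usable, moderately faithful ordination.

The same analyses are scriptable from the shell:

```sh
betageo simulate --scenario historical --seed 3 --out sim/
betageo run --occurrences sim/occurrences.csv --regions sim/regions.csv \
            --areas sim/areas.csv --out results/
```

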