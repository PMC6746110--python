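# anatidiv

Community-level biodiversity analysis for gridded presence/absence data,
built around the breeding-waterfowl (Anatidae) study design: global
1°-cell "communities", a species pool with a phylogeny ensemble and a
mixed-type trait table, and the question of whether local assemblages are
random draws from that pool or shaped by environmental filtering
(clustering) and competition (overdispersion).

The package computes, for every grid cell:

* **TD** — taxonomic diversity, the species richness of the cell;
* **PD** — Faith's phylogenetic diversity, the branch-length sum of the
  tree subgraph connecting the cell's species, averaged over an ensemble
  of trees: `PD(S) = Σ_{e ∈ spanned(S)} ℓ(e)`;
* **FD** — dendrogram functional diversity (Petchey & Gaston style): the
  same branch sum on an ultrametric UPGMA dendrogram built from Gower
  dissimilarity (`D = 1 − S`) over 14 mixed-type traits.

Departures from randomness are judged with tip-shuffle null models: 999
re-allocations of species across tree tips (preserving topology, branch
lengths and each cell's richness) give each cell a null distribution,
summarized as a standardized effect size `SES = (obs − mean_null)/SD_null`
and a quantile score (≤ 25 → significantly low, ≥ 975 → significantly
high).  Faunal regions come from UPGMA on pairwise Sørensen dissimilarity
`1 − 2a/(2a+b+c)` after dropping low-richness cells, and environmental
drivers are modeled per hemisphere with random forests (1,000 trees, 11
candidate predictors per split) on a VIF-screened predictor set, reporting
out-of-bag variance explained, permutation importance scaled to sum 100,
minimal-depth ranks and partial-dependence curves.

Because the original global inputs (range polygons, climate and
vegetation-index rasters) are large GIS products, the package ships a
first-class synthetic-data generator that emulates all four inputs —
birth-death tree ensembles, Brownian traits, a gridded environment with a
latitudinal seasonality gradient and a dekadal NDVI stack, and communities
assembled under *neutral*, *filtering* or *limiting-similarity* processes
— with known ground truth for recovery tests.

## Worked example

The analysis is organised as numbered drivers over the library
(`analysis/01_simulate_inputs.py` … `06_environmental_drivers.py`); the
same stages are available as `anatidiv` CLI subcommands (`simulate`,
`dendrogram`, `nulls`, `regions`, `run-all`).  Running the drivers in
order on the default two-hemisphere demo (filtering in the north,
limiting similarity in the south; seed 0) prints:

```
$ python analysis/01_simulate_inputs.py --seed 0
wrote inputs for 300 communities x 60 species to results/inputs
richness: mean 8.6, range 1-23; 7 southern cells exhausted the pool early

$ python analysis/03_diversity_maps.py
Pearson r: TD~PD 0.912, TD~FD 0.903, FD~PD 0.970
mean TD north 10.2 vs south 6.7 (the planted latitudinal gradient)

$ python analysis/04_null_models.py --seed 0
FD: median SES north -1.20 (lower calls 35), south +1.42 (higher calls 42)
PD: median SES north -1.42 (lower calls 58), south +0.71 (higher calls 7)
```

The three indices covary tightly (r > 0.9), northern communities are
functionally and phylogenetically clustered (negative SES, many
"significantly lower" calls — the signature of the planted environmental
filtering), and southern communities are overdispersed (positive SES) —
the contrast the pipeline is designed to detect.  `05_faunal_regions.py`
writes the cluster labels and the within-group dissimilarity curve over
k = 1..15, and `06_environmental_drivers.py` reports, per hemisphere and
index, the OOB variance explained and the top-ranked predictors (on the
demo, the retained seasonality proxies dominate the northern models).

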