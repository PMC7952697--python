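# neritrema

Mating-pattern analysis for the five sympatric *Littorina* (*Neritrema*)
periwinkle species of the North Atlantic intertidal — *L. saxatilis*,
*L. arcana* and *L. compressa* (the "saxatilis" cryptic-species group),
and *L. obtusata* and *L. fabalis* (the "obtusata" group).

The package is for ecologists and evolutionary biologists who observe
copulating pairs in the field and want to quantify **premating
reproductive isolation**: does each species mate with conspecific
females more often than random encounters would predict, and how strong
is the precopulatory barrier between each species pair?

## The statistics

**Random-mating null model.** Within a stratum (site-year × intertidal
level), every adult snail — male, female, or immature/trematode-castrated
(ITC) — is a potential *passive* partner with probability equal to its
category's share of the quadrat-census composition,
`P_A' = A′ / (A′ + B′ + C′ + …)`. The *active* (penis-inserting) male
categories get probabilities from the copulating pairs themselves,
`P_a = a / t` (species differ in copulatory activity). The expected
count for each cell is the product

```
S_aA' = P_a · P_A' · t
```

with `t` the total weighted pair count. Male-male pairs, whose active
partner cannot be determined, count 0.5 toward each of the two possible
orderings.

**Fidelity Index (FI).** For a focal male category,

```
FI = (O_consp − S_consp) / Σ_i S_i,focal
```

the observed minus expected number of copulations with conspecific
mature females over the summed expected copulations of that male
category (−1 avoidance, 0 random mating, 1 assortative). A female-side
mirror measures how often a female category is engaged by conspecific
males.

**Precopulatory isolation index (I_PC).** For a species pair (X, Y),
with `r_ij = O_ij / S_ij` over the four male × mature-female cells,

```
I_PC = (r_XX + r_YY − r_XY − r_YX) / (r_XX + r_YY + r_XY + r_YX)
```

(−1 disassortative, 0 random, 1 complete assortment). Both indices come
with bootstrap means, standard deviations and two-tail p-values for the
random-mating null (pairs resampled within stratum, census held fixed).

**Combination clustering.** The binary matrix of ever-observed partner-
type combinations is compared column-wise (active males) and row-wise
(passive categories) with the simple mismatch coefficient
`SMC = (f_10 + f_01) / (f_11 + f_10 + f_01 + f_00)` and clustered with
UPGMA.

**Size structure.** Paired t-tests of partner height differences,
permutation tests of partner-size correlation, a within-quadrat
random-pairing Monte-Carlo null for that correlation, and a
rank-variance permutation test of spatial segregation by size.

A synthetic-data generator (`neritrema.simulate`) emulates the quadrat
censuses and the mating process with tunable species preference and
size assortment, so every stage is testable without field data.

## Worked example

The packaged fixture transcribes the study's full pair table
(317 copulating pairs from two Barents Sea sites over three seasons):

```python
>>> import neritrema as nt
>>> records = nt.load_table2_pairs()
>>> s = nt.summary_counts(records)
>>> s["total_pairs"]
317.0
>>> s["pairs_by_class"]
{'conspecific_female': 191.0, 'heterospecific_female': 19.0,
 'male_male': 59.0, 'immature_or_castrated': 48.0}
>>> s["mature_female_pairs_by_active_species"]["saxatilis"]["conspecific"]
82.0
```

60% of all pairs (191/317) are potentially productive matings with a
conspecific female; *L. saxatilis* males were with conspecific females
in 82 of their 86 mature-female pairs. On synthetic data the indices
recover the generating regime:

```python
>>> from neritrema.indices import FidelityIndex
>>> cfg = nt.scenario("random")           # uniform preferences, no size effect
>>> pop = nt.simulate_population(cfg, seed=1)
>>> pairs = nt.simulate_matings(pop, cfg, seed=2)
>>> est = nt.bootstrap_index(pairs, pop, FidelityIndex("saxatilis"),
...                          cfg.strata[0].stratum, n_iter=1000, seed=7)
>>> round(est.point, 4), round(est.boot_sd, 4)
(-0.0006, 0.0066)
```

FI is indistinguishable from 0 under random mating, as it should be.

The same analyses run from the shell:

```bash
neritrema summarize --out out/summary              # packaged field data
neritrema simulate --scenario assortative --out out/sim --seed 42
neritrema all --pairs out/sim/pairs.csv --census out/sim/census.csv \
    --out out/run --seed 7
```

Each run writes CSV tables (expected frequencies, index estimates in
the study's table layout, size tests), Newick dendrograms, and a
manifest with checksums for exact reproduction.

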