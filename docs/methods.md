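# Methods

## The model of random mating

The analysis unit is the stratum: one site-year at one intertidal level
(upper vs lower), because the species sets of the two levels differ.
Under the null hypothesis of random mating every adult snail
(`older_than_one_year`) in a stratum — male, female or
immature/trematode-castrated (ITC) of any species — is an equally
likely passive partner, so passive-partner probabilities equal category
shares of the quadrat census. Active-male probabilities are estimated
from the copulating pairs themselves rather than the census, because
species differ in copulatory activity; this makes the expected matrix
`S_ij = P_active(j) · P_passive(i) · t` conserve each active column
total exactly (`Σ_i S_ij = a_j`). The model deliberately ignores
habitat preference and spatio-temporal activity: it estimates the
hypothetical chance of encountering partners of each category, which is
precisely what the isolation indices are measured against.

Census composition is estimated by pooling all quadrats in a stratum
(the default; quadrat areas are equal at 0.04 m²). Averaging
per-quadrat proportions instead is available via
`composition_method="per_quadrat"` for sensitivity analysis.
Eligibility is the `older_than_one_year` flag alone; no size filter is
applied. Passive categories observed in copulation but absent from the
census have undefined expected frequencies; those records are excluded
from the stratum's table and the exclusion is logged.

## Counting conventions

A male-male pair, whose active partner cannot be determined in the
field, is stored as two records of weight 0.5 with swapped roles and a
shared `pair_id`; weights therefore always sum to the number of
physical pairs, and weighted counts are kept as exact halves, never
rounded. A mating is classified *conspecific* when the passive partner
is a mature female of the active male's species; for 1.5-row males
(intermediate penial-gland morphology, presumed *saxatilis* × *arcana*
hybrids) both *L. saxatilis* and *L. arcana* females count as
conspecific. ITC snails carry only their species-group label — in the
CSV schema their species column holds the group token
(`saxatilis_group` / `obtusata_group`).

## Indices and bootstrap

`FI_male = (O_consp − S_consp) / Σ_i S_i,focal`, with the denominator
equal to the focal males' observed weighted total by column
conservation; hence `−1 ≤ FI_male ≤ 1`. The female-side index is the
exact mirror, dividing by the summed *expected* matings received
(`q_focal · t`). Because a female category's observed matings are not
constrained by that expectation, the female index is bounded below by
−1 but can exceed 1 under strong assortment; it is reported as is.
FI is not computed for 1.5-row males (their species, and hence their
conspecific class for the female-side comparison, is uncertain), and
1.5-row males are excluded from I_PC. I_PC uses only mature-female
cells and requires all four expected cells positive; a pair-stratum
failing this is excluded and logged. I_PC is computed per stratum,
never pooled.

Bootstrap inference resamples copulating-pair records with replacement
within the stratum at the observed sample size; male-male halves are
resampled as their whole pair so the 0.5-count structure is preserved.
The census composition is held fixed: the null hypothesis concerns the
mating pattern, and composition comes from a separate sampling design.
Each replicate recomputes observed counts and active frequencies and
re-evaluates the index. Replicates where the index is undefined (an
active category resampled to zero) are dropped and counted; estimates
with more than half the replicates dropped are flagged invalid. The
two-tail p-value for H0: index = 0 is
`min(1, 2·min(#{x ≤ 0}+1, #{x ≥ 0}+1)/(B+1))` — the +1 correction
avoids reporting p = 0. Defaults: B = 10 000 and a mandatory explicit
seed.

## Combination clustering

A combination is "present" if it occurs with non-zero weight in any
stratum. The simple mismatch coefficient includes joint absences in its
denominator (it is 1 minus the simple matching similarity), which is
appropriate here because a shared *absence* of a partner type is
informative about mating-spectrum similarity. UPGMA places a cluster
joined at distance d at height d/2 and serializes branch lengths as
height differences, giving an ultrametric tree (verified to 1e−9).
Ties during agglomeration are broken deterministically by sorting
labels before clustering. Zero-length comparison vectors are rejected
rather than assigned distance 0.

## Size statistics

Paired t-tests of active-minus-passive shell height run per active
species × stratum × mating class, only where ≥ 5 complete pairs exist
(smaller groups are skipped with a log entry); male-male pairs and
records lacking a height are excluded. The partner-size correlation
test shuffles passive heights (10 000 permutations, +1-corrected
two-sided p on |r|); for n ≤ 9 with enough requested permutations it
switches to exact enumeration of all n! arrangements. The
random-pairing Monte-Carlo null pairs males with mature conspecific
females without replacement within each quadrat, up to the smaller sex
count — the without-replacement rule and pair count per quadrat are
implementation choices (the alternative was unstated); quadrats are
processed in a canonical content-sorted order so p-values are invariant
to quadrat relabeling.

The segregation-by-size test splits the focal species at the
stratum-wide median ("local median" is read as per-stratum, not
per-quadrat — a per-quadrat split would force near-balanced ranks in
every quadrat and nullify the test); ties at the median go to the small
class. The statistic is the mean over quadrats (≥ 2 individuals) of the
per-quadrat *population* variance (divide by n) of the 0/1 ranks, so
each quadrat's contribution lies in [0, 0.25]; the population-variance
convention matters only for matching oracles since the statistic is
compared to its own permutation null. Low values indicate
size-homogeneous quadrats, i.e. spatial segregation;
p = (#{null < observed} + 1)/(n_perm + 1). Censuses whose focal ranks
are all one class are flagged degenerate.

## Synthetic data

`simulate_population` draws, per quadrat, Poisson species counts with
configurable sex ratio, ITC fraction and log-normal shell heights
(defaults: densities 3–12 adults per 0.04 m² quadrat, ~55% female, 20%
ITC, median heights 4.5–10 mm — magnitudes typical of dense intertidal
*Littorina* assemblages). `simulate_matings` draws the active male
category proportionally to activity weight × male abundance and the
passive partner proportionally to composition × preference Ψ × a
Gaussian kernel in height difference,
`exp(−β (h_active − h_passive − δ)²)`; δ < 0 reproduces the
males-smaller-than-mates pattern typical of gastropods. Passive
partners are sampled with replacement across pairs (the species are
polygamous); a male cannot be drawn as his own partner. With
probability `male_male_rate` the passive partner is drawn among males
and the pair is emitted as two 0.5-weight records; `male_male_rate =
None` matches the population's male share, in which case — with uniform
Ψ and β = 0 — the generator reduces exactly to the null model, which is
the basis of the Monte-Carlo equivalence checks and the FI calibration.

What the generator does *not* emulate: spatial micro-habitat structure
within a stratum (quadrats differ only by sampling noise), tidal or
seasonal dynamics, trail-following behaviour, and observation biases
such as the shorter duration of male-male copulations. Passing tests
therefore demonstrate statistical correctness of the estimators under
the stated sampling model, not robustness to those field complications.

## Calibration studies and problem sizes

The FI calibration simulates the `random` scenario (one stratum, five
species, 10 quadrats, 10 000 pairs) 500 times, bootstrapping each with
B = 1000; mean FI is required within ±0.02 of zero and the rejection
rate at α = 0.05 within two-sided binomial 95% bounds. The segregation
type-I study uses 500 i.i.d. censuses (8 quadrats, ~12 snails each,
log-normal heights) at 400 permutations each. Exhaustive-enumeration
oracles run at n = 4 pairs (24 permutations) for the correlation test
and 3 quadrats × 4 snails (binomial(12, k) arrangements) for the
segregation test. These sizes give Monte-Carlo error well inside the
asserted tolerances while keeping the full suite to a few minutes.

## Field-data transcription

The packaged `table2_pairs.csv` reconstructs the study's per-stratum
pair table as weighted records, with passive species assignments chosen
to satisfy, simultaneously: the per-stratum totals, the global mating-
class split, the per-species conspecific/heterospecific counts stated
in the text, the observed-combination matrix (`table3_combinations.csv`),
and 14 heterospecific male-male pairs. Where the published sources are
internally inconsistent (two different statements of the number of
*L. arcana*-male pairs with conspecific females), the transcription
follows the rendered pair table. Shell heights are not part of the
published table, so the fixture carries none and size analyses on it
are skipped; synthetic data exercises those paths. Tests that need a
census for these strata use a clearly-labelled synthetic stand-in
composition, since the study's quadrat compositions are only available
as unpublished supplementary material — printed FI/I_PC values are
therefore not reproduction targets, but all of their analytic
properties are verified.
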