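# Methods

## The analysis in brief

A PTR–ToF–MS screening campaign produces a samples × mass-peaks matrix of ion
count rates. The package converts these to headspace concentrations, removes
channels indistinguishable from blank vials and channels that are isotopologue
shadows of other peaks, and then asks two questions of the surviving matrix:
whether species separate in multivariate distance space (PERMANOVA, within- vs
between-group distance tests, dendrogram concordance with a sequence-side
phylogeny) and which individual peaks carry the separation (per-peak omnibus
tests and a ratio-threshold classification into generally increased vs
species-specific peaks).

## Concentration model

The ppbV conversion uses the standard proton-transfer kinetics: the analyte
number density is `[R] = I_RH⁺ / (I_H₃O⁺ · k · t)` with a single average rate
constant k = 2.0×10⁻⁹ cm³ s⁻¹, and the mixing ratio divides by the air number
density `N_air = P/(k_B T)` at the drift-tube conditions (defaults 2.8 mbar,
383.15 K). The reaction time t is instrument-specific (drift-tube geometry) and
enters only as a global linear factor; every downstream statistic —
correlations, distances up to scale, ratios, rank tests — is invariant to it,
so its default (10⁻⁴ s) is a placeholder, and concentrations are "absolute in
arbitrary units". For the same reason it is immaterial whether the correlation
filter runs on counts or on ppbV; the package runs it after conversion.

## Filtering

**Blank filter.** A peak is kept iff a one-sided test (cultures > blanks)
rejects at α = 0.05. The default test is the Mann–Whitney rank-sum — robust to
the heavy right tails of concentration data — with Welch's t as a config
alternative. No multiplicity correction is applied at this stage: the cost of
a false keep (one noise channel) is far below the cost of silently discarding
a real compound, and the downstream tests are unaffected by a few retained
noise channels.

**Correlation filter.** Peaks are visited in ascending m/z; a peak is removed
when its |Pearson r| with any already-kept peak exceeds 0.99 (strict
inequality, with a 10⁻¹² slack so a correlation of exactly 0.99 keeps both).
Ascending m/z makes the survivor the lighter member of each correlated pair,
which is the monoisotopic parent of an isotopologue (a ¹³C twin sits ~1.003 Th
above its parent at a fixed abundance ratio). Highest-mean-signal ordering is
available via config. Constant columns have undefined r, treated as 0 and kept.

## Distance statistics

PERMANOVA partitions the squared Euclidean distances:
`SS_T = Σ_{i<j} d²_ij / n`, `SS_W = Σ_g Σ_{i<j∈g} d²_ij / n_g`,
`F = (SS_B/(k−1)) / (SS_W/(n−k))`, `R² = SS_B/SS_T`. The p-value uses the
`(1+count)/(1+B)` estimator, so with B = 999 the smallest attainable p is
0.001; an exhaustive mode enumerates all distinct relabelings for small
designs and reports `count/total`. One factor is tested at a time (species,
location, season, isolation matrix, technical replicate); sequential
multi-factor partitioning is deliberately out of scope because heterogeneous
species-by-site distributions make those effects inseparable — per-factor R²
is reported and that limitation documented here.

The within/between test partitions the strictly-upper-triangle distances by
same/different group and applies a one-sided rank-sum (within < between),
using the exact null distribution when there are ≤ 40 pairs (ties otherwise
force the asymptotic approximation and misstate the minimal attainable p).
The pairs share samples and are therefore not independent; the test is used
as in common practice, and its null calibration on structureless data is
verified by simulation in the test suite (rejection ≈ nominal at α = 0.05).

Mantel correlates the upper triangles of two distance matrices and permutes
the row/column order of the second jointly, two-sided by default, with an
exhaustive mode for tiny n. Kruskal–Wallis uses mid-ranks with the standard
tie correction (all-identical data are defined as H = 0); Levene defaults to
group-median centering (Brown–Forsythe); Dunn's z-statistics use pooled
mid-ranks with tie correction and Holm's step-down adjustment over all pairs;
Tukey HSD is delegated to scipy. Holm: sort ascending, multiply p(i) by
(m−i+1), enforce monotonicity, cap at 1.

## Peak classification

Measurements are divided by their sample's mean peak concentration, making
every row mean exactly 1 and the procedure invariant to global rescaling.
A peak is a **candidate** iff some strain has all of its technical replicates
above ratio 1. For each candidate the per-species fraction of measurements
above the threshold is computed over all technical replicates of all strains
of the species (the natural reading of "measurements performed within each
species"; strain-level aggregation is not distinguished). A candidate is
**generally increased** if that fraction is ≥ 0.60 in *every* species.
Otherwise the enriched set is the species with fraction > 0.50; the peak is
**species-specific** if that set has 1–3 members ("one or a few" is
operationalized as at most 3, configurable) *and* the set accounts for more
than half of all the peak's above-threshold measurements. The last condition
operationalizes the word "only" in "above ratio 1 in > 50 % of the technical
replications of only one or a few species": a genuinely enriched peak has
essentially all of its above-ratio occurrences inside its enriched species,
whereas a baseline peak that merely straddles the sample mean scatters its
occurrences over all species and would otherwise be called specific whenever
1–3 species clear 50 % by chance. The condition can be disabled
(`require_confinement=False`) to obtain the bare fraction rule. Candidates
meeting neither rule stay **unclassified**, preserving the accounting
candidates = general + specific + unclassified rather than forcing a
dichotomy.

Annotation is a nearest-mass lookup (tolerance 0.005 Th) against a shipped
reference table of tentatively identified peaks; carbon counts are parsed from
the protonated sum formula (the charge-carrying proton does not change the
count). The class contrast reports median m/z and median carbon count per
class with two-sided rank-sum p-values.

## Dendrograms

The species-level matrix takes the median over all cross pairs of two species'
samples (single-level median; not strain-median-then-median). "Average
clustering" is size-weighted UPGMA — inter-cluster distance is the mean over
all cross pairs — with WPGMA as a config alternative; merge heights are half
the merge distance, so cophenetic distances reproduce merge distances, and
UPGMA is exact on ultrametric input. Ties are broken by the lexicographically
smallest pair of cluster representatives, making the tree deterministic.
Topology comparison uses the Robinson–Foulds distance over internal
bipartitions of the unrooted topologies (normalized by 2(n−3)) plus the
Pearson correlation of cophenetic distances — a deliberate quantitative
strengthening of the side-by-side visual comparison such studies usually
present. The sequence side accepts any precomputed distance matrix (remaining
agnostic about whether it came from ML branch lengths or raw distances) or
computes p-distances from an alignment with pairwise deletion of gaps and
ambiguity codes.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design: `n_species = 13` species ×
`strains_per_species = 5` biological × `tech_reps = 3` technical replicates,
`n_blanks = 6` blank vials, 403 raw peaks of which 139 are signal (including
~10 % isotopologue twins) and 264 noise. Baseline concentrations are
log-normal (median 2 ppbV, log-sd 0.8): concentration data are right-tailed,
and log-normal is the simplest matching family. Species-specific peaks sit at
trace level in most species and at an ordinary signal level (median ~10 ppbV,
chosen so enriched values clear the sample mean decisively) in their enriched
species; the enrichment factor is log-uniform on [100, 1000]. Generally
increased peaks carry a 5× fold in every species. General peaks draw m/z from
a light window (median ≈ 61 Th) and specific peaks from a heavier one
(median ≈ 93 Th), echoing the observation that broadly shared VOCs are smaller
molecules than species-specific ones.

Biological (between-strain, log-sd 0.5) and technical (between-vial, log-sd
0.15) variability are each split into a dominant per-culture scalar — overall
emission intensity: growth vigor, colony size, headspace equilibration — and a
smaller peak-specific component (shares 0.4 and 0.3 of the log-sd,
respectively, preserving the stated totals per peak). The split matters: a
purely scalar model would make all flat signal columns perfectly correlated
(the correlation filter would eat them), while purely per-cell noise would
blur the ratio rules; the scalar-dominant middle reflects that most
replicate-to-replicate variation in headspace fingerprints is a common
intensity factor, which the ratio normalization then cancels. Species-specific
peaks get an extra independent between-strain factor (log-sd 0.4), reflecting
the high within-species heterogeneity of regulated compounds, which also keeps
two specifics of the same species from correlating like isotopologues.

Noise channels are sparse spikes around the detection limit (zero with
probability 0.85, else log-normal around 0.05 ppbV), drawn from the same law
in cultures and blanks, at strain level so that zero technical noise yields
identical replicate rows. Sparsity makes the blank-filter rank-sum p-values
heavily discrete: an exchangeable channel essentially never tests as "above
blank", so the filter removes noise channels completely while the channels
remain marginally exchangeable with blanks. Blank levels of signal channels
are 1 % of baseline. Isotopologue twins copy their parent column times an
abundance scalar (uniform on [0.02, 0.15]) with 0.5 % per-strain jitter,
guaranteeing |r| > 0.99.

For the phylogeny comparison the generator draws a random ultrametric species
tree (uniform pair merges at heights increasing by U(0.25, 0.75), keeping
merge heights well separated), derives strain-level sequence distances from
its cophenetics (constant small within-species distance 0.02, optional
symmetric noise), and can lay volatilome species profiles at Euclidean
coordinates that realize the tree's cophenetic distances exactly (classical
MDS of the Gower-centered squared distances; ultrametrics are
Euclidean-embeddable). At zero noise the two sides are exactly concordant by
construction, which is what makes topology-recovery tests sharp.

What the generator does **not** emulate: raw ToF spectra and peak picking,
mass-axis drift, compound-specific rate constants and fragmentation,
correlated media/temperature batch effects, or any real phylogenetic signal in
which species effects and sequence divergence decouple. Passing tests
therefore show that the implementation recovers structure it is designed to
detect under a faithful rendering of the study design — not that the pipeline
is robust to every artifact of real instrument data.

## Numerical choices and degenerate inputs

Permutation tests take explicit seeds and record B; exhaustive modes enumerate
distinct label arrangements (identity included in the count). Constant columns:
r treated as 0 (correlation filter), H = 0 (Kruskal), p = 1 with undefined F
(ANOVA), NaN (Shapiro groups below n = 3, Levene with zero spread everywhere).
Zero or negative primary-ion signal, all-zero sample rows, missing blanks,
non-aligned sequences and malformed Newick all raise errors naming the
offending sample/field/position. The pipeline derives per-stage sub-seeds by
hashing `(seed, stage name)`, so disabling one stage does not shift another's
randomness; reports are byte-identical across reruns up to timestamps.

## Problem sizes

The shipped analysis and the acceptance script run the full design
(201 samples × 403 peaks) with B = 999 permutations; simulation-heavy checks
(null calibration, seed sweeps) use 10 seeds of the full design, 400
structureless 30-sample instances at B = 199, and exhaustive enumeration at
n ≤ 7 — sizes at which every permutation test is exact or well-resolved and
the whole battery completes in minutes on one core.

## Known limitations

One-factor PERMANOVA only; no PERMDISP companion test, so location/species
dispersion differences are not separated from location effects. The Mantel
test inherits its usual conservatism under autocorrelated distances. The
blank filter's lack of multiplicity correction trades a few false keeps for
recall, as discussed. The classification thresholds (ratio 1, 60 %, 50 %,
"few" = 3) are the procedure's definition, not estimates; sensitivity to them
is exposed via config rather than analyzed here.
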