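# Methods

## Sampling model and the gambit of the group

The observational unit is the instantaneous point sample: a focal
individual plus every individual within the proximity radius at that
instant. Each point sample is one sampling period — follows are not
collapsed — because association indices count periods, and collapsing a
10-minute follow into one row would discard the repeated-measures
structure the indices are built on. All members of {focal} ∪ neighbors
are treated as mutually associating (gambit of the group); this is the
standard resolution when only focal-centred proximity is recorded, and
it is exact for radii small enough that "within two body lengths of the
focal" implies mutual proximity. Point samples collected during any
individual's follow are pooled into one dataset: incidental proximity
records carry the same information as focal-centred ones under the
gambit, and pooling maximizes the per-dyad denominator.

Identifier matching is case-sensitive after whitespace stripping. Two
point-sample CSV dialects are accepted (long per-individual rows with a
role flag, and per-period neighbor-list rows); the long form is
canonical because it round-trips arbitrary ids without a reserved
delimiter.

## Simple ratio index

For an unordered dyad, SRI = x/(x + ya + yb + yab) with yNull = 0: a
period in which neither member is identified says nothing about the
dyad and is excluded from the denominator. Under single-focal sampling
every period contains one party, so yab (both identified, not
associated) is structurally zero; the per-row party partition is still
supported so that multi-party periods, if a data source provides them,
are counted correctly. A dyad whose denominator is empty (neither
member ever identified) gets SRI 0 rather than NaN — "no evidence of
association" — and is flagged in the matrix metadata, so downstream
metric code stays total. Mean association rates are arithmetic means
over unordered dyads with zeros included and sample (n−1) SDs; the
default is all dyads, with within-species and mixed-species filters as
parameters, since published colony-level means are reported over the
full mixed-species dyad set.

## Network and metrics

Edges are dyads with SRI strictly above a threshold (default 0), weight
= SRI. Conventions, chosen to match how such colony networks are
reported:

* **degree** is the binarized tie count, not weighted strength —
  published species means of order n−1 identify it as a count;
* **eigenvector centrality** is the principal eigenvector of the
  weighted adjacency (dense symmetric eigendecomposition), taken
  non-negative and rescaled so the maximum node scores 1; it is
  computed on the full matrix, so in a disconnected network the
  dominant component carries the mass. Near-degenerate components (two
  components with equal spectral radius) can mix arbitrarily; this is
  measure-zero for observed weights and is documented rather than
  special-cased;
* **betweenness** and **average path length** use geodesic length
  defined as the *sum of SRI weights* along the path — the sociogram
  convention in which tie weights are drawn as distances. This makes
  strong associations "long"; the conventional 1/weight distance is
  available via `distance="inverse"` but is not the default. Equally
  short paths share betweenness credit equally; betweenness is
  unnormalized pair counts;
* **clustering** is unweighted local clustering on the binarized
  network; degree < 2 nodes are undefined (NaN) and excluded from
  species means rather than scored 0, which would conflate "cannot
  cluster" with "does not cluster";
* **density** is |E| / C(n, 2). The identity mean degree = density ×
  (n−1) is used as a cross-check, including against the packaged
  published species-degree table.

Per-species summaries report arithmetic means and sample SDs per
metric, mirroring the group × species layout of published tables.

## Permutation inference

**Data-stream randomization.** One swap picks two periods p ≠ q and
individuals A ∈ p\q, B ∈ q\p and exchanges them; row sums (party
sizes) and column sums (observation counts) are conserved exactly,
which is verified after every chain in the tests. The null is built
from one serial chain: 1000 burn-in swaps, then the statistic recorded
every 10 swaps for 1000 iterations (all configurable; the chain
settings are recorded in the result metadata). These defaults follow
standard practice for serial swap null models; the sampling interval
trades autocorrelation against runtime and is not critical because
p-values use the marginal null distribution. A node-permutation
alternative (shuffling node identities of the observed matrix) is
provided for comparison; the data-stream null is the default because it
conditions on the observation schedule.

The pipeline's association test statistic is the **mean mixed-species
SRI**, lower tail. Under margin-preserving swaps the total number of
co-identifications Σ_rows C(party size, 2) is invariant, so the overall
mean SRI barely moves and is nearly uninformative; what the
randomization can move is the *allocation* of associations across dyad
classes, and species segregation shows up as an observed mixed-dyad
mean far below the null. The overall-mean statistic is computed and
reported alongside for completeness.

**Node-label permutation t-test.** Observed statistic mean(species 1) −
mean(species 2); labels shuffled without replacement per iteration; NaN
metric values are dropped with their labels. Two-tailed p is the
proportion of |null| ≥ |observed|; directional ps are always reported.
An exhaustive mode enumerates all C(n, n1) assignments for small inputs
and is what the tests compare against. For all tests the raw proportion
is the primary p-value (it can be exactly 0 at finite iterations, which
is how "p < 1/iterations" findings are reported); the add-one variant
(b+1)/(N+1) is reported alongside as the conservative estimator.
Bonferroni adjustment for the four-metric family gives 0.05/4 = 0.0125.
The two-tailed rule for the (non-centred) data-stream null is the
doubled smaller tail, capped at 1.

Reproducibility: every stochastic routine takes a seed; the pipeline
derives per-test child seeds from the run seed via `SeedSequence`, so
identical configuration + seed reproduces results bit for bit.

## Synthetic generator

The generator's role is to produce datasets with the statistical
structure the analysis assumes, under the study's sampling design, so
that parameter recovery is a meaningful test. Defaults:

| parameter | default | meaning |
|---|---|---|
| species_sizes | 18+9 (West-like) / 17+17 (East-like) | colony compositions |
| follows_per_individual | 18 | focal follows per individual |
| samples_per_follow | 10 | one-minute point samples per follow |
| p_within | 0.15 | per-sample join probability, same-species dyad |
| p_between | 0.01 | per-sample join probability, mixed dyad |
| gregariousness_sd | 0 | log-scale SD of per-individual multipliers (mean 1) |
| subgroup_split | none | optional cliques within one species |
| mixed_space_overlap | none | optional multiplicative damping of mixed dyads |

Each non-focal joins the focal's party independently with probability
clip(p_pair · g_focal · g_j, 0, 1). The p_within/p_between defaults
place the within/mixed contrast at roughly the order observed in
strongly assortative colonies while keeping per-sample party sizes
realistic (a handful of neighbors, a substantial solitary fraction).
Independence of neighbor draws is a deliberate simplification: real
parties are coherent (if B and C both flank A they are near each
other), associations are temporally autocorrelated within a follow, and
space use is structured. Consequently, passing tests demonstrate that
the estimator and tests recover planted dyadic structure under the
right sampling design — not that they are robust to spatial or temporal
confounding, which no simulation of this form can show.

`expected_sri` gives a plug-in closed form E[x]/(E[x]+E[ya]+E[yb]) for
the homogeneous model (gregariousness_sd = 0, no subgroup split),
computed exactly from the schedule composition. It is the ratio of
expectations rather than the expectation of the ratio, so it is
documented as an approximation and compared with Monte-Carlo means at a
0.02 tolerance.

## Numerical choices

* Oracle-equivalence tolerance 1e-9 absolute; exact-equality
  comparisons in p-values use a 1e-12 guard so "equal to the observed
  value" survives floating-point recomputation.
* Degenerate swap search: a swap is retried up to 1000 times before the
  GBI is declared degenerate (identical/nested periods).
* Eigenvector centrality on an all-zero adjacency returns all zeros
  with a warning instead of failing, matching the "no associations"
  semantics of the zero SRI matrix.
* Never-identified dyads, solitary-sample counts and unreachable path
  pairs are surfaced as metadata/log counts, not silently absorbed.

## Problem sizes in the test suite

The suite exercises: 1000 random instances (≤ 6 nodes) for brute-force
oracle equivalence; 10,000-swap margin-conservation chains; exhaustive
label-test enumeration up to 8 individuals; type-I calibration with 500
null replicates × 200 iterations (nominal 5%, accepted band ± 3 points);
and parameter recovery over 10 seeds at the full 18 × 10 schedule with
randomization chains of 500 burn-in swaps and 200 recorded iterations
(5 swaps apart). These sizes were chosen to give stable Monte-Carlo
margins at interactive runtimes; the library defaults remain 1000
iterations / 1000 burn-in.

## Known limitations

* The GBI stores one party per period unless a partition is supplied;
  co-occurrence of two independently observed parties in one period
  (yab > 0) never arises from the packaged samplers.
* The data-stream null uses a single serial chain; thinning is
  configurable but chain diagnostics (e.g. effective sample size of the
  null) are not computed.
* The sociogram plot is a convenience export, not a calibrated layout;
  inter-cluster distances in a spring layout are not the geodesic
  distances used by the metrics.
* Group assignment is taken from the roster; individuals observed in
  parties outside their roster group are an error, not a reassignment.
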