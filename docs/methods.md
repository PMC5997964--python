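# Methods

This note documents the statistical procedure, the numerical choices, the
synthetic-data design and the known limitations of `popsynth`.

## Data model

The reference data is a micro-sample of person records grouped into
households.  Household variables: housing type (6 categories), main
dwelling type (13), rooms (1–20), tenure (5), gross annual household
income (12 bands plus "Unspecified", 2011 ZAR).  Person variables: age in
18 five-year bands, gender (male/female; records with unspecified gender
are rejected at read time), population group (5), employment (2),
completed education (8), current schooling (9).  Member number 1 is the
household head; households without exactly one head, or with more than
one spouse, are rejected rather than repaired — the upstream sources give
no basis for repair.

Households partition into three types: **single-member** (n = 1),
**dual-role** (n ≥ 2 with a spouse present), **single-role** (otherwise).
`type_fractions` supports both household-share and individual-share
semantics via a flag; quota arithmetic (below) uses whichever fractions
the caller supplies, and the worked-example configuration treats them as
individual quotas.

Control totals per zone are 13 household income counts and 10 person
gender × race counts (gender-major order).  Zones are opaque string IDs
with WGS84 polygons; no administrative hierarchy is modelled.

## Structure learning

Structures are learnt per household type by greedy hill-climbing on the
BIC with natural logarithms,

    BIC(G) = Σ_v ℓ_v(Pa(v)) − (log N / 2) Σ_v (r_v − 1) q_v,

where ℓ_v is the multinomial log-likelihood of node v given its parents
at the MLE, r_v its cardinality and q_v the product of the declared
parent cardinalities (unobserved configurations are counted, matching
the convention of standard categorical-network software).  Moves are
single-edge add/delete/reverse; best improvement is taken each step, with
ties broken on the lexicographically first (child, parent) pair, no
random restarts and no tabu list, so the search is deterministic given
the data, the constraints and the declared node order.  An optional
maximum-parent cap bounds CPT size (default: none; the BIC penalty keeps
families small in practice).

Blacklists implement the causal shielding of demographics:

* `g1`: every edge into age, gender or race is forbidden (including among
  those three variables themselves);
* `g21`: edges into the head's/spouse's age, gender or race are forbidden
  *except* from the partner's same set of demographic variables;
  `g31`: the same without the partner exception;
* `g22`/`g32`: every edge except (head-or-spouse variable) → (member
  variable) is forbidden, which also makes all evidence variables roots.

Whitelists (required links with free orientation) are supported by the
search but empty in this pipeline.

CPTs are estimated as (count + s)/(config count + s·r).  Structure
scoring uses the MLE (s = 0), as BIC requires; sampling uses Laplace
smoothing s = 1 by default so that unseen parent configurations remain
samplable (they yield the uniform distribution).  There is no
missing-data handling: the data contract requires complete categorical
rows.

The household size n enters `g21` and `g31` as a categorical node whose
support is the sizes observed in the reference data.  Making it a node
(rather than an external count) lets household size depend on head and
spouse attributes.

## Sampling and pool generation

Sampling is ancestral in topological order, vectorized over draws.
Conditional sampling clamps evidence nodes and requires them to be roots
— exactly the situation the `g22`/`g32` blacklists guarantee; clamping a
non-root would require posterior inference, which is deliberately out of
scope.

Pool quotas for pool size P and fractions (f1, f2, f3): s1 = f1·P
(rounded half-up) single-member individuals are drawn from `g1`.
Dual-role households are appended whole — one `g21` draw for household
attributes, head, spouse and n, then n − 2 i.i.d. `g22` draws conditional
on that head and spouse — until their cumulative individuals reach
s2 = f2·P.  Single-role households are appended the same way (members
from `g32`, conditioned on the head) until the pool holds at least P
individuals.  Because whole households are appended, the dual-role and
total counts overshoot their thresholds by strictly less than one
maximum household size.  `g21` draws with n < 2 (possible only through
smoothing mass) are rejected and redrawn, which preserves the
conditional law on the valid support; 1000 consecutive rejections abort
with an error.  Members within a household are conditionally independent
given the head (and spouse) — the construction implies no within-sibling
dependence.

## Calibration (generalized raking)

Each pool household contributes a 23-entry design vector: a one-hot over
the income bands and its member counts per gender × race cell.  Zone
weights solve the exponential-tilting calibration problem
w_i = d_i·exp(x_iᵀλ) subject to Σ w_i x_i = t, the raking distance of
survey calibration; initial weights d_i = 1.  λ is found by Newton
iteration on the 23-dimensional dual with step halving on the maximum
relative constraint violation; when the Jacobian Σ w_i x_i x_iᵀ is
rank-deficient (the household total is implied by the income columns, for
instance) the step falls back to a least-squares (pseudo-inverse) solve.
Convergence tolerance is 1e-6 relative per constraint, maximum 100
iterations; non-convergence raises with diagnostics rather than
returning approximate weights.

Exponential tilting cannot produce exact zeros, so zones with zero
targets in some category are handled by *preflight exclusion*: every pool
household carrying mass in a zero-target category is excluded from that
zone's calibration (and logged); the zero constraints are then trivially
satisfied.  The "Unspecified" income band is a regular calibration
category, since control tables carry it.

## Assembly and replication

Each zone draws `sum(income_totals)` households from its calibrated pool
**with replacement**, probability proportional to weight — the pool is
only ~20% of the population, so reuse is unavoidable and the weights are
exactly the expected appearance rates.  Households are renumbered 0…H−1
across zones (zone IDs lexicographic, draw order within a zone), persons
0…N−1 with a back-pointer to their household.  Income is stored as the
upper value of the band in 2011 ZAR; the open-ended top band continues
the doubling progression of the published bands (4,915,200), and
"Unspecified" households carry the band label as a string attribute with
no numeric income element.  Home coordinates are uniform over the zone
polygon by bounding-box rejection sampling (an error after 10,000
rejections guards against degenerate slivers).  Replicate r re-draws
selections and coordinates with seed base_seed + r while sharing the one
calibrated weight set; the default replicate count is 100.

## XML containers

The writers emit the two linked MATSim containers: households
(households_v1.0 structure — `members` with `personId` references, an
`income` element, an `attributes` list) and population (population_v6
structure — person-level `attributes`).  Attribute value-type labels are
the literal Java class-type strings the dialect uses (`java.lang.String`,
`java.lang.Integer`, the MATSim coordinate class for `homeCoordWGS`),
written as fixed vocabulary constants.  Output is UTF-8 with fixed
attribute order, so writers are byte-deterministic; gzip wrapping uses a
zeroed timestamp for the same reason, and readers sniff the gzip magic
bytes.  `link_check` cross-validates member references, orphan persons
and back-pointers.

## Synthetic census fixtures

`synthetic_census` exists so that fitting, raking and assembly are
testable end to end with no external data.  `make_ground_truth` builds
generating networks that honour the blacklist semantics; a `small` level
models 4–6 variables per household type (unmodelled attributes are
filled with a constant so records stay schema-complete) and a `medium`
level models the full variable set.  Design choices that matter:

* Root nodes get spread marginals (at least 0.5/r mass per category) so
  every parent configuration is observed in realistic samples; child
  nodes get sharp CPTs (dominant probability 0.98, dominant category
  rotated across parent configurations so marginals stay spread).  Sharp
  CPTs make structure and parameters recoverable at PUMS-scale sample
  sizes — the point of the fixture is recoverability, not demographic
  realism.
* Household-size nodes get moderate (non-sharp) distributions with
  support capped at 8, keeping quota-overshoot bounds tight.
* Single-role generating sizes start at 2: a size-1 household with only a
  head *is* a single-member household under the classification, so this
  keeps the designed type mix (10/60/30) exactly recoverable.
* Zone control tables are exact recounts of a simulated full population,
  so calibration targets are attainable by construction; zone polygons
  are unit squares (degenerate polygons appear only in dedicated
  placement tests).

What passing fixtures do **not** show: realistic South African
demography, dependence structures weaker than the sharp fixture CPTs,
measurement error or missingness in real PUMS data, or calibration under
inconsistent (survey-estimated rather than recounted) control totals.

The parameter-recovery experiment fits the pipeline to a 10% micro-sample
(~10,000 households) of a 100,000-household medium fixture and checks
that ≥80% of generating edges appear in the learned skeletons and that
CPTs refit by MLE on the generating structures match the generating
tables to 0.05 sup-norm.  CPT recovery is measured on the families that
are modelled quantities — member variables in `g22`/`g32` (their
head/spouse roots are evidence, estimated only incidentally and with
size-biased weighting) and all families elsewhere — over parent
configurations observed in the sample.

## Problem sizes and defaults

Default experiment sizes were chosen so every property is measured at a
statistically meaningful scale: 5 zones × 2,000 households for pipeline
fixtures, a 120,000-individual pool for the quota/composition checks
(the worked-example configuration), 100,000 households for the recovery
experiment, 100 random ≤4-variable data sets for the search-oracle
comparison, and 2 replicates for the replication-design check (the
production default is 100).

## Known limitations

* Conditioning is restricted to root evidence; general inference
  (variable elimination, belief propagation) is out of scope.
* The hill-climbing search is a local optimizer; on the ≤4-variable
  oracle benchmark it reaches the global optimum in ≥90% of data sets,
  and the tests track that rate rather than assuming optimality.
* Raking weights are point calibrations; no variance estimation of the
  calibrated estimators is provided, and alternative calibration
  distances (logit, truncated linear) are not implemented.
* Sampling zones with replacement means a pool household can appear many
  times in one zone; diversity is bounded by the pool size.
* Placement is uniform within the zone polygon: no dwelling-level or
  land-use-aware placement.
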