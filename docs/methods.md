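# Methods

## Problem setting

An index group of long-term cancer survivors is to be compared against a
cancer-free comparison group recruited by one of two strategies: peer
nomination (survivors name up to two similar acquaintances) or a listed
sample (a purchased list hard-matched on sex and age within ±5 years).
Deciding between the strategies requires (i) tests of whether each comparison
group's marginal distributions match the survivors', (ii) a pair-level test
of which strategy produces closer individual matches, and (iii) recruitment
yield and cost accounting. Marginal and pair-level views answer different
questions and can disagree: identical margins are compatible with uniformly
poor pairs, as the worked fixture (1,10), (10,1), (1,10), (10,1) shows.

## Pair distances

For a matched pair and a variable with declared scale, the distance is

- continuous: absolute difference;
- binary / nominal: 0 if equal, 1 otherwise;
- ordinal: absolute difference of ranks in the declared level order
  (education uses less-than-HS < HS-grad < post-HS, i.e. ranks 1–3);
- any missing input: missing (the pair is excluded for that variable only).

Missing values are never imputed; every test is complete-case per variable,
which is why per-variable group sizes vary. Sex enters distances as simple
agreement/disagreement, equivalent to a 0/1 coding.

Lifetime smoking duration is derived as (age at last cigarette − age at first
cigarette), substituting current age for current smokers; never-smokers and
former smokers with unknown quit age are missing. A negative computed
duration is a data error, not a missing value.

## The partially paired permutation test

Let `d_i^P`, `d_i^L` be peer and listed distances keyed by survivor `i`. Some
survivors contribute to both groups (correlated observations), some to one.
The observed statistic is the midrank sum `W` of the peer group in the pooled
sample. The null hypothesis is exchangeability of the group labels given each
survivor: conditionally on a survivor, their peer and listed distances are
identically distributed.

The null distribution permutes labels in the ways that exchangeability
licenses, and only those:

- **clusters** (survivors in both groups): labels are permuted uniformly
  within the cluster, preserving the cluster's per-group counts. For the
  default one-peer/one-listed pair this is an independent fair swap, giving
  the familiar 2^k swap patterns; a survivor contributing two peers and one
  listed match (the `all` peer rule) forms a 3-observation cluster with
  C(3,2) = 3 assignments.
- **unpaired pool**: observations of single-group survivors are pooled and
  labels reassigned uniformly, preserving the observed unpaired counts —
  C(m, m_P) choices. Unpaired observations belong to distinct survivors, so
  under the null they are i.i.d. draws from a common distance distribution
  and fully exchangeable.

Arrangements therefore number `2^k · C(m, m_P)` (product of per-cluster
binomials in general). When that count is ≤ 10⁶ (configurable cap) the engine
enumerates exhaustively, exploiting the additivity of the rank sum across
clusters and the unpaired pool; the exact p-value is the proportion of
arrangements with `W* ≤ W` (the observed arrangement is one of them, so
p > 0). Above the cap, `n_perm` arrangements are sampled i.i.d. with a seeded
`numpy` generator and `p = (1 + #{W* ≤ W}) / (n_perm + 1)`, which is valid
(super-uniform) by the usual add-one argument. Requesting exact mode above
the cap raises a capacity error suggesting Monte Carlo; `auto` picks for you.

Directionality: smaller peer rank sum = smaller peer distances = better peer
matching, so the one-sided p-value is the lower tail. Swapping the two groups
maps the exact one-sided p to `1 − p + P(W* = W)`, an identity the test suite
verifies by enumeration. Two-sided p-values are the tail of `|W* − E[W*]|`,
with `E[W*]` available in closed form (per-cluster means plus the
proportional unpaired allocation). Ties use midranks throughout with no
continuity correction — the permutation null needs none. Because the rank-sum
lattice is discrete and ties between replicate and observed statistics count
against rejection, the test is mildly conservative (empirical size ≈ 0.043
at nominal 0.05 in the calibration suite — inside the exact binomial band,
never anti-conservative).

When a survivor has two completed peers, the default rule uses the **first
enrolled** peer (`first`; subject-id order, which the generator assigns in
enrollment order); `mean_distance` averages the two distances; `all` keeps
both as a correlated cluster as above. The choice is reported in the output.

## Marginal tests

The same permutation machinery applies with survivor/comparison labels:
survivor values and their matched comparison values form clusters; survivors
without a usable comparison value (and comparison values whose survivor value
is missing) enter the unpaired pool, so the survivor margin keeps its full n
even when the comparison group is less than half the size. Continuous
variables use the rank-sum statistic with the centred two-sided tail;
categorical variables (sex, race, education, employment) use the Pearson
chi-square deviation of the 2×K group-by-category table, whose upper tail is
the two-sided test (group sizes and pooled category totals are permutation
invariants, so the statistic reduces to a function of one group's category
counts). A single pooled category yields a degenerate result: p = 1 plus a
warning flag. By default every completed peer counts in the peer margin
(`peer_rule='all'`); the pair-level default of one peer per survivor applies
to distances only.

No multiple-testing adjustment is applied: the per-variable p-values are the
output of record, and their joint interpretation is left to the analyst.

## Recruitment accounting

`cost_per_complete = hourly_rate / completes_per_hour`, truncated to cents by
default (`rounding='half_up'` available): at $25/hr the rates 0.65, 0.40 and
0.60 completes/hour give $38.46, $62.50 and $41.66, the last of which is
41.666… and distinguishes the dialects. `total_cost` multiplies by completed
interviews and rounds half-up ($62.50 × 44 = $2750.00; $41.66 × 101 =
$4207.66). Yield denominators are arm-specific: usable numbers for the
survivor arm (100/372 → 27% at integer precision), nominees for the peer arm
(44/91 → 48.3% at one truncated decimal), numbers dialed for the listed arm
(101/544 → 19%). Integer yields round half-up while the one-decimal dialect
truncates; both are explicit options because published tables mix them.
The accounting module deliberately computes arm totals from its own formula
only — it does not special-case any externally printed total.

## Synthetic cohorts

The study emulator (`generate_cohort`) draws survivors from configured
marginals: age ~ N(64.9, 10.09²) floored at 30; 72% men; 94/2/4% white/black/
other; education 7/21.3/71.7% across the three levels; zero-inflated smoking
(15% current smokers whose 30-day days ~ N(28, 5²) clipped to [1, 30],
yielding mean ≈ 4.25 and SD ≈ 10.3 overall; 60% ever-smokers) and
zero-inflated alcohol quantities. Each survivor nominates at least one peer
with probability 0.61, a second with probability 30/61 given nomination, and
each nominee completes with probability 0.483 — so 100 survivors yield ≈ 61
nominators, ≈ 91 nominees and ≈ 44 completed peers. Peers copy the
survivor's categorical values with per-variable fidelity (education 0.8,
race 0.9, employment 0.5, smoking status 0.7), share the survivor's sex with
probability 0.35 (nominees were not required to be same-sex; this value
reproduces a ~43%-male peer group from a 72%-male index group), and perturb
continuous values around the survivor's with per-variable noise; peer age is
additionally shifted −7.5 years with SD 9.6 (chosen so the peer age SD lands
near 13.9 from a 10.09 base). Listed subjects share the survivor's sex
exactly and age uniformly within ±5 years — asserted invariants — with all
other variables drawn from the population independently of the survivor, and
complete with probability 0.96. A 2% per-variable missingness rate yields the
variable-specific group sizes typical of telephone surveys.

The funnel generator allocates each arm's candidates to usable/unusable
numbers, completions, and outcome stages (refused, no-answer, deceased,
ineligible, partial, not-used) by binomial/multinomial draws with stage
probabilities calibrated to the three recruitment flowcharts; counts conserve
exactly by construction.

What the emulator does **not** model: zip-code geography, telephone-number
mechanics, interviewer effects, any dependence between nomination propensity
and survivor characteristics, and the original categorical response scales of
the alcohol items (the per-month quantities are generated directly). Passing
tests on these cohorts validate the statistical machinery under the declared
dependence structure, not the behaviour of any particular real population.

## Validation harnesses

`generate_null_cohort` draws both comparison groups' values from the
*identical* conditional law given the survivor (age = survivor + N(0, 5²),
shared copy probabilities for categoricals, shared zero-handling), preserving
the realistic partially paired missingness pattern — by construction the
exchangeability null of the match-quality test. `generate_shifted_cohort`
adds a location shift to the designated variable (default: age) for the
listed arm only, making listed distances stochastically larger; shift 0 is
bit-identical to the null generator under the same seed. These harnesses do
not enforce the ±5-year listed age window: the window would truncate the
shift ladder and break exact exchangeability, and the hard-constraint
invariants are properties of the study emulator, not of the calibration null.

Calibration results are computed, not assumed: across 1000 null cohorts
(n = 100 survivors, 2000 Monte Carlo permutations) the one-sided rejection
rate at α = 0.05 falls inside the exact binomial 95% band around 0.05, and
empirical power increases monotonically across the shift ladder
{0, 0.5, 1, 2} × SD (500 replicates each), reaching > 0.95 at 2 SD. The
problem sizes used in the shipped acceptance script (1000 type-I replicates,
4 × 500 power replicates, 200 calibration seeds) are the package's standard
calibration settings and complete in well under a minute total.

## Numerical conventions and edge cases

- All randomness flows through `numpy.random.default_rng` seeds passed
  explicitly; identical inputs and seeds reproduce results bit-for-bit,
  including report JSON.
- Floating-point tail comparisons use a 10⁻⁹ relative tolerance so that
  midrank sums that are mathematically tied are counted as tied.
- Exact-mode results carry `seed = None` (no randomness was used);
  Monte Carlo results echo the seed.
- Degenerate inputs: one empty distance group → insufficient-data error at
  the single-test level, a flagged row (not a dropped one) at the report
  level; a single pooled category → p = 1 with a degenerate flag.
- Currency is computed in `decimal.Decimal` and only converted to float at
  the reporting boundary.
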