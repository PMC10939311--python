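# Methods

## Unit of analysis and aggregation

The pipeline treats the *experiment* — one or more injections of viral vector
into one brain region of one animal in one laboratory — as the unit of
analysis. Operationally an experiment is a unique key tuple over configured
fields, `(lab, animal, region)` by default. The vector label is deliberately
not part of the default key, even though a narrower reading of "one
experiment" would include it: the operational grouping that the published
reanalysis used (and that its experiment count reflects) keys on lab, animal
and region only. `--key-fields lab,animal,region,vector` opts into the
refined key; refining the key can only increase the number of experiments.
Injections into two regions of the same animal are always two experiments.

Each injection carries, per assessment domain (histology, physiology,
behavior), an ordinal outcome `MISSING(0) < FAILED(1) < WEAK(2) < STRONG(3)`.
The experiment-level outcome per domain is the rank-maximum over its
injections. The two cases usually stated for this rule — any strong injection
makes the experiment strong; otherwise any weak injection makes it weak —
extend by the same logic to: any failed injection (with no weak/strong) makes
it failed, and only an all-missing experiment is missing. The rank-maximum is
the only reading consistent with those stated cases. It is deliberately
generous: an experiment with twenty failed injections and one strong one
counts as a strong success.

## Rates and definitions

All statistics are raw proportions; no confidence intervals or tests are
computed (and none are in scope — a clustered bootstrap would be the natural
extension but is deliberately excluded). "Tested" means the experiment-level
outcome in the relevant domain(s) is non-missing; tested counts form every
denominator. Two success definitions apply throughout:

- **ANY** (liberal): aggregated outcome ≥ WEAK;
- **STRONG_ONLY** (strict): aggregated outcome = STRONG.

Strict rates reuse the tested denominators, so strict numerators are a subset
of liberal ones over identical denominators — an invariant the tests enforce.
Conjunction rates require every member domain tested (denominator) and every
member domain successful (numerator). The headline summary is the unweighted
mean of the two behavior-anchored pairwise conjunction proportions
(behavior∩physiology, behavior∩histology) — a mean of proportions, not pooled
counts, so both conjunctions weigh equally regardless of size.

Injection-level rates (the comparison figure to injection-based summaries) use
each injection directly: assessed if any domain is non-missing, successful if
any domain meets the definition.

Percent formatting is one decimal place with halves rounded away from zero
(`decimal.ROUND_HALF_UP`), which matters at exact halves: mean(48.6%, 57.5%) =
53.05% prints as 53.1%. The unrounded proportion is always retained alongside.

## Vocabulary harmonization

Raw annotations are lower-cased, trimmed and whitespace-collapsed, then looked
up in an explicit outcome map. The shipped default covers
`strong/strong success → STRONG`, `weak/weak success/mixed/partial/yes/success
→ WEAK`, `no/none/failed/failure → FAILED`, and NA-likes (blank, `na`, `n/a`,
`-`, `not tested`, ...) → MISSING. Two placements deserve a word:

- `mixed`/`partial` sit at WEAK because graded surveys group weak and mixed
  effects together below strong;
- `yes`/`success` also sit at WEAK: an ungraded affirmation counts as a
  success under the liberal definition but is never allowed to inflate the
  strict strong-only rates.

Strict mode (default) raises on any undeclared string, naming the string and
source row; lenient mode maps it to MISSING and logs. The region synonym
table ships empty — merging region spellings changes the experiment count, so
merges must come from the user's config, not from built-in guesses. Region
labels are case/whitespace-normalized either way, and canonicalization is
idempotent. Region classes (`PRIMARY_SENSORIMOTOR` vs `OTHER`) are likewise
config, not constants; unmapped regions classify as OTHER with a warning.

Lab and animal keys are compared case-insensitively after trimming
(multi-lab spreadsheets have inconsistent casing; over-splitting keys inflates
the experiment count). Rows with an empty lab or animal identifier are
rejected in strict mode rather than fused into a shared blank key.

## Synthetic cohort generator

The generator emulates the clustered structure the analysis assumes — and
nothing more. Hierarchy: `n_labs` labs × `animals_per_lab` animals × 
`regions_per_animal` regions sampled without replacement from a labelled
region pool; each (lab, animal, region) cell is one experiment with `m`
injections drawn from `injections_per_experiment` (a constant or a
distribution over positive counts).

Per experiment and domain, an assessment indicator is drawn with probability
`assess_prob[d]`; missingness is assigned at experiment level (a domain is
annotated on all of an experiment's injections or none), matching how
"tested" is defined downstream. Sporadic injection-level annotation gaps can
be layered on top via `injection_missing_prob`, but default to off.
Conditional on assessment, each injection's
outcome is an i.i.d. draw from `outcome_probs[d] = (p_failed, p_weak,
p_strong)` via inverse CDF.

Cross-domain correlation uses a one-parameter latent mixture: each experiment
draws a shared latent uniform, and every assessment/outcome draw reuses that
shared uniform with probability `cross_domain_rho` (fresh uniform otherwise).
This preserves all marginal probabilities exactly for any rho while inducing
positive dependence between domains (and between injections) within an
experiment — the simplest structure that produces the dependence real
conjunction rates imply. Closed-form expectations are only claimed for
`cross_domain_rho = 0`:

- P(experiment ≥ WEAK | tested, m) = 1 − p_failed^m,
- P(experiment STRONG | tested, m) = 1 − (1 − p_strong)^m,

averaged over the m-distribution, with conjunction expectations as products of
per-domain terms. Requesting closed forms with rho > 0 is an error rather
than an approximation.

Randomness is bit-reproducible given (params, seed): every animal and every
experiment owns a `numpy` `SeedSequence` substream keyed by its hierarchy
position, so growing one hierarchy dimension never reshuffles draws elsewhere
(tested).

### Default parameters

Defaults mirror the real multi-lab database's scale: `survey_scale_params()`
uses 45 labs × 4 animals × 2 regions (≈360 experiments, ≈200 animals), an
injections-per-experiment distribution over 1–8 with mean ≈2.8 (≈1000
injections), assessment probabilities (0.68, 0.51, 0.19) for
histology/physiology/behavior matching the observed per-domain tested shares,
and per-injection outcome probabilities — (0.30, 0.22, 0.48),
(0.33, 0.16, 0.51), (0.63, 0.095, 0.275) — chosen once so that the aggregated
experiment-level rates sit near the observed ones under that m-distribution.
`cross_domain_rho` defaults to 0.5 at survey scale (real domains are clearly
dependent) and to 0 in the plain constructor (the analytically checkable
case). What passing tests on synthetic cohorts show is that the *pipeline*
computes its statistics correctly on data with this structure; they cannot
validate the vocabulary or region config against any particular real file.

## Numerical and degenerate-input choices

- Zero denominators yield an explicitly undefined rate (`defined = False`,
  percent `"NA"`), never an exception or a 0/0 coercion.
- Aggregating an empty outcome collection is a precondition error (an
  experiment always has ≥ 1 injection).
- Experiments are emitted sorted by key, so reports are byte-identical across
  runs and input orderings; record order never changes any statistic.
- Report outputs are staged in a temporary directory and moved into place
  atomically; a failed run leaves no partial report.

## Known limitations

- Proportions only: no uncertainty quantification, and no modelling of
  non-independence between experiments in the same animal beyond the grouping
  itself.
- The default vocabulary is a best-effort covering of common annotation
  spellings; real files must be run in strict mode first and the config
  extended until ingest is clean.
- The generator does not fit its parameters to real data and does not emulate
  lab-specific annotation quirks, injection-level sporadic missingness
  (available as structure but off by default), or region-frequency skew
  beyond the composition of the region pool.
- The deposited redacted database is not redistributed; the reproduction test
  requires a local copy and a checked column/vocabulary config.
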