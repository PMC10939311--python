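# optoaudit

Experiment-level success-rate reanalysis of clustered viral-vector injection
databases, built for the open nonhuman-primate (NHP) optogenetics resource but
usable on any injection-level table with the same shape.

## The problem

Multi-lab NHP optogenetics databases record one row per viral-vector
injection, with free-text outcome annotations for up to three assessment
domains: histology (viral expression), neurophysiology (altered neural
activity) and behavior (altered behavior). Injection-level success counts
overstate the independent evidence, because injections cluster within brain
regions, animals and laboratories — several adjacent injections into one area
of one monkey are not independent experiments. `optoaudit`:

1. **harmonizes** free-text annotations onto a four-level ordinal scale,
   `MISSING(0) < FAILED(1) < WEAK(2) < STRONG(3)`, through an explicit,
   overridable vocabulary (strict by default: undeclared strings are errors,
   never silent coercions);
2. **groups** injections into *experiments* — unique conjunctions of
   (laboratory, animal, brain region) — and aggregates each domain by the
   rank-maximum: for experiment $e$ with injections $i$,
   $A_d(e) = \max_i \, y_{d,i}$, so one strong injection makes the experiment
   a strong success in that domain and only an all-missing experiment stays
   missing;
3. **computes rates** as raw proportions $k/n$ over *tested* experiments
   ($A_d(e) \ne \text{MISSING}$), under a liberal definition
   (success $\iff A_d \ge \text{WEAK}$) and a strict one
   (success $\iff A_d = \text{STRONG}$), for single domains, domain
   conjunctions (e.g. behavior ∩ physiology: every member domain tested and
   successful), the triple-assessed subset, a primary-sensorimotor region
   breakdown, injection-level comparison rates, and the headline unweighted
   mean of the two behavior-anchored conjunction rates;
4. **simulates** hierarchical synthetic cohorts (labs → animals → regions →
   injections) with experiment-level missingness and a latent per-experiment
   quality variable for cross-domain correlation. In the independent case the
   experiment-level strong rate has the closed form
   $P(A_d = \text{STRONG} \mid \text{tested}, m) = 1 - (1 - p_\text{strong})^m$,
   so the whole pipeline is testable against analytic expectations without any
   real data.

## Worked example

```bash
# generate a small synthetic cohort and run the full report on it
optoaudit simulate --seed 5 --n-labs 2 --out cohort.csv
optoaudit report --input cohort.csv --out-dir report/
```

which prints (cohort shape first, report second):

```
48 injections (16 experiments) -> cohort.csv
48 injections, 16 experiments -> report/
```

`report/report.json` then contains, among the rest, the per-domain
experiment-level rates — for this seed

```json
"histology": {
  "any":         {"numerator": 11, "denominator": 11, "percent": "100.0%"},
  "strong_only": {"numerator": 10, "denominator": 11, "percent": "90.9%"}
}
```

meaning 11 of the 16 experiments assessed histology at all, all of them showed
at least a weak effect (100.0%) and 10 a strong one (90.9%). The same directory
holds the tidy metric table (`metrics.csv`), the experiment-level table, the
input with appended experiment identifiers, stacked-bar figure data, the
validation report and the echoed run config.

The library mirrors the CLI one-to-one:

```python
import optoaudit as oa

records = oa.read_database("cohort.csv")
experiments = oa.build_experiments(records)          # (lab, animal, region) key
rate = oa.domain_success_rate(experiments, oa.Domain.BEHAVIOR, oa.SuccessDefinition.ANY)
print(rate)                                          # e.g. "3/4 (75.0%)"
```

Subcommands `validate`, `group`, `rates`, `conjunction`, `regions`, `figures`,
`simulate` and `report` each expose one pipeline stage; `--strict/--lenient`
controls vocabulary handling, `--key-fields lab,animal,region,vector` refines
the experiment key.

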