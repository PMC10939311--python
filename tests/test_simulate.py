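"""Synthetic cohort generator: determinism, closed forms, round-trips."""

import dataclasses

import numpy as np
import pytest

import optoaudit as oa
from optoaudit.simulate import (
    GeneratorParams,
    ParameterError,
    cohort_frame,
    expected_rates,
    generate_cohort,
)
from optoaudit.vocab import Domain, OutcomeLevel


def small_params(**kw):
    base = dict(n_labs=2, animals_per_lab=3, regions_per_animal=2, seed=1)
    base.update(kw)
    return GeneratorParams(**base)


def test_experiment_count_is_product_of_hierarchy_sizes():
    p = GeneratorParams(n_labs=3, animals_per_lab=5, regions_per_animal=2, seed=0)
    assert p.n_experiments == 30
    cohort = generate_cohort(p)
    assert len(oa.build_experiments(cohort.records)) == 30


def test_degenerate_parameters_give_all_strong():
    p = small_params(
        assess_prob={d: 1.0 for d in Domain},
        outcome_probs={d: (0.0, 0.0, 1.0) for d in Domain},
    )
    cohort = generate_cohort(p)
    experiments = oa.build_experiments(cohort.records)
    for e in experiments:
        assert all(v is OutcomeLevel.STRONG for v in e.agg_outcomes.values())
    for d in Domain:
        r = oa.domain_success_rate(experiments, d, oa.SuccessDefinition.STRONG_ONLY)
        assert r.proportion == 1.0 and r.denominator == len(experiments)


def test_same_params_same_seed_bit_identical():
    p = small_params(cross_domain_rho=0.4)
    a, b = generate_cohort(p), generate_cohort(p)
    assert a.records == b.records
    assert cohort_frame(a).to_csv(index=False) == cohort_frame(b).to_csv(index=False)
    c = generate_cohort(dataclasses.replace(p, seed=p.seed + 1))
    assert c.records != a.records


def test_substreams_stable_under_hierarchy_growth():
    """Adding labs does not reshuffle the draws of existing labs."""
    small = generate_cohort(small_params(n_labs=2))
    big = generate_cohort(small_params(n_labs=4))
    lab1_small = [r for r in small.records if r.lab_id == "lab01"]
    lab1_big = [r for r in big.records if r.lab_id == "lab01"]
    strip = lambda rs: [(r.animal_id, r.region_raw, dict(r.outcomes)) for r in rs]
    assert strip(lab1_small) == strip(lab1_big)


def test_strong_rate_within_binomial_error_bound():
    # one injection per experiment: the experiment-level strong rate is Binomial(n, 0.3)
    p = GeneratorParams(
        n_labs=10,
        animals_per_lab=25,
        regions_per_animal=8,
        injections_per_experiment=1,
        assess_prob={d: 1.0 for d in Domain},
        outcome_probs={d: (0.5, 0.2, 0.3) for d in Domain},
        seed=3,
    )
    assert p.n_experiments == 2000
    experiments = oa.build_experiments(generate_cohort(p).records)
    r = oa.domain_success_rate(experiments, Domain.HISTOLOGY, oa.SuccessDefinition.STRONG_ONLY)
    bound = 3 * np.sqrt(0.3 * 0.7 / 2000)
    assert abs(r.proportion - 0.3) < bound


@pytest.mark.parametrize(
    "m,ps,expected",
    [(2, 0.5, 0.75), (1, 0.5, 0.5), (3, 0.3, 1 - 0.7**3)],
)
def test_expected_strong_rate_closed_form(m, ps, expected):
    p = small_params(
        injections_per_experiment=m,
        outcome_probs={d: (1 - ps, 0.0, ps) for d in Domain},
    )
    rates = expected_rates(p)
    assert rates["domain:histology:strong_only"] == pytest.approx(expected)


def test_expected_rates_require_independence():
    with pytest.raises(ParameterError):
        expected_rates(small_params(cross_domain_rho=0.5))
    with pytest.raises(ParameterError):
        expected_rates(small_params(injection_missing_prob=0.1))


def test_sporadic_injection_missingness_option():
    p = small_params(
        n_labs=4,
        animals_per_lab=10,
        assess_prob={d: 1.0 for d in Domain},
        injection_missing_prob=0.5,
        seed=2,
    )
    records = generate_cohort(p).records
    n_missing = sum(
        1 for r in records for d in Domain if r.outcomes[d] is OutcomeLevel.MISSING
    )
    assert 0 < n_missing < 3 * len(records)
    # off by default: with assessment certain, no gaps appear
    p0 = small_params(n_labs=4, animals_per_lab=10, assess_prob={d: 1.0 for d in Domain}, seed=2)
    assert all(
        r.outcomes[d] is not OutcomeLevel.MISSING
        for r in generate_cohort(p0).records
        for d in Domain
    )


def test_aggregation_amplifies_with_more_injections():
    ps = 0.275
    strong = [
        expected_rates(small_params(injections_per_experiment=m))["domain:behavior:strong_only"]
        for m in (1, 2, 4, 8)
    ]
    assert strong == sorted(strong)
    assert strong[0] == pytest.approx(ps)


@pytest.mark.parametrize(
    "bad",
    [
        dict(outcome_probs={d: (0.5, 0.5, 0.5) for d in Domain}),
        dict(assess_prob={d: 1.5 for d in Domain}),
        dict(cross_domain_rho=1.2),
        dict(injections_per_experiment={0: 1.0}),
        dict(injections_per_experiment={1: 0.4, 2: 0.4}),
        dict(regions_per_animal=99),
    ],
)
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ParameterError):
        small_params(**bad)


def test_cohort_round_trips_through_csv_ingest(tmp_path):
    cohort = generate_cohort(small_params(cross_domain_rho=0.3))
    path = oa.write_cohort_csv(cohort, tmp_path / "cohort.csv")
    records = oa.read_database(path)
    assert records == list(cohort.records)
    assert oa.validate_records(records).empty_key_rows == []


def test_generated_cohorts_pass_validation():
    cohort = generate_cohort(small_params(seed=9))
    report = oa.validate_records(cohort.records)
    assert report.n_records == len(cohort.records)
    assert report.empty_key_rows == []


def test_worked_fixture_shape_and_shuffle_invariance(vocab):
    from optoaudit.simulate import WORKED_FIXTURE_EXPECTED as E

    fx = oa.make_worked_fixture()

    experiments = oa.build_experiments(fx.records)
    assert len(fx.records) == E["n_injections"]
    assert len(experiments) == E["n_experiments"]
    assert tuple(sorted(e.n_injections for e in experiments)) == tuple(sorted(E["group_sizes"]))
    rng = np.random.default_rng(0)
    shuffled = list(fx.records)
    rng.shuffle(shuffled)
    a = oa.summarize(list(fx.records), experiments, vocab)
    b = oa.summarize(shuffled, oa.build_experiments(shuffled), vocab)
    assert a.to_json() == b.to_json()
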