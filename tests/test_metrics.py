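"""Success-rate metrics: formatting, definitions, conjunctions, figure data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import optoaudit as oa
from optoaudit.metrics import PAIRWISE_CONJUNCTIONS, RateResult, SuccessDefinition
from optoaudit.vocab import Domain, OutcomeLevel

import naive_reference as naive
from conftest import make_record, random_records

ANY, STRONG = SuccessDefinition.ANY, SuccessDefinition.STRONG_ONLY


@pytest.mark.parametrize(
    "num,den,expected",
    [
        (39, 383, "10.2%"),
        (226, 261, "86.6%"),
        (168, 197, "85.3%"),
        (47, 74, "63.5%"),
        (35, 72, "48.6%"),
        (25, 40, "62.5%"),
        (23, 40, "57.5%"),
        (254, 383, "66.3%"),
        (29, 254, "11.4%"),
        (0, 5, "0.0%"),
        (1, 8, "12.5%"),  # exact half rounds away from zero
        (1, 1, "100.0%"),
    ],
)
def test_format_percent_one_decimal_half_away_from_zero(num, den, expected):
    assert oa.format_percent(num, den) == expected
    assert RateResult(num, den).percent_text == expected


def test_format_percent_zero_denominator_is_undefined_marker():
    assert oa.format_percent(0, 0) == "NA"
    r = RateResult(0, 0)
    assert not r.defined and r.proportion is None


def test_rate_result_rejects_impossible_counts():
    with pytest.raises(ValueError):
        RateResult(5, 3)
    with pytest.raises(ValueError):
        RateResult(-1, 3)


def test_headline_average_is_mean_of_proportions_not_pooled_counts():
    conj_any = (RateResult(45, 72), RateResult(25, 40))
    conj_strong = (RateResult(35, 72), RateResult(23, 40))
    out = oa.headline_summary(conj_any, conj_strong)
    assert out["any_percent"] == "62.5%"
    # mean(48.6%, 57.5%) = 53.05% -> 53.1%; pooled 58/112 would give 51.8%
    assert out["strong_only_percent"] == "53.1%"


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 50), st.integers(1, 50))
def test_headline_mean_of_equal_rates_is_identity(num, den):
    num = min(num, den)
    r = RateResult(num, den)
    out = oa.headline_summary((r, r), (r, r))
    assert out["any"] == pytest.approx(num / den)
    assert out["any_percent"] == oa.format_percent(num, den)


def test_headline_undefined_input_gives_undefined_output():
    out = oa.headline_summary((RateResult(0, 0), RateResult(1, 2)), (RateResult(0, 0), RateResult(0, 2)))
    assert out["any"] is None and out["any_percent"] == "NA"


def test_conjunction_requires_two_domains():
    with pytest.raises(ValueError):
        oa.conjunction_success_rate([], [Domain.BEHAVIOR], ANY)


def test_domain_rate_empty_denominator_flagged_not_raised():
    records = [make_record("A", "m1", "V1", OutcomeLevel.STRONG, OutcomeLevel.WEAK, OutcomeLevel.MISSING, 1)]
    experiments = oa.build_experiments(records)
    r = oa.domain_success_rate(experiments, Domain.BEHAVIOR, ANY)
    assert not r.defined


def test_injection_level_single_all_strong_injection():
    records = [make_record("A", "m1", "V1", *[OutcomeLevel.STRONG] * 3, 1)]
    assert oa.injection_level_rates(records, ANY).to_dict()["percent"] == "100.0%"
    assert oa.injection_level_rates(records, STRONG).numerator == 1


def test_all_metrics_equal_naive_reference_on_random_cohorts():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        records = random_records(rng)
        experiments = oa.build_experiments(records)
        for domain in Domain:
            for sd in (ANY, STRONG):
                r = oa.domain_success_rate(experiments, domain, sd)
                assert (r.numerator, r.denominator) == naive.naive_domain_rate(
                    records, domain, sd.threshold
                )
        for pair in PAIRWISE_CONJUNCTIONS:
            for sd in (ANY, STRONG):
                r = oa.conjunction_success_rate(experiments, pair, sd)
                assert (r.numerator, r.denominator) == naive.naive_conjunction_rate(
                    records, pair, sd.threshold
                )
        triple, _ = oa.triple_assessed_summary(experiments, ANY)
        assert (triple.numerator, triple.denominator) == naive.naive_conjunction_rate(
            records, tuple(Domain), OutcomeLevel.WEAK
        )
        for sd in (ANY, STRONG):
            r = oa.injection_level_rates(records, sd)
            assert (r.numerator, r.denominator) == naive.naive_injection_rate(records, sd.threshold)
        assert oa.figure1_counts(experiments) == naive.naive_figure1(records)
        assert oa.figure2_counts(experiments) == naive.naive_figure2(records)


def test_strong_numerators_subset_of_any_with_same_denominators():
    rng = np.random.default_rng(5)
    for _ in range(50):
        experiments = oa.build_experiments(random_records(rng))
        for domain in Domain:
            a = oa.domain_success_rate(experiments, domain, ANY)
            s = oa.domain_success_rate(experiments, domain, STRONG)
            assert s.denominator == a.denominator and s.numerator <= a.numerator
        for pair in PAIRWISE_CONJUNCTIONS:
            a = oa.conjunction_success_rate(experiments, pair, ANY)
            s = oa.conjunction_success_rate(experiments, pair, STRONG)
            assert s.denominator == a.denominator and s.numerator <= a.numerator


def test_conjunction_and_triple_subset_bounds():
    rng = np.random.default_rng(6)
    for _ in range(50):
        experiments = oa.build_experiments(random_records(rng))
        triple = oa.conjunction_success_rate(experiments, tuple(Domain), ANY)
        for pair in PAIRWISE_CONJUNCTIONS:
            conj = oa.conjunction_success_rate(experiments, pair, ANY)
            for d in pair:
                assert conj.denominator <= oa.domain_success_rate(experiments, d, ANY).denominator
            assert triple.denominator <= conj.denominator


def test_figure_counts_consistent_with_rates():
    rng = np.random.default_rng(9)
    for _ in range(30):
        experiments = oa.build_experiments(random_records(rng))
        fig1 = oa.figure1_counts(experiments)
        for domain in Domain:
            assert sum(fig1[domain].values()) == len(experiments)
            a = oa.domain_success_rate(experiments, domain, ANY)
            assert fig1[domain][OutcomeLevel.WEAK] + fig1[domain][OutcomeLevel.STRONG] == a.numerator
        fig2 = oa.figure2_counts(experiments)
        for pair in PAIRWISE_CONJUNCTIONS:
            label = "+".join(sorted(d.value for d in pair))
            total, any_n, strong_n = fig2[label]
            assert total >= any_n >= strong_n
            a = oa.conjunction_success_rate(experiments, pair, ANY)
            s = oa.conjunction_success_rate(experiments, pair, STRONG)
            assert (total, any_n, strong_n) == (a.denominator, a.numerator, s.numerator)


def test_figure2_empty_cohort():
    assert set(oa.figure2_counts([]).values()) == {(0, 0, 0)}


def test_region_breakdown_empty_mapping_classifies_other(vocab):
    records = [make_record("A", "m1", "V1", *[OutcomeLevel.STRONG] * 3, 1)]
    experiments = oa.build_experiments(records)
    empty = oa.default_vocabulary()
    out = oa.region_breakdown(experiments, empty)
    assert out["sensorimotor_share"].numerator == 0
    out = oa.region_breakdown(experiments, vocab)
    assert out["sensorimotor_share"].to_dict()["percent"] == "100.0%"
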