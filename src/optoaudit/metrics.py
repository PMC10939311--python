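"""Success-rate statistics over experiments and injections.

All rates are raw proportions with explicit numerators and denominators. The
denominator for a domain is the number of experiments *tested* in that domain
(aggregated outcome not MISSING); conjunction denominators require every
member domain to be tested. Two success definitions are supported: the
liberal ANY definition (weak or strong counts) and the strict STRONG_ONLY
definition (only strong counts), whose numerators are always a subset of the
liberal ones over the same denominators.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .grouping import Experiment
from .ingest import InjectionRecord
from .vocab import Domain, OutcomeLevel, VocabularyMap

__all__ = [
    "SuccessDefinition",
    "RateResult",
    "SummaryReport",
    "format_percent",
    "domain_success_rate",
    "conjunction_success_rate",
    "triple_assessed_summary",
    "region_breakdown",
    "injection_level_rates",
    "headline_summary",
    "figure1_counts",
    "figure2_counts",
    "summarize",
]

SENSORIMOTOR = "PRIMARY_SENSORIMOTOR"

PAIRWISE_CONJUNCTIONS: tuple[frozenset[Domain], ...] = (
    frozenset({Domain.BEHAVIOR, Domain.PHYSIOLOGY}),
    frozenset({Domain.BEHAVIOR, Domain.HISTOLOGY}),
)


class SuccessDefinition(enum.Enum):
    """Liberal vs strict success: minimum outcome level that counts."""

    ANY = OutcomeLevel.WEAK
    STRONG_ONLY = OutcomeLevel.STRONG

    @property
    def threshold(self) -> OutcomeLevel:
        return self.value


def format_percent(numerator: int, denominator: int) -> str:
    """Percentage to one decimal place, half rounded away from zero.

    A zero denominator yields the undefined marker ``"NA"``.
    """
    if denominator == 0:
        return "NA"
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


@dataclass(frozen=True)
class RateResult:
    """numerator/denominator proportion with printed-percent formatting."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.numerator < 0 or self.denominator < 0 or self.numerator > self.denominator:
            raise ValueError(f"invalid rate {self.numerator}/{self.denominator}")

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def proportion(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None

    @property
    def percent_text(self) -> str:
        return format_percent(self.numerator, self.denominator)

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent_text})"

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "proportion": self.proportion,
            "percent": self.percent_text,
        }


def _succeeds(level: OutcomeLevel, definition: SuccessDefinition) -> bool:
    return level >= definition.threshold


def domain_success_rate(
    experiments: Sequence[Experiment],
    domain: Domain,
    definition: SuccessDefinition,
) -> RateResult:
    """Success rate among experiments tested in one domain."""
    tested = [e for e in experiments if e.agg_outcomes[domain] is not OutcomeLevel.MISSING]
    hits = sum(1 for e in tested if _succeeds(e.agg_outcomes[domain], definition))
    return RateResult(numerator=hits, denominator=len(tested))


def conjunction_success_rate(
    experiments: Sequence[Experiment],
    domains: Iterable[Domain],
    definition: SuccessDefinition,
) -> RateResult:
    """Rate of simultaneous success in every listed domain, among co-tested experiments."""
    domains = frozenset(domains)
    if len(domains) < 2:
        raise ValueError("a conjunction needs at least two domains")
    tested = [
        e
        for e in experiments
        if all(e.agg_outcomes[d] is not OutcomeLevel.MISSING for d in domains)
    ]
    hits = sum(1 for e in tested if all(_succeeds(e.agg_outcomes[d], definition) for d in domains))
    return RateResult(numerator=hits, denominator=len(tested))


def triple_assessed_summary(
    experiments: Sequence[Experiment],
    definition: SuccessDefinition = SuccessDefinition.ANY,
) -> tuple[RateResult, dict[str, RateResult]]:
    """Success among experiments assessed in all three domains, plus per-region splits."""
    overall = conjunction_success_rate(experiments, tuple(Domain), definition)
    by_region: dict[str, RateResult] = {}
    tested = [
        e
        for e in experiments
        if all(e.agg_outcomes[d] is not OutcomeLevel.MISSING for d in Domain)
    ]
    for region in sorted({e.region for e in tested}):
        sub = [e for e in tested if e.region == region]
        hits = sum(
            1 for e in sub if all(_succeeds(e.agg_outcomes[d], definition) for d in Domain)
        )
        by_region[region] = RateResult(numerator=hits, denominator=len(sub))
    return overall, by_region


def region_breakdown(
    experiments: Sequence[Experiment], vocab: VocabularyMap
) -> dict[str, RateResult]:
    """Where the experiments concentrated.

    Returns the share of experiments in primary sensorimotor regions and,
    among those, the share that assessed both behavior and physiology.
    """
    sensorimotor = [e for e in experiments if vocab.region_class(e.region) == SENSORIMOTOR]
    both_tested = [
        e
        for e in sensorimotor
        if e.agg_outcomes[Domain.BEHAVIOR] is not OutcomeLevel.MISSING
        and e.agg_outcomes[Domain.PHYSIOLOGY] is not OutcomeLevel.MISSING
    ]
    return {
        "sensorimotor_share": RateResult(len(sensorimotor), len(experiments)),
        "sensorimotor_behavior_and_physiology_tested": RateResult(
            len(both_tested), len(sensorimotor)
        ),
    }


def injection_level_rates(
    records: Sequence[InjectionRecord], definition: SuccessDefinition
) -> RateResult:
    """Per-injection success rate, the comparison figure to the original survey.

    An injection counts as assessed if at least one domain is non-missing and
    as a success if at least one domain meets the definition.
    """
    assessed = [
        r for r in records if any(v is not OutcomeLevel.MISSING for v in r.outcomes.values())
    ]
    hits = sum(1 for r in assessed if any(_succeeds(v, definition) for v in r.outcomes.values()))
    return RateResult(numerator=hits, denominator=len(assessed))


def headline_summary(
    conj_any: tuple[RateResult, RateResult],
    conj_strong: tuple[RateResult, RateResult],
) -> dict[str, str | float | None]:
    """Unweighted mean of the two pairwise-conjunction rates, per definition.

    The mean is of proportions, not of pooled counts, so the two conjunctions
    weigh equally regardless of how many experiments each one covers.
    """
    out: dict[str, str | float | None] = {}
    for label, pair in (("any", conj_any), ("strong_only", conj_strong)):
        if all(r.defined for r in pair):
            mean = sum(r.proportion for r in pair) / 2
            pct = (Decimal(str(mean)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
            out[label] = mean
            out[f"{label}_percent"] = f"{pct}%"
        else:
            out[label] = None
            out[f"{label}_percent"] = "NA"
    return out


def figure1_counts(experiments: Sequence[Experiment]) -> dict[Domain, dict[OutcomeLevel, int]]:
    """Per-domain counts of experiments at each outcome level (stacked-bar data)."""
    counts = {d: {level: 0 for level in OutcomeLevel} for d in Domain}
    for e in experiments:
        for d in Domain:
            counts[d][e.agg_outcomes[d]] += 1
    return counts


def figure2_counts(
    experiments: Sequence[Experiment],
) -> dict[str, tuple[int, int, int]]:
    """Per pairwise conjunction: (co-tested total, any-success, strong-in-both)."""
    out: dict[str, tuple[int, int, int]] = {}
    for domains in PAIRWISE_CONJUNCTIONS:
        label = "+".join(sorted(d.value for d in domains))
        if experiments:
            total = conjunction_success_rate(experiments, domains, SuccessDefinition.ANY)
            strong = conjunction_success_rate(experiments, domains, SuccessDefinition.STRONG_ONLY)
            out[label] = (total.denominator, total.numerator, strong.numerator)
        else:
            out[label] = (0, 0, 0)
    return out


@dataclass
class SummaryReport:
    """Every statistic the pipeline computes on one database, JSON-serializable."""

    n_injections: int
    n_experiments: int
    domain_rates: dict[str, dict[str, RateResult]]
    conjunctions: dict[str, dict[str, RateResult]]
    triple: dict[str, RateResult]
    triple_by_region: dict[str, RateResult]
    region: dict[str, RateResult]
    injection_level: dict[str, RateResult]
    headline: dict[str, str | float | None]
    figure1: dict[str, dict[str, int]]
    figure2: dict[str, tuple[int, int, int]]

    def to_dict(self) -> dict:
        rr = lambda m: {k: v.to_dict() for k, v in m.items()}
        return {
            "n_injections": self.n_injections,
            "n_experiments": self.n_experiments,
            "domain_rates": {d: rr(v) for d, v in self.domain_rates.items()},
            "conjunctions": {c: rr(v) for c, v in self.conjunctions.items()},
            "triple": rr(self.triple),
            "triple_by_region": rr(self.triple_by_region),
            "region": rr(self.region),
            "injection_level": rr(self.injection_level),
            "headline": dict(self.headline),
            "figure1": self.figure1,
            "figure2": {k: list(v) for k, v in self.figure2.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def metrics_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (metric, definition) with counts and percent."""
        rows = []

        def add(metric: str, definition: str, r: RateResult) -> None:
            rows.append(
                {
                    "metric": metric,
                    "definition": definition,
                    "numerator": r.numerator,
                    "denominator": r.denominator,
                    "percent": r.percent_text,
                }
            )

        for d, defs in self.domain_rates.items():
            for name, r in defs.items():
                add(f"domain:{d}", name, r)
        for c, defs in self.conjunctions.items():
            for name, r in defs.items():
                add(f"conjunction:{c}", name, r)
        for name, r in self.triple.items():
            add("triple", name, r)
        for region, r in self.triple_by_region.items():
            add(f"triple_region:{region}", "any", r)
        for name, r in self.region.items():
            add(f"region:{name}", "-", r)
        for name, r in self.injection_level.items():
            add("injection_level", name, r)
        return pd.DataFrame(rows)


def summarize(
    records: Sequence[InjectionRecord],
    experiments: Sequence[Experiment],
    vocab: VocabularyMap,
) -> SummaryReport:
    """Compute the full report from ingested records and built experiments."""
    defs = {"any": SuccessDefinition.ANY, "strong_only": SuccessDefinition.STRONG_ONLY}
    domain_rates = {
        d.value: {name: domain_success_rate(experiments, d, sd) for name, sd in defs.items()}
        for d in Domain
    }
    conjunctions = {}
    for domains in PAIRWISE_CONJUNCTIONS:
        label = "+".join(sorted(d.value for d in domains))
        conjunctions[label] = {
            name: conjunction_success_rate(experiments, domains, sd) for name, sd in defs.items()
        }
    triple = {}
    triple_by_region: dict[str, RateResult] = {}
    for name, sd in defs.items():
        overall, by_region = triple_assessed_summary(experiments, sd)
        triple[name] = overall
        if name == "any":
            triple_by_region = by_region
    region = region_breakdown(experiments, vocab)
    injection_level = {
        name: injection_level_rates(records, sd) for name, sd in defs.items()
    }
    bp = "+".join(sorted((Domain.BEHAVIOR.value, Domain.PHYSIOLOGY.value)))
    bh = "+".join(sorted((Domain.BEHAVIOR.value, Domain.HISTOLOGY.value)))
    headline = headline_summary(
        (conjunctions[bp]["any"], conjunctions[bh]["any"]),
        (conjunctions[bp]["strong_only"], conjunctions[bh]["strong_only"]),
    )
    fig1 = {
        d.value: {level.name: n for level, n in counts.items()}
        for d, counts in figure1_counts(experiments).items()
    }
    return SummaryReport(
        n_injections=len(records),
        n_experiments=len(experiments),
        domain_rates=domain_rates,
        conjunctions=conjunctions,
        triple=triple,
        triple_by_region=triple_by_region,
        region=region,
        injection_level=injection_level,
        headline=headline,
        figure1=fig1,
        figure2=figure2_counts(experiments),
    )
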