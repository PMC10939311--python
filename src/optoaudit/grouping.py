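"""Experiment-level grouping and ordinal outcome aggregation.

The unit of analysis is the *experiment*: one or more injections into one
brain region of one animal in one laboratory. Injections are grouped by the
unique conjunction of (lab, animal, region) — the vector label can be added to
the key by configuration — and each experiment's per-domain outcome is the
rank-maximum over its injections: any strong success makes the experiment a
strong success for that domain, otherwise any weak success makes it weak,
otherwise any failure makes it failed, and an experiment whose injections were
all unassessed stays missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ingest import InjectionRecord
from .vocab import Domain, OutcomeLevel

__all__ = [
    "ExperimentKey",
    "Experiment",
    "GroupingError",
    "DEFAULT_KEY_FIELDS",
    "assign_experiment_keys",
    "aggregate_outcomes",
    "build_experiments",
    "experiments_frame",
    "records_frame_with_ids",
]

#: The operational grouping key. The vector label is deliberately not part of
#: the default key; it can be opted in via ``key_fields``.
DEFAULT_KEY_FIELDS: tuple[str, ...] = ("lab", "animal", "region")

_KEY_GETTERS = {
    "lab": lambda r: r.lab_id,
    "animal": lambda r: r.animal_id,
    "region": lambda r: r.region_canonical,
    "vector": lambda r: r.vector_label,
}


class GroupingError(ValueError):
    """A record lacks a configured key field."""


@dataclass(frozen=True)
class ExperimentKey:
    """Identity of one experiment: the configured key-field values, in order."""

    fields: tuple[str, ...]
    values: tuple[str, ...]

    def __str__(self) -> str:
        return "/".join(self.values)

    @property
    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.fields, self.values))


@dataclass(frozen=True)
class Experiment:
    """A grouped experiment with aggregated per-domain outcomes."""

    key: ExperimentKey
    records: tuple[InjectionRecord, ...]
    agg_outcomes: Mapping[Domain, OutcomeLevel]

    @property
    def n_injections(self) -> int:
        return len(self.records)

    @property
    def region(self) -> str:
        return self.key.as_dict.get("region", "")


def assign_experiment_keys(
    records: Iterable[InjectionRecord],
    key_fields: Sequence[str] = DEFAULT_KEY_FIELDS,
) -> dict[ExperimentKey, list[InjectionRecord]]:
    """Partition records by their unique key tuple, preserving first-seen order.

    Every input record lands in exactly one group; a record with an empty or
    absent key field raises :class:`GroupingError` with row provenance.
    """
    key_fields = tuple(key_fields)
    if not key_fields or any(f not in _KEY_GETTERS for f in key_fields):
        raise GroupingError(f"key_fields must be a non-empty subset of {sorted(_KEY_GETTERS)}")
    groups: dict[ExperimentKey, list[InjectionRecord]] = {}
    for record in records:
        values = []
        for f in key_fields:
            v = _KEY_GETTERS[f](record)
            if not v:
                raise GroupingError(
                    f"record at source row {record.source_row} has empty key field {f!r}"
                )
            values.append(v)
        key = ExperimentKey(fields=key_fields, values=tuple(values))
        groups.setdefault(key, []).append(record)
    return groups


def aggregate_outcomes(levels: Iterable[OutcomeLevel]) -> OutcomeLevel:
    """Experiment-level outcome for one domain: the rank-maximum.

    STRONG dominates WEAK dominates FAILED dominates MISSING, so a single
    strong injection makes the whole experiment strong for that domain and
    only an all-missing experiment stays missing.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("aggregate_outcomes requires a non-empty collection of levels")
    return max(levels)


def build_experiments(
    records: Iterable[InjectionRecord],
    key_fields: Sequence[str] = DEFAULT_KEY_FIELDS,
) -> list[Experiment]:
    """Group records and aggregate each domain's outcome per experiment.

    The result is a partition: the experiments' injection counts sum to the
    number of input records. Output order is deterministic (sorted by key) so
    downstream reports are byte-stable regardless of input order.
    """
    groups = assign_experiment_keys(records, key_fields)
    experiments = []
    for key in sorted(groups, key=lambda k: k.values):
        recs = groups[key]
        agg = {d: aggregate_outcomes([r.outcomes[d] for r in recs]) for d in Domain}
        experiments.append(Experiment(key=key, records=tuple(recs), agg_outcomes=agg))
    return experiments


def experiments_frame(experiments: Sequence[Experiment]) -> pd.DataFrame:
    """One row per experiment: key fields, n_injections, aggregated outcomes."""
    rows = []
    for e in experiments:
        row = dict(e.key.as_dict)
        row["n_injections"] = e.n_injections
        for d in Domain:
            row[d.value] = e.agg_outcomes[d].name
        rows.append(row)
    return pd.DataFrame(rows)


def records_frame_with_ids(
    records: Sequence[InjectionRecord],
    key_fields: Sequence[str] = DEFAULT_KEY_FIELDS,
) -> pd.DataFrame:
    """The input records as a frame with an appended experiment-identifier column.

    Identifiers are ``E001..`` in sorted-key order, mirroring how the deposited
    analysis appends experiment ids to the injection table.
    """
    key_fields = tuple(key_fields)
    groups = assign_experiment_keys(records, key_fields)
    ordered = sorted(groups, key=lambda k: k.values)
    ids = {key: f"E{i + 1:03d}" for i, key in enumerate(ordered)}
    rows = []
    for r in records:
        values = tuple(_KEY_GETTERS[f](r) for f in key_fields)
        key = ExperimentKey(fields=key_fields, values=values)
        rows.append(
            {
                "source_row": r.source_row,
                "lab": r.lab_id,
                "animal": r.animal_id,
                "region": r.region_canonical,
                "vector": r.vector_label or "",
                **{d.value: r.outcomes[d].name for d in Domain},
                "experiment_id": ids[key],
            }
        )
    return pd.DataFrame(rows)
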