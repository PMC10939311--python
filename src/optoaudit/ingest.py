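"""Read an injection-level database into validated records.

The expected input is a spreadsheet export (CSV or XLSX) with one row per
viral-vector injection: laboratory identifier, animal identifier, brain-region
label, optional vector label, and free-text outcome annotations for the three
assessment domains. Row count is always conserved in strict mode — a record is
emitted for every data row or ingest fails with provenance, never a silent
drop.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .vocab import (
    Domain,
    OutcomeLevel,
    VocabularyMap,
    canonicalize_region,
    harmonize_outcome,
    normalize_token,
)

logger = logging.getLogger("optoaudit")

__all__ = [
    "InjectionRecord",
    "ColumnConfig",
    "SchemaError",
    "ValidationError",
    "ValidationReport",
    "read_database",
    "records_from_frame",
    "validate_records",
    "DEFAULT_COLUMNS",
]


class SchemaError(ValueError):
    """A configured source column is absent from the input file."""


class ValidationError(ValueError):
    """A data row violates a structural requirement (e.g. empty key)."""


#: Logical fields the pipeline needs, with their default source column names.
DEFAULT_COLUMNS: dict[str, str] = {
    "lab": "lab",
    "animal": "animal",
    "region": "region",
    "vector": "vector",
    "histology": "histology",
    "physiology": "physiology",
    "behavior": "behavior",
}

_DOMAIN_FIELDS = {
    "histology": Domain.HISTOLOGY,
    "physiology": Domain.PHYSIOLOGY,
    "behavior": Domain.BEHAVIOR,
}

ColumnConfig = Mapping[str, str]


@dataclass(frozen=True)
class InjectionRecord:
    """One viral-vector injection with per-domain ordinal outcomes.

    ``outcomes`` always contains an entry for every :class:`Domain`
    (MISSING when the domain was not annotated). ``source_row`` is the
    1-based data-row index in the source file, kept for provenance.
    """

    lab_id: str
    animal_id: str
    region_raw: str
    region_canonical: str
    vector_label: str | None
    outcomes: Mapping[Domain, OutcomeLevel]
    source_row: int

    def __post_init__(self) -> None:
        missing = [d for d in Domain if d not in self.outcomes]
        if missing:
            raise ValueError(f"outcomes missing domains {missing} (row {self.source_row})")


def _cell(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
        return ""
    return str(value)


def records_from_frame(
    frame: pd.DataFrame,
    column_config: ColumnConfig | None = None,
    vocab: VocabularyMap | None = None,
    *,
    strict: bool = True,
) -> list[InjectionRecord]:
    """Convert a raw dataframe (one row per injection) into records.

    In strict mode rows with an empty lab or animal identifier are rejected
    (a blank key would fuse unrelated experiments); in lenient mode they are
    kept as-is and surface in :func:`validate_records`.
    """
    from .vocab import default_vocabulary

    cols = dict(DEFAULT_COLUMNS)
    if column_config:
        cols.update(column_config)
    vocab = vocab if vocab is not None else default_vocabulary()

    required = [k for k in cols if k != "vector"]
    absent = [cols[k] for k in required if cols[k] not in frame.columns]
    if absent:
        raise SchemaError(f"configured columns not found in input: {absent}")
    has_vector = cols.get("vector") in frame.columns

    records: list[InjectionRecord] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        source_row = i + 1
        lab = normalize_token(_cell(row[cols["lab"]]))
        animal = normalize_token(_cell(row[cols["animal"]]))
        region_raw = _cell(row[cols["region"]])
        if strict and (not lab or not animal):
            raise ValidationError(f"empty lab/animal identifier at source row {source_row}")
        if strict and not normalize_token(region_raw):
            raise ValidationError(f"empty region label at source row {source_row}")
        outcomes = {
            domain: harmonize_outcome(
                _cell(row[cols[fname]]), vocab, lenient=not strict, source_row=source_row
            )
            for fname, domain in _DOMAIN_FIELDS.items()
        }
        vector = _cell(row[cols["vector"]]) if has_vector else ""
        records.append(
            InjectionRecord(
                lab_id=lab,
                animal_id=animal,
                region_raw=region_raw,
                region_canonical=canonicalize_region(region_raw, vocab) if normalize_token(region_raw) else "",
                vector_label=normalize_token(vector) or None,
                outcomes=outcomes,
                source_row=source_row,
            )
        )
    return records


def read_database(
    path: str | Path,
    column_config: ColumnConfig | None = None,
    vocab: VocabularyMap | None = None,
    *,
    strict: bool = True,
    sheet: int | str = 0,
) -> list[InjectionRecord]:
    """Read a CSV or XLSX injection database into one record per data row.

    Parameters
    ----------
    path
        CSV (UTF-8, header row) or spreadsheet; spreadsheets use the first
        sheet unless ``sheet`` says otherwise.
    column_config
        Mapping from the logical fields (lab, animal, region, vector,
        histology, physiology, behavior) to the source column names;
        unspecified fields use :data:`DEFAULT_COLUMNS`.
    strict
        Strict mode (default) raises on undeclared outcome strings and empty
        keys; lenient mode logs and continues.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
        frame = pd.read_excel(path, sheet_name=sheet, dtype=object)
    else:
        frame = pd.read_csv(path, dtype=object, keep_default_na=False)
    records = records_from_frame(frame, column_config, vocab, strict=strict)
    if len(records) != len(frame):
        raise ValidationError(
            f"row conservation violated: {len(frame)} data rows, {len(records)} records"
        )
    return records


@dataclass
class ValidationReport:
    """Pure summary of an ingested record set (no mutation, no side effects)."""

    n_records: int = 0
    n_labs: int = 0
    n_animals: int = 0
    n_regions: int = 0
    missing_per_domain: dict[str, int] = field(default_factory=dict)
    empty_key_rows: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_labs": self.n_labs,
            "n_animals": self.n_animals,
            "n_regions": self.n_regions,
            "missing_per_domain": dict(self.missing_per_domain),
            "empty_key_rows": list(self.empty_key_rows),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def validate_records(records: Iterable[InjectionRecord]) -> ValidationReport:
    """Count records, distinct keys, per-domain missingness and empty keys."""
    records = list(records)
    labs = {r.lab_id for r in records if r.lab_id}
    animals = {(r.lab_id, r.animal_id) for r in records if r.animal_id}
    regions = {r.region_canonical for r in records if r.region_canonical}
    missing = {
        d.value: sum(1 for r in records if r.outcomes[d] is OutcomeLevel.MISSING) for d in Domain
    }
    empty = [r.source_row for r in records if not (r.lab_id and r.animal_id and r.region_canonical)]
    return ValidationReport(
        n_records=len(records),
        n_labs=len(labs),
        n_animals=len(animals),
        n_regions=len(regions),
        missing_per_domain=missing,
        empty_key_rows=empty,
    )
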