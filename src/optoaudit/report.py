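"""One-shot report: ingest → grouping → metrics, with staged atomic outputs.

A run is fully described by a :class:`RunConfig`, which can be loaded from a
TOML file and is echoed into the output directory for provenance. Outputs are
written to a temporary staging directory and moved into place only when every
stage has succeeded, so a failed run never leaves a partial report behind.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .grouping import DEFAULT_KEY_FIELDS, build_experiments, experiments_frame, records_frame_with_ids
from .ingest import read_database, validate_records
from .metrics import SummaryReport, summarize
from .vocab import OutcomeLevel, VocabularyMap, default_vocabulary

logger = logging.getLogger("optoaudit")

__all__ = ["RunConfig", "run_report", "load_config", "vocabulary_from_dict"]


@dataclass
class RunConfig:
    """Everything a report run needs, serializable to/from TOML."""

    input_path: str
    out_dir: str = "optoaudit_report"
    columns: dict[str, str] = field(default_factory=dict)
    key_fields: tuple[str, ...] = DEFAULT_KEY_FIELDS
    strict: bool = True
    sheet: int | str = 0
    outcome_map: dict[str, str] = field(default_factory=dict)
    region_synonyms: dict[str, str] = field(default_factory=dict)
    region_classes: dict[str, str] = field(default_factory=dict)

    def vocabulary(self) -> VocabularyMap:
        vocab = default_vocabulary()
        for raw, level in self.outcome_map.items():
            vocab.outcome_map[raw.strip().lower()] = OutcomeLevel[level.upper()]
        vocab.region_synonyms.update(
            {k.strip().lower(): v for k, v in self.region_synonyms.items()}
        )
        vocab.region_classes.update({k: v.upper() for k, v in self.region_classes.items()})
        return vocab

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "out_dir": self.out_dir,
            "columns": dict(self.columns),
            "key_fields": list(self.key_fields),
            "strict": self.strict,
            "sheet": self.sheet,
            "outcome_map": dict(self.outcome_map),
            "region_synonyms": dict(self.region_synonyms),
            "region_classes": dict(self.region_classes),
        }


def vocabulary_from_dict(data: dict) -> VocabularyMap:
    """Build a vocabulary from parsed config sections (used by the CLI)."""
    cfg = RunConfig(
        input_path="",
        outcome_map=data.get("outcome_map", {}),
        region_synonyms=data.get("region_synonyms", {}),
        region_classes=data.get("region_classes", {}),
    )
    return cfg.vocabulary()


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from a TOML file; keyword overrides win."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    kwargs = {
        "input_path": data.get("input_path", ""),
        "out_dir": data.get("out_dir", "optoaudit_report"),
        "columns": data.get("columns", {}),
        "key_fields": tuple(data.get("key_fields", DEFAULT_KEY_FIELDS)),
        "strict": data.get("strict", True),
        "sheet": data.get("sheet", 0),
        "outcome_map": data.get("outcome_map", {}),
        "region_synonyms": data.get("region_synonyms", {}),
        "region_classes": data.get("region_classes", {}),
    }
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def _figure1_frame(report: SummaryReport) -> pd.DataFrame:
    rows = [
        {"panel": domain, "category": level, "count": n}
        for domain, counts in report.figure1.items()
        for level, n in counts.items()
    ]
    return pd.DataFrame(rows)


def _figure2_frame(report: SummaryReport) -> pd.DataFrame:
    rows = []
    for conj, (total, any_n, strong_n) in report.figure2.items():
        rows.append({"panel": conj, "category": "total_tested", "count": total})
        rows.append({"panel": conj, "category": "any_success", "count": any_n})
        rows.append({"panel": conj, "category": "strong_in_both", "count": strong_n})
    return pd.DataFrame(rows)


def run_report(config: RunConfig) -> SummaryReport:
    """Execute the full pipeline and write all outputs atomically.

    Writes into ``config.out_dir``: ``report.json``, ``metrics.csv``,
    ``experiments.csv``, ``records_with_ids.csv``, ``figure1_data.csv``,
    ``figure2_data.csv``, ``validation.json`` and ``config.json``.
    """
    vocab = config.vocabulary()
    records = read_database(
        config.input_path, config.columns or None, vocab, strict=config.strict, sheet=config.sheet
    )
    validation = validate_records(records)
    experiments = build_experiments(records, config.key_fields)
    report = summarize(records, experiments, vocab)

    out_dir = Path(config.out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".optoaudit_stage_", dir=out_dir.parent))
    try:
        (staging / "report.json").write_text(report.to_json() + "\n")
        report.metrics_frame().to_csv(staging / "metrics.csv", index=False)
        experiments_frame(experiments).to_csv(staging / "experiments.csv", index=False)
        records_frame_with_ids(records, config.key_fields).to_csv(
            staging / "records_with_ids.csv", index=False
        )
        _figure1_frame(report).to_csv(staging / "figure1_data.csv", index=False)
        _figure2_frame(report).to_csv(staging / "figure2_data.csv", index=False)
        (staging / "validation.json").write_text(validation.to_json() + "\n")
        (staging / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        if out_dir.exists():
            shutil.rmtree(out_dir)
        staging.rename(out_dir)
    except BaseException:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    logger.info(
        "report written to %s (%d injections, %d experiments)",
        out_dir,
        report.n_injections,
        report.n_experiments,
    )
    return report
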