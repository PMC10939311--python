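"""Ordinal outcome scale, outcome domains, and controlled-vocabulary harmonization.

Multi-lab injection databases annotate outcomes with free text ("Strong",
"mixed", "not tested", blank cells ...). Every downstream statistic assumes a
four-level ordinal scale per assessment domain, so the first pipeline stage
maps raw strings onto that scale through an explicit, user-overridable
vocabulary. Lookups of undeclared strings are detectable events: an error in
strict mode, a logged MISSING in lenient mode — never a silent coercion.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger("optoaudit")

__all__ = [
    "OutcomeLevel",
    "Domain",
    "VocabularyMap",
    "VocabularyError",
    "default_vocabulary",
    "harmonize_outcome",
    "canonicalize_region",
    "normalize_token",
]


class OutcomeLevel(enum.IntEnum):
    """Four-level ordinal outcome for one assessment domain of one injection.

    MISSING means the domain was not assessed or not reported — it is not a
    failure and is excluded from rate denominators downstream.
    """

    MISSING = 0
    FAILED = 1
    WEAK = 2
    STRONG = 3


class Domain(enum.Enum):
    """The three ways an injection's efficacy is evaluated."""

    HISTOLOGY = "histology"
    PHYSIOLOGY = "physiology"
    BEHAVIOR = "behavior"


class VocabularyError(KeyError):
    """Raised in strict mode when a raw annotation is not in the vocabulary."""


_WS = re.compile(r"\s+")


def normalize_token(raw: str) -> str:
    """Lower-case, trim and collapse internal whitespace."""
    return _WS.sub(" ", str(raw).strip().lower())


#: Strings treated as "no annotation" before any vocabulary lookup.
NA_TOKENS = frozenset({"", "na", "n/a", "nan", "-", "--", "not tested", "missing", "nt"})


@dataclass
class VocabularyMap:
    """Total mappings from raw annotation strings to canonical values.

    Attributes
    ----------
    outcome_map
        normalized raw outcome string -> OutcomeLevel.
    region_synonyms
        normalized raw region string -> canonical region label. Ships empty
        by default: inventing merges would silently change the experiment
        count, so users supply the table from the deposited analysis config.
    region_classes
        canonical region label -> region class, one of
        ``"PRIMARY_SENSORIMOTOR"`` or ``"OTHER"``.
    """

    outcome_map: dict[str, OutcomeLevel] = field(default_factory=dict)
    region_synonyms: dict[str, str] = field(default_factory=dict)
    region_classes: dict[str, str] = field(default_factory=dict)

    def region_class(self, canonical_region: str) -> str:
        """Class of a canonical region; unmapped regions are OTHER (logged)."""
        cls = self.region_classes.get(canonical_region)
        if cls is None:
            logger.warning("region %r absent from region_classes; classified OTHER", canonical_region)
            return "OTHER"
        return cls


#: Default raw-outcome vocabulary. "mixed"/"partial" rank below strong, with
#: the weak successes; unqualified affirmations ("yes", "success") carry no
#: strength grading and are also placed at WEAK so they never inflate the
#: strict (strong-only) rates.
DEFAULT_OUTCOME_MAP: dict[str, OutcomeLevel] = {
    "strong": OutcomeLevel.STRONG,
    "strong success": OutcomeLevel.STRONG,
    "weak": OutcomeLevel.WEAK,
    "weak success": OutcomeLevel.WEAK,
    "mixed": OutcomeLevel.WEAK,
    "partial": OutcomeLevel.WEAK,
    "yes": OutcomeLevel.WEAK,
    "success": OutcomeLevel.WEAK,
    "no": OutcomeLevel.FAILED,
    "none": OutcomeLevel.FAILED,
    "failed": OutcomeLevel.FAILED,
    "failure": OutcomeLevel.FAILED,
}


def default_vocabulary() -> VocabularyMap:
    """The vocabulary used when no config overrides it (synonym table empty)."""
    return VocabularyMap(outcome_map=dict(DEFAULT_OUTCOME_MAP))


def harmonize_outcome(
    raw: str | None,
    vocab: VocabularyMap,
    *,
    lenient: bool = False,
    source_row: int | None = None,
) -> OutcomeLevel:
    """Map one raw outcome annotation onto the four-level ordinal scale.

    Empty and NA-like strings map to MISSING. Undeclared strings raise
    :class:`VocabularyError` in strict mode (the default) and map to MISSING
    with a logged warning in lenient mode. Pure: identical inputs always give
    identical outputs.
    """
    if raw is None:
        return OutcomeLevel.MISSING
    token = normalize_token(raw)
    if token in NA_TOKENS:
        return OutcomeLevel.MISSING
    try:
        return vocab.outcome_map[token]
    except KeyError:
        where = f" (source row {source_row})" if source_row is not None else ""
        if lenient:
            logger.warning("outcome %r not in vocabulary%s; treated as MISSING", raw, where)
            return OutcomeLevel.MISSING
        raise VocabularyError(f"outcome annotation {raw!r} not in vocabulary{where}") from None


def canonicalize_region(raw: str, vocab: VocabularyMap) -> str:
    """Canonical region label: trim, case-normalize, apply the synonym table.

    Unmapped labels pass through upper-cased with a logged warning, so the
    operation is idempotent and never drops a region.
    """
    token = normalize_token(raw)
    if token in vocab.region_synonyms:
        return vocab.region_synonyms[token]
    canonical = token.upper()
    # second-chance lookup so already-canonical spellings stay stable
    if normalize_token(canonical) in vocab.region_synonyms:
        return vocab.region_synonyms[normalize_token(canonical)]
    if vocab.region_synonyms:
        logger.debug("region %r not in synonym table; passing through as %r", raw, canonical)
    return canonical
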