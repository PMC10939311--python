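"""Hierarchical synthetic injection databases with known ground truth.

The generator emulates the structure the analysis assumes: injections nested
in experiments (region within animal within lab), heterogeneous
injections-per-experiment counts, experiment-level per-domain missingness, and
cross-domain outcome correlation induced by a single latent per-experiment
"quality" draw. With the correlation turned off, every pipeline statistic has
a closed form (:func:`expected_rates`), so the whole pipeline can be checked
against analytic expectations without any real data.

Randomness is deterministic given ``(params, seed)``: each animal and each
experiment owns an independent substream keyed by its position in the
hierarchy, so changing one hierarchy size never reshuffles unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import InjectionRecord
from .vocab import Domain, OutcomeLevel

__all__ = [
    "GeneratorParams",
    "SyntheticCohort",
    "ParameterError",
    "generate_cohort",
    "expected_rates",
    "make_worked_fixture",
    "cohort_frame",
    "write_cohort_csv",
    "survey_scale_params",
    "WORKED_FIXTURE_EXPECTED",
]


class ParameterError(ValueError):
    """Invalid probability or hierarchy specification."""


_LEVEL_LABEL = {
    OutcomeLevel.MISSING: "",
    OutcomeLevel.FAILED: "failed",
    OutcomeLevel.WEAK: "weak",
    OutcomeLevel.STRONG: "strong",
}

#: Default region pool: label and region class. Two thirds of the pool are
#: primary sensory/motor areas, mirroring how heavily real NHP optogenetics
#: work concentrates there.
DEFAULT_REGION_POOL: tuple[tuple[str, str], ...] = (
    ("V1", "PRIMARY_SENSORIMOTOR"),
    ("V2", "PRIMARY_SENSORIMOTOR"),
    ("M1", "PRIMARY_SENSORIMOTOR"),
    ("S1", "PRIMARY_SENSORIMOTOR"),
    ("A1", "PRIMARY_SENSORIMOTOR"),
    ("PMD", "PRIMARY_SENSORIMOTOR"),
    ("AMY", "OTHER"),
    ("HPC", "OTHER"),
    ("DLPFC", "OTHER"),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the hierarchical cohort generator.

    ``injections_per_experiment`` is either a constant count or a mapping
    ``{m: probability}`` over positive counts. ``outcome_probs`` gives, per
    domain, the per-injection probabilities of (failed, weak, strong)
    conditional on the domain being assessed; each triple must sum to 1.
    ``cross_domain_rho`` in [0, 1] is the probability that an injection's
    outcome draw (and an experiment's assessment draw) reuses the experiment's
    shared latent uniform instead of a fresh one — 0 gives full independence,
    1 makes all domains of an experiment move together. The mixture preserves
    all marginal probabilities exactly. ``injection_missing_prob`` adds
    sporadic per-injection annotation gaps on top of the experiment-level
    assessment indicators; it is off by default.
    """

    n_labs: int = 3
    animals_per_lab: int | Sequence[int] = 4
    regions_per_animal: int = 2
    injections_per_experiment: int | Mapping[int, float] = 3
    assess_prob: Mapping[Domain, float] = field(
        default_factory=lambda: {Domain.HISTOLOGY: 0.68, Domain.PHYSIOLOGY: 0.51, Domain.BEHAVIOR: 0.19}
    )
    outcome_probs: Mapping[Domain, tuple[float, float, float]] = field(
        default_factory=lambda: {
            Domain.HISTOLOGY: (0.30, 0.22, 0.48),
            Domain.PHYSIOLOGY: (0.33, 0.16, 0.51),
            Domain.BEHAVIOR: (0.63, 0.095, 0.275),
        }
    )
    cross_domain_rho: float = 0.0
    injection_missing_prob: float = 0.0
    region_pool: tuple[tuple[str, str], ...] = DEFAULT_REGION_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.injection_missing_prob <= 1.0:
            raise ParameterError("injection_missing_prob must be in [0, 1]")
        if self.n_labs < 1 or self.regions_per_animal < 1:
            raise ParameterError("hierarchy sizes must be >= 1")
        if self.regions_per_animal > len(self.region_pool):
            raise ParameterError("regions_per_animal exceeds the region pool size")
        for d in Domain:
            p = self.assess_prob[d]
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"assess_prob[{d}] = {p} outside [0, 1]")
            triple = self.outcome_probs[d]
            if len(triple) != 3 or any(q < 0 or q > 1 for q in triple):
                raise ParameterError(f"outcome_probs[{d}] must be three probabilities")
            if abs(sum(triple) - 1.0) > 1e-9:
                raise ParameterError(f"outcome_probs[{d}] must sum to 1, got {sum(triple)!r}")
        if not 0.0 <= self.cross_domain_rho <= 1.0:
            raise ParameterError("cross_domain_rho must be in [0, 1]")
        for m, p in self._injection_dist().items():
            if m < 1 or p < 0:
                raise ParameterError("injections_per_experiment must be over positive counts")
        if abs(sum(self._injection_dist().values()) - 1.0) > 1e-9:
            raise ParameterError("injections_per_experiment probabilities must sum to 1")

    def _animals(self) -> list[int]:
        if isinstance(self.animals_per_lab, int):
            if self.animals_per_lab < 1:
                raise ParameterError("animals_per_lab must be >= 1")
            return [self.animals_per_lab] * self.n_labs
        counts = list(self.animals_per_lab)
        if len(counts) != self.n_labs:
            raise ParameterError("per-lab animal list length must equal n_labs")
        return counts

    def _injection_dist(self) -> dict[int, float]:
        if isinstance(self.injections_per_experiment, int):
            return {self.injections_per_experiment: 1.0}
        return {int(m): float(p) for m, p in self.injections_per_experiment.items()}

    @property
    def n_experiments(self) -> int:
        return sum(self._animals()) * self.regions_per_animal


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus the ground truth that produced them."""

    records: tuple[InjectionRecord, ...]
    params: GeneratorParams
    latent: tuple[float, ...]  # per-experiment shared latent uniform


def _draw_level(u: float, probs: tuple[float, float, float]) -> OutcomeLevel:
    """Inverse-CDF draw over (failed, weak, strong) at uniform u."""
    pf, pw, _ = probs
    if u < pf:
        return OutcomeLevel.FAILED
    if u < pf + pw:
        return OutcomeLevel.WEAK
    return OutcomeLevel.STRONG


def generate_cohort(params: GeneratorParams) -> SyntheticCohort:
    """Generate one synthetic cohort (bit-reproducible for fixed params+seed).

    Assessment is decided at experiment level: a domain is either annotated on
    every injection of the experiment or on none, matching how "tested" is
    defined downstream. When ``cross_domain_rho > 0`` the assessment and
    outcome draws reuse the experiment's shared latent uniform with
    probability rho, correlating domains within an experiment.
    """
    dist = params._injection_dist()
    ms = np.array(sorted(dist))
    mps = np.array([dist[m] for m in ms])
    rho = params.cross_domain_rho
    domains = tuple(Domain)

    records: list[InjectionRecord] = []
    latents: list[float] = []
    source_row = 0
    for li, n_animals in enumerate(params._animals()):
        lab = f"lab{li + 1:02d}"
        for ai in range(n_animals):
            animal = f"m{li + 1:02d}{ai + 1:02d}"
            animal_rng = np.random.default_rng(np.random.SeedSequence([params.seed, li, ai]))
            region_idx = animal_rng.choice(
                len(params.region_pool), size=params.regions_per_animal, replace=False
            )
            for k, ri in enumerate(region_idx):
                region = params.region_pool[int(ri)][0]
                rng = np.random.default_rng(np.random.SeedSequence([params.seed, li, ai, k]))
                q_assess = rng.random()
                q_outcome = rng.random()
                latents.append(q_outcome)
                m = int(rng.choice(ms, p=mps))
                assessed = {}
                for d in domains:
                    u = q_assess if rng.random() < rho else rng.random()
                    assessed[d] = u < params.assess_prob[d]
                for _ in range(m):
                    source_row += 1
                    outcomes = {}
                    for d in domains:
                        if not assessed[d]:
                            outcomes[d] = OutcomeLevel.MISSING
                            continue
                        if params.injection_missing_prob and rng.random() < params.injection_missing_prob:
                            outcomes[d] = OutcomeLevel.MISSING  # sporadic per-injection gap
                            continue
                        u = q_outcome if rng.random() < rho else rng.random()
                        outcomes[d] = _draw_level(u, params.outcome_probs[d])
                    records.append(
                        InjectionRecord(
                            lab_id=lab,
                            animal_id=animal,
                            region_raw=region,
                            region_canonical=region,
                            vector_label="aav",
                            outcomes=outcomes,
                            source_row=source_row,
                        )
                    )
    return SyntheticCohort(records=tuple(records), params=params, latent=tuple(latents))


def expected_rates(params: GeneratorParams) -> dict[str, float]:
    """Closed-form experiment-level expectations (independent case only).

    For an assessed domain with per-injection strong probability ``p_strong``
    and ``m`` i.i.d. injections, the experiment aggregates to STRONG with
    probability ``1 - (1 - p_strong)**m`` and to at-least-WEAK with probability
    ``1 - p_failed**m``; both are averaged over the injections-per-experiment
    distribution. Conjunction rates multiply the per-domain terms, which is
    exact only when ``cross_domain_rho = 0``.
    """
    if params.cross_domain_rho != 0.0:
        raise ParameterError("closed forms require cross_domain_rho = 0")
    if params.injection_missing_prob != 0.0:
        raise ParameterError("closed forms require injection_missing_prob = 0")
    dist = params._injection_dist()
    out: dict[str, float] = {}
    per_domain: dict[Domain, dict[str, float]] = {}
    for d in Domain:
        pf, _, ps = params.outcome_probs[d]
        p_any = sum(p * (1 - pf**m) for m, p in dist.items())
        p_strong = sum(p * (1 - (1 - ps) ** m) for m, p in dist.items())
        per_domain[d] = {"any": p_any, "strong_only": p_strong}
        out[f"domain:{d.value}:any"] = p_any
        out[f"domain:{d.value}:strong_only"] = p_strong
        out[f"domain:{d.value}:tested"] = params.assess_prob[d]
    for pair in ((Domain.BEHAVIOR, Domain.PHYSIOLOGY), (Domain.BEHAVIOR, Domain.HISTOLOGY)):
        label = "+".join(sorted(d.value for d in pair))
        out[f"conjunction:{label}:tested"] = float(
            np.prod([params.assess_prob[d] for d in pair])
        )
        for name in ("any", "strong_only"):
            out[f"conjunction:{label}:{name}"] = float(
                np.prod([per_domain[d][name] for d in pair])
            )
    out["triple:tested"] = float(np.prod([params.assess_prob[d] for d in Domain]))
    for name in ("any", "strong_only"):
        out[f"triple:{name}"] = float(np.prod([per_domain[d][name] for d in Domain]))
    return out


def survey_scale_params(seed: int = 0, cross_domain_rho: float = 0.5) -> GeneratorParams:
    """Defaults at the scale of the real multi-lab database.

    45 labs with ~4 animals each (≈200 monkeys), two regions per animal
    (≈360 experiments) and a skewed injections-per-experiment distribution
    with mean ≈2.8 (≈1000 injections); assessment probabilities follow the
    observed per-domain tested shares and outcome probabilities were chosen so
    the aggregated experiment-level rates land near the observed ones.
    """
    return GeneratorParams(
        n_labs=45,
        animals_per_lab=4,
        regions_per_animal=2,
        injections_per_experiment={
            1: 0.35, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.08, 6: 0.05, 7: 0.04, 8: 0.03,
        },
        cross_domain_rho=cross_domain_rho,
        seed=seed,
    )


def cohort_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Cohort in the CSV schema the ingest stage reads (round-trip property)."""
    rows = []
    for r in cohort.records:
        rows.append(
            {
                "lab": r.lab_id,
                "animal": r.animal_id,
                "region": r.region_raw,
                "vector": r.vector_label or "",
                **{d.value: _LEVEL_LABEL[r.outcomes[d]] for d in Domain},
            }
        )
    return pd.DataFrame(
        rows, columns=["lab", "animal", "region", "vector", "histology", "physiology", "behavior"]
    )


def write_cohort_csv(cohort: SyntheticCohort, path: str | Path) -> Path:
    path = Path(path)
    cohort_frame(cohort).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Worked fixture: a hand-built 10-record, 4-experiment cohort whose every
# metric was enumerated by hand. The expected values are frozen here and
# asserted against the full pipeline in the test suite.
# ---------------------------------------------------------------------------

_WORKED_ROWS: tuple[tuple[str, str, str, str, str, str, str], ...] = (
    # lab,   animal, region, vector, histology, physiology, behavior
    ("laba", "m1", "V1", "aav5", "strong", "weak", ""),
    ("laba", "m1", "V1", "aav5", "weak", "failed", "weak"),
    ("laba", "m1", "AMY", "aav5", "failed", "", ""),
    ("laba", "m2", "V1", "aav5", "strong", "strong", "strong"),
    ("labb", "m3", "V1", "lenti", "weak", "weak", "failed"),
    ("labb", "m3", "V1", "lenti", "", "failed", "failed"),
    ("labb", "m3", "V1", "lenti", "mixed", "", "weak"),
    ("laba", "m1", "V1", "aav5", "", "", "strong"),
    ("laba", "m2", "V1", "aav5", "strong", "weak", ""),
    ("labb", "m3", "V1", "lenti", "weak", "failed", ""),
)

#: Hand-enumerated expectations for the worked fixture. Experiments:
#: laba/m1/V1 (rows 1,2,8), laba/m1/AMY (row 3), laba/m2/V1 (rows 4,9),
#: labb/m3/V1 (rows 5,6,7,10).
WORKED_FIXTURE_EXPECTED: dict = {
    "n_injections": 10,
    "n_experiments": 4,
    "group_sizes": (3, 1, 2, 4),
    "domain_rates": {
        "histology": {"any": (3, 4), "strong_only": (2, 4)},
        "physiology": {"any": (3, 3), "strong_only": (1, 3)},
        "behavior": {"any": (3, 3), "strong_only": (2, 3)},
    },
    "conjunctions": {
        "behavior+physiology": {"any": (3, 3), "strong_only": (1, 3)},
        "behavior+histology": {"any": (3, 3), "strong_only": (2, 3)},
    },
    "triple": {"any": (3, 3), "strong_only": (1, 3)},
    "triple_by_region": {"V1": (3, 3)},
    "region": {
        "sensorimotor_share": (3, 4),
        "sensorimotor_behavior_and_physiology_tested": (3, 3),
    },
    "injection_level": {"any": (8, 10), "strong_only": (4, 10)},
    "headline_percent": {"any": "100.0%", "strong_only": "50.0%"},
    "figure1": {
        "histology": {"MISSING": 0, "FAILED": 1, "WEAK": 1, "STRONG": 2},
        "physiology": {"MISSING": 1, "FAILED": 0, "WEAK": 2, "STRONG": 1},
        "behavior": {"MISSING": 1, "FAILED": 0, "WEAK": 1, "STRONG": 2},
    },
    "figure2": {
        "behavior+physiology": (3, 3, 1),
        "behavior+histology": (3, 3, 2),
    },
}


def make_worked_fixture() -> SyntheticCohort:
    """The fixed hand-enumerated cohort used in docs and tests.

    Region classes for it: V1 is PRIMARY_SENSORIMOTOR, AMY is OTHER.
    """
    from .vocab import default_vocabulary

    vocab = default_vocabulary()
    records = []
    for i, (lab, animal, region, vector, hist, phys, beh) in enumerate(_WORKED_ROWS):
        records.append(
            InjectionRecord(
                lab_id=lab,
                animal_id=animal,
                region_raw=region,
                region_canonical=region,
                vector_label=vector,
                outcomes={
                    Domain.HISTOLOGY: _parse_label(hist, vocab),
                    Domain.PHYSIOLOGY: _parse_label(phys, vocab),
                    Domain.BEHAVIOR: _parse_label(beh, vocab),
                },
                source_row=i + 1,
            )
        )
    params = GeneratorParams(n_labs=2, animals_per_lab=[2, 1], regions_per_animal=1, seed=0)
    return SyntheticCohort(records=tuple(records), params=params, latent=())


def _parse_label(label: str, vocab) -> OutcomeLevel:
    from .vocab import harmonize_outcome

    return harmonize_outcome(label, vocab)
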