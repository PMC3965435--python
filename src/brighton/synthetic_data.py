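"""Synthetic VAERS-like corpora with planted Brighton-positive cases.

Real AEFI extracts are not redistributable (the terminology is licensed
and the expert-adjudicated report sets were released only under FOIA),
so every other module is exercised on generated corpora that emulate the
relevant structure of passive surveillance data:

* a MedDRA-like background vocabulary of opaque codes (``SYN:000001``…)
  whose frequencies follow a Zipf law — spontaneous reports are dominated
  by a few very common nonspecific terms;
* planted positive cases: a certainty level is drawn from ``level_mix``,
  a minimal criterion set satisfying that level's rule is sampled from
  the updated (negation-free) catalog, and the corresponding
  reporting-vocabulary codes are emitted, sometimes through the compound
  "with/without" codes so both guideline variants can be exercised on
  identical bytes;
* reporting noise: each supporting finding is *omitted* with probability
  ``p_omit_finding`` (omission yields unknown, never absent — passive
  reports do not distinguish unchecked from negative), background
  reports acquire isolated criterion atoms at a configured rate, and an
  anaphylaxis diagnosis code is attached with class-conditional
  probabilities (diagnosis codes are notoriously unreliable: most
  adjudicated cases carry none).

Generation is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from brighton.core_model import (
    CASE,
    NON_CASE,
    ReadDiagnostics,
    Report,
    Status,
    build_report,
    default_mapping,
    write_labels,
    write_reports,
)
from brighton.guideline_engine import (
    And,
    AtLeast,
    Atom,
    CriteriaCatalog,
    CriterionExpr,
    Not,
    Or,
    build_catalog,
)

ANAPHYLAXIS_CODE = "anaphylactic_reaction"

# compound reporting codes: (code, positive atoms it asserts, atoms it
# asserts absent)
_COMPOUNDS = (
    (
        "generalized_pruritus_with_skin_rash",
        frozenset({"generalized_pruritus", "skin_rash"}),
        frozenset(),
    ),
    (
        "generalized_pruritus_without_skin_rash",
        frozenset({"generalized_pruritus"}),
        frozenset({"skin_rash"}),
    ),
    (
        "capillary_refill_gt3s_without_hypotension",
        frozenset({"capillary_refill_gt3s"}),
        frozenset({"measured_hypotension"}),
    ),
    (
        "difficulty_breathing_without_wheeze_or_stridor",
        frozenset({"difficulty_breathing"}),
        frozenset({"bilateral_wheeze", "stridor"}),
    ),
)

P_COMPOUND_CODE = 0.5  # chance an eligible finding is serialized compound


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one generated corpus.

    Defaults emulate the H1N1 surveillance setting the engine is meant
    for: ~6000 reports with a ~4% adjudicated-case prevalence, positive
    levels dominated by Level 2, moderate under-reporting of supporting
    findings, and diagnosis codes present on only a few percent of true
    cases.
    """

    n_reports: int = 6034
    prevalence: float = 0.039
    level_mix: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.68, 3: 0.02}
    )
    p_omit_finding: float = 0.15
    p_spurious_brighton_term: float = 0.05
    p_anaphylaxis_code_given_case: float = 0.04
    p_anaphylaxis_code_given_noncase: float = 0.0005
    vocab_size: int = 2000
    background_term_law: float = 1.5  # Zipf exponent
    background_mean_terms: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for name in (
            "prevalence",
            "p_omit_finding",
            "p_spurious_brighton_term",
            "p_anaphylaxis_code_given_case",
            "p_anaphylaxis_code_given_noncase",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if set(self.level_mix) - {1, 2, 3}:
            raise ValueError("level_mix keys must be levels 1, 2, 3")
        total = sum(self.level_mix.values())
        if total <= 0:
            raise ValueError("level_mix must have positive total mass")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["level_mix"] = {str(k): v for k, v in self.level_mix.items()}
        return d


@dataclass
class SyntheticCorpus:
    """Generated reports with gold labels and planting provenance."""

    reports: list
    labels: dict  # report_id -> case | non_case
    planted_levels: dict  # report_id -> level, positives only
    config: SimulationConfig
    diagnostics: ReadDiagnostics = field(default_factory=ReadDiagnostics)


# --- minimal witness sampling -------------------------------------------


def minimal_satisfying_atoms(expr: CriterionExpr, rng: np.random.Generator) -> set:
    """A minimal atom set making a negation-free expression present."""
    if isinstance(expr, Atom):
        return {expr.name}
    if isinstance(expr, Not):
        raise ValueError("cannot plant through a negated expression")
    if isinstance(expr, And):
        out: set = set()
        for sub in expr.operands:
            out |= minimal_satisfying_atoms(sub, rng)
        return out
    if isinstance(expr, Or):
        choice = expr.operands[int(rng.integers(len(expr.operands)))]
        return minimal_satisfying_atoms(choice, rng)
    if isinstance(expr, AtLeast):
        idx = rng.choice(len(expr.operands), size=expr.k, replace=False)
        out = set()
        for i in idx:
            out |= minimal_satisfying_atoms(expr.operands[int(i)], rng)
        return out
    raise TypeError(f"unsupported expression node {type(expr).__name__}")


def _pick(rng: np.random.Generator, items: list):
    if not items:
        raise ValueError("no criterion available for the requested witness")
    return items[int(rng.integers(len(items)))]


def sample_level_atoms(
    level: int, catalog: CriteriaCatalog, rng: np.random.Generator
) -> set:
    """Sample a minimal criterion-atom set that satisfies ``level``'s rule
    under the (negation-free) planting catalog.

    Witnesses are built so they do not accidentally satisfy a *higher*
    level; a planted report may still classify higher once noise terms
    are added, which is why recovery is asserted as level >= planted.
    """
    by = catalog.criteria_by
    derm, cardio, resp = "dermatologic_mucosal", "cardiovascular", "respiratory"
    other_minor_systems = [derm, "gastrointestinal", "laboratory"]
    atoms: set = set()
    if level == 1:
        atoms |= minimal_satisfying_atoms(_pick(rng, by(derm, "major")).expr, rng)
        side = cardio if rng.random() < 0.5 else resp
        atoms |= minimal_satisfying_atoms(_pick(rng, by(side, "major")).expr, rng)
    elif level == 2:
        clause = int(rng.integers(3))
        if clause == 0:  # both non-dermatologic majors
            atoms |= minimal_satisfying_atoms(_pick(rng, by(cardio, "major")).expr, rng)
            atoms |= minimal_satisfying_atoms(_pick(rng, by(resp, "major")).expr, rng)
        elif clause == 1:  # one major + a minor from another system
            anchor = cardio if rng.random() < 0.5 else resp
            atoms |= minimal_satisfying_atoms(_pick(rng, by(anchor, "major")).expr, rng)
            other = _pick(
                rng,
                [s for s in other_minor_systems + [cardio, resp] if s != anchor],
            )
            atoms |= minimal_satisfying_atoms(_pick(rng, by(other, "minor")).expr, rng)
        else:  # dermatologic major + cardiovascular/respiratory minor
            atoms |= minimal_satisfying_atoms(_pick(rng, by(derm, "major")).expr, rng)
            side = cardio if rng.random() < 0.5 else resp
            atoms |= minimal_satisfying_atoms(_pick(rng, by(side, "minor")).expr, rng)
    elif level == 3:
        anchor = cardio if rng.random() < 0.5 else resp
        atoms |= minimal_satisfying_atoms(_pick(rng, by(anchor, "minor")).expr, rng)
        pool = [s for s in [cardio, resp] + other_minor_systems if s != anchor]
        chosen = rng.choice(len(pool), size=2, replace=False)
        for i in chosen:
            atoms |= minimal_satisfying_atoms(
                _pick(rng, by(pool[int(i)], "minor")).expr, rng
            )
    else:
        raise ValueError(f"no witness strategy for level {level!r}")
    return atoms


# --- serialization through reporting codes -------------------------------


def _serialize_atoms(atoms: set, rng: np.random.Generator) -> list:
    """Emit reporting-vocabulary codes for a planted atom set, routing
    eligible findings through compound codes half the time."""
    remaining = set(atoms)
    codes: list[str] = []
    for code, positives, absents in _COMPOUNDS:
        if positives <= remaining and not (absents & remaining):
            if rng.random() < P_COMPOUND_CODE:
                codes.append(code)
                remaining -= positives
    codes.extend(sorted(remaining))
    return codes


# --- corpus generation ---------------------------------------------------


def generate(config: SimulationConfig) -> SyntheticCorpus:
    """Generate a labeled corpus under ``config``.

    Positives draw a certainty level from ``level_mix`` and receive the
    codes of a minimal witness for it (plus the two temporal atoms);
    every emitted criterion code is then dropped independently with
    ``p_omit_finding``.  All reports receive Zipf-distributed background
    terms; non-cases may acquire one spurious criterion atom; anaphylaxis
    diagnosis codes attach with the class-conditional probabilities.
    """
    rng = np.random.default_rng(config.seed)
    mapping = default_mapping()
    catalog = build_catalog("updated")

    levels = sorted(k for k, v in config.level_mix.items() if v > 0)
    mix = np.array([config.level_mix[k] for k in levels], dtype=float)
    mix = mix / mix.sum()
    for level in levels:  # fail fast on an unplantable mix
        sample_level_atoms(level, catalog, np.random.default_rng(0))

    criterion_atoms = sorted(catalog.atom_codes - set(catalog.temporal_atoms))
    zipf_p = np.arange(1, config.vocab_size + 1, dtype=float) ** (
        -config.background_term_law
    )
    zipf_p /= zipf_p.sum()

    width = max(6, len(str(config.n_reports)))
    reports: list[Report] = []
    labels: dict[str, str] = {}
    planted: dict[str, int] = {}
    diagnostics = ReadDiagnostics()

    for i in range(config.n_reports):
        rid = f"R{i + 1:0{width}d}"
        is_case = rng.random() < config.prevalence
        codes: list[str] = []
        if is_case:
            level = int(levels[rng.choice(len(levels), p=mix)])
            planted[rid] = level
            atoms = sample_level_atoms(level, catalog, rng)
            emitted = _serialize_atoms(atoms, rng) + list(catalog.temporal_atoms)
            codes.extend(
                c for c in emitted if rng.random() >= config.p_omit_finding
            )
        else:
            if rng.random() < config.p_spurious_brighton_term:
                codes.append(criterion_atoms[int(rng.integers(len(criterion_atoms)))])
        p_flag = (
            config.p_anaphylaxis_code_given_case
            if is_case
            else config.p_anaphylaxis_code_given_noncase
        )
        if rng.random() < p_flag:
            codes.append(ANAPHYLAXIS_CODE)
        n_bg = int(rng.poisson(config.background_mean_terms))
        if n_bg > 0:
            ranks = rng.choice(config.vocab_size, size=n_bg, p=zipf_p) + 1
            codes.extend(f"SYN:{int(r):06d}" for r in ranks)
        codes = sorted(set(codes))
        reports.append(build_report(rid, codes, mapping, None, diagnostics))
        labels[rid] = CASE if is_case else NON_CASE

    return SyntheticCorpus(
        reports=reports,
        labels=labels,
        planted_levels=planted,
        config=config,
        diagnostics=diagnostics,
    )


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> dict:
    """Write ``reports.csv``, ``labels.csv`` and ``provenance.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_reports(corpus.reports, out / "reports.csv")
    write_labels(corpus.labels, out / "labels.csv")
    provenance = {
        "config": corpus.config.to_dict(),
        "planted_levels": corpus.planted_levels,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return provenance


# --- in-text worked-example fixtures -------------------------------------

_FIXTURES = {
    # three present findings; open-world it reaches no level, closed-world
    # the difficulty-breathing minor respiratory criterion fires
    "worked_369695": {
        "codes": ["generalized_erythema", "generalized_urticaria", "difficulty_breathing"],
        "statuses": None,
    },
    # the skin-rash family: a diagnosis-confirmation report (anaphylaxis
    # code attached) with measured hypotension, generalized pruritus and
    # both temporal findings; the three variants differ only in the
    # recorded skin-rash status
    "skin_rash_yes": {
        "codes": [
            "rapid_progression",
            "sudden_onset",
            "measured_hypotension",
            "generalized_pruritus",
            "skin_rash",
            ANAPHYLAXIS_CODE,
        ],
        "statuses": ["present", "present", "present", "present", "present", "present"],
    },
    "skin_rash_no": {
        "codes": [
            "rapid_progression",
            "sudden_onset",
            "measured_hypotension",
            "generalized_pruritus",
            "skin_rash",
            ANAPHYLAXIS_CODE,
        ],
        "statuses": ["present", "present", "present", "present", "absent", "present"],
    },
    "skin_rash_unknown": {
        "codes": [
            "rapid_progression",
            "sudden_onset",
            "measured_hypotension",
            "generalized_pruritus",
            ANAPHYLAXIS_CODE,
        ],
        "statuses": None,
    },
    # one minor cardiovascular criterion, one minor respiratory, one minor
    # gastrointestinal: the two Level-3 readings disagree on this report
    "level3_interpretation": {
        "codes": [
            "tachycardia",
            "reduced_central_pulse_volume",
            "persistent_dry_cough",
            "nausea",
        ],
        "statuses": None,
    },
}


def make_fixture_report(name: str) -> Report:
    """Reports transcribed from the worked classification examples."""
    spec = _FIXTURES.get(name)
    if spec is None:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    statuses = spec["statuses"]
    return build_report(
        name,
        spec["codes"],
        default_mapping(),
        [Status.from_token(s) for s in statuses] if statuses else None,
    )
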