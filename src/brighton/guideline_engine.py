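"""Three-valued rule engine for the Brighton anaphylaxis case definition.

The case definition is encoded as *data* (YAML catalogs shipped with the
package), not code: a catalog lists the Brighton criterion atoms, the
major/minor criteria per organ system as boolean expressions over those
atoms, and the level rules as predicates over per-system counts of
satisfied criteria.  Keeping the rules declarative means a corrected or
alternative guideline version is a new catalog file, not a code change.

Criterion expressions are evaluated under strong-Kleene semantics over
the truth ordering ``absent < unknown < present``: conjunction is the
minimum, disjunction the maximum, and negation the order reflection
(``not unknown = unknown``).  This captures the reporting reality that an
unlisted finding may be unknown, missing, or silently negative.  The
closed-world reading — everything not positively stated is absent — is an
explicit transformation (:func:`closed_world_complete`), mirroring how
negation had to be injected into passively reported data before the
original (negation-bearing) criteria could fire.

Two catalog variants ship:

* ``original`` — minor criteria carry negated atoms ("generalized
  pruritus *without* skin rash"), and the Level-3 "two different systems"
  clause excludes both cardiovascular and respiratory systems.
* ``updated`` — negation-free minor criteria (compound "without X" terms
  decomposed into constituents) and Level-3 excluding only the system
  supplying the anchoring minor criterion.

``original_closed_world`` is the original catalog applied after
closed-world completion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

from brighton.core_model import Report, Status, TermCode, TermMapping

SYSTEMS = (
    "dermatologic_mucosal",
    "cardiovascular",
    "respiratory",
    "gastrointestinal",
    "laboratory",
)

VARIANTS = ("original", "original_closed_world", "updated")


# --- criterion expressions ----------------------------------------------


@dataclass(frozen=True)
class Atom:
    name: str


@dataclass(frozen=True)
class Not:
    operand: "CriterionExpr"


@dataclass(frozen=True)
class And:
    operands: tuple


@dataclass(frozen=True)
class Or:
    operands: tuple


@dataclass(frozen=True)
class AtLeast:
    k: int
    operands: tuple

    def __post_init__(self) -> None:
        if not (1 <= self.k <= len(self.operands)):
            raise ValueError(
                f"at_least needs 1 <= k <= {len(self.operands)}, got k={self.k}"
            )


CriterionExpr = Union[Atom, Not, And, Or, AtLeast]


def parse_expr(form) -> CriterionExpr:
    """Parse the s-expression-like nested-list encoding used in catalogs."""
    if not isinstance(form, (list, tuple)) or not form:
        raise ValueError(f"malformed expression: {form!r}")
    head = form[0]
    if head == "atom":
        (name,) = form[1:]
        return Atom(str(name))
    if head == "not":
        (operand,) = form[1:]
        return Not(parse_expr(operand))
    if head in ("and", "or"):
        operands = tuple(parse_expr(f) for f in form[1:])
        if not operands:
            raise ValueError(f"{head} needs at least one operand")
        return And(operands) if head == "and" else Or(operands)
    if head == "at_least":
        k = int(form[1])
        return AtLeast(k, tuple(parse_expr(f) for f in form[2:]))
    raise ValueError(f"unknown expression head: {head!r}")


def unparse_expr(expr: CriterionExpr):
    if isinstance(expr, Atom):
        return ["atom", expr.name]
    if isinstance(expr, Not):
        return ["not", unparse_expr(expr.operand)]
    if isinstance(expr, And):
        return ["and", *map(unparse_expr, expr.operands)]
    if isinstance(expr, Or):
        return ["or", *map(unparse_expr, expr.operands)]
    return ["at_least", expr.k, *map(unparse_expr, expr.operands)]


def expr_atoms(expr: CriterionExpr) -> set:
    """All atom names referenced by an expression."""
    if isinstance(expr, Atom):
        return {expr.name}
    if isinstance(expr, Not):
        return expr_atoms(expr.operand)
    out: set = set()
    for sub in expr.operands:
        out |= expr_atoms(sub)
    return out


def expr_has_negation(expr: CriterionExpr) -> bool:
    if isinstance(expr, Atom):
        return False
    if isinstance(expr, Not):
        return True
    return any(expr_has_negation(sub) for sub in expr.operands)


def eval_expr(
    expr: CriterionExpr,
    report: Report,
    atoms: Iterable[str] | None = None,
) -> Status:
    """Evaluate a criterion expression on a report, three-valued.

    Strong-Kleene: AND is the minimum and OR the maximum over
    ``absent < unknown < present``; NOT reflects the ordering.
    ``at_least(k, L)`` is present when at least ``k`` members evaluate
    present, absent when more than ``len(L) - k`` members are absent
    (so ``k`` presents are no longer attainable), and unknown otherwise.

    If ``atoms`` is given, referencing an atom outside it raises
    ``ValueError`` naming the atom.
    """
    if atoms is not None:
        vocab = set(atoms)
        unknown_atoms = expr_atoms(expr) - vocab
        if unknown_atoms:
            raise ValueError(f"unknown atom(s) in expression: {sorted(unknown_atoms)}")
    return _eval(expr, report)


def _eval(expr: CriterionExpr, report: Report) -> Status:
    if isinstance(expr, Atom):
        return report.status_of(expr.name)
    if isinstance(expr, Not):
        return Status(2 - _eval(expr.operand, report))
    if isinstance(expr, And):
        return Status(min(_eval(sub, report) for sub in expr.operands))
    if isinstance(expr, Or):
        return Status(max(_eval(sub, report) for sub in expr.operands))
    values = [_eval(sub, report) for sub in expr.operands]
    n_present = sum(v is Status.PRESENT for v in values)
    n_absent = sum(v is Status.ABSENT for v in values)
    if n_present >= expr.k:
        return Status.PRESENT
    if n_absent > len(values) - expr.k:
        return Status.ABSENT
    return Status.UNKNOWN


# --- criteria and level rules -------------------------------------------


@dataclass(frozen=True)
class Criterion:
    """One Brighton criterion: an organ system, a major/minor weight and
    a boolean expression over finding atoms."""

    criterion_id: str
    system: str
    weight: str  # "major" | "minor"
    expr: CriterionExpr

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r} in {self.criterion_id}")
        if self.weight not in ("major", "minor"):
            raise ValueError(f"weight must be major/minor in {self.criterion_id}")


@dataclass(frozen=True)
class SystemCounts:
    """Per-system counts of satisfied major and minor criteria."""

    major: Mapping[str, int]
    minor: Mapping[str, int]

    def n_major(self, system: str) -> int:
        return self.major.get(system, 0)

    def n_minor(self, system: str) -> int:
        return self.minor.get(system, 0)

    def n_systems_with_minor(self, excluding: Sequence[str]) -> int:
        return sum(
            1
            for s, n in self.minor.items()
            if n > 0 and s not in excluding
        )


@dataclass(frozen=True)
class LevelRule:
    """Predicate over :class:`SystemCounts` for one certainty level.

    Encoded in the same nested-list algebra as criterion expressions,
    with count atoms ``[major_ge, system, k]``, ``[minor_ge, system, k]``
    and ``[systems_with_minor_ge, [excluded...], k]``.
    """

    level: int
    form: tuple

    def holds(self, counts: SystemCounts) -> bool:
        return _eval_rule(self.form, counts)


def _freeze(form):
    if isinstance(form, list):
        return tuple(_freeze(f) for f in form)
    return form


def _eval_rule(form, counts: SystemCounts) -> bool:
    head = form[0]
    if head == "and":
        return all(_eval_rule(f, counts) for f in form[1:])
    if head == "or":
        return any(_eval_rule(f, counts) for f in form[1:])
    if head == "major_ge":
        _, system, k = form
        _check_system(system)
        return counts.n_major(system) >= int(k)
    if head == "minor_ge":
        _, system, k = form
        _check_system(system)
        return counts.n_minor(system) >= int(k)
    if head == "systems_with_minor_ge":
        _, excluded, k = form
        for s in excluded:
            _check_system(s)
        return counts.n_systems_with_minor(excluding=excluded) >= int(k)
    raise ValueError(f"unknown level-rule head: {head!r}")


def _check_system(system: str) -> None:
    if system not in SYSTEMS:
        raise ValueError(f"level rule references unknown system {system!r}")


# --- outcome categories --------------------------------------------------


class Category(str, enum.Enum):
    """The six outcome categories a report can be assigned."""

    LEVEL_1 = "level_1"
    LEVEL_2 = "level_2"
    LEVEL_3 = "level_3"
    INSUFFICIENT_EVIDENCE = "insufficient_evidence"
    NOT_A_CASE = "not_a_case"
    NO_EVIDENCE = "no_evidence"

    @property
    def level(self) -> int | None:
        """Numeric certainty level for positive categories, else None."""
        return {"level_1": 1, "level_2": 2, "level_3": 3}.get(self.value)

    @property
    def is_positive(self) -> bool:
        return self.level is not None


# Coarse ordering used by monotonicity checks: more evidence can only move
# a report rightwards.  insufficient_evidence and not_a_case share a rank
# (they differ only by the reported-diagnosis flag, not by evidence).
CATEGORY_RANK = {
    Category.NO_EVIDENCE: 0,
    Category.NOT_A_CASE: 1,
    Category.INSUFFICIENT_EVIDENCE: 1,
    Category.LEVEL_3: 2,
    Category.LEVEL_2: 3,
    Category.LEVEL_1: 4,
}


@dataclass(frozen=True)
class ClassificationResult:
    """Brighton outcome for one report, with satisfied criteria as provenance."""

    report_id: str
    category: Category
    satisfied: tuple
    variant: str


# --- catalog -------------------------------------------------------------


@dataclass(frozen=True)
class CriteriaCatalog:
    """A guideline variant: atoms, criteria, level rules and policy flags."""

    variant: str
    atoms: Mapping[str, TermCode]  # atom code -> TermCode
    criteria: tuple
    level_rules: Mapping[int, LevelRule]
    temporal_atoms: tuple
    require_temporal: bool = False
    closed_world: bool = False

    def __post_init__(self) -> None:
        ids = [c.criterion_id for c in self.criteria]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate criterion ids in catalog")
        vocab = set(self.atoms)
        for c in self.criteria:
            missing = expr_atoms(c.expr) - vocab
            if missing:
                raise ValueError(
                    f"criterion {c.criterion_id} references undeclared atoms "
                    f"{sorted(missing)}"
                )
        for level in (1, 2, 3):
            if level not in self.level_rules:
                raise ValueError(f"catalog lacks a rule for level {level}")

    @property
    def atom_codes(self) -> set:
        return set(self.atoms)

    def criteria_by(self, system: str, weight: str) -> list:
        return [
            c for c in self.criteria if c.system == system and c.weight == weight
        ]


def load_catalog(
    path: str | Path,
    require_temporal: bool = False,
    closed_world: bool = False,
) -> CriteriaCatalog:
    """Load a criteria catalog from its YAML representation."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    atoms = {
        code: TermCode(code=code, label=label, vocabulary="brighton-atom")
        for code, label in doc["atoms"].items()
    }
    criteria = tuple(
        Criterion(
            criterion_id=item["id"],
            system=item["system"],
            weight=item["weight"],
            expr=parse_expr(item["expr"]),
        )
        for item in doc["criteria"]
    )
    level_rules = {
        int(level): LevelRule(level=int(level), form=_freeze(form))
        for level, form in doc["level_rules"].items()
    }
    return CriteriaCatalog(
        variant=doc["variant"],
        atoms=atoms,
        criteria=criteria,
        level_rules=level_rules,
        temporal_atoms=tuple(doc.get("temporal_atoms", ())),
        require_temporal=require_temporal,
        closed_world=closed_world,
    )


def build_catalog(variant: str, require_temporal: bool = False) -> CriteriaCatalog:
    """Return one of the shipped guideline variants.

    ``original`` and ``updated`` evaluate reports open-world;
    ``original_closed_world`` is the original catalog with closed-world
    completion applied inside :func:`classify`.  ``require_temporal``
    gates every positive level on the sudden-onset AND rapid-progression
    atoms being present (the temporal conditions of the case definition);
    it is relaxed when classifying data whose coding cannot express them.
    """
    from importlib.resources import files

    if variant not in VARIANTS:
        raise ValueError(f"unknown catalog variant {variant!r}; use one of {VARIANTS}")
    name = "catalog_updated.yaml" if variant == "updated" else "catalog_original.yaml"
    catalog = load_catalog(
        files("brighton.data").joinpath(name),
        require_temporal=require_temporal,
        closed_world=(variant == "original_closed_world"),
    )
    if variant == "original_closed_world":
        catalog = CriteriaCatalog(
            variant=variant,
            atoms=catalog.atoms,
            criteria=catalog.criteria,
            level_rules=catalog.level_rules,
            temporal_atoms=catalog.temporal_atoms,
            require_temporal=require_temporal,
            closed_world=True,
        )
    return catalog


# --- closed-world completion ---------------------------------------------


def closed_world_complete(report: Report, catalog: CriteriaCatalog) -> Report:
    """Return a copy of ``report`` with every catalog atom of unknown
    status recorded as absent.

    This simulates the closed-world assumption implicit in passive
    reports: what was not positively stated is treated as checked and
    negative.  Present/absent findings are untouched; the input report is
    not modified.  Idempotent.
    """
    findings = dict(report.findings)
    for atom in catalog.atoms:
        if findings.get(atom, Status.UNKNOWN) is Status.UNKNOWN:
            findings[atom] = Status.ABSENT
    return report.with_findings(findings)


# --- classification ------------------------------------------------------


def satisfied_criteria(report: Report, catalog: CriteriaCatalog) -> list:
    """Criteria whose expressions evaluate to present on the report.

    A criterion evaluating to *unknown* is not satisfied: a strict
    three-valued reading would push every incompletely coded report into
    a negative category, so unknown contributes nothing either way.
    """
    vocab = catalog.atom_codes
    return [
        c for c in catalog.criteria if eval_expr(c.expr, report, vocab) is Status.PRESENT
    ]


def count_by_system(criteria: Sequence[Criterion]) -> SystemCounts:
    major: dict[str, int] = {}
    minor: dict[str, int] = {}
    for c in criteria:
        bucket = major if c.weight == "major" else minor
        bucket[c.system] = bucket.get(c.system, 0) + 1
    return SystemCounts(major=major, minor=minor)


def classify(report: Report, catalog: CriteriaCatalog) -> ClassificationResult:
    """Assign one of the six Brighton outcome categories to a report.

    The highest level (1 > 2 > 3) whose rule holds over the per-system
    counts of satisfied criteria wins.  With ``require_temporal`` set,
    positive levels additionally demand the sudden-onset and
    rapid-progression atoms present.  When no level holds, the outcome is
    ``insufficient_evidence`` if the report carries a reported
    anaphylaxis diagnosis, ``no_evidence`` if no catalog atom is present
    at all, and ``not_a_case`` otherwise.
    """
    working = closed_world_complete(report, catalog) if catalog.closed_world else report
    satisfied = satisfied_criteria(working, catalog)
    counts = count_by_system(satisfied)

    temporal_ok = True
    if catalog.require_temporal:
        temporal_ok = all(
            working.status_of(a) is Status.PRESENT for a in catalog.temporal_atoms
        )

    category = None
    if temporal_ok:
        for level in (1, 2, 3):
            if catalog.level_rules[level].holds(counts):
                category = Category(f"level_{level}")
                break
    if category is None:
        if report.has_reported_anaphylaxis:
            category = Category.INSUFFICIENT_EVIDENCE
        elif not (report.present_atoms() & catalog.atom_codes):
            # closed-world completion adds only absents, so presence is
            # judged on the original report
            category = Category.NO_EVIDENCE
        else:
            category = Category.NOT_A_CASE

    return ClassificationResult(
        report_id=report.report_id,
        category=category,
        satisfied=tuple(c.criterion_id for c in satisfied),
        variant=catalog.variant,
    )


def classify_corpus(
    reports: Iterable[Report], catalog: CriteriaCatalog
) -> list:
    return [classify(r, catalog) for r in reports]


# --- compound-term decomposition ----------------------------------------


def decompose_compound(code: str, mapping: TermMapping) -> list:
    """Break a compound reporting code into (atom, status) constituents.

    A compound such as "capillary refill time > 3 s without hypotension"
    asserts its positive part present and its "without X" part absent;
    encoding it as a single opaque term loses the negative assertion and
    blocks correct classification.  A non-compound code yields the
    identity singleton with status present.
    """
    pairs = mapping.entries.get(code)
    if pairs is None:
        return [(code, Status.PRESENT)]
    return list(pairs)
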