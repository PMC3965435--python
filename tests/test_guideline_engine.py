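"""Three-valued evaluation, closed-world completion, and the six-way
classification, validated against the printed worked examples and an
independent truth-table oracle."""

import itertools
import random

import pytest

from brighton.core_model import Report, Status
from brighton.guideline_engine import (
    And,
    AtLeast,
    Atom,
    CATEGORY_RANK,
    Category,
    Not,
    Or,
    build_catalog,
    classify,
    closed_world_complete,
    decompose_compound,
    eval_expr,
    expr_atoms,
    expr_has_negation,
)
from brighton.synthetic_data import SimulationConfig, generate, make_fixture_report

# --- independent Kleene oracle ------------------------------------------
# Statuses map to {0, 1/2, 1}; negation is 1-v, conjunction min,
# disjunction max, and at-least-k expands structurally into the
# disjunction of all k-subsets' conjunctions.

_VAL = {Status.ABSENT: 0.0, Status.UNKNOWN: 0.5, Status.PRESENT: 1.0}
_STATUS = {v: s for s, v in _VAL.items()}


def oracle_eval(expr, assignment):
    if isinstance(expr, Atom):
        return _VAL[assignment.get(expr.name, Status.UNKNOWN)]
    if isinstance(expr, Not):
        return 1.0 - oracle_eval(expr.operand, assignment)
    if isinstance(expr, And):
        return min(oracle_eval(e, assignment) for e in expr.operands)
    if isinstance(expr, Or):
        return max(oracle_eval(e, assignment) for e in expr.operands)
    subsets = itertools.combinations(expr.operands, expr.k)
    return max(
        min(oracle_eval(e, assignment) for e in subset) for subset in subsets
    )


def random_expr(rng, atoms, depth):
    if depth == 0 or rng.random() < 0.3:
        return Atom(rng.choice(atoms))
    kind = rng.choice(["not", "and", "or", "at_least"])
    if kind == "not":
        return Not(random_expr(rng, atoms, depth - 1))
    n = rng.randint(2, 4)
    operands = tuple(random_expr(rng, atoms, depth - 1) for _ in range(n))
    if kind == "and":
        return And(operands)
    if kind == "or":
        return Or(operands)
    return AtLeast(rng.randint(1, n), operands)


def all_assignments(atoms):
    for combo in itertools.product(list(Status), repeat=len(atoms)):
        yield dict(zip(atoms, combo))


def test_eval_matches_oracle_exhaustively():
    """Engine evaluation equals the subset-expansion oracle on every
    status assignment, for 60 random expressions of depth <= 3 over
    <= 4 atoms."""
    rng = random.Random(20240)
    atoms = ["a1", "a2", "a3", "a4"]
    for _ in range(60):
        expr = random_expr(rng, atoms, 3)
        for assignment in all_assignments(sorted(expr_atoms(expr))):
            report = Report("t", findings=assignment)
            got = eval_expr(expr, report)
            assert _VAL[got] == oracle_eval(expr, assignment)


def test_at_least_counting_rule_brute_force():
    """at_least(2, L) over four atoms agrees with the counting rule on
    all 3^4 status vectors."""
    atoms = ["w", "x", "y", "z"]
    expr = AtLeast(2, tuple(Atom(a) for a in atoms))
    for assignment in all_assignments(atoms):
        values = list(assignment.values())
        n_present = values.count(Status.PRESENT)
        n_absent = values.count(Status.ABSENT)
        if n_present >= 2:
            expected = Status.PRESENT
        elif n_absent > 2:
            expected = Status.ABSENT
        else:
            expected = Status.UNKNOWN
        assert eval_expr(expr, Report("t", findings=assignment)) == expected
    sample = dict(zip(atoms, [Status.PRESENT, Status.ABSENT, Status.UNKNOWN, Status.PRESENT]))
    assert eval_expr(expr, Report("t", findings=sample)) is Status.PRESENT


def test_kleene_negation_of_unknown_is_unknown():
    assert eval_expr(Not(Atom("x")), Report("t")) is Status.UNKNOWN


def test_eval_unknown_atom_raises_with_name():
    with pytest.raises(ValueError, match="mystery_atom"):
        eval_expr(Atom("mystery_atom"), Report("t"), atoms={"skin_rash"})


def test_at_least_k_bounds():
    with pytest.raises(ValueError):
        AtLeast(0, (Atom("x"),))
    with pytest.raises(ValueError):
        AtLeast(3, (Atom("x"), Atom("y")))


# --- closed-world completion --------------------------------------------


def test_closed_world_369695_gains_absents(original_catalog):
    report = make_fixture_report("worked_369695")
    completed = closed_world_complete(report, original_catalog)
    assert completed.status_of("bilateral_wheeze") is Status.ABSENT
    assert completed.status_of("stridor") is Status.ABSENT
    assert completed.status_of("difficulty_breathing") is Status.PRESENT
    # original untouched
    assert report.status_of("bilateral_wheeze") is Status.UNKNOWN


def test_closed_world_idempotent_and_total(original_catalog, small_corpus):
    for report in small_corpus.reports[:50]:
        once = closed_world_complete(report, original_catalog)
        twice = closed_world_complete(once, original_catalog)
        assert dict(once.findings) == dict(twice.findings)
        assert set(once.findings) >= original_catalog.atom_codes
        for atom, status in report.findings.items():
            if status is not Status.UNKNOWN:
                assert once.findings[atom] == status


def test_closed_world_empty_report_all_absent(original_catalog):
    completed = closed_world_complete(Report("e"), original_catalog)
    assert set(completed.findings.values()) == {Status.ABSENT}
    assert set(completed.findings) == original_catalog.atom_codes


# --- worked-example classifications -------------------------------------


@pytest.mark.parametrize(
    "fixture,variant,expected",
    [
        ("skin_rash_yes", "original", Category.LEVEL_1),
        ("skin_rash_no", "original", Category.LEVEL_2),
        ("skin_rash_unknown", "original", Category.INSUFFICIENT_EVIDENCE),
        ("skin_rash_unknown", "updated", Category.LEVEL_2),
        ("worked_369695", "original", Category.NOT_A_CASE),
        ("worked_369695", "original_closed_world", Category.LEVEL_2),
        ("level3_interpretation", "original", Category.NOT_A_CASE),
        ("level3_interpretation", "updated", Category.LEVEL_3),
    ],
)
def test_worked_examples(fixture, variant, expected):
    """The in-text worked reports classify as printed: the skin-rash
    trio under the original rules, report 369695 before/after negation,
    and the report on which the two Level-3 readings disagree."""
    result = classify(make_fixture_report(fixture), build_catalog(variant))
    assert result.category is expected


def test_skin_rash_unknown_without_diagnosis_code_is_not_a_case(original_catalog):
    report = make_fixture_report("skin_rash_unknown")
    stripped = Report(
        report_id=report.report_id,
        findings=dict(report.findings),
        raw_terms=report.raw_terms,
        has_reported_anaphylaxis=False,
    )
    assert classify(stripped, original_catalog).category is Category.NOT_A_CASE


def test_empty_report_is_no_evidence():
    for variant in ("original", "updated", "original_closed_world"):
        assert (
            classify(Report("empty"), build_catalog(variant)).category
            is Category.NO_EVIDENCE
        )


# --- temporal gate -------------------------------------------------------


def test_temporal_relaxation_keeps_level_1():
    """With the temporal gate relaxed, the Level-1 example still reaches
    Level 1 after removing sudden onset and rapid progression."""
    report = make_fixture_report("skin_rash_yes")
    findings = {
        a: s
        for a, s in report.findings.items()
        if a not in ("sudden_onset", "rapid_progression")
    }
    stripped = report.with_findings(findings)
    relaxed = build_catalog("original", require_temporal=False)
    gated = build_catalog("original", require_temporal=True)
    assert classify(stripped, relaxed).category is Category.LEVEL_1
    assert not classify(stripped, gated).category.is_positive
    # with both temporal atoms present the gate passes
    assert classify(report, gated).category is Category.LEVEL_1


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="unknown catalog variant"):
        build_catalog("brighton_v9")


# --- level precedence and monotonicity ----------------------------------


def test_level_precedence(updated_catalog, mapping):
    """A report satisfying the Level-1 rule is never categorized lower,
    even though it also satisfies Level 2 and Level 3 rules."""
    from brighton.core_model import build_report

    report = build_report(
        "rich",
        [
            "generalized_urticaria",
            "measured_hypotension",
            "bilateral_wheeze",
            "difficulty_breathing",
            "persistent_dry_cough",
            "tachycardia",
            "capillary_refill_gt3s",
            "nausea",
            "elevated_mast_cell_tryptase",
        ],
        mapping,
    )
    from brighton.guideline_engine import count_by_system, satisfied_criteria

    counts = count_by_system(satisfied_criteria(report, updated_catalog))
    assert all(updated_catalog.level_rules[lv].holds(counts) for lv in (1, 2, 3))
    assert classify(report, updated_catalog).category is Category.LEVEL_1


def test_updated_catalog_is_negation_free(updated_catalog, original_catalog):
    assert not any(expr_has_negation(c.expr) for c in updated_catalog.criteria)
    assert any(expr_has_negation(c.expr) for c in original_catalog.criteria)


def test_monotone_in_evidence_under_updated_catalog(updated_catalog):
    """Flipping any atom to present never lowers the category ordering
    when criteria contain no negated atoms."""
    rng = random.Random(7)
    atoms = sorted(updated_catalog.atom_codes)
    for _ in range(150):
        findings = {
            a: rng.choice(list(Status))
            for a in rng.sample(atoms, rng.randint(0, 8))
        }
        report = Report("m", findings=findings)
        before = CATEGORY_RANK[classify(report, updated_catalog).category]
        atom = rng.choice(atoms)
        if findings.get(atom) is Status.PRESENT:
            continue
        flipped = dict(findings)
        flipped[atom] = Status.PRESENT
        after = CATEGORY_RANK[classify(Report("m", findings=flipped), updated_catalog).category]
        assert after >= before


def test_updated_open_world_dominates_original_closed_world(
    small_corpus, updated_catalog, original_cw_catalog
):
    """Decomposing compound terms makes negation injection unnecessary:
    the updated open-world pipeline never ranks a report below the
    original-plus-negation pipeline."""
    for report in small_corpus.reports:
        ocw = classify(report, original_cw_catalog).category
        upd = classify(report, updated_catalog).category
        assert CATEGORY_RANK[upd] >= CATEGORY_RANK[ocw]


def test_exactly_one_category_and_satisfied_subset(small_corpus, original_catalog):
    ids = {c.criterion_id for c in original_catalog.criteria}
    for report in small_corpus.reports[:100]:
        result = classify(report, original_catalog)
        assert isinstance(result.category, Category)
        assert set(result.satisfied) <= ids
        if result.category.is_positive:
            assert result.satisfied


# --- compound decomposition ---------------------------------------------


@pytest.mark.parametrize(
    "code,expected",
    [
        (
            "capillary_refill_gt3s_without_hypotension",
            [("capillary_refill_gt3s", Status.PRESENT), ("measured_hypotension", Status.ABSENT)],
        ),
        (
            "generalized_pruritus_with_skin_rash",
            [("generalized_pruritus", Status.PRESENT), ("skin_rash", Status.PRESENT)],
        ),
        ("nausea", [("nausea", Status.PRESENT)]),
        ("totally_new_code", [("totally_new_code", Status.PRESENT)]),
    ],
)
def test_decompose_compound(code, expected, mapping):
    assert decompose_compound(code, mapping) == expected
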