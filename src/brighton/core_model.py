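"""Domain types and flat-file readers/writers for coded AEFI reports.

An adverse-event report is modelled as a set of *raw* reporting-vocabulary
codes (MedDRA-like) plus the clinical-finding *atoms* they map to.  Each
atom carries a tri-state status: ``present``, ``absent`` or ``unknown``.
Any atom a report does not list is implicitly ``unknown`` — the open-world
reading; converting unknowns to absents is an explicit, separate step in
:mod:`brighton.guideline_engine`.

File formats (all plain text):

* ``reports.csv`` — columns ``report_id``, ``terms`` (``;``-separated
  codes) and an optional positional ``statuses`` column.
* ``mapping.tsv`` — tab-separated ``code``, ``atom``, ``asserted_status``,
  ``is_anaphylaxis_diagnosis_term``; one row per (code, atom) pair, so a
  compound code occupies several rows.
* ``labels.csv`` — columns ``report_id``, ``label`` (``case``/``non_case``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

TERM_DELIMITER = ";"


class Status(enum.IntEnum):
    """Tri-state truth value of a clinical finding.

    The integer ordering ``ABSENT < UNKNOWN < PRESENT`` is the Kleene
    truth ordering used by the rule engine (conjunction = min,
    disjunction = max, negation = reflection).
    """

    ABSENT = 0
    UNKNOWN = 1
    PRESENT = 2

    @property
    def token(self) -> str:
        return self.name.lower()

    @classmethod
    def from_token(cls, token: str) -> "Status":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise ValueError(f"not a finding status: {token!r}") from None


@dataclass(frozen=True)
class TermCode:
    """A coded term in some vocabulary (reporting code or Brighton atom)."""

    code: str
    label: str
    vocabulary: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("term code must be non-empty")
        if not self.label:
            raise ValueError(f"term {self.code!r} needs a non-empty label")


@dataclass(frozen=True)
class Finding:
    """One Brighton criterion atom with its tri-state status."""

    atom: str
    status: Status


@dataclass(frozen=True)
class Report:
    """A coded AEFI report.

    ``findings`` is a partial function atom -> status; querying an
    unlisted atom via :meth:`status_of` yields ``UNKNOWN``.  ``raw_terms``
    preserves the pre-mapping reporting-vocabulary codes (the screening
    classifier works on these).  ``has_reported_anaphylaxis`` flags
    reports that carry an anaphylaxis(-like) diagnosis code.
    """

    report_id: str
    findings: Mapping[str, Status] = field(default_factory=dict)
    raw_terms: frozenset = field(default_factory=frozenset)
    has_reported_anaphylaxis: bool = False

    def status_of(self, atom: str) -> Status:
        return self.findings.get(atom, Status.UNKNOWN)

    def present_atoms(self) -> set:
        return {a for a, s in self.findings.items() if s is Status.PRESENT}

    def with_findings(self, findings: Mapping[str, Status]) -> "Report":
        return Report(
            report_id=self.report_id,
            findings=dict(findings),
            raw_terms=self.raw_terms,
            has_reported_anaphylaxis=self.has_reported_anaphylaxis,
        )


# --- merge lattice -------------------------------------------------------

_MERGE_RANK = {Status.UNKNOWN: 0, Status.ABSENT: 1, Status.PRESENT: 2}


def merge_finding(existing: Status, incoming: Status) -> tuple[Status, bool]:
    """Combine two statuses asserted for the same atom.

    Definite information wins over unknown, and presence wins over
    absence (``present > absent > unknown``).  A direct present-vs-absent
    contradiction resolves to ``present`` but is flagged so callers can
    record it in diagnostics.

    Returns ``(merged_status, conflict)``.
    """
    merged = existing if _MERGE_RANK[existing] >= _MERGE_RANK[incoming] else incoming
    conflict = {existing, incoming} == {Status.PRESENT, Status.ABSENT}
    return merged, conflict


# --- term mapping --------------------------------------------------------


@dataclass(frozen=True)
class TermMapping:
    """Reporting-vocabulary code -> Brighton atom assertions.

    ``entries[code]`` is a tuple of ``(atom, asserted_status)`` pairs;
    compound codes (e.g. "capillary refill > 3 s *without* hypotension")
    have several pairs, the "without X" part asserting X absent.
    ``diagnosis_codes`` are anaphylaxis(-like) diagnosis terms: they map
    to no atom but set the report's reported-anaphylaxis flag.
    """

    entries: Mapping[str, tuple]
    diagnosis_codes: frozenset = field(default_factory=frozenset)

    def covers(self, code: str) -> bool:
        return code in self.entries or code in self.diagnosis_codes

    @property
    def atoms(self) -> set:
        return {atom for pairs in self.entries.values() for atom, _ in pairs}

    def apply(
        self,
        codes: Sequence[str],
        statuses: Sequence[Status] | None = None,
    ) -> tuple[dict, bool, list, list]:
        """Map raw codes to findings.

        ``statuses`` gives a per-code reported status (positional,
        defaulting to present).  A code reported *absent* flips its
        asserted-present atoms to absent and drops asserted-absent ones
        (absence of a compound does not license inferring its parts);
        a code reported *unknown* contributes no finding.

        Returns ``(findings, has_reported_anaphylaxis, unmapped_codes,
        conflicting_atoms)``.
        """
        if statuses is None:
            statuses = [Status.PRESENT] * len(codes)
        if len(statuses) != len(codes):
            raise ValueError(
                f"{len(codes)} terms but {len(statuses)} statuses"
            )
        findings: dict[str, Status] = {}
        unmapped: list[str] = []
        conflicts: list[str] = []
        flagged = False
        for code, reported in zip(codes, statuses):
            if code in self.diagnosis_codes:
                if reported is Status.PRESENT:
                    flagged = True
                continue
            pairs = self.entries.get(code)
            if pairs is None:
                unmapped.append(code)
                continue
            if reported is Status.UNKNOWN:
                continue
            for atom, asserted in pairs:
                if reported is Status.ABSENT:
                    if asserted is not Status.PRESENT:
                        continue
                    status = Status.ABSENT
                else:
                    status = asserted
                if atom in findings:
                    merged, conflict = merge_finding(findings[atom], status)
                    if conflict:
                        conflicts.append(atom)
                    findings[atom] = merged
                else:
                    findings[atom] = status
        return findings, flagged, unmapped, conflicts


def read_mapping(path: str | Path) -> TermMapping:
    """Read a ``mapping.tsv`` table into a :class:`TermMapping`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"code", "atom", "asserted_status", "is_anaphylaxis_diagnosis_term"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mapping file {path} lacks columns: {sorted(missing)}")
    entries: dict[str, list] = {}
    diagnosis: set[str] = set()
    for row in df.itertuples(index=False):
        code = row.code.strip()
        if not code:
            raise ValueError(f"mapping file {path} has an empty code")
        if str(row.is_anaphylaxis_diagnosis_term).strip().lower() in {"1", "true", "yes"}:
            diagnosis.add(code)
        atom = row.atom.strip()
        if not atom:
            continue
        status = Status.from_token(row.asserted_status)
        entries.setdefault(code, []).append((atom, status))
    return TermMapping(
        entries={c: tuple(pairs) for c, pairs in entries.items()},
        diagnosis_codes=frozenset(diagnosis),
    )


def default_mapping() -> TermMapping:
    """The shipped reporting-code mapping.

    This table is a *synthetic stand-in*: the MedDRA-to-Brighton mapping
    used in practice is built on the licensed MedDRA terminology and is
    not distributable.  Codes here simply mirror the Brighton atom names,
    plus the clinically attested compound codes and anaphylaxis-like
    diagnosis terms.
    """
    from importlib.resources import files

    return read_mapping(files("brighton.data").joinpath("mapping_synthetic.tsv"))


# --- diagnostics ---------------------------------------------------------


@dataclass
class ReadDiagnostics:
    """Non-fatal issues collected while reading a report corpus."""

    unmapped: list = field(default_factory=list)  # (report_id, code)
    conflicts: list = field(default_factory=list)  # (report_id, atom)

    def unmapped_codes(self) -> set:
        return {code for _, code in self.unmapped}


# --- report corpus I/O ---------------------------------------------------


def _split_terms(cell: str) -> list[str]:
    return [t.strip() for t in str(cell).split(TERM_DELIMITER) if t.strip()]


def build_report(
    report_id: str,
    codes: Sequence[str],
    mapping: TermMapping,
    statuses: Sequence[Status] | None = None,
    diagnostics: ReadDiagnostics | None = None,
) -> Report:
    """Construct a :class:`Report` from raw codes via a mapping."""
    findings, flagged, unmapped, conflicts = mapping.apply(codes, statuses)
    if diagnostics is not None:
        diagnostics.unmapped.extend((report_id, c) for c in unmapped)
        diagnostics.conflicts.extend((report_id, a) for a in conflicts)
    return Report(
        report_id=str(report_id),
        findings=findings,
        raw_terms=frozenset(codes),
        has_reported_anaphylaxis=flagged,
    )


def read_reports(
    path: str | Path, mapping: TermMapping
) -> tuple[list[Report], ReadDiagnostics]:
    """Read a ``reports.csv`` corpus.

    Every row yields one report; raw terms are preserved and findings are
    populated through ``mapping``.  Codes the mapping does not cover are
    collected in the returned diagnostics rather than silently dropped.

    Raises ``ValueError`` on a duplicate ``report_id`` (naming the id) or
    a malformed row (naming the line number).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "report_id" not in df.columns or "terms" not in df.columns:
        raise ValueError(f"report file {path} needs columns report_id, terms")
    dupes = df["report_id"][df["report_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate report_id {dupes.iloc[0]!r} in {path}")
    has_status = "statuses" in df.columns
    diagnostics = ReadDiagnostics()
    reports: list[Report] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        if not str(row.report_id).strip():
            raise ValueError(f"{path} line {line_no}: empty report_id")
        codes = _split_terms(row.terms)
        statuses = None
        if has_status:
            tokens = _split_terms(row.statuses)
            if tokens:
                if len(tokens) != len(codes):
                    raise ValueError(
                        f"{path} line {line_no}: {len(codes)} terms but "
                        f"{len(tokens)} statuses"
                    )
                try:
                    statuses = [Status.from_token(t) for t in tokens]
                except ValueError as exc:
                    raise ValueError(f"{path} line {line_no}: {exc}") from None
        reports.append(
            build_report(row.report_id, codes, mapping, statuses, diagnostics)
        )
    return reports, diagnostics


def write_reports(reports: Iterable[Report], path: str | Path) -> None:
    """Write reports back to ``reports.csv`` (raw terms only).

    Statuses are not serialized per raw term (findings derive from the
    mapping at read time), so this writer round-trips corpora whose terms
    are all reported present — which generated corpora are.
    """
    rows = [
        {"report_id": r.report_id, "terms": TERM_DELIMITER.join(sorted(r.raw_terms))}
        for r in reports
    ]
    pd.DataFrame(rows, columns=["report_id", "terms"]).to_csv(path, index=False)


# --- gold labels ---------------------------------------------------------

CASE = "case"
NON_CASE = "non_case"

GoldLabels = dict  # report_id -> "case" | "non_case"


def read_labels(path: str | Path) -> GoldLabels:
    """Read ``labels.csv`` into a dict report_id -> label."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "report_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"label file {path} needs columns report_id, label")
    labels: dict[str, str] = {}
    for row in df.itertuples(index=False):
        rid = str(row.report_id)
        label = row.label.strip()
        if label not in (CASE, NON_CASE):
            raise ValueError(f"label for {rid!r} must be case/non_case, got {label!r}")
        if rid in labels:
            raise ValueError(f"duplicate gold label for report {rid!r}")
        labels[rid] = label
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"report_id": rid, "label": lab} for rid, lab in labels.items()],
        columns=["report_id", "label"],
    ).to_csv(path, index=False)


# --- classification results I/O -----------------------------------------


def write_classifications(results: Sequence, path: str | Path) -> None:
    """Write classification results (one row per report) to CSV.

    Columns: ``report_id``, ``category``, ``variant``, ``satisfied``
    (``;``-joined criterion ids).  Round-trips losslessly through
    :func:`read_classifications`.
    """
    rows = [
        {
            "report_id": r.report_id,
            "category": r.category.value,
            "variant": r.variant,
            "satisfied": TERM_DELIMITER.join(r.satisfied),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["report_id", "category", "variant", "satisfied"]).to_csv(
        path, index=False
    )


def read_classifications(path: str | Path) -> list:
    """Read a classification-results CSV written by :func:`write_classifications`."""
    from brighton.guideline_engine import Category, ClassificationResult

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        ClassificationResult(
            report_id=row.report_id,
            category=Category(row.category),
            satisfied=tuple(_split_terms(row.satisfied)),
            variant=row.variant,
        )
        for row in df.itertuples(index=False)
    ]
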