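"""Expanded-SMQ screening: χ² term selection and tf-idf cosine scoring.

The Brighton engine is a diagnosis-confirmation instrument — very
specific, not very sensitive.  For screening, reports are instead ranked
by the cosine similarity between their term vector and a query vector
built from a Standardized MedDRA Query (SMQ) term set, after *expanding*
the base SMQ with reporting-vocabulary terms whose 2x2 association with
the gold case label exceeds the χ² critical value at the chosen
significance level (3.841 at α = 0.05, one degree of freedom).

Term vectors are weighted by tf·idf with binary tf (coded reports carry
term *sets*) and idf(t) = ln(N / df_t) with no smoothing; terms unseen in
the fitting corpus carry no weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from brighton.core_model import CASE, Report

DF_ONE = 1  # all term/label tables are 2x2


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Term-by-label counts: a = term & case, b = term & non-case,
    c = no-term & case, d = no-term & non-case."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def chi2(self) -> float:
        return chi2_statistic(self.a, self.b, self.c, self.d)


def chi2_statistic(a: int, b: int, c: int, d: int) -> float:
    """Pearson χ² for a 2x2 table, no continuity correction:
    N(ad - bc)² / ((a+b)(c+d)(a+c)(b+d)).

    A zero marginal (term present in all or in no reports, or a
    single-class corpus) makes the statistic undefined; it is taken as 0,
    so such terms are never selected.
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


@dataclass(frozen=True)
class TermScore:
    code: str
    chi2: float
    p_value: float


def chi2_critical_value(alpha: float) -> float:
    """χ² critical value at df = 1 (3.841 for α = 0.05)."""
    return float(stats.chi2.ppf(1.0 - alpha, DF_ONE))


def chi2_scores(
    reports: Sequence[Report], labels: Mapping[str, str]
) -> list[TermScore]:
    """Score every distinct raw term's association with the gold label."""
    if not reports:
        raise ValueError("cannot score terms on an empty corpus")
    missing = [r.report_id for r in reports if r.report_id not in labels]
    if missing:
        raise ValueError(f"reports without gold label: {missing[:5]}")
    is_case = np.array([labels[r.report_id] == CASE for r in reports])
    n = len(reports)
    n_case = int(is_case.sum())
    # document frequency split by label, in one pass over the corpus
    case_df: dict[str, int] = {}
    total_df: dict[str, int] = {}
    for r, pos in zip(reports, is_case):
        for t in r.raw_terms:
            total_df[t] = total_df.get(t, 0) + 1
            if pos:
                case_df[t] = case_df.get(t, 0) + 1
    scores = []
    for code in sorted(total_df):
        a = case_df.get(code, 0)
        b = total_df[code] - a
        c = n_case - a
        d = (n - n_case) - b
        chi2 = chi2_statistic(a, b, c, d)
        p = float(stats.chi2.sf(chi2, DF_ONE))
        scores.append(TermScore(code=code, chi2=chi2, p_value=p))
    return scores


def chi2_select(
    reports: Sequence[Report],
    labels: Mapping[str, str],
    alpha: float = 0.05,
) -> list[TermScore]:
    """Terms whose χ² strictly exceeds the df=1 critical value at ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    critical = chi2_critical_value(alpha)
    return [s for s in chi2_scores(reports, labels) if s.chi2 > critical]


# --- SMQ assembly --------------------------------------------------------

BASE_SMQ = "base_smq"
CHI2_SELECTED = "chi2_selected"
BOTH = "both"


@dataclass(frozen=True)
class ExpandedSMQ:
    """Union of the base SMQ and the χ²-selected terms, with provenance."""

    terms: frozenset
    provenance: Mapping[str, str]  # code -> base_smq | chi2_selected | both

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.terms):
            raise ValueError("provenance must cover exactly the SMQ terms")


def expand_smq(base: Iterable[str], selected: Sequence[TermScore]) -> ExpandedSMQ:
    """Merge base-SMQ terms with selected terms, de-duplicated."""
    base_set = {str(t) for t in base}
    sel_set = {s.code for s in selected}
    provenance = {}
    for code in base_set | sel_set:
        if code in base_set and code in sel_set:
            provenance[code] = BOTH
        elif code in base_set:
            provenance[code] = BASE_SMQ
        else:
            provenance[code] = CHI2_SELECTED
    return ExpandedSMQ(terms=frozenset(provenance), provenance=provenance)


def read_smq(path: str | Path) -> list[str]:
    """One code per line; blank lines and ``#`` comments ignored."""
    terms = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line)
    return terms


def default_base_smq() -> list[str]:
    """The shipped 77-term synthetic stand-in for an anaphylaxis SMQ."""
    from importlib.resources import files

    return read_smq(files("brighton.data").joinpath("smq_base_synthetic.txt"))


def write_smq(smq: ExpandedSMQ, path: str | Path) -> None:
    pd.DataFrame(
        [{"code": c, "provenance": smq.provenance[c]} for c in sorted(smq.terms)],
        columns=["code", "provenance"],
    ).to_csv(path, index=False)


# --- tf-idf cosine scoring ----------------------------------------------


def fit_idf(reports: Sequence[Report]) -> dict[str, float]:
    """idf(t) = ln(N / df_t) over the corpus, for terms with df >= 1."""
    if not reports:
        raise ValueError("cannot fit idf on an empty corpus")
    n = len(reports)
    df: dict[str, int] = {}
    for r in reports:
        for t in r.raw_terms:
            df[t] = df.get(t, 0) + 1
    return {t: log(n / d) for t, d in df.items()}


@dataclass(frozen=True)
class ScreeningModel:
    """Expanded SMQ + corpus idf weights + a score threshold."""

    smq: ExpandedSMQ
    idf: Mapping[str, float]
    threshold: float


def cosine_score(report: Report, model: ScreeningModel) -> float:
    """Cosine similarity between the report's tf-idf vector and the SMQ
    query vector (tf = 1 on every SMQ term, same idf weights).

    Terms without an idf weight (unseen in the fitting corpus) are
    dropped from both vectors.  If either vector is all-zero the score is
    0; otherwise it lies in [0, 1] because all weights are non-negative.
    """
    idf = model.idf
    report_w = {t: idf[t] for t in report.raw_terms if t in idf}
    query_w = {t: idf[t] for t in model.smq.terms if t in idf}
    dot = sum(w * query_w[t] for t, w in report_w.items() if t in query_w)
    norm_r = sqrt(sum(w * w for w in report_w.values()))
    norm_q = sqrt(sum(w * w for w in query_w.values()))
    if norm_r == 0.0 or norm_q == 0.0:
        return 0.0
    return dot / (norm_r * norm_q)


def screen(reports: Sequence[Report], model: ScreeningModel) -> pd.DataFrame:
    """Score every report and call positives at ``score >= threshold``."""
    rows = []
    for r in reports:
        score = cosine_score(r, model)
        rows.append(
            {
                "report_id": r.report_id,
                "score": score,
                "call": bool(score >= model.threshold),
            }
        )
    return pd.DataFrame(rows, columns=["report_id", "score", "call"])


def youden_threshold(scores: Sequence[float], is_case: Sequence[bool]) -> float:
    """Score cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the distinct observed scores (calls use ``>=``); ties
    on J resolve to the highest cutoff, i.e. the most specific operating
    point among the maximizers.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    if not y.any() or y.all():
        raise ValueError("Youden threshold needs both classes present")
    best_j, best_t = -np.inf, None
    for t in np.unique(scores)[::-1]:
        calls = scores >= t
        sens = (calls & y).sum() / y.sum()
        spec = (~calls & ~y).sum() / (~y).sum()
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def fit_screening_model(
    reports: Sequence[Report],
    labels: Mapping[str, str],
    base_smq: Iterable[str],
    alpha: float = 0.05,
) -> ScreeningModel:
    """Fit the full screening pipeline on one corpus: χ²-select terms,
    expand the SMQ, fit idf, and place the threshold at the Youden point
    of the fitting corpus."""
    selected = chi2_select(reports, labels, alpha=alpha)
    smq = expand_smq(base_smq, selected)
    idf = fit_idf(reports)
    model = ScreeningModel(smq=smq, idf=idf, threshold=0.0)
    scored = screen(reports, model)
    is_case = [labels[rid] == CASE for rid in scored["report_id"]]
    threshold = youden_threshold(scored["score"].to_numpy(), is_case)
    return ScreeningModel(smq=smq, idf=idf, threshold=threshold)


def split_fit_screen(
    reports: Sequence[Report],
    labels: Mapping[str, str],
    base_smq: Iterable[str],
    alpha: float = 0.05,
    split: float = 0.5,
    seed: int = 0,
) -> dict:
    """Train/test protocol: fit idf, select terms and choose the
    threshold on a random ``split`` fraction, evaluate on the rest.

    Returns a dict with the fitted ``model``, the ``train``/``test``
    report lists and the scored test-set DataFrame.
    """
    if not 0 < split < 1:
        raise ValueError("split fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reports))
    n_train = int(round(split * len(reports)))
    train = [reports[i] for i in order[:n_train]]
    test = [reports[i] for i in order[n_train:]]
    model = fit_screening_model(train, labels, base_smq, alpha=alpha)
    return {
        "model": model,
        "train": train,
        "test": test,
        "test_scores": screen(test, model),
    }
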