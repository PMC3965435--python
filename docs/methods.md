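# Methods

## The classification problem

A coded AEFI report is a set of reporting-vocabulary terms. A term
mapping translates each code into one or more Brighton criterion
*atoms*, each with an asserted status; compound codes ("capillary refill
time > 3 s without hypotension") contribute several assertions, the
"without X" part asserting X absent. A report is then a partial function
atom → {present, absent, unknown}; atoms the report does not mention are
unknown. Codes the mapping does not cover are preserved as raw terms
(the screening stage uses them) and surfaced in a diagnostics list, never
silently dropped. Two codes asserting the same atom merge under the
lattice present > absent > unknown; a present-vs-absent contradiction
resolves to present and is flagged.

## Three-valued rule semantics

Criterion expressions (`atom`, `not`, `and`, `or`, `at_least(k, …)`) are
evaluated under strong-Kleene logic with `absent < unknown < present`:
conjunction is the minimum, disjunction the maximum, negation the order
reflection, and `at_least(k, L)` is present when ≥ k members are
present, absent when more than |L| − k members are absent, unknown
otherwise. A criterion evaluating to unknown is *not satisfied*: treating
unknown as disqualifying would push every incompletely coded report into
a negative category, which is the known failure mode of applying a
diagnosis-confirmation guideline to passive reports.

Closed-world completion is an explicit transformation (unknown → absent
on every catalog atom), not a hidden default. It is idempotent and never
touches a definite status. The `original_closed_world` variant applies
it before classification; everything else is open-world.

## Catalogs

The case definition is shipped as YAML data: 33 atoms, 24 criteria over
five organ systems, and one count-predicate per level. The source case
definition is published as prose; the transcription here follows its
major/minor structure (dermatologic majors: generalized
urticaria/erythema, angioedema, pruritus with rash; cardiovascular
majors: measured hypotension, uncompensated shock as at-least-3-of-4;
respiratory majors: bilateral wheeze, stridor, upper-airway swelling,
respiratory distress as at-least-2-of-5; minors per system, including a
laboratory minor for elevated mast-cell tryptase). Level rules:

* **Level 1** — ≥1 dermatologic major AND (≥1 cardiovascular major OR
  ≥1 respiratory major).
* **Level 2** — both non-dermatologic majors; or one of them plus ≥1
  minor from a *different* system; or a dermatologic major plus a
  cardiovascular or respiratory minor.
* **Level 3** — ≥1 cardiovascular-or-respiratory minor plus minors from
  ≥2 further systems. The `original` catalog reads "further" as
  excluding both cardiovascular and respiratory; the `updated` catalog
  excludes only the system supplying the anchoring minor. The two
  readings genuinely disagree (e.g. a report with one cardiovascular,
  one respiratory and one gastrointestinal minor is Level 3 only under
  the updated reading), which is why both ship.

The `updated` catalog also replaces every negation-bearing minor
criterion by its positive part (pruritus alone is a sufficient minor
criterion; the "no skin rash" conjunct exists in the original text only
to separate it from the corresponding major). A structural consequence,
asserted in the tests: the updated open-world pipeline never ranks a
report below the original-plus-negation pipeline, and on generated
corpora the per-level counts coincide.

When no level rule holds, the outcome is `insufficient_evidence` only if
the report carries an anaphylaxis(-like) diagnosis code — the category's
full name is *reported* anaphylaxis with insufficient evidence;
`no_evidence` if no catalog atom is present at all; `not_a_case`
otherwise. The diagnosis-code list lives in the mapping file under a
reserved flag, not in code, because the set of anaphylaxis-like terms is
open-ended.

The temporal conditions (sudden onset AND rapid progression) gate every
positive level when `require_temporal` is set. The default is relaxed,
because standard reporting vocabularies cannot encode these two findings
and a strict reading would classify every real-world report negatively.

## Screening model

Term selection builds, for each distinct raw term, the 2×2 table of term
presence against the gold label and computes Pearson's χ² without
continuity correction (the selection threshold 3.841 is the uncorrected
df = 1 critical value at α = 0.05; selection is strict `>`). Terms with
a zero marginal score 0 and are never selected. The expanded SMQ is the
de-duplicated union of the base list and the selected terms, each term
tagged with its provenance.

Vectors use binary tf (coded reports are term sets) and
idf(t) = ln(N/df_t) with no smoothing; terms unseen in the fitting
corpus are dropped from both vectors. The score is the cosine of the
report and query vectors; with non-negative weights it lies in [0, 1],
and its ranking is invariant to global positive rescaling of idf. The
default operating threshold is the Youden-J maximizer on the fitting
(or training) corpus; a 50/50 train/test protocol (`split_fit_screen`)
and a full-corpus mode are both provided.

## Evaluation

Sensitivity and specificity take Clopper–Pearson exact binomial
intervals (conservative, assumption-free at these small positive
counts). The AUC is the Mann–Whitney rank statistic with ties counted
one half; its interval uses DeLong's placement-based variance. The
trapezoid area under the threshold-sweep curve equals the rank statistic
exactly on tie-free scores (a test asserts agreement to 1e-12). When the
guideline engine is evaluated as a screen, levels 1–3 count positive and
`insufficient_evidence` counts negative by default (it marks a reported
diagnosis lacking evidence, not evidence).

## Synthetic corpora

The generator emulates an H1N1-era passive-surveillance corpus. Defaults
(one choice, held fixed): 6034 reports, prevalence 0.039, planted level
mix 0.30/0.68/0.02 across levels 1/2/3 (the approximate split of
confirmed positives), omission probability 0.15 per emitted finding,
spurious-criterion-atom rate 0.05 among negatives, anaphylaxis diagnosis
codes attached with probability 0.04 given case and 0.0005 given
non-case (diagnosis coding of true cases is known to be very sparse),
2000-code background vocabulary under a Zipf(1.5) law with a mean of 3
background terms per report.

Positives draw a level, receive a *minimal* criterion witness sampled
from the updated (negation-free) catalog plus the two temporal atoms,
and are serialized through the reporting vocabulary; eligible findings
go through compound "with/without" codes half the time, so both
guideline variants are exercised on identical bytes. Omission removes
the code entirely — omitted information is unknown, never absent, which
is precisely the ambiguity the closed-world machinery exists to manage.
Witnesses never accidentally satisfy a higher level, so recovery is
asserted as *level ≥ planted* (added noise terms can only raise a
category under the negation-free catalog, never lower it).

What the generator does not emulate: free-text narratives, real
MedDRA hierarchy and coding idiosyncrasies, correlated symptom clusters
beyond the planted criteria, temporal onset intervals, duplicate or
follow-up reports. Passing tests therefore demonstrate the logic and the
statistical machinery, not performance on real surveillance data; the
printed sensitivities/AUCs on synthetic corpora are properties of the
generator's noise model.

Problem sizes in the test and acceptance suites (1000-report noise-free
recovery, 10 000-report variant-equivalence sweep, 20 paired
2000-report screening corpora) were chosen as the smallest sizes at
which the corresponding claims are stable across seeds.

## Numerical and design notes

* `screen` calls positive at `score >= threshold`; a threshold of 0
  therefore calls every report. To call exactly the reports sharing a
  weighted term with the query, use any strictly positive epsilon.
* Youden ties resolve to the highest candidate threshold (the most
  specific maximizer); candidates are the distinct observed scores.
* χ² selection compares the statistic to the critical value strictly
  (`>`), so a term sitting exactly on the boundary is excluded.
* All randomness flows from one integer seed; the CLI derives per-stage
  seeds by SHA-256 hashing (stable across runs and platforms, each
  below 2³¹).
* Degenerate inputs: an empty report is `no_evidence` under every
  variant; single-class corpora raise informative errors in χ²
  selection, Youden search and ROC computation rather than returning
  NaN.
* The shipped mapping and base SMQ are synthetic stand-ins (marked so in
  their filenames); users with licensed terminology supply their own
  files in the same two-column formats.
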