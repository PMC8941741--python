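"""The five-question de-labelling algorithm as a traceable rule engine.

The algorithm screens the medical history of a patient labelled as
penicillin-allergic and issues a binary recommendation: *de-label* (the
β-lactam in question may be administered, under supervision) or *use an
alternative antibiotic*.  Questions are evaluated strictly in order:

* Q1 — complaints incompatible with allergy (isolated abdominal pain,
  palpitation, headache...) or an onset latency clearly too long for an
  allergic mechanism (urticaria > 2 days, exanthema > 1 week after the
  last dose).  Yes → de-label.
* Q2 — urticarial/exanthematous rash in childhood or adolescence without
  systemic symptoms (almost always infection-triggered).  Yes → de-label.
* Q3 — prolonged urticaria episode without respiratory or cardiovascular
  involvement.  Yes → de-label.
* Q4 — measles-like (maculopapular) exanthema in timely relation to
  intake, arising in adulthood.  Yes → alternative antibiotic.
* Q5 — reached whenever Q1–Q4 were all answered no or uncertain: any
  indicator of a severe drug reaction (onset within minutes,
  cardiovascular/respiratory signs, incident during anesthesia, mucosal
  erosions, cutaneous blisters, hepatitis, nephritis, blood-cell drop)
  → alternative antibiotic; otherwise → de-label.

An uncertain answer routes like "no" at Q1–Q4 and like "no severe
evidence" at Q5; the latter makes Q5 the algorithm's residual-risk locus
(absence of documented severity resolves to de-labelling).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .types import (
    Decision,
    GroundTruth,
    OnsetLatency,
    PatientHistory,
    Question,
    QuestionAnswer,
    Recommendation,
    TriState,
)

#: Age (years) at the reaction from which a rash counts as adult-onset.
ADULT_AGE_THRESHOLD = 18.0

_LATE_LATENCIES = frozenset(
    {OnsetLatency.DAYS_URTICARIA_GT2, OnsetLatency.WEEKS_EXANTHEMA_GT1}
)


def evaluate_question(
    q: Question,
    history: PatientHistory,
    adult_threshold: float = ADULT_AGE_THRESHOLD,
) -> TriState:
    """Answer a single question from the structured history.

    Returns yes when the question's defining condition is established,
    no when the driving fields definitively rule it out, and uncertain
    when the records leave it open.
    """
    if q is Question.Q1:
        if (
            history.symptoms_incompatible_with_allergy is TriState.YES
            or history.onset_latency in _LATE_LATENCIES
        ):
            return TriState.YES
        if (
            history.symptoms_incompatible_with_allergy is TriState.UNCERTAIN
            or history.onset_latency is OnsetLatency.UNKNOWN
        ):
            return TriState.UNCERTAIN
        return TriState.NO
    if q is Question.Q2:
        rash = history.rash_in_childhood_no_systemic
        age = history.age_at_reaction_years
        if rash is TriState.YES and (age is None or age < adult_threshold):
            return TriState.YES
        if rash is TriState.UNCERTAIN:
            return TriState.UNCERTAIN
        return TriState.NO
    if q is Question.Q3:
        return history.prolonged_urticaria_no_systemic
    if q is Question.Q4:
        return history.measles_like_exanthema_adult
    if q is Question.Q5:
        # severe_indicators is an explicit set: an empty set asserts that
        # no severe-reaction evidence was found, so Q5 is never uncertain.
        return TriState.YES if history.severe_indicators else TriState.NO
    raise ValueError(f"unknown question {q!r}")


def apply_algorithm(
    history: PatientHistory, adult_threshold: float = ADULT_AGE_THRESHOLD
) -> Decision:
    """Run the five questions in order and return the traced decision."""
    trace: list[QuestionAnswer] = []
    for q in (Question.Q1, Question.Q2, Question.Q3, Question.Q4):
        answer = evaluate_question(q, history, adult_threshold)
        trace.append(QuestionAnswer(question=q, answer=answer))
        if answer is TriState.YES:
            rec = (
                Recommendation.ALTERNATIVE_ANTIBIOTIC
                if q is Question.Q4
                else Recommendation.DE_LABEL
            )
            return Decision(
                case_id=history.case_id,
                recommendation=rec,
                deciding_question=q,
                answer_trace=tuple(trace),
            )
    answer = evaluate_question(Question.Q5, history, adult_threshold)
    trace.append(QuestionAnswer(question=Question.Q5, answer=answer))
    rec = (
        Recommendation.ALTERNATIVE_ANTIBIOTIC
        if answer is TriState.YES
        else Recommendation.DE_LABEL
    )
    return Decision(
        case_id=history.case_id,
        recommendation=rec,
        deciding_question=Question.Q5,
        answer_trace=tuple(trace),
    )


def classify_cohort(
    histories: Iterable[PatientHistory], adult_threshold: float = ADULT_AGE_THRESHOLD
) -> list[Decision]:
    """Apply the algorithm to every record of a cohort."""
    return [apply_algorithm(h, adult_threshold) for h in histories]


def _pair(decisions: Sequence[Decision], truths: Sequence[GroundTruth]):
    truth_by_id = {t.case_id: t for t in truths}
    if len(truth_by_id) != len(truths):
        raise ValueError("duplicate case_id in ground truths")
    if len({d.case_id for d in decisions}) != len(decisions):
        raise ValueError("duplicate case_id in decisions")
    if set(truth_by_id) != {d.case_id for d in decisions}:
        raise ValueError("decisions and ground truths must share case_ids one-to-one")
    return [(d, truth_by_id[d.case_id]) for d in decisions]


def route_counts(
    decisions: Sequence[Decision], truths: Sequence[GroundTruth]
) -> pd.DataFrame:
    """Tabulate counts by (deciding question, recommendation, allergic).

    Returns a DataFrame with a ``count`` column on a complete
    MultiIndex (all 5 × 2 × 2 combinations, zeros included); counts sum
    to the cohort size and marginalising over the deciding question
    yields the 2×2 classification-vs-truth table.
    """
    pairs = _pair(decisions, truths)
    index = pd.MultiIndex.from_product(
        [
            [q.value for q in Question],
            [r.value for r in Recommendation],
            [True, False],
        ],
        names=["deciding_question", "recommendation", "allergic"],
    )
    counts = pd.Series(0, index=index, name="count")
    for d, t in pairs:
        counts.loc[(d.deciding_question.value, d.recommendation.value, t.allergic)] += 1
    return counts.to_frame()
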