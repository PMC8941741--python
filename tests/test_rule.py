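"""The five-question rule engine: single questions, routing, trace invariants."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delabel import (
    GroundTruth,
    OnsetLatency,
    PatientHistory,
    Question,
    Recommendation,
    SevereIndicator,
    TriState,
    apply_algorithm,
    evaluate_question,
    route_counts,
)

from .conftest import histories


def hist(**kw) -> PatientHistory:
    base = dict(
        case_id="t",
        symptoms_incompatible_with_allergy=TriState.NO,
        onset_latency=OnsetLatency.MINUTES,
        rash_in_childhood_no_systemic=TriState.NO,
        age_at_reaction_years=40.0,
        prolonged_urticaria_no_systemic=TriState.NO,
        measles_like_exanthema_adult=TriState.NO,
        severe_indicators=frozenset(),
    )
    base.update(kw)
    return PatientHistory(**base)


@pytest.mark.parametrize(
    "q, kwargs, expected",
    [
        # Q1: non-specific complaints (isolated headache) or late onset
        (Question.Q1, dict(symptoms_incompatible_with_allergy=TriState.YES), TriState.YES),
        (Question.Q1, dict(onset_latency=OnsetLatency.DAYS_URTICARIA_GT2), TriState.YES),
        (Question.Q1, dict(onset_latency=OnsetLatency.WEEKS_EXANTHEMA_GT1), TriState.YES),
        (Question.Q1, dict(onset_latency=OnsetLatency.UNKNOWN), TriState.UNCERTAIN),
        (
            Question.Q1,
            dict(symptoms_incompatible_with_allergy=TriState.UNCERTAIN),
            TriState.UNCERTAIN,
        ),
        (Question.Q1, {}, TriState.NO),
        # Q2: childhood/adolescent rash without systemic symptoms
        (
            Question.Q2,
            dict(rash_in_childhood_no_systemic=TriState.YES, age_at_reaction_years=10.0),
            TriState.YES,
        ),
        (
            Question.Q2,
            dict(rash_in_childhood_no_systemic=TriState.YES, age_at_reaction_years=None),
            TriState.YES,
        ),
        (
            Question.Q2,
            dict(rash_in_childhood_no_systemic=TriState.YES, age_at_reaction_years=30.0),
            TriState.NO,
        ),
        (Question.Q2, dict(rash_in_childhood_no_systemic=TriState.UNCERTAIN), TriState.UNCERTAIN),
        # Q3: prolonged urticaria without systemic involvement
        (Question.Q3, dict(prolonged_urticaria_no_systemic=TriState.YES), TriState.YES),
        (Question.Q3, {}, TriState.NO),
        # Q4: adult-onset maculopapular exanthema
        (Question.Q4, dict(measles_like_exanthema_adult=TriState.YES), TriState.YES),
        (Question.Q4, dict(measles_like_exanthema_adult=TriState.UNCERTAIN), TriState.UNCERTAIN),
        # Q5: any severe-reaction indicator, incl. incidents under anesthesia
        (
            Question.Q5,
            dict(severe_indicators=frozenset({SevereIndicator.INCIDENT_DURING_ANESTHESIA})),
            TriState.YES,
        ),
        (Question.Q5, {}, TriState.NO),
    ],
)
def test_evaluate_question(q, kwargs, expected):
    assert evaluate_question(q, hist(**kwargs)) is expected


def test_q2_adult_threshold_configurable():
    h = hist(rash_in_childhood_no_systemic=TriState.YES, age_at_reaction_years=20.0)
    assert evaluate_question(Question.Q2, h) is TriState.NO
    assert evaluate_question(Question.Q2, h, adult_threshold=21.0) is TriState.YES


@pytest.mark.parametrize(
    "kwargs, question, recommendation",
    [
        # fixed-drug-eruption-like history: blistering caught at Q5
        (
            dict(severe_indicators=frozenset({SevereIndicator.CUTANEOUS_BLISTERS})),
            Question.Q5,
            Recommendation.ALTERNATIVE_ANTIBIOTIC,
        ),
        (
            dict(measles_like_exanthema_adult=TriState.YES),
            Question.Q4,
            Recommendation.ALTERNATIVE_ANTIBIOTIC,
        ),
        ({}, Question.Q5, Recommendation.DE_LABEL),
        (
            dict(symptoms_incompatible_with_allergy=TriState.YES),
            Question.Q1,
            Recommendation.DE_LABEL,
        ),
        (
            dict(rash_in_childhood_no_systemic=TriState.YES, age_at_reaction_years=8.0),
            Question.Q2,
            Recommendation.DE_LABEL,
        ),
        (
            dict(prolonged_urticaria_no_systemic=TriState.YES),
            Question.Q3,
            Recommendation.DE_LABEL,
        ),
    ],
)
def test_apply_algorithm_routing(kwargs, question, recommendation):
    d = apply_algorithm(hist(**kwargs))
    assert d.deciding_question is question
    assert d.recommendation is recommendation
    assert d.answer_trace[-1].question is question


def test_earlier_yes_takes_precedence_over_severe_flags():
    """A Q1 yes decides before Q5 ever sees the severe indicators."""
    d = apply_algorithm(
        hist(
            symptoms_incompatible_with_allergy=TriState.YES,
            severe_indicators=frozenset({SevereIndicator.HEPATITIS}),
        )
    )
    assert d.deciding_question is Question.Q1
    assert d.recommendation is Recommendation.DE_LABEL


@settings(max_examples=200, deadline=None)
@given(histories())
def test_decision_invariants_on_arbitrary_histories(h):
    """One deciding question; Q1–Q3 de-label, Q4 refers; trace is ordered."""
    d = apply_algorithm(h)  # Decision model validates trace/consistency itself
    assert d.case_id == h.case_id
    if d.deciding_question in (Question.Q1, Question.Q2, Question.Q3):
        assert d.recommendation is Recommendation.DE_LABEL
    if d.deciding_question is Question.Q4:
        assert d.recommendation is Recommendation.ALTERNATIVE_ANTIBIOTIC
    # determinism
    assert apply_algorithm(h) == d


@settings(max_examples=200, deadline=None)
@given(histories(), st.sampled_from(list(SevereIndicator)))
def test_severe_flags_monotone(h, flag):
    """Adding a severe indicator never converts a referral into de-labelling."""
    before = apply_algorithm(h)
    after = apply_algorithm(
        h.model_copy(update={"severe_indicators": h.severe_indicators | {flag}})
    )
    if before.recommendation is Recommendation.ALTERNATIVE_ANTIBIOTIC:
        assert after.recommendation is Recommendation.ALTERNATIVE_ANTIBIOTIC


def test_fixture_recommendation_totals(fixture_cohort, fixture_decisions):
    """Recommendations split 351 de-label / 449 alternative on the fixture.

    Oracle: the published per-question routing sums, 330 + 21 de-labelled
    and 265 + 184 referred.
    """
    recs = [d.recommendation for d in fixture_decisions]
    assert recs.count(Recommendation.DE_LABEL) == 351
    assert recs.count(Recommendation.ALTERNATIVE_ANTIBIOTIC) == 449


def test_fixture_route_counts(fixture_cohort, fixture_decisions):
    _, truths = fixture_cohort
    counts = route_counts(fixture_decisions, truths)
    assert int(counts["count"].sum()) == 800
    assert counts.loc[("Q1", "de_label", False), "count"] == 68
    assert counts.loc[("Q2", "de_label", False), "count"] == 66
    assert counts.loc[("Q3", "de_label", False), "count"] == 95
    assert counts.loc[("Q5", "alternative_antibiotic", False), "count"] == 70
    # allergic patients incorrectly de-labelled: 3/2/6 at Q1–Q3 plus 10 at Q5
    assert counts.loc[("Q1", "de_label", True), "count"] == 3
    assert counts.loc[("Q2", "de_label", True), "count"] == 2
    assert counts.loc[("Q3", "de_label", True), "count"] == 6
    assert counts.loc[("Q5", "de_label", True), "count"] == 10


def test_route_counts_empty_cohort():
    counts = route_counts([], [])
    assert int(counts["count"].sum()) == 0


def test_route_counts_unmatched_ids_rejected():
    d = apply_algorithm(hist())
    with pytest.raises(ValueError, match="one-to-one"):
        route_counts([d], [GroundTruth(case_id="other", allergic=False)])
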