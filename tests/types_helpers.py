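"""Tiny constructors for hand-built decisions and ground truths in tests."""

from __future__ import annotations

from delabel import (
    AnaphylaxisSeverity,
    Decision,
    DelayedSubtype,
    GroundTruth,
    Mechanism,
    Question,
    QuestionAnswer,
    Recommendation,
    TriState,
)

_NO = TriState.NO


def decision(case_id: str, positive: bool) -> Decision:
    """A minimal valid Q5 decision: positive = alternative antibiotic."""
    answer = TriState.YES if positive else TriState.NO
    trace = tuple(
        QuestionAnswer(question=q, answer=_NO)
        for q in (Question.Q1, Question.Q2, Question.Q3, Question.Q4)
    ) + (QuestionAnswer(question=Question.Q5, answer=answer),)
    return Decision(
        case_id=case_id,
        recommendation=Recommendation.ALTERNATIVE_ANTIBIOTIC
        if positive
        else Recommendation.DE_LABEL,
        deciding_question=Question.Q5,
        answer_trace=trace,
    )


def truth(
    case_id: str,
    allergic: bool,
    severity: AnaphylaxisSeverity | None = None,
    subtype: DelayedSubtype | None = None,
) -> GroundTruth:
    if not allergic:
        return GroundTruth(case_id=case_id, allergic=False)
    if severity is not None:
        return GroundTruth(
            case_id=case_id,
            allergic=True,
            mechanism=Mechanism.IMMEDIATE_ANAPHYLAXIS,
            anaphylaxis_severity=severity,
        )
    return GroundTruth(
        case_id=case_id,
        allergic=True,
        mechanism=Mechanism.DELAYED,
        delayed_subtype=subtype or DelayedSubtype.MACULOPAPULAR_EXANTHEMA,
    )
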