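"""PEN-FAST point score for penicillin-allergy risk stratification.

PEN-FAST is a published bedside decision rule.  After the gating PEN
question (patient reports a penicillin allergy — assumed satisfied for
every record in scope here), four items are scored:

* F — five years or less since the reaction: 2 points
* A — anaphylaxis or angioedema: 2 points
* S — severe cutaneous adverse reaction: 2 points
* T — treatment was required for the reaction: 1 point

A total below 3 points classifies the case as low risk (eligible for
de-labelling).  This implementation scores A and S as independent
2-point items (maximum total 7).  An unknown item scores 0: the rule is
a screen, and a feature that is not documented cannot add risk points;
the 0 is still recorded per item so callers can audit it.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .types import PatientHistory, PenFastResult

#: Points awarded per item when answered yes.
ITEM_POINTS = {"F": 2, "A": 2, "S": 2, "T": 1}

#: Totals strictly below this cutoff are low risk.
LOW_RISK_CUTOFF = 3


def _points(item: str, answer: Optional[bool]) -> int:
    return ITEM_POINTS[item] if answer else 0


def pen_fast(history: PatientHistory) -> PenFastResult:
    """Score one case with the PEN-FAST rule."""
    item_points = {
        "F": _points("F", history.penfast_five_years_or_less),
        "A": _points("A", history.penfast_anaphylaxis_or_angioedema),
        "S": _points("S", history.penfast_severe_cutaneous),
        "T": _points("T", history.penfast_treatment_required),
    }
    total = sum(item_points.values())
    return PenFastResult(
        case_id=history.case_id,
        item_points=item_points,
        total=total,
        low_risk=total < LOW_RISK_CUTOFF,
    )


def pen_fast_cohort(histories: Iterable[PatientHistory]) -> list[PenFastResult]:
    """Score every record of a cohort."""
    return [pen_fast(h) for h in histories]
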