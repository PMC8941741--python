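"""Domain types for penicillin (β-lactam) allergy de-labelling cohorts.

A cohort is a list of :class:`PatientHistory` records — one per suspected
β-lactam hypersensitivity reaction — optionally paired with
:class:`GroundTruth` records carrying the allergist-adjudicated diagnosis
(allergy proven, with mechanism and severity/subtype, or excluded by a
negative challenge test).  :class:`Decision` captures the output of the
five-question de-labelling algorithm together with a full answer trace.

All models are frozen pydantic models: construction validates, instances
are immutable and hashable.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class TriState(str, enum.Enum):
    """Answer to a history question: affirmed, denied, or unresolvable."""

    YES = "yes"
    NO = "no"
    UNCERTAIN = "uncertain"


class OnsetLatency(str, enum.Enum):
    """Coarse timing of symptom onset relative to the last drug intake.

    The two "late" codes encode the latency thresholds beyond which an
    allergic mechanism is implausible: urticaria starting more than two
    days, or exanthema more than one week, after the last dose.
    """

    MINUTES = "minutes"
    HOURS_TO_DAYS = "hours_to_days"
    DAYS_URTICARIA_GT2 = "days_urticaria_gt2"
    WEEKS_EXANTHEMA_GT1 = "weeks_exanthema_gt1"
    UNKNOWN = "unknown"


class SevereIndicator(str, enum.Enum):
    """History features suggesting a severe drug reaction (question 5)."""

    ONSET_WITHIN_MINUTES = "onset_within_minutes"
    CARDIOVASCULAR_SIGNS = "cardiovascular_signs"
    RESPIRATORY_SIGNS = "respiratory_signs"
    INCIDENT_DURING_ANESTHESIA = "incident_during_anesthesia"
    MUCOSAL_EROSIONS = "mucosal_erosions"
    CUTANEOUS_BLISTERS = "cutaneous_blisters"
    HEPATITIS = "hepatitis"
    NEPHRITIS = "nephritis"
    BLOOD_CELL_DROP = "blood_cell_drop"


class CulpritClass(str, enum.Enum):
    AMINOPENICILLIN = "aminopenicillin"
    CEPHALOSPORIN = "cephalosporin"
    BENZYL_PHENOXYMETHYL_PENICILLIN = "benzyl_phenoxymethyl_penicillin"
    OTHER = "other"
    UNCLEAR = "unclear"


class Route(str, enum.Enum):
    ORAL = "oral"
    INTRAVENOUS = "intravenous"
    INTRAMUSCULAR = "intramuscular"
    UNCLEAR = "unclear"


class RecallInterval(str, enum.Enum):
    """Time between the index reaction and allergy work-up."""

    LE_1Y = "le_1y"
    Y1_5 = "y1_5"
    Y5_10 = "y5_10"
    GT_10Y = "gt_10y"
    UNCLEAR = "unclear"


class ReportedType(str, enum.Enum):
    IMMEDIATE = "immediate"
    DELAYED = "delayed"
    UNCERTAIN = "uncertain"


class Question(str, enum.Enum):
    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"
    Q5 = "Q5"


class Recommendation(str, enum.Enum):
    DE_LABEL = "de_label"
    ALTERNATIVE_ANTIBIOTIC = "alternative_antibiotic"


class Mechanism(str, enum.Enum):
    IMMEDIATE_ANAPHYLAXIS = "immediate_anaphylaxis"
    DELAYED = "delayed"


class AnaphylaxisSeverity(str, enum.Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class DelayedSubtype(str, enum.Enum):
    MACULOPAPULAR_EXANTHEMA = "maculopapular_exanthema"
    SDRIFE = "SDRIFE"
    FDE = "FDE"
    DRESS = "DRESS"


class PatientHistory(BaseModel):
    """Structured medical history of one suspected β-lactam reaction.

    Tri-state fields answer "does the history establish this feature?"
    with yes / no / uncertain; ``uncertain`` means the records do not
    allow either a yes or a no.  Factual fields (latency, culprit drug,
    route, recall interval) carry an explicit unknown/unclear code, and
    ``age_at_reaction_years`` and the four PEN-FAST item fields use
    ``None`` for unknown.
    """

    model_config = ConfigDict(frozen=True)

    case_id: str = Field(min_length=1)
    symptoms_incompatible_with_allergy: TriState = TriState.UNCERTAIN
    onset_latency: OnsetLatency = OnsetLatency.UNKNOWN
    rash_in_childhood_no_systemic: TriState = TriState.UNCERTAIN
    age_at_reaction_years: Optional[float] = Field(default=None, ge=0, le=120)
    prolonged_urticaria_no_systemic: TriState = TriState.UNCERTAIN
    measles_like_exanthema_adult: TriState = TriState.UNCERTAIN
    severe_indicators: frozenset[SevereIndicator] = frozenset()
    culprit_class: CulpritClass = CulpritClass.UNCLEAR
    route: Route = Route.UNCLEAR
    recall_interval: RecallInterval = RecallInterval.UNCLEAR
    reported_type: ReportedType = ReportedType.UNCERTAIN
    penfast_five_years_or_less: Optional[bool] = None
    penfast_anaphylaxis_or_angioedema: Optional[bool] = None
    penfast_severe_cutaneous: Optional[bool] = None
    penfast_treatment_required: Optional[bool] = None


class GroundTruth(BaseModel):
    """Allergist-adjudicated diagnosis for one case.

    ``allergic`` is True when β-lactam hypersensitivity was proven by
    positive skin or challenge testing and False when a negative challenge
    excluded it.  Mechanism detail is present exactly when allergic:
    immediate-type anaphylaxis carries a severity grade, delayed-type
    hypersensitivity a clinical subtype.
    """

    model_config = ConfigDict(frozen=True)

    case_id: str = Field(min_length=1)
    allergic: bool
    mechanism: Optional[Mechanism] = None
    anaphylaxis_severity: Optional[AnaphylaxisSeverity] = None
    delayed_subtype: Optional[DelayedSubtype] = None

    @model_validator(mode="after")
    def _check_consistency(self) -> "GroundTruth":
        if self.allergic:
            if self.mechanism is None:
                raise ValueError("allergic case requires a mechanism")
            if self.mechanism is Mechanism.IMMEDIATE_ANAPHYLAXIS:
                if self.anaphylaxis_severity is None or self.delayed_subtype is not None:
                    raise ValueError(
                        "immediate-type case requires anaphylaxis_severity and no delayed_subtype"
                    )
            else:
                if self.delayed_subtype is None or self.anaphylaxis_severity is not None:
                    raise ValueError(
                        "delayed-type case requires delayed_subtype and no anaphylaxis_severity"
                    )
        else:
            if (
                self.mechanism is not None
                or self.anaphylaxis_severity is not None
                or self.delayed_subtype is not None
            ):
                raise ValueError("non-allergic case must not carry mechanism detail")
        return self

    @property
    def stratum(self) -> str:
        """Ground-truth stratum label used for stratified reporting."""
        if not self.allergic:
            return "excluded"
        if self.mechanism is Mechanism.IMMEDIATE_ANAPHYLAXIS:
            return self.anaphylaxis_severity.value
        return self.delayed_subtype.value


class QuestionAnswer(BaseModel):
    model_config = ConfigDict(frozen=True)

    question: Question
    answer: TriState


class Decision(BaseModel):
    """Outcome of the de-labelling algorithm for one case.

    The recommendation is binary: de-label (administer the β-lactam in
    question) or use an alternative antibiotic.  ``answer_trace`` records
    every question evaluated, in order; ``deciding_question`` is the one
    that fixed the recommendation (the last entry of the trace).
    """

    model_config = ConfigDict(frozen=True)

    case_id: str = Field(min_length=1)
    recommendation: Recommendation
    deciding_question: Question
    answer_trace: tuple[QuestionAnswer, ...]

    @model_validator(mode="after")
    def _check_trace(self) -> "Decision":
        if not self.answer_trace:
            raise ValueError("answer_trace must not be empty")
        if self.answer_trace[-1].question is not self.deciding_question:
            raise ValueError("deciding_question must be the last trace entry")
        expected = [Question.Q1, Question.Q2, Question.Q3, Question.Q4, Question.Q5]
        for i, qa in enumerate(self.answer_trace):
            if qa.question is not expected[i]:
                raise ValueError("answer_trace must visit Q1..Q5 in order without gaps")
            if i < len(self.answer_trace) - 1 and qa.answer is TriState.YES:
                raise ValueError("only the deciding question may be answered yes")
        q = self.deciding_question
        rec = self.recommendation
        if q in (Question.Q1, Question.Q2, Question.Q3) and rec is not Recommendation.DE_LABEL:
            raise ValueError(f"{q.value} decisions must recommend de_label")
        if q is Question.Q4 and rec is not Recommendation.ALTERNATIVE_ANTIBIOTIC:
            raise ValueError("Q4 decisions must recommend alternative_antibiotic")
        return self


class PenFastResult(BaseModel):
    """PEN-FAST point score for one case.

    Items: F — five years or less since the reaction (2 points),
    A — anaphylaxis or angioedema (2 points), S — severe cutaneous
    adverse reaction (2 points), T — treatment required for the reaction
    (1 point).  A total below 3 classifies the case as low risk.
    """

    model_config = ConfigDict(frozen=True)

    case_id: str = Field(min_length=1)
    item_points: dict[str, int]
    total: int = Field(ge=0, le=7)
    low_risk: bool

    @model_validator(mode="after")
    def _check_score(self) -> "PenFastResult":
        if set(self.item_points) != {"F", "A", "S", "T"}:
            raise ValueError("item_points must map exactly F, A, S, T")
        for item in "FAS":
            if self.item_points[item] not in (0, 2):
                raise ValueError(f"item {item} must score 0 or 2")
        if self.item_points["T"] not in (0, 1):
            raise ValueError("item T must score 0 or 1")
        if self.total != sum(self.item_points.values()):
            raise ValueError("total must equal the sum of item points")
        if self.low_risk != (self.total < 3):
            raise ValueError("low_risk must be total < 3")
        return self
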