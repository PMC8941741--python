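from __future__ import annotations

import pytest
from hypothesis import strategies as st

from delabel import (
    AnaphylaxisSeverity,
    CulpritClass,
    DelayedSubtype,
    GroundTruth,
    Mechanism,
    OnsetLatency,
    PatientHistory,
    RecallInterval,
    ReportedType,
    Route,
    SevereIndicator,
    TriState,
    classify_cohort,
    generate_fixture,
)

# ---------------------------------------------------------------- strategies

tristates = st.sampled_from(list(TriState))
optional_bools = st.one_of(st.none(), st.booleans())


def histories(case_id: st.SearchStrategy[str] | None = None) -> st.SearchStrategy[PatientHistory]:
    """Arbitrary valid patient histories."""
    if case_id is None:
        case_id = st.text(
            alphabet="abcdefghijklmnopqrstuvwxyz0123456789_-", min_size=1, max_size=12
        )
    return st.builds(
        PatientHistory,
        case_id=case_id,
        symptoms_incompatible_with_allergy=tristates,
        onset_latency=st.sampled_from(list(OnsetLatency)),
        rash_in_childhood_no_systemic=tristates,
        age_at_reaction_years=st.one_of(
            st.none(), st.floats(min_value=0, max_value=120, allow_nan=False)
        ),
        prolonged_urticaria_no_systemic=tristates,
        measles_like_exanthema_adult=tristates,
        severe_indicators=st.frozensets(st.sampled_from(list(SevereIndicator)), max_size=4),
        culprit_class=st.sampled_from(list(CulpritClass)),
        route=st.sampled_from(list(Route)),
        recall_interval=st.sampled_from(list(RecallInterval)),
        reported_type=st.sampled_from(list(ReportedType)),
        penfast_five_years_or_less=optional_bools,
        penfast_anaphylaxis_or_angioedema=optional_bools,
        penfast_severe_cutaneous=optional_bools,
        penfast_treatment_required=optional_bools,
    )


def truth_for(case_id: str) -> st.SearchStrategy[GroundTruth]:
    """Arbitrary valid ground truth for one case."""
    immediate = st.builds(
        GroundTruth,
        case_id=st.just(case_id),
        allergic=st.just(True),
        mechanism=st.just(Mechanism.IMMEDIATE_ANAPHYLAXIS),
        anaphylaxis_severity=st.sampled_from(list(AnaphylaxisSeverity)),
    )
    delayed = st.builds(
        GroundTruth,
        case_id=st.just(case_id),
        allergic=st.just(True),
        mechanism=st.just(Mechanism.DELAYED),
        delayed_subtype=st.sampled_from(list(DelayedSubtype)),
    )
    excluded = st.just(GroundTruth(case_id=case_id, allergic=False))
    return st.one_of(excluded, immediate, delayed)


@st.composite
def cohorts(draw, max_size: int = 8):
    """Small cohorts with unique case ids and matching ground truths."""
    raw = draw(st.lists(histories(), min_size=0, max_size=max_size))
    hist = [h.model_copy(update={"case_id": f"c{i}"}) for i, h in enumerate(raw)]
    truths = [draw(truth_for(h.case_id)) for h in hist]
    return hist, truths


# ------------------------------------------------------------------ fixtures


@pytest.fixture(scope="session")
def fixture_cohort():
    return generate_fixture()


@pytest.fixture(scope="session")
def fixture_decisions(fixture_cohort):
    hist, _ = fixture_cohort
    return classify_cohort(hist)
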