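"""Synthetic cohorts of suspected β-lactam hypersensitivity cases.

Two generation modes share one cell structure — the joint distribution
of (ground-truth stratum, deciding question, recommendation):

* ``generate_fixture`` builds the deterministic 800-record reference
  cohort whose routing through the five-question algorithm reproduces
  every published count of the source study: 595 non-allergic cases
  (de-labelled via Q1/Q2/Q3/Q5 = 68/66/95/101, referred via Q4/Q5 =
  195/70) and 205 allergic cases (de-labelled 3/2/6 at Q1–Q3 and 10 at
  Q5; referred 106 at Q4 and 78 at Q5), with anaphylaxis severities
  26/27/17 (mild/moderate/severe) and delayed subtypes 117/12/3/3
  (maculopapular exanthema / SDRIFE / FDE / DRESS).
* ``generate_stochastic`` draws cohorts of any size from a
  :class:`CohortSpec` — cell probabilities plus reaction-type,
  culprit-drug, intake-route and recall-interval marginals — with a
  seeded, per-record random stream.

Descriptive attributes (reported reaction type, culprit class, route,
recall interval) are assigned independently of the routing cell, since
the study publishes only their marginals; the fixture hits the printed
marginal counts exactly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .rule import apply_algorithm
from .types import (
    AnaphylaxisSeverity,
    CulpritClass,
    DelayedSubtype,
    GroundTruth,
    Mechanism,
    OnsetLatency,
    PatientHistory,
    Question,
    RecallInterval,
    Recommendation,
    ReportedType,
    Route,
    SevereIndicator,
    TriState,
)


class GenerationError(RuntimeError):
    """A constructed record failed to route to its intended cell."""


#: Internal seed for the fixture's attribute interleaving (the fixture
#: itself takes no seed: it is a single, byte-identical reference cohort).
_FIXTURE_SEED = 800_2022

COHORT_SIZE = 800

# (stratum, deciding question, recommendation, count) — the fixture's
# joint routing cells.  Margins over question and over stratum both
# match the published tables; the within-allergic joint (not published)
# assigns mild anaphylaxis de-labellings to Q1/Q3 (urticaria histories)
# and maculopapular-exanthema de-labellings to Q1/Q2/Q5.
FIXTURE_CELLS: tuple[tuple[str, Question, Recommendation, int], ...] = (
    ("excluded", Question.Q1, Recommendation.DE_LABEL, 68),
    ("excluded", Question.Q2, Recommendation.DE_LABEL, 66),
    ("excluded", Question.Q3, Recommendation.DE_LABEL, 95),
    ("excluded", Question.Q4, Recommendation.ALTERNATIVE_ANTIBIOTIC, 195),
    ("excluded", Question.Q5, Recommendation.ALTERNATIVE_ANTIBIOTIC, 70),
    ("excluded", Question.Q5, Recommendation.DE_LABEL, 101),
    ("mild", Question.Q1, Recommendation.DE_LABEL, 1),
    ("mild", Question.Q3, Recommendation.DE_LABEL, 6),
    ("mild", Question.Q5, Recommendation.ALTERNATIVE_ANTIBIOTIC, 19),
    ("moderate", Question.Q5, Recommendation.DE_LABEL, 1),
    ("moderate", Question.Q5, Recommendation.ALTERNATIVE_ANTIBIOTIC, 26),
    ("severe", Question.Q5, Recommendation.ALTERNATIVE_ANTIBIOTIC, 17),
    ("maculopapular_exanthema", Question.Q1, Recommendation.DE_LABEL, 2),
    ("maculopapular_exanthema", Question.Q2, Recommendation.DE_LABEL, 2),
    ("maculopapular_exanthema", Question.Q4, Recommendation.ALTERNATIVE_ANTIBIOTIC, 106),
    ("maculopapular_exanthema", Question.Q5, Recommendation.DE_LABEL, 7),
    ("SDRIFE", Question.Q5, Recommendation.DE_LABEL, 2),
    ("SDRIFE", Question.Q5, Recommendation.ALTERNATIVE_ANTIBIOTIC, 10),
    ("FDE", Question.Q5, Recommendation.ALTERNATIVE_ANTIBIOTIC, 3),
    ("DRESS", Question.Q5, Recommendation.ALTERNATIVE_ANTIBIOTIC, 3),
)

_ANAPHYLAXIS_STRATA = frozenset({"mild", "moderate", "severe"})
_DELAYED_STRATA = frozenset({"maculopapular_exanthema", "SDRIFE", "FDE", "DRESS"})

# Severe-reaction indicator flags the generator assigns when routing a
# record to a Q5 referral, by stratum.  FDE (cutaneous blisters) and
# DRESS (hepatitis) follow the study's explicit account; the rest are
# synthetic scaffolding consistent with the clinical picture.
_Q5_FLAGS: dict[str, tuple[SevereIndicator, ...]] = {
    "mild": (SevereIndicator.ONSET_WITHIN_MINUTES,),
    "moderate": (SevereIndicator.ONSET_WITHIN_MINUTES, SevereIndicator.RESPIRATORY_SIGNS),
    "severe": (
        SevereIndicator.ONSET_WITHIN_MINUTES,
        SevereIndicator.CARDIOVASCULAR_SIGNS,
        SevereIndicator.RESPIRATORY_SIGNS,
    ),
    "SDRIFE": (SevereIndicator.MUCOSAL_EROSIONS,),
    "FDE": (SevereIndicator.CUTANEOUS_BLISTERS,),
    "DRESS": (SevereIndicator.HEPATITIS,),
}

# The study's descriptive marginals: reaction-type column counts and,
# conditional on reaction type, culprit class, route and recall interval.
TABLE1_REPORTED_TYPE: dict[str, int] = {"immediate": 334, "delayed": 421, "uncertain": 45}
TABLE1_CONDITIONALS: dict[str, dict[str, dict[str, int]]] = {
    "culprit_class": {
        "aminopenicillin": {"immediate": 111, "delayed": 287, "uncertain": 13},
        "cephalosporin": {"immediate": 144, "delayed": 47, "uncertain": 3},
        "benzyl_phenoxymethyl_penicillin": {"immediate": 45, "delayed": 55, "uncertain": 9},
        "other": {"immediate": 4, "delayed": 2, "uncertain": 0},
        "unclear": {"immediate": 30, "delayed": 30, "uncertain": 20},
    },
    "route": {
        "oral": {"immediate": 235, "delayed": 346, "uncertain": 40},
        "intravenous": {"immediate": 97, "delayed": 75, "uncertain": 2},
        "intramuscular": {"immediate": 1, "delayed": 0, "uncertain": 1},
        "unclear": {"immediate": 1, "delayed": 0, "uncertain": 2},
    },
    "recall_interval": {
        "le_1y": {"immediate": 214, "delayed": 274, "uncertain": 3},
        "y1_5": {"immediate": 31, "delayed": 46, "uncertain": 2},
        "y5_10": {"immediate": 13, "delayed": 14, "uncertain": 3},
        "gt_10y": {"immediate": 71, "delayed": 80, "uncertain": 30},
        "unclear": {"immediate": 5, "delayed": 7, "uncertain": 7},
    },
}

_ATTR_ENUMS = {
    "culprit_class": CulpritClass,
    "route": Route,
    "recall_interval": RecallInterval,
}


class CohortSpec(BaseModel):
    """Sampling specification for stochastic cohorts.

    ``stratum_weights`` maps ``"stratum/question/recommendation"`` cell
    keys to probabilities (or unnormalised counts — they are normalised
    at draw time).  ``table1_marginals`` carries the reaction-type
    marginal and, per attribute, value counts conditional on reaction
    type.  A fixed ``seed`` makes the cohort reproducible.
    """

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=0)
    stratum_weights: dict[str, float]
    table1_marginals: dict
    seed: int = 0
    mode: str = "stochastic"

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.mode not in ("fixture", "stochastic"):
            raise ValueError("mode must be 'fixture' or 'stochastic'")
        if not self.stratum_weights:
            raise ValueError("stratum_weights must not be empty")
        total = 0.0
        for key, w in self.stratum_weights.items():
            stratum, q, rec = _parse_cell_key(key)
            _check_cell(stratum, q, rec)
            if w < 0:
                raise ValueError(f"negative weight for cell {key!r}")
            total += w
        if total <= 0:
            raise ValueError("stratum_weights must have positive total mass")
        rt = self.table1_marginals.get("reported_type")
        if not rt or any(c not in rt for c in TABLE1_REPORTED_TYPE):
            raise ValueError("table1_marginals must give all three reported_type weights")
        return self


def _cell_key(stratum: str, q: Question, rec: Recommendation) -> str:
    return f"{stratum}/{q.value}/{rec.value}"


def _parse_cell_key(key: str) -> tuple[str, Question, Recommendation]:
    try:
        stratum, q, rec = key.split("/")
        return stratum, Question(q), Recommendation(rec)
    except ValueError as exc:
        raise ValueError(f"malformed cell key {key!r}") from exc


def _check_cell(stratum: str, q: Question, rec: Recommendation) -> None:
    if stratum != "excluded" and stratum not in _ANAPHYLAXIS_STRATA | _DELAYED_STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    if q in (Question.Q1, Question.Q2, Question.Q3) and rec is not Recommendation.DE_LABEL:
        raise ValueError(f"cell {stratum}/{q.value}: Q1-Q3 routes must de-label")
    if q is Question.Q4 and rec is not Recommendation.ALTERNATIVE_ANTIBIOTIC:
        raise ValueError("Q4 routes must recommend the alternative antibiotic")


def _truth_for(case_id: str, stratum: str) -> GroundTruth:
    if stratum == "excluded":
        return GroundTruth(case_id=case_id, allergic=False)
    if stratum in _ANAPHYLAXIS_STRATA:
        return GroundTruth(
            case_id=case_id,
            allergic=True,
            mechanism=Mechanism.IMMEDIATE_ANAPHYLAXIS,
            anaphylaxis_severity=AnaphylaxisSeverity(stratum),
        )
    return GroundTruth(
        case_id=case_id,
        allergic=True,
        mechanism=Mechanism.DELAYED,
        delayed_subtype=DelayedSubtype(stratum),
    )


def _history_for_cell(
    case_id: str,
    stratum: str,
    q: Question,
    rec: Recommendation,
    k: int,
    attrs: dict[str, str],
) -> PatientHistory:
    """Build a history that the rule engine routes to the given cell.

    ``k`` indexes the record within its cell and drives deterministic
    variation (which Q1 trigger, childhood age, which severe flags).
    """
    fields: dict[str, object] = dict(
        case_id=case_id,
        symptoms_incompatible_with_allergy=TriState.NO,
        onset_latency=OnsetLatency.HOURS_TO_DAYS,
        rash_in_childhood_no_systemic=TriState.NO,
        age_at_reaction_years=float(25 + k % 50),
        prolonged_urticaria_no_systemic=TriState.NO,
        measles_like_exanthema_adult=TriState.NO,
        severe_indicators=frozenset(),
    )
    if q is Question.Q1:
        variant = k % 3
        if variant == 0:
            fields["symptoms_incompatible_with_allergy"] = TriState.YES
        elif variant == 1:
            fields["onset_latency"] = OnsetLatency.DAYS_URTICARIA_GT2
        else:
            fields["onset_latency"] = OnsetLatency.WEEKS_EXANTHEMA_GT1
    elif q is Question.Q2:
        fields["rash_in_childhood_no_systemic"] = TriState.YES
        fields["age_at_reaction_years"] = float(5 + k % 13)
    elif q is Question.Q3:
        fields["prolonged_urticaria_no_systemic"] = TriState.YES
    elif q is Question.Q4:
        fields["measles_like_exanthema_adult"] = TriState.YES
    elif rec is Recommendation.ALTERNATIVE_ANTIBIOTIC:  # Q5 referral
        if stratum == "excluded":
            # symptoms retrospectively misread as severe: cycle the flags
            all_flags = tuple(SevereIndicator)
            fields["severe_indicators"] = frozenset({all_flags[k % len(all_flags)]})
        else:
            flags = set(_Q5_FLAGS[stratum])
            if stratum in _ANAPHYLAXIS_STRATA:
                fields["onset_latency"] = OnsetLatency.MINUTES
                if stratum == "severe" and k % 3 == 0:
                    flags.add(SevereIndicator.INCIDENT_DURING_ANESTHESIA)
            fields["severe_indicators"] = frozenset(flags)
    else:  # Q5 de-labelling: nothing established, no severe evidence
        variant = k % 3
        if variant == 1:
            fields["symptoms_incompatible_with_allergy"] = TriState.UNCERTAIN
        elif variant == 2:
            fields["measles_like_exanthema_adult"] = TriState.UNCERTAIN

    reported = ReportedType(attrs["reported_type"])
    recall = RecallInterval(attrs["recall_interval"])
    history = PatientHistory(
        **fields,
        culprit_class=CulpritClass(attrs["culprit_class"]),
        route=Route(attrs["route"]),
        recall_interval=recall,
        reported_type=reported,
        penfast_five_years_or_less=recall in (RecallInterval.LE_1Y, RecallInterval.Y1_5),
        penfast_anaphylaxis_or_angioedema=stratum in _ANAPHYLAXIS_STRATA,
        penfast_severe_cutaneous=stratum == "DRESS",
        penfast_treatment_required=stratum in ("moderate", "severe", "DRESS"),
    )
    decision = apply_algorithm(history)
    if decision.deciding_question is not q or decision.recommendation is not rec:
        raise GenerationError(
            f"record {case_id} built for cell {_cell_key(stratum, q, rec)} routed to "
            f"{decision.deciding_question.value}/{decision.recommendation.value}"
        )
    return history


def _interleaved_attributes(n: int, rng: np.random.Generator) -> list[dict[str, str]]:
    """Assign descriptive attributes hitting the marginal counts exactly.

    Reaction types are shuffled over the cohort; each conditional
    attribute is shuffled within its reaction-type block, so attributes
    are independent of record order (hence of routing cell) while every
    marginal count is exact.
    """
    scale, remainder = divmod(n, COHORT_SIZE)
    if remainder:
        raise ValueError(f"exact-marginal assignment requires n to be a multiple of {COHORT_SIZE}")
    types: list[str] = []
    for value, count in TABLE1_REPORTED_TYPE.items():
        types.extend([value] * (count * scale))
    order = rng.permutation(n)
    attrs = [{"reported_type": types[j]} for j in order]

    for attr, table in TABLE1_CONDITIONALS.items():
        for category, count in TABLE1_REPORTED_TYPE.items():
            values: list[str] = []
            for value, per_cat in table.items():
                values.extend([value] * (per_cat[category] * scale))
            perm = rng.permutation(len(values))
            slots = [a for a in attrs if a["reported_type"] == category]
            for slot, j in zip(slots, perm):
                slot[attr] = values[j]
    return attrs


def generate_fixture() -> tuple[list[PatientHistory], list[GroundTruth]]:
    """Build the deterministic 800-record reference cohort.

    Byte-identical across calls; every record is verified to route to
    its intended (stratum, question, recommendation) cell.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    attrs = _interleaved_attributes(COHORT_SIZE, rng)
    histories: list[PatientHistory] = []
    truths: list[GroundTruth] = []
    i = 0
    for stratum, q, rec, count in FIXTURE_CELLS:
        for k in range(count):
            case_id = f"case_{i + 1:04d}"
            histories.append(_history_for_cell(case_id, stratum, q, rec, k, attrs[i]))
            truths.append(_truth_for(case_id, stratum))
            i += 1
    assert i == COHORT_SIZE
    return histories, truths


def default_spec(n: int = COHORT_SIZE, seed: int = 0) -> CohortSpec:
    """Spec whose cell weights equal the fixture counts normalised by 800."""
    weights = {
        _cell_key(stratum, q, rec): count / COHORT_SIZE
        for stratum, q, rec, count in FIXTURE_CELLS
    }
    marginals = {
        "reported_type": dict(TABLE1_REPORTED_TYPE),
        "conditionals": TABLE1_CONDITIONALS,
    }
    return CohortSpec(
        n=n, stratum_weights=weights, table1_marginals=marginals, seed=seed, mode="stochastic"
    )


def _cumulative(weights: list[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    return np.cumsum(w / w.sum())


def generate_stochastic(
    spec: CohortSpec,
) -> tuple[list[PatientHistory], list[GroundTruth]]:
    """Draw a seeded stochastic cohort from a :class:`CohortSpec`.

    Each record consumes its own child random stream (spawned from the
    root seed), so adding attributes to one record never perturbs the
    draws of another and the same seed always reproduces the cohort.
    """
    if spec.mode == "fixture":
        return generate_fixture()
    cells = sorted(spec.stratum_weights.items())
    cell_defs = [_parse_cell_key(key) for key, _ in cells]
    cell_cum = _cumulative([w for _, w in cells])

    rt = spec.table1_marginals["reported_type"]
    rt_values = list(rt)
    rt_cum = _cumulative([rt[v] for v in rt_values])
    conditionals = spec.table1_marginals.get("conditionals", TABLE1_CONDITIONALS)
    cond_cum: dict[str, dict[str, tuple[list[str], np.ndarray]]] = {}
    for attr, table in conditionals.items():
        cond_cum[attr] = {}
        for category in rt_values:
            values = [v for v in table if table[v].get(category, 0) > 0]
            weights = [table[v][category] for v in values]
            cond_cum[attr][category] = (values, _cumulative(weights))

    width = max(len(str(spec.n)), 4)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n)
    histories: list[PatientHistory] = []
    truths: list[GroundTruth] = []
    for i in range(spec.n):
        rng = np.random.default_rng(children[i])
        stratum, q, rec = cell_defs[int(np.searchsorted(cell_cum, rng.random()))]
        category = rt_values[int(np.searchsorted(rt_cum, rng.random()))]
        attrs = {"reported_type": category}
        for attr, per_cat in cond_cum.items():
            values, cum = per_cat[category]
            attrs[attr] = values[int(np.searchsorted(cum, rng.random()))]
        k = int(rng.integers(0, 10_000))
        case_id = f"s{i + 1:0{width}d}"
        histories.append(_history_for_cell(case_id, stratum, q, rec, k, attrs))
        truths.append(_truth_for(case_id, stratum))
    return histories, truths
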