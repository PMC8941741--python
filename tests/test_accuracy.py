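"""2×2 tables, accuracy metrics, Wilson intervals, prevalence adjustment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from delabel import (
    GroundTruth,
    TwoByTwo,
    contingency,
    format_percent,
    metrics,
    pen_fast_cohort,
    prevalence_adjusted,
    stratified_report,
)
from delabel.rule import apply_algorithm

from .test_rule import hist
from .types_helpers import decision, truth


def test_contingency_manual_six_records():
    """Direct enumeration on a six-record toy cohort."""
    predictions = [
        decision("a", positive=True),
        decision("b", positive=True),
        decision("c", positive=False),
        decision("d", positive=False),
        decision("e", positive=True),
        decision("f", positive=False),
    ]
    truths = [
        truth("a", allergic=True),   # tp
        truth("b", allergic=False),  # fp
        truth("c", allergic=True),   # fn
        truth("d", allergic=False),  # tn
        truth("e", allergic=True),   # tp
        truth("f", allergic=False),  # tn
    ]
    t = contingency(predictions, truths)
    assert (t.tp, t.fp, t.fn, t.tn) == (2, 1, 1, 2)


def test_contingency_all_correct_toy():
    predictions = [decision(c, positive=p) for c, p in zip("abcd", [True, True, False, False])]
    truths = [truth(c, allergic=p) for c, p in zip("abcd", [True, True, False, False])]
    t = contingency(predictions, truths)
    assert t.fp == 0 and t.fn == 0 and t.n == 4


def test_contingency_accepts_penfast_results():
    """PEN-FAST results count as positive when not low risk."""
    histories = [
        hist().model_copy(
            update={
                "case_id": "hi",
                "penfast_five_years_or_less": True,
                "penfast_anaphylaxis_or_angioedema": True,
            }
        ),
        hist().model_copy(update={"case_id": "lo"}),
    ]
    results = pen_fast_cohort(histories)
    t = contingency(results, [truth("hi", allergic=True), truth("lo", allergic=False)])
    assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)


def test_metrics_on_published_table_prints_exact_percents():
    report = metrics(TwoByTwo(tp=184, fp=265, fn=21, tn=330))
    assert format_percent(report.sensitivity.value) == "89.8"
    assert format_percent(report.specificity.value) == "55.5"
    assert format_percent(report.ppv.value) == "41.0"
    assert format_percent(report.npv.value) == "94.0"
    assert report.prevalence.value == pytest.approx(205 / 800)
    assert "sensitivity" in report.summary()


def test_metrics_perfect_classifier():
    report = metrics(TwoByTwo(tp=1, fp=0, fn=0, tn=1))
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        assert getattr(report, name).value == 1.0


def test_undefined_metrics_are_explicit():
    report = metrics(TwoByTwo(tp=0, fp=0, fn=0, tn=5))
    assert report.sensitivity.value is None  # no allergic cases
    assert report.ppv.value is None  # nothing referred
    assert report.specificity.value == 1.0
    assert "undefined" in str(report.sensitivity)


def test_rounding_is_half_up():
    assert format_percent(0.25649) == "25.6"
    assert format_percent(0.0005) == "0.1"
    assert format_percent(0.97725) == "97.7"  # 43/44 rounds down
    assert format_percent(43 / 44) == "97.7"


def test_prevalence_adjusted_published_penfast_values():
    ppv, npv = prevalence_adjusted(0.707, 0.785, 58 / 622)
    assert format_percent(ppv) == "25.3"
    assert format_percent(npv) == "96.3"


def test_prevalence_adjusted_trivial_and_domain():
    assert prevalence_adjusted(1.0, 1.0, 0.3) == (1.0, 1.0)
    with pytest.raises(ValueError, match="prevalence"):
        prevalence_adjusted(0.5, 0.5, 1.5)
    ppv, npv = prevalence_adjusted(0.0, 1.0, 0.5)
    assert ppv is None  # degenerate denominator
    assert npv == 0.5


@settings(max_examples=100, deadline=None)
@given(
    tp=st.integers(0, 500),
    fp=st.integers(0, 500),
    fn=st.integers(0, 500),
    tn=st.integers(0, 500),
)
def test_bayes_identity_with_cohort_prevalence(tp, fp, fn, tn):
    """metrics∘contingency agrees with the Bayes formula at the cohort's own
    prevalence to 1e-12 (algebraic identity, checked numerically)."""
    t = TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)
    report = metrics(t)
    se, sp, p = report.sensitivity.value, report.specificity.value, report.prevalence.value
    if None in (se, sp, p):
        return
    ppv, npv = prevalence_adjusted(se, sp, p)
    if report.ppv.value is not None and ppv is not None:
        assert abs(ppv - report.ppv.value) < 1e-12
    if report.npv.value is not None and npv is not None:
        assert abs(npv - report.npv.value) < 1e-12


@settings(max_examples=100, deadline=None)
@given(k=st.integers(0, 50), n=st.integers(1, 50))
def test_wilson_interval_contains_point_estimate(k, n):
    if k > n:
        return
    report = metrics(TwoByTwo(tp=k, fp=0, fn=n - k, tn=0))
    est = report.sensitivity
    assert est.ci_low - 1e-12 <= est.value <= est.ci_high + 1e-12
    assert 0.0 <= est.ci_low and est.ci_high <= 1.0


def test_wilson_coverage_matches_enumeration():
    """Empirical coverage of the 95% sensitivity CI over seeded binomial
    cohorts matches the exact enumerated Wilson coverage within
    Monte-Carlo error, and that exact coverage sits near the nominal level."""
    n, p, reps = 50, 0.7, 2000
    k_grid = np.arange(n + 1)
    lo, hi = proportion_confint(k_grid, n, alpha=0.05, method="wilson")
    exact = binom.pmf(k_grid, n, p)[(lo <= p) & (p <= hi)].sum()
    assert abs(exact - 0.95) < 0.02  # discreteness slack around nominal

    rng = np.random.default_rng(7)
    draws = rng.binomial(n, p, size=reps)
    covered = 0
    for k in draws:
        report = metrics(TwoByTwo(tp=int(k), fp=0, fn=n - int(k), tn=0))
        covered += report.sensitivity.ci_low <= p <= report.sensitivity.ci_high
    empirical = covered / reps
    mc_se = np.sqrt(exact * (1 - exact) / reps)
    assert abs(empirical - exact) < 3 * mc_se


def test_stratified_report_fixture_rows(fixture_cohort, fixture_decisions):
    _, truths = fixture_cohort
    report = stratified_report(fixture_decisions, truths)
    anaphylaxis = report.strata["anaphylaxis"]
    assert (anaphylaxis.de_labelled, anaphylaxis.referred) == (8, 62)
    assert anaphylaxis.substrata["severe"].referred == 17
    assert anaphylaxis.substrata["severe"].de_labelled == 0
    delayed = report.strata["delayed"]
    assert (delayed.substrata["SDRIFE"].de_labelled, delayed.substrata["SDRIFE"].referred) == (2, 10)


def test_strata_partition_marginals(fixture_cohort, fixture_decisions):
    """Stratum counts partition the allergic margin of the 2×2 table."""
    _, truths = fixture_cohort
    report = stratified_report(fixture_decisions, truths)
    referred = de_labelled = 0
    for node in report.strata.values():
        assert node.referred == sum(s.referred for s in node.substrata.values())
        assert node.n == sum(s.n for s in node.substrata.values())
        referred += node.referred
        de_labelled += node.de_labelled
    assert referred == report.table.tp
    assert de_labelled == report.table.fn


def test_empty_stratum_absent_not_zero_divided():
    h = hist().model_copy(update={"case_id": "only"})
    d = apply_algorithm(h)
    report = stratified_report([d], [GroundTruth(case_id="only", allergic=False)])
    assert report.strata == {}
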