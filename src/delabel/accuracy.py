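"""Diagnostic-accuracy statistics for de-labelling decision rules.

The evaluation is a standard 2×2 comparison of a rule's binary output
against the allergist's adjudication.  The positive prediction is the
cautious one — "use an alternative antibiotic" for the five-question
algorithm, "not low risk" for PEN-FAST — so that sensitivity measures
how reliably truly allergic patients are kept away from the drug and
specificity how many non-allergic patients are freed of their label:

    sensitivity = tp / (tp + fn)      specificity = tn / (tn + fp)
    PPV = tp / (tp + fp)              NPV = tn / (tn + fn)
    prevalence = (tp + fn) / n

Interval estimates use the Wilson score method by default (well-behaved
in small strata); any method supported by
``statsmodels.stats.proportion.proportion_confint`` can be requested.
Display rounding is half-up to one decimal on the percent scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Union

from statsmodels.stats.proportion import proportion_confint

from .rule import _pair
from .types import (
    AnaphylaxisSeverity,
    Decision,
    DelayedSubtype,
    GroundTruth,
    Mechanism,
    PenFastResult,
    Recommendation,
)

Prediction = Union[Decision, PenFastResult]


def round_percent(x: float) -> float:
    """Round a proportion to one decimal on the percent scale, half-up."""
    return float(Decimal(repr(x * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_percent(x: Optional[float]) -> str:
    """Render a proportion as a one-decimal percent string (e.g. ``89.8``)."""
    if x is None:
        return "NA"
    return f"{round_percent(x):.1f}"


@dataclass(frozen=True)
class TwoByTwo:
    """Counts of a binary rule against adjudicated allergy status.

    tp: allergic and flagged for an alternative antibiotic;
    tn: non-allergic and de-labelled.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its defining counts and confidence interval.

    ``value`` is None when the defining denominator is zero (the metric
    is undefined, never silently zero).
    """

    numerator: int
    denominator: int
    value: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __str__(self) -> str:
        if self.value is None:
            return f"undefined ({self.numerator}/{self.denominator})"
        s = f"{format_percent(self.value)}% ({self.numerator}/{self.denominator})"
        if self.ci_low is not None:
            s += f" [{format_percent(self.ci_low)}, {format_percent(self.ci_high)}]"
        return s


def _estimate(
    numerator: int, denominator: int, ci_level: float, ci_method: str
) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(numerator, denominator, None)
    value = numerator / denominator
    low, high = proportion_confint(
        numerator, denominator, alpha=1.0 - ci_level, method=ci_method
    )
    # clamp float noise at the boundary of the proportion scale
    return MetricEstimate(
        numerator, denominator, value, max(0.0, float(low)), min(1.0, float(high))
    )


@dataclass(frozen=True)
class StratumReport:
    """Referral outcome within one ground-truth subgroup of allergic cases."""

    name: str
    n: int
    de_labelled: int
    referred: int
    correct_referral: MetricEstimate
    substrata: dict[str, "StratumReport"] = field(default_factory=dict)


@dataclass(frozen=True)
class AccuracyReport:
    """Results container for a 2×2 diagnostic-accuracy evaluation.

    Carries the contingency table, the five headline estimates with
    confidence intervals, and (optionally) nested per-stratum referral
    reports.  ``summary()`` renders a plain-text results table.
    """

    table: TwoByTwo
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    prevalence: MetricEstimate
    ci_level: float
    strata: dict[str, StratumReport] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.table.n

    def headline(self) -> str:
        return (
            f"sensitivity {format_percent(self.sensitivity.value)}%, "
            f"specificity {format_percent(self.specificity.value)}%, "
            f"PPV {format_percent(self.ppv.value)}%, "
            f"NPV {format_percent(self.npv.value)}%"
        )

    def summary(self) -> str:
        t = self.table
        pct = int(round(self.ci_level * 100))
        lines = [
            "Diagnostic accuracy report",
            "==========================",
            f"n = {t.n}   (tp {t.tp}, fp {t.fp}, fn {t.fn}, tn {t.tn})",
            "",
            f"{'metric':<12} {'estimate':<22} {pct}% CI ({'wilson'})",
            "-" * 52,
        ]
        for name in ("sensitivity", "specificity", "ppv", "npv", "prevalence"):
            est: MetricEstimate = getattr(self, name)
            lines.append(f"{name:<12} {str(est)}")
        if self.strata:
            lines += ["", "Strata (correctly referred / n):"]

            def walk(node: StratumReport, depth: int) -> None:
                lines.append(
                    f"{'  ' * depth}{node.name:<36} {node.referred}/{node.n}"
                    f" ({format_percent(node.correct_referral.value)}%)"
                )
                for sub in node.substrata.values():
                    walk(sub, depth + 1)

            for node in self.strata.values():
                walk(node, 1)
        return "\n".join(lines)


def _predicted_positive(p: Prediction) -> bool:
    if isinstance(p, Decision):
        return p.recommendation is Recommendation.ALTERNATIVE_ANTIBIOTIC
    return not p.low_risk


def contingency(
    predictions: Sequence[Prediction], truths: Sequence[GroundTruth]
) -> TwoByTwo:
    """Cross-tabulate rule output against adjudicated allergy status.

    Works identically for de-labelling decisions (positive = alternative
    antibiotic) and PEN-FAST results (positive = not low risk).
    """
    pairs = _pair(predictions, truths)
    tp = fp = fn = tn = 0
    for p, t in pairs:
        positive = _predicted_positive(p)
        if t.allergic:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(
    t: TwoByTwo, ci_level: float = 0.95, ci_method: str = "wilson"
) -> AccuracyReport:
    """Compute the headline accuracy metrics with confidence intervals."""
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    return AccuracyReport(
        table=t,
        sensitivity=_estimate(t.tp, t.tp + t.fn, ci_level, ci_method),
        specificity=_estimate(t.tn, t.tn + t.fp, ci_level, ci_method),
        ppv=_estimate(t.tp, t.tp + t.fp, ci_level, ci_method),
        npv=_estimate(t.tn, t.tn + t.fn, ci_level, ci_method),
        prevalence=_estimate(t.tp + t.fn, t.n, ci_level, ci_method),
        ci_level=ci_level,
    )


def prevalence_adjusted(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[Optional[float], Optional[float]]:
    """Predictive values implied by Bayes' theorem at a given prevalence.

        PPV = se·p / (se·p + (1−sp)·(1−p))
        NPV = sp·(1−p) / (sp·(1−p) + (1−se)·p)

    Lets sensitivity/specificity measured in one population be projected
    onto another prevalence.  Degenerate denominators yield ``None``.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= v <= 1.0 or math.isnan(v):
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    p = prevalence
    ppv_den = sensitivity * p + (1.0 - specificity) * (1.0 - p)
    npv_den = specificity * (1.0 - p) + (1.0 - sensitivity) * p
    ppv = sensitivity * p / ppv_den if ppv_den > 0 else None
    npv = specificity * (1.0 - p) / npv_den if npv_den > 0 else None
    return ppv, npv


_SEVERITY_ORDER = [s.value for s in AnaphylaxisSeverity]
_SUBTYPE_ORDER = [s.value for s in DelayedSubtype]


def _stratum_report(
    name: str,
    pairs: list[tuple[Prediction, GroundTruth]],
    ci_level: float,
    ci_method: str,
    substrata: Optional[dict[str, StratumReport]] = None,
) -> StratumReport:
    referred = sum(_predicted_positive(p) for p, _ in pairs)
    n = len(pairs)
    return StratumReport(
        name=name,
        n=n,
        de_labelled=n - referred,
        referred=referred,
        correct_referral=_estimate(referred, n, ci_level, ci_method),
        substrata=substrata or {},
    )


def stratified_report(
    predictions: Sequence[Prediction],
    truths: Sequence[GroundTruth],
    ci_level: float = 0.95,
    ci_method: str = "wilson",
) -> AccuracyReport:
    """Full accuracy report with nested ground-truth strata.

    Among proven-allergic cases the report nests anaphylaxis (split by
    severity grade) and delayed-type hypersensitivity (split by clinical
    subtype); each stratum carries its correct-referral proportion.
    Empty strata are omitted rather than reported as 0/0.
    """
    pairs = _pair(predictions, truths)
    report = metrics(contingency(predictions, truths), ci_level, ci_method)

    strata: dict[str, StratumReport] = {}
    immediate = [
        (p, t) for p, t in pairs if t.allergic and t.mechanism is Mechanism.IMMEDIATE_ANAPHYLAXIS
    ]
    if immediate:
        severities = {}
        for sev in _SEVERITY_ORDER:
            sub = [(p, t) for p, t in immediate if t.anaphylaxis_severity.value == sev]
            if sub:
                severities[sev] = _stratum_report(sev, sub, ci_level, ci_method)
        strata["anaphylaxis"] = _stratum_report(
            "anaphylaxis", immediate, ci_level, ci_method, severities
        )
    delayed = [(p, t) for p, t in pairs if t.allergic and t.mechanism is Mechanism.DELAYED]
    if delayed:
        subtypes = {}
        for sub_name in _SUBTYPE_ORDER:
            sub = [(p, t) for p, t in delayed if t.delayed_subtype.value == sub_name]
            if sub:
                subtypes[sub_name] = _stratum_report(sub_name, sub, ci_level, ci_method)
        strata["delayed"] = _stratum_report("delayed", delayed, ci_level, ci_method, subtypes)

    return AccuracyReport(
        table=report.table,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        ppv=report.ppv,
        npv=report.npv,
        prevalence=report.prevalence,
        ci_level=ci_level,
        strata=strata,
    )
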