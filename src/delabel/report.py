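"""Publication-style rendering and the self-contained reproduction harness.

``reproduce()`` runs the complete pipeline on the deterministic fixture
cohort — generate, classify with the five-question algorithm, score
PEN-FAST, evaluate — and diffs every reproduced figure against the
published value: the 2×2 outcome table with its four headline metrics,
the per-stratum referral rows, the per-question routing counts, and the
Bayes-consistency check of the published PEN-FAST predictive values at
their own cohort prevalence (58/622).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .accuracy import (
    AccuracyReport,
    format_percent,
    prevalence_adjusted,
    round_percent,
    stratified_report,
)
from .penfast import pen_fast_cohort
from .rule import classify_cohort, route_counts
from .simulate import generate_fixture
from .types import GroundTruth, Question, Recommendation

# Published reference values the harness checks itself against.
EXPECTED_TWO_BY_TWO = {"tp": 184, "fp": 265, "fn": 21, "tn": 330}
EXPECTED_HEADLINE = {"sensitivity": 89.8, "specificity": 55.5, "ppv": 41.0, "npv": 94.0}
EXPECTED_STRATA = {  # (de-labelled, referred)
    "anaphylaxis": (8, 62),
    "anaphylaxis/mild": (7, 19),
    "anaphylaxis/moderate": (1, 26),
    "anaphylaxis/severe": (0, 17),
    "delayed": (13, 122),
    "delayed/maculopapular_exanthema": (11, 106),
    "delayed/SDRIFE": (2, 10),
    "delayed/FDE": (0, 3),
    "delayed/DRESS": (0, 3),
}
EXPECTED_ROUTING = {  # (question, recommendation, allergic) -> count
    ("Q1", "de_label", False): 68,
    ("Q2", "de_label", False): 66,
    ("Q3", "de_label", False): 95,
    ("Q4", "alternative_antibiotic", False): 195,
    ("Q5", "alternative_antibiotic", False): 70,
    ("Q5", "de_label", False): 101,
    ("Q1", "de_label", True): 3,
    ("Q2", "de_label", True): 2,
    ("Q3", "de_label", True): 6,
    ("Q4", "alternative_antibiotic", True): 106,
    ("Q5", "alternative_antibiotic", True): 78,
    ("Q5", "de_label", True): 10,
}
PENFAST_PUBLISHED = {"sensitivity": 0.707, "specificity": 0.785, "allergic": 58, "n": 622}
EXPECTED_PENFAST = {"ppv": 25.3, "npv": 96.3}
EXPECTED_MODSEV = {"referred": 43, "n": 44, "percent": 97.7}


def render_table2(report: AccuracyReport) -> str:
    """Render the outcome-vs-adjudication comparison table.

    Rows follow the publication layout: the non-allergic row, the
    proven-allergic row, then the anaphylaxis block (by severity) and
    the delayed-type block (by subtype), each as
    ``de-labelled  referred  sum``.
    """
    t = report.table
    lines = [
        "Allergy testing vs outcome of the de-labelling algorithm",
        f"{'':40s} {'De-label':>12} {'Alternative':>12} {'Sum':>10}",
    ]

    def pct_row(name: str, de: int, alt: int, indent: int = 0) -> str:
        n = de + alt
        if n == 0:
            return f"{'  ' * indent}{name:<40s} {'—':>12} {'—':>12} {0:>10}"
        return (
            f"{'  ' * indent}{name:<40s}"
            f" {f'{de} ({format_percent(de / n)}%)':>12}"
            f" {f'{alt} ({format_percent(alt / n)}%)':>12}"
            f" {f'{n} (100%)':>10}"
        )

    def count_row(name: str, de: int, alt: int, indent: int) -> str:
        return f"{'  ' * indent}{name:<40s} {de:>12} {alt:>12} {de + alt:>10}"

    lines.append(pct_row("Hypersensitivity excluded", t.tn, t.fp))
    lines.append(pct_row("Allergic hypersensitivity proven (any type)", t.fn, t.tp))
    for block, label in (("anaphylaxis", "Immediate-type (anaphylaxis)"), ("delayed", "Delayed-type")):
        node = report.strata.get(block)
        if node is None:
            lines.append(f"  {label:<40s} [absent]")
            continue
        lines.append(pct_row(label, node.de_labelled, node.referred, 1))
        for sub in node.substrata.values():
            lines.append(count_row(sub.name, sub.de_labelled, sub.referred, 2))
    return "\n".join(lines)


def render_routing(counts: pd.DataFrame) -> str:
    """Render nonzero per-question routing counts, split by allergy status."""
    lines = ["Per-question routing (deciding question, recommendation):"]
    for allergic, label in ((False, "non-allergic"), (True, "allergic")):
        lines.append(f"  {label}:")
        for (q, rec, a), row in counts.iterrows():
            if a == allergic and row["count"] > 0:
                lines.append(f"    {q} -> {rec:<24s} {int(row['count']):>4}")
    return "\n".join(lines)


@dataclass
class ReproductionResult:
    """Outcome of the fixture reproduction run."""

    text: str
    mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def reproduce() -> ReproductionResult:
    """Run the full pipeline on the fixture and diff against the record.

    Hermetic: no inputs, no randomness beyond the fixture's fixed
    internal interleaving, deterministic output.
    """
    mismatches: list[str] = []

    def check(name: str, actual, expected) -> None:
        if actual != expected:
            mismatches.append(f"{name}: expected {expected!r}, got {actual!r}")

    histories, truths = generate_fixture()
    decisions = classify_cohort(histories)
    pen_fast_cohort(histories)  # exercised for completeness; not compared
    report = stratified_report(decisions, truths)
    counts = route_counts(decisions, truths)

    t = report.table
    for name, expected in EXPECTED_TWO_BY_TWO.items():
        check(f"2x2 {name}", getattr(t, name), expected)
    for name, expected in EXPECTED_HEADLINE.items():
        check(name, round_percent(getattr(report, name).value), expected)

    flat = {}
    for key, node in report.strata.items():
        flat[key] = (node.de_labelled, node.referred)
        for sub in node.substrata.values():
            flat[f"{key}/{sub.name}"] = (sub.de_labelled, sub.referred)
    for key, expected in EXPECTED_STRATA.items():
        check(f"stratum {key}", flat.get(key), expected)

    for key, expected in EXPECTED_ROUTING.items():
        check(f"routing {key}", int(counts.loc[key, "count"]), expected)

    anaphylaxis = report.strata.get("anaphylaxis")
    modsev_ref = modsev_n = 0
    if anaphylaxis is not None:
        for sev in ("moderate", "severe"):
            sub = anaphylaxis.substrata.get(sev)
            if sub is not None:
                modsev_ref += sub.referred
                modsev_n += sub.n
    check("moderate+severe referred", modsev_ref, EXPECTED_MODSEV["referred"])
    check("moderate+severe n", modsev_n, EXPECTED_MODSEV["n"])
    check(
        "moderate+severe percent",
        round_percent(modsev_ref / modsev_n) if modsev_n else None,
        EXPECTED_MODSEV["percent"],
    )

    pf_prev = PENFAST_PUBLISHED["allergic"] / PENFAST_PUBLISHED["n"]
    ppv, npv = prevalence_adjusted(
        PENFAST_PUBLISHED["sensitivity"], PENFAST_PUBLISHED["specificity"], pf_prev
    )
    check("PEN-FAST adjusted ppv", round_percent(ppv), EXPECTED_PENFAST["ppv"])
    check("PEN-FAST adjusted npv", round_percent(npv), EXPECTED_PENFAST["npv"])

    sections = [
        render_table2(report),
        "",
        render_routing(counts),
        "",
        f"Headline: {report.headline()}",
        f"Moderate-to-severe anaphylaxis referred: {modsev_ref}/{modsev_n}"
        f" ({format_percent(modsev_ref / modsev_n)}%)",
        "",
        "PEN-FAST Bayes consistency at prevalence "
        f"{PENFAST_PUBLISHED['allergic']}/{PENFAST_PUBLISHED['n']}: "
        f"PPV {format_percent(ppv)}%, NPV {format_percent(npv)}%",
        "",
        "Reproduction: OK" if not mismatches else "Reproduction: FAILED",
        *(f"  MISMATCH {m}" for m in mismatches),
    ]
    return ReproductionResult(text="\n".join(sections), mismatches=mismatches)


def report_to_dict(report: AccuracyReport) -> dict:
    """JSON-serialisable form of an accuracy report."""

    def est(e) -> dict:
        return {
            "numerator": e.numerator,
            "denominator": e.denominator,
            "value": e.value,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
        }

    def stratum(node) -> dict:
        return {
            "n": node.n,
            "de_labelled": node.de_labelled,
            "referred": node.referred,
            "correct_referral": est(node.correct_referral),
            "substrata": {k: stratum(v) for k, v in node.substrata.items()},
        }

    t = report.table
    return {
        "n": report.n,
        "ci_level": report.ci_level,
        "table": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
        "metrics": {
            name: est(getattr(report, name))
            for name in ("sensitivity", "specificity", "ppv", "npv", "prevalence")
        },
        "strata": {k: stratum(v) for k, v in report.strata.items()},
    }
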