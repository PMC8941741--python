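# Methods

## The classifiers

### Five-question de-labelling algorithm

The algorithm is a fixed-order decision list over a structured history.
Each question maps deterministically onto record fields:

| Q | yes-condition | yes → |
|---|---------------|-------|
| Q1 | `symptoms_incompatible_with_allergy = yes`, or onset latency coded `days_urticaria_gt2` / `weeks_exanthema_gt1` | de-label |
| Q2 | `rash_in_childhood_no_systemic = yes` and age at reaction (when known) < adult threshold | de-label |
| Q3 | `prolonged_urticaria_no_systemic = yes` | de-label |
| Q4 | `measles_like_exanthema_adult = yes` | alternative antibiotic |
| Q5 | `severe_indicators` non-empty | alternative antibiotic |

A question answers *uncertain* when its driving fields are themselves
uncertain/unknown and no definitive yes-condition holds; uncertain routes
exactly like no, so Q5 is reached whenever none of Q1–Q4 is affirmed. At
Q5 an empty indicator set — including the case where nothing was
documented — resolves to de-labelling. This is the algorithm's
residual-risk locus and is deliberate: the binary output leaves no third
option, and treating undocumented severity as severe would collapse the
screen's specificity. Callers can audit it through the answer trace
attached to every decision.

Design points that the published description leaves open, fixed here:

* **Adult threshold.** Adulthood for Q2 is age ≥ 18 years at the
  reaction, the conventional bound; it is a keyword argument
  (`adult_threshold`) on `evaluate_question` / `apply_algorithm` /
  `classify_cohort`. Q4 needs no separate age check because its input
  field (`measles_like_exanthema_adult`) already asserts adult onset.
* **Q1 tie-break.** Either yes-condition (incompatible symptoms, late
  latency) suffices; no precedence is needed.
* **Onset within minutes** appears twice on purpose: as a latency code
  (irrelevant to Q1, whose late codes are the only latency triggers) and
  as a Q5 severe indicator (a few minutes between intake and reaction is
  itself anaphylaxis-suspicious).

### PEN-FAST

Items F/A/S (2 points each) and T (1 point), total 0–7, low risk ⇔
total < 3. An unknown item scores 0 — a bedside screen cannot award risk
points for an undocumented feature — and the zero is recorded per item so
the imputation is auditable. Note that this scoring treats
anaphylaxis/angioedema and severe cutaneous reaction as independent
2-point items (maximum 7); other published formulations combine them into
one item (maximum 5). The discrepancy is documented, not resolved: this
package follows the description it evaluates against.

## Accuracy statistics

The positive prediction is the cautious one ("alternative antibiotic",
or "not low risk" for PEN-FAST), so sensitivity measures protection of
truly allergic patients and NPV is the safety figure for a de-label
recommendation. Point estimates are the defining count ratios; a metric
whose denominator is zero is reported as explicitly undefined, never as
zero. Confidence intervals are Wilson score at 95% by default — chosen
for its behaviour in small strata (several strata here have n ≤ 3) — with
the method configurable to anything
`statsmodels.stats.proportion.proportion_confint` supports. Interval
bounds are clamped to [0, 1] to absorb float noise at the boundary.

Prevalence-adjusted predictive values follow Bayes' theorem,

    PPV = se·p / (se·p + (1−sp)(1−p))
    NPV = sp·(1−p) / (sp·(1−p) + (1−se)p),

and agree with the count-based PPV/NPV to numerical identity when `p` is
the cohort's own prevalence (property-tested at 1e-12). Degenerate
denominators yield undefined, and arguments outside [0, 1] are a domain
error.

Display rounding is half-up to one decimal on the percent scale,
implemented in decimal arithmetic on the value's shortest float
representation; all percentages in tables and summaries use it. No
multiple-testing machinery is provided: the evaluation is descriptive.

## Synthetic cohorts

### What the fixture emulates

`generate_fixture()` builds an 800-record cohort whose joint distribution
of (ground-truth stratum × deciding question × recommendation) equals the
published routing of a retrospective evaluation: 595 non-allergic cases
(de-labelled 68/66/95 at Q1–Q3 and 101 at Q5; referred 195 at Q4 and 70
at Q5) and 205 allergic cases (de-labelled 3/2/6 at Q1–Q3 and 10 at Q5;
referred 106 at Q4 and 78 at Q5), with anaphylaxis severities 26/27/17
and delayed subtypes 117/12/3/3. Record attributes are *constructed per
cell* so that the rule engine provably routes each record to its intended
cell; generation re-runs the classifier on every record and raises
`GenerationError` naming the cell on any mismatch. The fixture is fully
deterministic (byte-identical across calls) and takes no parameters: it
is the study condition, not a dial.

Two joints are not published and are fixed here as modelling choices:

* **Stratum × question for the 21 allergic de-labellings.** Only the two
  margins are published (3/2/6/10 by question; 7 mild / 1 moderate /
  11 MPE / 2 SDRIFE by stratum). The fixture uses mild = 1×Q1 + 6×Q3,
  moderate = 1×Q5, MPE = 2×Q1 + 2×Q2 + 7×Q5, SDRIFE = 2×Q5 — clinically
  plausible (prolonged urticaria precedes mild anaphylaxis histories,
  childhood rash precedes exanthema histories) and margin-consistent.
  Every reported figure depends only on the margins, so any consistent
  joint reproduces them.
* **Severe-indicator flags for Q5 referrals.** FDE → cutaneous blisters
  and DRESS → hepatitis follow the published account. Anaphylaxis strata
  get onset-within-minutes plus cardiovascular/respiratory signs scaled
  with severity (every third severe case also an anesthesia incident);
  SDRIFE → mucosal erosions; the 70 non-allergic Q5 referrals cycle
  deterministically through all nine flags ("complaints incorrectly
  interpreted as severe"). All of these are synthetic scaffolding.

Descriptive attributes (reported reaction type 334/421/45, culprit class,
route, recall interval) match the published marginals exactly but are
assigned *independently of the routing cell* by a seeded interleaving
(fixed internal seed; the fixture API stays parameter-free), because only
marginals are published. Consequence: in the fixture, reported type does
not correlate with mechanism — fine for evaluating the algorithm, which
never reads these fields, but the fixture should not be used to study
reported-type × outcome associations. Age at reaction is likewise
non-inferential scaffolding: children (5–17) for Q2-routed records,
adults (25–74) elsewhere.

PEN-FAST item fields are derived from the latent stratum: A true for
anaphylaxis strata, S true for DRESS, T true for moderate/severe
anaphylaxis and DRESS, F from a recall interval of five years or less.
The source evaluation never applied PEN-FAST to its own cohort, so these
fields support exercising the scorer, not validating it.

### Stochastic mode

`generate_stochastic(spec)` draws each record's cell from the spec's
(possibly unnormalised) cell weights and its descriptive attributes from
reaction-type-conditional marginals; `default_spec()` uses the fixture
counts normalised by 800. Randomness follows a strict contract: one root
seed spawns one child stream per record (`numpy` `SeedSequence.spawn`),
and every draw for a record comes from its own stream — so adding a new
attribute never perturbs other records' draws, and a fixed seed
reproduces the cohort exactly. Expected cell frequencies equal the spec
weights; the law-of-large-numbers check in the test suite verifies the
non-allergic fraction at n = 80,000 within three binomial standard
errors (the size chosen to keep that check to a few tens of seconds on
one CPU while making the three-standard-error band ±0.5%).

### What passing tests do and do not show

The fixture reproduces every published count by construction, so the
end-to-end tests validate the *implementation* of the rules, the routing
and the statistics — not the clinical performance of the algorithm on new
patients. Real histories are free-text, incomplete and inconsistently
recalled; the generator emulates none of that (structured fields only, no
recall error, no missingness process beyond the explicit uncertain
codes). External validity rests on the original study design, not on
this package.

## File format and degenerate inputs

Cohorts interchange as UTF-8 CSV (header mandatory, columns exactly the
field names, semicolon-joined indicator flags) or JSON arrays with the
same keys. Blank cells resolve conservatively: tri-state questions →
uncertain (absence of information must never silently de-label), factual
enums → their unknown/unclear code, age and PEN-FAST items → unknown.
Duplicate case ids, unknown enum values (with row number) and missing
mandatory columns are hard errors; round-trips are the identity on valid
cohorts (property-tested for both formats). Empty cohorts, empty strata
(omitted, never 0/0) and all-one-class 2×2 tables (undefined metrics) are
handled explicitly.

## Known limitations

* The algorithm consumes structured attributes; mapping free-text or EHR
  narratives onto them is out of scope.
* The fixture's attribute-independence assumption (above) limits it to
  evaluating the classifiers themselves.
* Reported confidence intervals are the package's addition; the source
  evaluation published point estimates only.
* The pooled PEN-FAST consistency check projects published sensitivity/
  specificity through Bayes' theorem; it does not re-derive the PEN-FAST
  development model.
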