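# Methods

## Model and assumptions

`comcatva` treats per-death classification as naive-Bayes inference over a
discrete category set. A probbase supplies a prior π over categories and
conditionals P(response | category) for substantive (indicator, yes/no)
pairs; for one record the unnormalized mass of category c is

    mass(c) = π(c) · Π over substantive responses r of P(r | c),

the product running over responses for which the probbase has a matching
row. Normalization happens once, at the end. The structural assumptions
are those of the InterVA family:

* responses are conditionally independent given the category;
* missing, "don't know" and "refused" answers carry no information
  (they contribute no factor — the ternary YES/NO/MISSING response model);
* a NO response is informative only when the probbase supplies a `no` row
  for that indicator, so whether negative evidence updates the posterior is
  a property of the supplied matrix, not of the engine;
* the engine has no notion of the year of death: any variation over time in
  the outputs is driven entirely by the interview data.

Two decision rules sit on the posterior. For the six circumstantial
categories (COMCATs), the argmax is assigned only when its likelihood
strictly exceeds the dominance threshold (default 0.5) — a likelihood of
exactly 0.5 does not dominate — and degenerate posteriors (all categories
annihilated by zero factors) fall to the derived "multiple" category rather
than erroring, so a field dataset always processes end to end. Two
categories cannot both exceed 0.5, so argmax ties above threshold are
impossible; ties below it are irrelevant. For causes, categories are
reported in descending likelihood (ties broken by category order) while the
likelihood is at least `report_threshold` (default 0.1) and at most
`max_causes` (default 3) are taken; the remaining mass is the
"indeterminate" residual. Neither "multiple" nor "indeterminate" is ever a
probbase column — both are decision-rule outcomes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `comcat_threshold` | 0.5 | dominance threshold (strict) for a single COMCAT |
| `max_causes` | 3 | maximum causes reported per death |
| `report_threshold` | 0.1 | minimum likelihood for a cause to be reported |
| age bands | <5, 5–19, 20–49, 50–69, 70+ | configurable demographic bands |
| rate scale `per` | 1000 | rates are deaths per `per` person-years |

The 0.5 threshold is the defining dominance rule; `max_causes` and
`report_threshold` are reporting conventions in the InterVA style, exposed
as settings because no single convention is canonical.

## Numerical choices

Products are formed in ordinary floating point; the engine switches to
log-space accumulation (with −∞ for exact zeros and a max-subtraction
before exponentiation) whenever any factor is below 1e-12, and also
whenever the plain product underflows to zero without any exactly-zero
factor — several hundred moderate factors can underflow double precision.
The switch changes results only at the level of float rounding; the test
suite checks the engine against an exact rational-arithmetic oracle to
1e-9. Because normalization is deferred to the end, the posterior is
exactly invariant to response order and to rescaling any conditional row by
a positive constant. Non-degenerate posteriors sum to 1 within 1e-9.

Probbase loading normalizes the prior row (recording the pre-normalization
sum, so priors may be authored as weights or counts) and enforces
rectangularity and the [0,1] range on conditional cells. Cells may be
authored as grade symbols resolved through a user-supplied numeric table;
the package deliberately ships **no** default symbol mapping, because the
expert matrices those symbols come from are not public and inventing
numbers for them would misrepresent the consensus values.

## Population summaries

Category fractions are simple complete-partition proportions (including the
derived categories, so they sum to 1). Stratum rates are `per` × deaths /
person-years; deaths in a stratum with no exposure are a hard error.
Standardization is *direct*: Σ weight(age, sex) × rate, with the
"internal" standard defined as the whole dataset's own person-year
distribution over age×sex (a deaths-based internal standard is provided as
an alternative, `weights_from_counts`). The "internally standardised"
phrasing common in HDSS demonstrations does not pin down the weight source;
person-years is this package's documented default interpretation. Within
each age×sex cell, year-specific rates are pooled by unweighted mean before
weighting. The standardized rate is a convex combination and therefore lies
within [min, max] of the contributing stratum rates. COMCAT-by-cause
rankings break count ties by the canonical category order (traditions,
emergencies, recognition, resources, health_systems, inevitability,
multiple), so output is stable. Broad-cause grouping is a user-editable
lookup table; a starter table for common WHO-2016 cause labels ships with
the package, and unmapped labels become "ungrouped" with a warning.

## Synthetic data generator

`synthgen` emulates exactly the statistical structure the engine assumes: a
true category per death drawn from a mixture; each indicator answered YES
with probability P(yes | true category) from a generated probbase, NO
otherwise; missingness applied independently; demographics drawn from an
age×sex×year mixture. The generated probbase gives each category a
round-robin signature subset of indicators whose YES odds are multiplied by
`sharpness` over a baseline YES probability drawn uniformly on [0.1, 0.4];
`sharpness = 1` yields identical category columns (no signal), large values
approach separability. Defaults — 6 categories with a uniform mixture, 500
records, sharpness 20, 10% missingness, uniform demographics over the five
default age bands × two sexes — define a scenario sized so that the whole
suite and the acceptance script run in seconds while recovery accuracy and
its non-discriminative control are well separated.

Because the generator matches the engine's conditional-independence
assumption, recovery experiments measure the engine's correctness, not
robustness to misspecification; a `response_correlation` toggle (copying a
response from the previous indicator with the given probability) is
provided to break that assumption deliberately. What passing recovery tests
do **not** show: performance on real VA data, where indicators are
correlated, probbases are imperfect, and the true category is itself a
construct. The demonstration-scale findings reported for real HDSS
populations are not reproducible from this package because both the field
dataset and the expert consensus matrices are external to it.

All randomness flows through explicitly seeded NumPy generators (one
derived stream per operation, no global state); identical scenarios produce
byte-identical CSV bundles, and `process`/`summarize` are fully
deterministic.

## Design choices where the design was open

* **Ternary responses.** "Don't know"/"refused" collapse to MISSING. If the
  production implementation treats them differently, outputs will diverge
  on records rich in such answers; this is a documented divergence risk.
* **Uniform COMCAT prior in the shipped synthetic matrix.** Whether the
  production sub-model uses distinct priors is unstated; uniform is the
  assumption here, and any user probbase can override it.
* **Probbase decides the indicator scope.** The engine does not restrict
  which indicators feed the circumstantial model; the shipped synthetic
  matrix covers the ten circumstantial items only, but a probbase spanning
  the full instrument works unchanged.
* **Wide-format CSV ingest** (one column per indicator id), with unknown
  columns ignored rather than rejected so instrument supersets load
  cleanly; a long-format reader is out of scope.
* **CLI surface** limited to `simulate` / `process` / `summarize` /
  `validate` with YAML config defaults; all randomness is confined to
  `simulate`.

## Known limitations

No physician-review workflow, no hierarchical (InSilicoVA-style)
estimation, no uncertainty intervals on fractions, no life-table or
years-of-life-lost computation, and no attempt to bit-match legacy
executables. Cause-probbase values are not shipped at all — the cause side
of the engine is exercised with synthetic matrices only.
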