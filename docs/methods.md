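# Methods

## The case/non-case model

The package implements the standard disproportionality ("case/non-case")
design for spontaneous-report databases.  Every report is classified on
two axes: *case* (the reaction list contains the event preferred term,
matched literally and case-insensitively — no dictionary hierarchy is
consulted) and *exposed* (at least one exposure-class drug among the
**suspect** drugs; concomitant mentions do not create exposure, matching
a single-suspect design).  The 2×2 cells a/b/c/d follow the usual
convention (a = exposed cases … d = unexposed non-cases).  The ROR is a
reporting ratio, not a risk ratio: there is no denominator population,
and all inference is about reporting disproportion.

Margin-level input reconstructs cells from published aggregates as
b = drug_total − a, c = event_total − a, d = grand − a − b − c.  The
per-drug count column is interpreted as the **total** number of reports
mentioning the drug (a + b), because only that reading reproduces every
published per-drug ROR and reconciles the class-level b with the printed
class-row total; a `drug_total_includes_cases=False` flag accepts raw-b
input instead.  Note that per-drug c deliberately includes event reports
of *other* exposure-class drugs — each drug is compared against the whole
rest of the database, again matching the published numbers.

## Cohort construction

* **Deduplication** is id-based: one report per registration id, keeping
  the earliest complete receipt date (ties: file order).  No
  probabilistic record linkage.
* **Window filtering** uses the receipt date at month precision
  (year-only dates are compared by year).  The source study does not say
  whether its window used receipt or onset dates; receipt was chosen as
  the date that defines membership in a reporting-period population.
* **Multi-exposure exclusion** removes reports with ≥ 2 distinct
  exposure-class suspect drugs; the **combined-exposure exclusion**
  removes reports with one exposure drug plus any other drug of the wider
  antihyperglycemic class in *any* role (the stricter reading, since
  co-prescription is what the criterion targets).
* **Prior-event-history exclusion** compares the history entry's
  diagnosis year with the earliest event onset year (year granularity —
  histories carry only years); entries without a year are kept.

Each removal is logged once per tripped reason in a JSON-serializable
exclusion log, the accounting a published table never shows.

## Wald inference

CI on the log scale with z defaulting to the exact 97.5 % normal quantile
(1.959964).  On the study's tables the choice between 1.959964 and 1.96
is invisible at one printed decimal for every point estimate and for the
class-level CI; on the smallest-count row one CI digit straddles the
rounding boundary between the two quantiles, which the tests document
rather than hide.  Zero-cell policy `report_zero` (default): a = 0 rows
print as ROR 0 with no CI; any other zero cell flags the ratio as
undefined/infinite.  `haldane_half` adds 0.5 to every cell instead.
Display rounding is half-away-from-zero at 1 decimal; full precision is
kept internally.

## Exact conditional inference

Conditional on both margins, cell a follows Fisher's noncentral
hypergeometric distribution with odds parameter ψ.  The central log-pmf
over the support is computed once via log-gamma; tilted pmfs, conditional
means and tail sums are evaluated in log space (`logsumexp`-style
normalization), so supports of a few thousand points on tables with
margins in the millions cost milliseconds.

* **p-value**: two-sided probability-mass method — the sum of
  probabilities of all support points whose central pmf ≤ the observed
  pmf × (1 + 10⁻⁷).  The relative tie tolerance matches mainstream exact
  test implementations and absorbs floating-point ties.
* **Conditional MLE**: the ψ solving E[X | ψ] = a (the score equation of
  the conditional likelihood).
* **Exact CI**: lower bound solves P(X ≥ a | ψ) = α/2, upper solves
  P(X ≤ a | ψ) = α/2; both tails are strictly monotone in ψ (tested), so
  the roots are unique; bounds are 0 / ∞ when a sits on a support edge.

Two solver modes exist because reference software leaves a visible
numerical fingerprint.  R's `stats::fisher.test` brackets each root on
the direct odds scale below 1 and on the *reciprocal* scale above 1, and
stops Brent's method at `uniroot`'s default tolerance (machine ε^0.25
absolute on the solving scale).  For strong signals on very large tables
that tolerance reaches the first decimal of the estimate: on the
class-level table the exact conditional-MLE root is 153.504, while the
reference pipeline prints 154.2136.  The default `cmle_solver="reference"`
mirrors the reference scheme (bracket, scale and tolerance, verified
digit-for-digit against R at printed precision on every study row) so
that published software output is reproduced; `cmle_solver="precise"`
solves the same equations to ~1e-12 and is cross-checked against scipy's
conditional odds-ratio machinery in the tests.  A side effect of the
reference tolerance: the exact-CI upper bound of an a = 0 row with a tiny
drug margin is tolerance-limited (visibly coarse); report tables print
such rows as 0 without an interval, and the precise solver tightens them.

## Sensitivity analysis

Reports mentioning any drug from a configurable exclusion list
(literature drugs associated with the event; default list of 17) are
removed in any role by default (`suspect_only` available — the source
study's wording, "associated with the prescription of", motivates
any-role).  "Psoralens" is matched as a substance prefix; a synonym hook
maps brand names.  The filtered cohort then goes through the identical
analysis.  Because the post-exclusion database totals were never
published, the tests assert structural properties (cells never increase;
a disjoint list is the identity) and the direction experiment described
below, not the published sensitivity numbers.

## Descriptive profile

Percentages always use the full group size as denominator, including
unspecified rows, rounded half-away-from-zero to 1 decimal.  Age bands:
[0, 65), [65, 85] (both ends inclusive, matching the published labels),
(85, ∞), plus unspecified.  Tracked history conditions are matched by
case-insensitive literal term with a small synonym table.  EU membership
comes from a bundled 27-state table (2024 composition).

Intervals (latency = earliest exposure-drug start → earliest event
onset; onset → drug end; drug end → event resolution) are computed only
when both endpoints reach month precision; a missing day is imputed as
the 15th (bounded error ≤ 15 days); a missing month excludes the date.
Months = days / 30.4375.  Negative intervals are excluded and counted in
a quality flag.  Withdrawal-timing bands are disjoint: 0 days, (0, 30]
days (boundary inclusive), > 365 days, remainder, plus unevaluable.

## The synthetic generator

The generator emulates what the analysis assumes about the real data:

* exposure frequencies per drug (defaults: drug_total/grand_total of the
  published margins; controls at plausible common-drug rates of 0.5 %
  and 1 %);
* a baseline event probability of 5215/11,451,738 among background
  reports;
* per-drug target RORs (defaults: the published values).  Events are
  assigned by **odds multiplication** — a report's event odds are the
  baseline odds times its drug's target ROR (times a confounder
  multiplier when contaminated) — so the generating parameter *is* the
  estimand and log-ROR recovery is unbiased in expectation (tested at
  3-standard-error tolerance);
* demographics: age ~ Normal(77, 10.6) truncated to [18, 105]; a 63.2 %
  male share before masking; missingness 31 % (age), 7.3 % (gender), 5 %
  (country); a reporter mix of 64 % physicians and 21 % other health
  professionals; a country mix dominated by non-EU reporting;
* timing: lognormal latency with median 11 months and mean 19 months
  (two lognormal parameters cannot also match the reported SD of 22.1
  months; the implied SD is ≈ 27 months, a documented compromise in
  favor of the two central-tendency targets); exponential
  onset-to-withdrawal (median 36 days) with an 11.8 % same-day point
  mass, and exponential withdrawal-to-resolution (median 33 days);
* contaminants with configurable probabilities: duplicates (0.5 %),
  second suspect exposure drugs (1 %), antihyperglycemic co-medication
  (5 %), prior event history (0.2 %), and confounder co-medication
  (5 % at odds multiplier 10) — so deduplication, the exclusions and the
  sensitivity filter all have work to do and can be checked against the
  generator's bookkeeping columns.

It does **not** emulate: dictionary-coded reaction vocabularies, country-
specific reporting dynamics or drug availability, correlations between
demographics and exposure, report-quality drift over time, or free-text
noise in substance names.  Passing tests therefore demonstrate that the
pipeline and estimators are correct under the stated statistical
structure — not that the package would resolve coding or linkage problems
in raw regulatory extracts.

## Study conditions used by the statistical tests

The reproduction tests run the published-margin computations exactly and
the stochastic experiments at these sizes, chosen as the package's own
test conditions: parameter recovery at n = 200,000 reports × 50 seeds
(exposure 1 %, baseline 10⁻³, target ROR 150; the CI must cover the
target in ≥ 90 % of seeds); sensitivity direction at n = 30,000 × 20
seeds (20 % confounder contamination at odds multiplier 10; the
class-level ROR must increase after filtering in ≥ 90 % of seeds); null
calibration at n = 8,000 × 200 seeds (target ROR 1; CI coverage of 1
within 95 % ± 3 %); and the Fisher p-value against a rational-arithmetic
enumeration oracle on 1,000 random tables with N ≤ 60.

## Known limitations

* Literal preferred-term matching only; no MedDRA hierarchy, so
  lower-level-term variants of the event would be missed in real data.
* Id-based deduplication cannot catch re-registered duplicates.
* The ROR quantifies reporting disproportion; no causal or incidence
  interpretation is licensed, and no shrinkage metrics (PRR, IC, EBGM)
  or mid-p variants are implemented.
* Exact-CI bounds of zero-count rows under the reference solver are
  tolerance-limited (see above).
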