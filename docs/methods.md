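# Methods

## Scope and data model

The package analyzes spontaneous adverse-event reports of the kind
collected by large post-marketing surveillance systems: one record per
submitted report version, carrying patient demographics, one or more
drug entries (free-text product name, role code, start date), one or
more reaction preferred terms (PTs), outcome codes, and a receipt date.
The normalized `SafetyReport` model is dialect-agnostic: the same
record is produced from '$'-delimited quarterly tables or from the
package's single-table CSV interchange, and nothing downstream depends
on which dialect was read.  Field semantics (safetyreportid,
receiptdate, reporter country, reaction MedDRA PT, medicinal product)
follow the public spontaneous-reporting vocabulary; no legacy pre-2012
schema and no XML E2B parsing is supported.

Dates may be partial (year, year–month, or full).  A partial date is
stored as the *earliest* calendar date consistent with the token plus a
precision tag.  This gives a total order for version comparison while
letting each stage decide admissibility: version retention accepts any
precision, time-to-onset requires day precision on both dates.

Ages are converted to years from the reported unit (decades ×10,
months /12, weeks /52.1775, days /365.25, hours /8766); values outside
[0, 120] years after conversion are treated as data errors, logged, and
set missing.  Unknown units are logged and set missing rather than
guessed.

## Two-step cleaning

Spontaneous databases contain versioned resubmissions (follow-ups under
one report id) and duplicates (one case submitted by several sources
under different ids).  Cleaning is exact-key and two-step:

1. **Last version per id.**  The survivor maximizes receipt date;
   partial dates compare by their earliest consistent date; a residual
   tie keeps the lexicographically largest id, matching the practice of
   version ids growing with resubmission.
2. **Six-field duplicates.**  Among reports agreeing on (sex, age,
   reporter country, receipt date, sorted reaction PT multiset, sorted
   verbatim drug-name multiset), exactly one survives — the smallest
   report id, a deterministic tie-break.  Missing values compare equal
   to each other: missingness is treated as a value of the key field,
   which makes the rule total and testable.

The key deliberately uses *verbatim* drug names because cleaning
precedes dictionary normalization in the pipeline; normalizing first
would merge reports that the submitters wrote differently.  No
probabilistic record linkage is attempted.  Both steps are idempotent
and the removal counts are logged per step.

## Vocabulary normalization

Drug products arrive as free text.  The archive maps canonicalized
synonyms (case-folded, punctuation-stripped, whitespace-collapsed) to
ingredients and pharmacological classes; the bundled archive covers 20
VEGF(R)-pathway agents across anti-VEGF mAb, anti-VEGFR mAb, VEGF-trap,
TKI and other-antiangiogenic classes with common brand names and
research codes, and is curated by the package authors — it is not an
official product dictionary.  Combination products are split on '/'
and '+' and each component is mapped independently.  Fuzzy matching is
off by default; when enabled it accepts a synonym at edit distance
exactly 1 only if the match is unique across the archive (two
candidate ingredients → unmapped), computed with edlib.  Archive
loading fails loudly on synonym collisions and on ingredients lacking a
self-synonym.

MedDRA SMQ membership is licensed content, so the package bundles only
SMQ *headers* (the nine narrow cardiovascular categories plus the
three embolic/thrombotic sub-SMQs with their parent link); member PTs
come from a user-supplied CSV or from synthetic fixtures.  PT→SMQ
mapping uses narrow scope only and closes upward over parent links, so
membership in a venous or arterial sub-SMQ implies membership in the
embolic-and-thrombotic parent.  The full MedDRA HLT/HLGT/SOC hierarchy
is not traversed.

## Disproportionality statistics

The counting unit is the cleaned report: each report contributes to
exactly one cell of the 2×2 table, and repeated PTs or drugs within a
report count once.  Drug exposure defaults to suspect roles only
(primary + secondary suspect), configurable to all roles; the default
is a deliberate, visible choice since reporting practice differs on
concomitant medication.  The comparator is all other reports in the
cleaned window.  In class-versus-class panels a report exposed to both
classes appears in each class's exposure set (an exclusion flag is
available).

Both measures derive from the same shrunk observed/expected ratio
(N_observed + 0.5)/(N_expected + 0.5): the reported ROR equals that
ratio and IC = log2 of it, so `ic == log2(ror_shrunk)` is an exact
identity of every output row, not an approximation.  The additive 0.5
stabilizes small counts and pulls ratios toward 1; the IC interval
bounds use closed-form constants (−3.3, −2) and (+2.4, −0.5) on powers
−1/2 and −3/2 of (N + 0.5), giving asymmetric bounds whose widths
decrease monotonically in N and remain defined at N = 0.

The ROR 95% interval uses the Woolf standard error
sqrt(1/a + 1/b + 1/c + 1/d) around a selectable point estimate.  The
default center is the shrunk observed/expected ratio, for consistency
with the single reported ROR column; the classical odds ratio ad/bc is
exposed as an alternative.  These two centers are different statistics
— an observed/expected reporting ratio is not an odds ratio — and the
Woolf error strictly belongs to the classical one, so the default
interval should be read as approximate.  Any zero cell leaves the
interval undefined (returned as None, flagged, never substituted).

The signal rule is: at least `min_reports` (default 3) observed reports
AND (ROR025 > 1 OR IC025 > 0).  An undefined ROR bound simply fails its
clause.  Because the Woolf interval is narrower than the conservative
IC bound at small N, the OR-rule can flag borderline cells through the
ROR clause alone; panels in the shipped analysis show this behavior.
No multiple-testing adjustment is applied.

Presentation rounding is 2 decimal places, half away from zero; full
precision is retained internally.  N (%) columns use the panel total as
denominator.

## Time to onset and outcomes

Time to onset is event date minus the earliest day-precision start date
among the matching ingredient's entries (first exposure).  Exclusions
are values, not errors, and every one is counted by reason: missing
start, missing event, partial-precision date, or negative interval
(start after onset, treated as aberrant).  Same-day onset (0 days) is
kept.  Summaries report the median and quartiles by type-7 linear
interpolation and cumulative onset proportions at 30 and 90 days as
percentages to 1 dp.

Outcome severity assigns one category per report by precedence (death >
life-threatening > hospitalization > disability > congenital anomaly >
other serious), so category percentages partition the reports that have
any outcome; an all-outcomes sensitivity mode counts every category a
report carries.  The default denominator is all reports in the group,
configurable to reports with at least one recorded outcome.  The
headline severity metric is the combined death + life-threatening
percentage.

## The synthetic generator

The generator emulates the structural features the pipeline must
survive: versioned resubmissions (same id, earlier receipt date, partly
stale reactions), duplicate submissions (fresh id, identical six-field
key by construction), synonym and typo noise on product names, partial
and missing dates, demographic margins, and log-normal onset delays.
Each report draws one suspect drug from catalog marginals and, with
probability 0.3, a second drug from the same marginals (collision means
a one-drug report, so rare agents stay rare as co-medication).

Event sampling plants ground truth multiplicatively: a report whose
drugs elevate a PT fires it at base_rate × max λ over its drugs; the
max keeps each drug–event pair interpretable on its own.  Reports with
no elevating drug fire at a slightly deflated rate chosen so the
marginal PT rate stays exactly at base_rate.  The deflation is what
makes λ *identifiable*: the planted multiplier then equals the
report-level observed/expected reporting ratio that the pipeline
estimates, rather than that ratio diluted by the exposed reports' own
contribution to the event margin (a 7–8% bias at λ = 4 with 2% exposure
otherwise).  Under λ ≡ 1 no deflation occurs and drug and event
indicators are exactly independent.

The default configuration is a desk-scale cohort of 100,000 base
reports: five target agents and two background drugs, eight PTs spread
over four SMQ groups plus non-cardiovascular background terms, λ of 3,
4 and 2 on three pairs, onset medians of 23 days (hypertension-like,
short) and 51 days (thromboembolism-like, long) with σ = 1, 5%
duplication and versioning, and realistic missingness (25% missing
start dates, 15% missing event dates, 10% month-precision starts).
Rates were chosen once so that planted pairs yield on the order of
10²–10³ observed reports — large enough for stable estimates, small
enough to run in seconds.

What the generator does **not** emulate: secular reporting trends,
stimulated reporting and notoriety bias, correlated multi-event
syndromes, free-text noise beyond single-character typos, or
geographic/reporter heterogeneity in event rates.  Passing recovery
tests therefore demonstrates correctness of the pipeline's mechanics on
data with known structure, not robustness to every bias of real
spontaneous-report streams.

The truth check compares pipeline output to the sidecar: every planted
duplicate pair and versioned id must resolve to the correct single
survivor (a versioned id may legitimately vanish when the six-field
rule collapses it into a coincidentally identical report — at 10⁵
reports a handful of such collisions are expected and are the dedup
rule working as specified); planted ratios must be recovered within
λ·[0.8, 1.25]; onset medians within median·[0.93, 1.08], applied only
when at least 2,000 records support the estimate, since the sampling
error of a log-normal median at a few hundred records exceeds that
band's width.

## Problem sizes and numerical choices

The shipped analysis and the test suite run at sizes chosen as a
realistic desk-scale study: 100,000-report cohorts for calibration and
recovery checks (10 seeds each), 250-report cohorts across 100 seeds
for dedup recovery, 1,000 random ≤20-report instances for
contingency-builder equivalence against a brute-force classifier, and
~5,000 onset records for median recovery.  Null calibration uses 20
unplanted drug–event pairs over 10 seeds and requires the IC025 > 0
exceedance to stay below 5%; the closed-form IC bound is conservative
at N ≈ 20, so the observed rate is typically nearer 1%.

Determinism: every stochastic component is driven by a single
numpy Generator seeded from the config; identical configs are
reproduced record for record.  Ties are broken lexicographically
everywhere (version retention, duplicate survivorship, panel row
order), so reruns and platform changes cannot reorder output.

Known limitations: the exact-key duplicate rule cannot catch
near-duplicates differing in any key field; the Woolf interval around
a shrunk reporting ratio is approximate by construction; percentages
and medians are presentation-rounded, so derived identities (e.g. a
combined percentage versus the sum of its parts) hold only to the last
printed digit; and the bundled drug archive, while covering the target
agent classes, is a curated convenience rather than an exhaustive
product dictionary.
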