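# Methods

This note documents the statistical model choices, numerical conventions
and known limitations of `adrassess`. Everything quantitative stated here
is computed by the package's tests or by `scripts/acceptance.py`.

## The decision-flow engine

A tool is a finite, acyclic directed graph of yes/no questions whose leaves
are ordinal outcome categories. The engine is deliberately tool-agnostic:
the LCAT and LAAT graphs are *data* (YAML under `src/adrassess/data/`),
validated on load for acyclicity, branch completeness (every question has a
yes- and a no-edge), edge-target existence, outcome reachability, and a
contiguous 0-based ordinal score set with unique scores. Evaluation is a
deterministic traversal; an unanswered question *on the active path* is an
error (the tools require explicit clinical judgement at each node, so no
default answer is ever substituted), while answers to off-path questions
are ignored with a warning.

Transcription status of the bundled graphs: the question wordings printed
in the published translation table (Brazilian-Portuguese v1/v2 of five
modified questions) are reproduced byte-identically and tested as such. The
remaining wiring and wordings are reconstructed from the tools' published
descriptions (binary decisions; a positive rechallenge or the same event in
the patient's history defines causality; an insufficiently documented case
is unassessable for avoidability) and are individually flagged
`transcription: reconstructed` in the YAML so a figure-accurate source can
be merged without touching code. The engine-level guarantees (all four
outcomes reachable, replay determinism, verbatim printed texts) hold for
the bundled graphs and are enforced by tests.

Language tags are BCP-47 style (`en`, `pt-BR`); version tags `original`,
`v1`, `v2`. The English stem printed in the translation table as
"lost-lasting disability" is carried as "long-lasting" (the original
wording); the printed variant is preserved in a config comment.

## Agreement statistics

All statistics operate on a k × k cross-tabulation (rows = rater 2,
columns = rater 1, mirroring the published per-category table layout; every
statistic is orientation-symmetric).

**Proportions.** %EA and %ED use the Wald normal approximation
p̂ ± z·√(p̂(1−p̂)/n) on the percentage scale, truncated to [0, 100]. The
truncation flag is set only when the unclipped bound strictly exceeds the
limit; a degenerate p̂ ∈ {0, 1} interval collapses to a point at the
boundary without a flag. Extreme disagreement uses the strict inequality
|s₁ − s₂| > 2 on the 0–3 ordinal scores; with four categories only a 0-vs-3
split qualifies. At threshold 0, %ED is exactly 100 − %EA.

**Kappa.** Cohen's κ = (P₀ − P_e)/(1 − P_e). Its standard error is the
simplified Fleiss form √(P₀(1−P₀)/(n(1−P_e)²)); statistics packages differ
in the last digit of kappa CIs (this data's lower bound computes to 0.53
where 0.52 has been printed elsewhere), so kappa interval bounds should not
be over-interpreted at the second decimal. Weighted kappa uses
disagreement weights (linear |i−j| by default; quadratic; binary) with
expected weights from the marginal products; its SE is the
Fleiss–Cohen–Everitt (1969) large-sample formula in agreement-weight form.
Degenerate marginals (P_e = 1, possible only when both raters use a single
category) make kappa undefined; the result is flagged rather than raised so
a full report can always be assembled. Interpretation uses Altman's bands
with upper-inclusive boundaries at 0.20/0.40/0.60/0.80 — the boundaries are
implemented as a gap-free partition of (−∞, 1].

**Cronbach's alpha.** Raw alpha over the raters' ordinal score vectors,
α = r/(r−1)·(1 − Σσ²ⱼ/σ²_T), computed with population (1/n) variances; the
value is invariant to the denominator convention. The confidence interval
is Feldt's F interval with degrees of freedom (n−1) and (n−1)(r−1), clearly
an interval-method choice rather than a reproduction of any particular
software. Two identities anchor the implementation: for two raters, raw
alpha equals the stepped-up consistency intraclass correlation
2ρ/(1+ρ) with ρ = (MSB − MSE)/(MSB + MSE) from the two-way ANOVA
decomposition (always), and equals the Spearman–Brown step-up 2r/(1+r) of
the Pearson correlation exactly when the raters' score variances are equal.
Both are verified from first principles in the property tests; the popular
Pearson form is *not* an identity for raw alpha under unequal variances.

## Reconstruction from published per-category tables

A published one-vs-rest 2×2 table per category fixes, for the full k × k
table, each rater's marginal for that category and the diagonal cell. The
enumerator backtracks over off-diagonal cells (row-major, so output order
is lexicographic) and returns every non-negative integer table satisfying
all three constraint sets, or an infeasibility diagnosis naming the
violated constraint. A category with no printed 2×2 is retained as an
explicit row/column, with the rater's marginal deficit relative to n
assigned to it.

Among feasible tables, selection is by minimal total linear off-diagonal
disagreement — chosen because, of the candidate reconstructions, it is the
most charitable to the raters and is *value-blind*: it never looks at the
statistics one hopes to reproduce. A tie is reported as ambiguity, not
broken arbitrarily. Separately, a cross-check compares the selected (or
every) candidate's implied summary statistics with the published ones at
printed precision (0.01 on unitless coefficients, which also covers the
κ = 0.7368-computed vs 0.73-printed truncation/rounding ambiguity; 0.1 on
percentages printed to one decimal) and flags disagreement.

For the causality (LCAT) data the constraints admit exactly two tables
(total linear disagreement 5 and 7); the minimum-disagreement table
reproduces the published weighted kappa (0.82), alpha (0.95), %EA (80.77)
and %ED (0), and is expanded — in row-major cell order, a pure bookkeeping
convention since all statistics are permutation-invariant — into the 26
rating pairs shipped as `lcat_ratings.csv`. For the avoidability (LAAT)
data the printed rater-2 marginals sum to 23 of 26 (read as three
unprinted "unassessable" ratings); enumeration yields four candidates, the
minimum-disagreement selection is tied, and *no* candidate reproduces the
published alpha/weighted-kappa summaries (computed ranges α 0.45–0.70,
κ_w 0.51–0.58 against printed 0.85 and 0.68). The package therefore
surfaces the inconsistency and blesses no avoidability fixture; forcing
agreement would misrepresent the published record.

## Synthetic data

**Ratings.** The copy-mixture model: rater 1 draws from a category
marginal p; with probability *a* rater 2 copies rater 1, else draws
independently from p. Then P₀ = a + (1−a)Σpᵢ² and P_e = Σpᵢ², so the
population Cohen's kappa equals *a* exactly — an analytic recovery target
used by the parameter-recovery tests (mean κ̂ within ±0.02 of a over 200
replicates at n = 1,000). The model emulates pure chance-plus-copying
agreement; it does not produce the *ordinal clustering* of real rater
disagreement (near-miss errors), so weighted-kappa behaviour on real data
is exercised only through the reconstructed fixture, not the simulator.

**Case reports.** Ages, sex, diagnoses, events and suspected
anti-infectives follow the validation study's case-mix frequencies (26
reports from 22 inpatients aged 0–17 of a paediatric teaching hospital;
pneumonia the most frequent diagnosis, nausea/vomiting the most frequent
event). The published counts do not specify which patients carried multiple
reports, so surplus reports are assigned to uniformly chosen patients.
Timelines and dechallenge/rechallenge observations are plausible fillers,
not fitted to any data. These reports exercise the data model and the
assessment workflow; passing tests on them says nothing about real-world
rater behaviour.

All generators take an explicit seed and create one fresh generator per
call; there is no global random state.

## Problem sizes and numerical conventions

Reported values render half-up, locale-independent; the summary block
prints percentages to one decimal with two-decimal CI bounds, the
per-category block to two decimals throughout, matching the published
layouts. Machine JSON keeps full precision and plain hyphens. The test
suite's Monte-Carlo checks run at n = 50,000–100,000 draws for closed-form
limits and 200 × 1,000 for parameter recovery — sizes at which the
Monte-Carlo error is an order of magnitude below the asserted tolerances.
Enumeration is exercised up to k = 4, n = 30 against an independent
composition-based brute force; the backtracking scales far beyond that but
published-table reconstruction needs only k = 4, n = 26.

## Known limitations

- Two raters only for %ED and the crosstab pipeline; alpha accepts r ≥ 2.
  No Fleiss multi-rater kappa generalisation.
- Wald (not Wilson/exact) intervals, by design, to mirror the validated
  reporting convention; they are known to undercover near the boundaries.
- No bootstrap or resampling intervals.
- Integer tables only in the enumerator; no fractional fitting.
- The engine consumes explicit yes/no answers; it performs no free-text
  inference over case narratives, and the Naranjo and Hallas instruments
  are out of scope.
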