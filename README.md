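# adrassess

Decision-flow engines for the **Liverpool Causality Assessment Tool (LCAT)**
and **Liverpool Avoidability Assessment Tool (LAAT)** — with full bilingual
(English / Brazilian-Portuguese) question banks — together with the complete
inter-rater *measurement-equivalence* statistics suite used to validate
translated versions of such instruments, and a constrained
contingency-table enumerator that recovers full paired rating data from
published one-vs-rest agreement tables.

## Who this is for

Pharmacovigilance teams and pharmacoepidemiology researchers who assess
adverse drug reactions (ADRs) in children. The Liverpool tools are binary
(yes/no) flow diagrams: LCAT classifies the *causality* of a suspected ADR
as unlikely < possible < probable < definite (scored 0–3), LAAT classifies
its *avoidability* as unassessable < not avoidable < possibly avoidable <
definitely avoidable (0–3). Validating a translated instrument requires
showing measurement equivalence between independent raters, which is what
the statistics here quantify.

## What it computes

For a cases × raters matrix of ordinal categories (two raters), over the
k × k inter-rater cross-tabulation with cell proportions
$p_{ij}$, row/column marginals $p_{i\cdot}, p_{\cdot j}$:

- **% exact agreement** $\%EA = 100\,\sum_i p_{ii}$ and **% extreme
  disagreement** $\%ED$ (ordinal scores differing by more than 2), each with
  a Wald interval $\hat p \pm z_{1-\alpha/2}\sqrt{\hat p(1-\hat p)/n}$
  truncated to [0, 100] (truncation flagged);
- per-category **one-vs-rest 2×2 agreement** with the same intervals;
- **Cohen's kappa** $\kappa = (P_o - P_e)/(1 - P_e)$,
  $P_e = \sum_i p_{i\cdot}p_{\cdot i}$, with the simplified Fleiss
  asymptotic SE, and **weighted kappa**
  $\kappa_w = 1 - \sum w_{ij} p_{ij} \big/ \sum w_{ij} p_{i\cdot}p_{\cdot j}$
  with linear $w_{ij}=|i-j|$ (default), quadratic, or binary weights
  (binary reduces $\kappa_w$ to $\kappa$ exactly), interpreted on Altman's
  bands (poor/fair/moderate/good/very good);
- **Cronbach's alpha** over the raters' score vectors,
  $\alpha = \frac{r}{r-1}\left(1 - \sum_j \sigma_j^2 / \sigma_T^2\right)$,
  with Feldt's F-based interval;
- **constrained enumeration**: every non-negative integer k × k table with
  prescribed row marginals, column marginals and diagonal — exactly the
  constraints fixed by published per-category 2×2 tables — with a
  value-blind minimum-disagreement selection and a cross-check against
  published summary statistics that *flags* inconsistencies instead of
  forcing agreement;
- a **copy-mixture simulator** (rater 2 copies rater 1 with probability
  *a*, else rates independently) whose population kappa equals *a*, and a
  paediatric ADR case-report generator following the validation study's
  case mix.

## Worked example

Reconstruct the Brazilian-Portuguese validation study's 26 paired causality
ratings from its printed per-category tables and compute the full report:

```bash
adrassess reliability --tool LCAT \
    --ratings src/adrassess/data/lcat_ratings.csv
```

prints

```
Measurement equivalence — LCAT (n = 26)

Scale                       LCAT (95% CI)
Cronbach's alpha            0.95 (0.89–0.98)
Cohen's Kappa               0.74 (0.53–0.94)
Weighted Kappa (linear)     0.82 (0.67–0.97)
% Exact Agreement           80.8 (65.62–95.92)
% Extreme Disagreement (>2) 0.0 (0.00–0.00)
Kappa interpretation        good (weighted: very good)

Per-category exact agreement (one vs rest)
Category                 Both yes  R2 only  R1 only  Both no     %EA  95% CI                  SE
unlikely                        3        0        1       22   96.15  88.76–100.00^a        3.77
possible                        7        1        3       15   84.62  70.75–98.48           7.08
probable                        6        4        0       16   84.62  70.75–98.48           7.08
definite                        5        0        1       20   96.15  88.76–100.00^a        3.77

^a Upper bound truncated to 100.00% to keep logical coherence
```

Reading this: the two raters (a pharmacist and a paediatrician) assigned the
identical causality category in 21/26 cases (80.8%), never disagreed by more
than two ordinal steps, and the chance-corrected agreement is "good"
(κ = 0.74) unweighted and "very good" (κ_w = 0.82) once near-miss
disagreements are down-weighted by ordinal distance. The `^a` marker shows
Wald upper bounds clipped at 100%.

Running a single case through the causality flow:

```bash
echo '{"suspect_adr": "yes", "drug_before_event": "yes",
       "alternative_cause": "no", "dechallenge": "yes",
       "rechallenge": "yes"}' > answers.json
adrassess assess --tool LCAT --answers answers.json --lang pt-BR
```

returns outcome `definite` (label "Definida", ordinal score 3) with the full
question trail — a positive rechallenge defines the reaction.

`adrassess reconstruct --tool LAAT` demonstrates the cross-check behaviour:
the avoidability summaries published alongside the per-category tables
cannot be reproduced from any table consistent with those counts, and the
output says so (`"consistent_with_published": false`) rather than forcing a
fit.

The same functionality is available as a library
(`adrassess.reliability_report`, `adrassess.feasible_tables`, …); see the
module docstrings and `docs/methods.md`.

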