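# Methods

## The problem and the model

A rare gene fusion (MAML2 rearrangement, usually CRTC1–MAML2) is diagnostic
evidence in the mucoepidermoid (MEC) versus adenosquamous carcinoma (ASC)
differential: its presence confirms MEC and excludes ASC; its absence is
uninformative for MEC but supportive for ASC. The package quantifies the
marker's added value from three kinds of routine data — test-order timelines,
final-versus-working diagnoses, and an expert survey — rather than from a
designed accuracy study.

### Test-order intent

Intent is derived exclusively from the four report-timeline milestones,
stored as integer day offsets with the surgical order at day 0:

- **diagnostic** ⇔ `t_mol_signout ≤ t_surg_signout` — the pathologist held
  the case for the molecular result. The tie is classified diagnostic
  because the result was available at sign-out; the convention is
  configurable only by editing the classifier, and the choice is documented
  here because the boundary case is genuinely ambiguous.
- **confirmatory** otherwise, upgraded to **confirmatory-therapeutic** when
  `t_mol_order − t_surg_signout >` a threshold (default 30 days): such late
  orders serve therapeutic target identification, not diagnosis. The delay
  is measured from sign-out (not from any amendment date), and the upgrade
  can only apply to confirmatory cases — a diagnostic order cannot postdate
  sign-out.

A case is **molecularly changed** when working and final diagnosis differ
after collapsing the final marker substates to {MEC, ASC, OTHER}. An UNKNOWN
working diagnosis always counts as changed: the result resolved an open
differential. Benefit accounting reports a *core* benefit (changed +
unchanged marker-positive MEC confirmations, over all tested cases, integer
percent) and an *extended* benefit that also credits unchanged
marker-negative ASC confirmations (exclusion value). 45/55 rounds to 82% by
the module's round-half-even integer convention; truncation would print 81 —
the count, 45, is the stable quantity.

### Diagnostic performance

Truth is the adjudicated final diagnosis restricted to the MEC-vs-ASC
domain; the index test is the marker call. Sens/spec/PPV/NPV carry exact
Clopper–Pearson intervals on their own denominators; any metric with a zero
denominator is reported as a flagged `None`, never as 0 or 100, because
degenerate cells are routine in small scenario filters. Youden's J
(= Se + Sp − 1) summarizes a setting; the *combined average J* — the mean of
the marker's screening-role J and exclusion-role J, expressed as a percent —
captures a composite biomarker in one number. The inverted-marker view
evaluates marker *absence* as a rule-in for ASC by swapping truth and
negating the test, which maps the 2×2 table (tp, fp, fn, tn) to
(tn, fn, fp, tp); the map is an involution, which the tests exercise.

Fisher's exact test uses the standard minimum-likelihood two-sided rule
(sum of hypergeometric probabilities ≤ that of the observed table). This is
the rule scipy and R implement; the alternative "doubling" rule gives
different values, which is why the choice is pinned here and the tests
compare against a full enumeration oracle.

### The transition model

Working and final diagnoses are states of a memoryless process with exactly
one transition; no multi-step chains are modeled because none exist in the
data-generating process. Estimation is maximum likelihood: row counts
normalized by row totals, with no smoothing — at these cohort sizes the
estimates are summary statistics of one practice, not converged
probabilities, and pseudocounts would disguise that. Zero cells are
therefore surfaced through two distinct masks: `unobserved_mask` (count is
zero; the transition may still be possible) and `structural_zero` (ASC
origin → marker-positive MEC, impossible under the exclusion rule).
Destination precedence: a final diagnosis of MEC splits on the marker; ASC
and OTHER finals ignore it, and a final MEC without a definitive marker call
is a state-assignment error rather than a silent bucket.

### Economics

All currency arithmetic is in integer cents (the unit cost is converted
once, by rounding, at entry), so `savings = universal − actual` and
`value_added + non_contributory = actual` hold exactly and printed totals
are exact multiples of the unit cost. The default unit cost is the CPT
81445 clinical-laboratory fee-schedule amount, USD 597.91. The value-added
count defaults to the extended benefit from intent accounting but is an
explicit argument, since the eligible universe (all MEC/ASC diagnoses, not
just tested ones) comes from outside the cohort file.

### Survey indices

RII = ΣV / (A·N) with V the 0–100 ratings, A the scale maximum, and N by
default the number of raters *of that item*, so partial response does not
deflate a scenario's score; a panel-size N mode is provided for comparison.
SRO sums explicit ranks over respondents holding a complete permutation
(partial rankings are excluded — they would bias the sum toward whatever was
ranked). For R complete rankers of S scenarios, ΣSRO = R·S(S+1)/2 exactly;
this identity is a test. Intra-rater reliability is the Spearman correlation
between a respondent's explicit ranks and the ranks implied by their own
ratings (ties → average ranks); "high-reliability" subsetting, when wanted,
takes the top tertile of that correlation. RII ties in the aggregate table
break by lower SRO, then lexically by scenario key, so reports are
deterministic.

## Synthetic data

The stochastic generator draws, per case: a working diagnosis from a 3-state
mix; a final state from that origin's transition row; an order intent from a
3-state mix; and a timeline realizing that intent, with shifted-geometric
integer gaps (surgical TAT mean 10 d, molecular TAT mean 14 d, confirmatory
order gap mean 7 d) — geometric because report intervals are nonnegative,
integer, and right-skewed, and no empirical TAT distribution is available to
fit. Marker status and fusion calls derive from the final state, so every
generated record satisfies the cohort invariants by construction. Default
parameters are the observed study conditions: 55 cases, working mix
23 MEC / 25 ASC / 7 other, the empirical transition rows, and intent mix
11 diagnostic / 26 confirmatory / 18 therapeutic. A spec putting positive
mass on the forbidden ASC → MAML2+ MEC cell is rejected up front.

Two deterministic reference cohorts reproduce practice-scale marginals
exactly:

- `reference_cohort()` — 55 cases. Working MEC: 19 confirmatory (8
  marker-positive) + 4 diagnostic, finals (7, 6, 9, 1) over
  (MEC+, MEC−, ASC, other); working ASC: 20 confirmatory (15
  therapeutic-delay) + 5 diagnostic, finals 24 ASC + 1 other; working
  other/unknown: 5 confirmatory + 2 diagnostic unknowns, finals 2 MEC+,
  1 ASC, 4 other. This yields 44:11 confirmatory:diagnostic, 18 late orders
  (15 ASC), 14 changed diagnoses, core benefit 21/55 = 38%, and overall
  sensitivity 9/15 = 60%. One reconciliation was forced: a working-MEC
  positive count of 9 cannot coexist with 7 final MEC+ under the
  "positive marker excludes final ASC" invariant (positives can only land
  in MEC+ or, exceptionally, a final of *other*), so the fixture carries 8
  working-MEC positives — all 8 in the confirmatory subset, preserving the
  8/19 = 42% confirmatory detection rate — and the held (diagnostic) MEC
  subset is 0/4 positive.
- `screening_cohort()` — 8106 cases across six site groups with 23
  positives (18/307 in head and neck) and per-site fusion-partner calls
  (17 + 2 CRTC1, 1 CRTC3, 1 YAP1, 1 KMT2A, 1 SAMSN1). Only the fields
  feeding frequency tabulation are meaningful; timelines are placeholders.

The survey generator rates each scenario as latent importance × 100 plus
Gaussian noise (default sd 10 Likert points), clipped to the scale, and
ranks a second noisy realization; exactly `round(rate × n)` respondents
(default 13 of 15 — the value implied by the rank-sum identity on the
observed panel) return complete permutations. The default latent profile is
the observed consensus RII ordering over the seven scenarios.

**What the generators do not emulate:** per-case correlation between grade,
site and marker status beyond simple conditionals; assay failures and QC
attrition; multiple specimens per patient (the model assumes one record per
tested tumor); drift in ordering practice over time; and any dependence of
survey ratings on respondent subspecialty. Passing tests therefore
demonstrate correctness of the estimators on data with the assumed
structure, not robustness to those real-world features.

## Numerical choices

- Clopper–Pearson via the beta-quantile form (statsmodels), with the k = 0
  lower and k = n upper endpoints pinned to exactly 0 and 1; the test oracle
  re-derives endpoints by bisection on the binomial CDF.
- Frequencies print at 2 decimals (site tables) or 1 decimal (shares);
  raw counts are always retained so no information is lost to rounding.
- Reports serialize through JSON with non-finite values rejected rather
  than emitted, so written reports always round-trip.
- Integer-cent currency, round-half-even at the single entry point.
- Problem sizes in the statistical tests (5000-case recovery cohorts,
  2000-draw coverage simulations, enumeration oracles up to n ≈ 40) are
  chosen so each check isolates estimator error well above Monte-Carlo
  noise while the whole suite stays interactive (a few seconds).

## Known limitations

- Single-transition model only; no covariates on transition probabilities.
- The per-setting 2×2 denominators behind some published composite tables
  are not recoverable from marginal counts, so scenario filters here are
  defined by the intent classifier, not by reverse-engineered tables.
- Intent is purely timeline-derived; it cannot distinguish a deliberately
  held case from a slow sign-out.
- The exact binomial interval is conservative; coverage above nominal is
  expected and tested for, not corrected.
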