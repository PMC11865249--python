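# Methods

## Scope and data model

The package operates on spontaneous adverse-event reports in a simplified
FAERS-like form. A case report carries demographics (sex, age in years,
reporter type), a receipt year, a worst outcome, a non-empty list of drug
mentions (each with a role code — primary suspect, secondary suspect,
concomitant, interacting — and an optional free-text indication marker), and
a non-empty set of adverse-event preferred terms. On disk a dataset is a
directory of `$`-delimited quarterly tables (`DEMO`, `DRUG`, `REAC`, `OUTC`)
keyed by a primary id formed from case id and version; the dialect is
deliberately minimal but preserves the features that matter for cleaning:
versioned resubmissions, bit-identical duplicate rows, missing ages, and
backslash-joined combination product names.

## Cleaning pipeline

1. **Read.** Rows with the wrong field count are collected in a reject list
   with a reason, never silently dropped; a missing table type is a hard
   error.
2. **Assemble.** The four tables are joined per primary id. Reports lacking
   any drug or any reaction are excluded as incomplete and counted.
   Bit-identical repeated demographic rows collapse (counted); the same
   primary id with conflicting demographics is rejected with a reason.
3. **Deduplicate.** One report per case id survives: highest version, ties
   broken by latest receipt year, then by earliest provenance (input order).
   This order is total, so deduplication is deterministic, idempotent and
   stable.
4. **Standardize names.** Verbatim drug names are upper-cased,
   whitespace-collapsed and looked up exactly in a verbatim→generic mapping;
   no fuzzy matching, for reproducibility. Unmapped names keep an
   `UNRESOLVED:` marker and are listed once, with counts, in a coverage
   summary.
5. **Cohort filter.** Minimum age (default 18; reports with missing age are
   excluded when a minimum is active, because the criterion cannot be
   verified — a `keep_missing_age` switch restores them), optional required
   event term, and optional required drug role and/or indication (both must
   hold on the same mention). The postoperative-analgesia context, which has
   no structured field in spontaneous reports, is modelled as an indication
   marker on the suspect drug. Exclusions are tallied by the first failing
   criterion so kept + excluded always equals the input count.

## Signal statistics

All statistics derive from the 2×2 table (a, b, c, d) of one drug against
one event within a chosen background — either the full deduplicated dataset
or the filtered cohort; both are supported because screening tools differ on
this point and the choice materially changes the expected counts. The
background is always reported alongside results.

- ROR = ad/bc, Wald 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)), two-sided
  Fisher exact p. The +0.5 Haldane–Anscombe correction is applied to all four
  cells only when some cell is zero, and flagged; unmodified tables stay
  exact. The p-value always uses the raw integer table.
- Relative reporting ratio RRR = a/E₀ with E₀ = (a+b)(a+c)/N; defined as 0
  at a = 0. (E₀ = 0 with a > 0 cannot occur on integer tables since
  E₀ ≥ a²/N.)
- Safety signal = log₂((a+½)/(E₀+½)). The screening tool this mirrors
  publishes no formula; this operationalization is chosen so that "> 0" is
  exactly "observed exceeds expected" under a half-count shrinkage that keeps
  the metric finite and continuous at a = 0.
- Information component. Default (`gamma`): the same shrunk log₂ ratio, with
  95% credible bounds log₂(q_Γ(α; a+½, 1)/(E₀+½)) at α = 0.025, 0.975 — a
  gamma posterior on the co-report intensity with the margins held fixed.
  This form was chosen as the default because it admits an exact Monte-Carlo
  oracle (sample the gamma, transform, take quantiles), which the tests use.
  The classical closed-form moment approximation with uniform-marginal priors
  (`bate1998`: E[IC] and Var[IC] from the Beta/Dirichlet prior system
  α₁=β₁=1, α=β=2, γ₁₁=1 with the joint prior scaled for zero prior IC;
  CI = E ± 1.96·sd) is selectable. Under the default method IC equals the
  safety signal by construction — a documented coupling, not a coincidence.
- Rule sets, strict inequalities exactly as published: `aersmine`
  a ≥ 2 ∧ signal > 0 ∧ RRR > 2; `ror` CI lower limit > 1; `bcpnn`
  a ≥ 3 ∧ IC lower limit > 0. No multiple-testing adjustment is applied in
  the screen, matching the practice the pipeline reproduces.

A monotonicity caveat: ROR strictly increases in a at fixed b, c, d, but the
observed/expected family (RRR, safety signal, IC) does not — when the
off-cells are small, E₀ grows superlinearly in a and the ratio can plateau or
fall (e.g. (3,1,1,5) → (4,1,1,5) lowers the RRR). All four statistics do
strictly increase when a report moves from the discordant cells into
agreement (a+1, b−1, c−1, d+1), i.e. at fixed margins; the property tests
assert that form.

## Subgroups and correlations

The default strata are adult males/females (age 25–65, both ends inclusive)
and elderly males/females (strictly above 65). Ages 18–24 and missing ages
fall in no stratum; the gap is part of the subgroup definition this pipeline
reproduces and is preserved rather than patched. Within each stratum, tables
are rebuilt against that stratum's own background, and three drugs × strata
matrices are produced: absolute count (a), safety signal, RRR. A stratum with
no reports yields a missing column (NaN, not zero) plus a warning.

Drug profiles are correlated pairwise with Pearson's r over the strata axis
by default (a drugs × years axis is available as an option — published
analyses rarely state which axis they used, so both are supported and the
choice is recorded in the run manifest). With four-point profiles |r| is
noisy; pairs sharing fewer than three non-missing cells or with zero variance
are excluded with a reason, and a small-profile warning is emitted rather
than silently reporting. Negative-pair rankings sort ascending in r with a
total tie-break on the name pair.

## Descriptive layer

Counts are exact; every percentage is 100·count/total rounded half-up to two
decimals in exact decimal arithmetic, which reproduces printed baseline
tables bit for bit. Drug rankings count a drug once per report, rank by count
descending with alphabetical tie-break, and state their percentage
denominator explicitly — total reports or total distinct per-report mentions,
because published rankings use both conventions.

## Synthetic data generator

The generator emulates the structure of a spontaneous-report database with
fully configurable marginals; its defaults are the study conditions used
throughout the tests:

- **Demographics**: sex 61.92 / 31.27 / 6.81% (female/male/unspecified) and
  the eight-band age distribution and reporter mix of a large published
  dizziness cohort's baseline table; ages are drawn uniformly within the
  selected band (rounded to 2 decimals, missing in the "Not Specified" band)
  since bands, not exact ages, drive downstream logic — except the subgroup
  strata, which use the drawn age.
- **Trend**: yearly weights rise linearly from 2004 to a 2015 peak, then
  plateau at 75% of the peak — the qualitative shape of the published yearly
  series ("rising, peaking in 2015, stabilizing high"). The plateau level is
  set low enough that the peak year is identifiable from 10,000 reports.
- **Outcomes**: dominated by non-serious (50%), with hospitalization,
  other-serious, death, life-threatening, disability and unspecified filling
  the remainder — the qualitative mix of published outcome panels.
- **Drugs**: each report draws k distinct drugs (k uniform on a configured
  interval) by weighted sampling without replacement (Gumbel top-k); one
  mention, uniform among them, is the primary suspect, and carries the
  postoperative-analgesia indication marker at a configured rate; the others
  are secondary suspect or concomitant at random.
- **Events**: each preferred term is an independent Bernoulli with
  probability odds/(1+odds), where odds = p/(1−p) of its baseline probability
  times the product of the planted effects whose drug is present (and whose
  stratum restriction, if any, the report satisfies). A term with baseline
  probability 1 is included on every report; the default vocabulary carries
  one such term so every generated report has a reaction and the
  write→read→assemble→deduplicate round trip is exactly the identity.
- **Duplicates**: a configurable fraction of near-copies is appended, half
  version-incremented and half bit-identical — both flavours occur in real
  submissions and exercise both deduplication branches.

Because the event model is odds-multiplicative and per-term independent, the
expected 2×2 table of any unrestricted drug–event pair is available in closed
form (`expected_contingency`): the drug-set probabilities of the successive
weighted draw are enumerated exactly by the recursion
f(S) = Σ_{j∈S} f(S∖{j})·w_j/(1−W_{S∖{j}}), and the event probability is
evaluated per set. This oracle is independent of the sampling path and is the
analytic cross-check for the generator and the screening stack. Expectations
of stratum-restricted signals depend on the demographic mix and are not
implemented; those signals are validated through ranking behaviour instead.

What the generator does **not** emulate: drug co-prescription correlation
structure (drugs are drawn independently given k), free-text name noise
beyond exact verbatims, dose/regimen fields, reporting-rate secular trends
within a drug, and event–event dependence beyond shared planted drugs.
Passing tests therefore demonstrate correctness of the statistics and
plumbing under a clean generative model, not robustness to the messiness of
real report streams.

## Experiment sizes and test conditions

- Marginal fidelity: n = 50,000; each configured category within 3 binomial
  standard errors (exact binomial test below the normal regime, i.e. when
  np(1−p) < 9).
- Planted-effect recovery: odds factors 2, 5, 10 at n = 50,000, three seeds,
  median RRR within 30% of the factor. Each planted signal gets its own
  event term — signals sharing one event would inflate the common event
  margin and bias every other signal's RRR downward — and sampling weights
  shrink as the effect grows (0.04, 0.02, 0.0075), because both logistic
  saturation and background contamination scale with drug prevalence ×
  effect. With these settings the asymptotic RRRs are ≈1.84, 4.17 and 8.17.
- Null calibration: 40 drugs × 25 events (1,000 pairs), all effects 1, at
  n = 20,000 so every margin exceeds 20; the ROR rule (a one-sided exceedance
  of a 95% interval) must fire on 0.5–5% of pairs.
- Stratum-restricted planting: event baseline 0.03 and drug weight 0.05 so
  each null stratum expects ~15 co-reports, making a signal-level RRR (> 2)
  there a > 3.5σ fluctuation while the planted stratum separates cleanly.
- Monte-Carlo IC oracle: 10⁶ gamma draws per table, 20 tables, agreement
  within 0.02 on the log₂ scale.

These problem sizes are the package's chosen study conditions; they complete
the full test suite and the acceptance script in well under a minute each on
a single core.

## Known limitations

- The safety-signal formula is this package's operationalization of an
  unpublished tool metric; absolute values are not comparable to that tool,
  only signs and orderings.
- Fisher exact p-values are reported but the decision rules deliberately use
  only interval bounds; published p-values produced by unnamed tests are not
  reproduced.
- Percentages round half-up at two decimals; other software may use banker's
  rounding and differ in the last digit.
- The four-point correlation profiles inherit all the fragility of
  small-sample Pearson correlations; the exclusion rules and warnings flag,
  but cannot remove, that noise.
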