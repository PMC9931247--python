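# Methods

This note documents the models, rules and numerical choices implemented in
`obesity_lca`, and what the synthetic-data validation does and does not show.

## Cohort definitions

A **case** patient's *index visit* is the first visit (ordered by day offset,
ties broken by visit id) at which an obese BMI was recorded. The *pre-index*
visit is the latest visit before it and is required for inclusion — a patient
whose first observed visit is already obese cannot be shown to be *newly*
obese and is excluded (`no_pre_index`). The *post-index* visit is the earliest
visit after the index and is optional. Exclusions are data, not errors: every
excluded patient is logged with a reason, and when a case or control is
excluded its match partner is removed too (`match_partner_excluded`), so the
1:1 pairing stays total and the per-stage accounting identity
`in = retained + excluded` holds exactly.

**Temporal diagnoses** tag a diagnosis category with its visit timing
(1 = pre-index, 2 = index, 3 = post-index), rendered `"1-ALL04"`. The
canonical feature order is (timing ascending, code lexicographic) everywhere,
so all outputs are byte-stable. Binarization sets entry (patient, `t-code`)
to 1 iff the code was recorded at the patient's role-`t` visit; patients
without a post-index visit have all timing-3 entries 0 by construction.

**Demographic rules.** Hispanic/Latino ethnicity dominates any recorded race;
missing race *and* ethnicity → Unknown; unrecognized race strings →
Heterogeneous Other. Medicaid/CHIP enrollment is read from the index visit's
payer list; when that list is empty, all visits within ±365 days of the index
are scanned (the window is configurable to one-sided), and a patient with no
payer anywhere in the window is dropped from the study population. Age bins
are half-open — [2, 5), [5, 12), [12, 19) — using exact (not completed-year)
age at index derived from the birth offset; ages outside [2, 19) are invalid
by study definition.

## Pattern mining

Because timing tags are absolute, containment of a temporal pattern in a
patient record reduces to tagged-set inclusion, and the pattern lattice is the
subset lattice of the tagged vocabulary. Mining is the classic vertical
(id-list) scheme: frequent single items seed patient-id sets; candidate
(k+1)-item patterns join two frequent k-item patterns sharing a (k−1)-item
prefix; candidates with any infrequent k-subpattern are pruned (downward
closure); supports come from exact id-set intersection, never estimation. The
support denominator is all included case patients — including those without a
post-index visit, whose records simply cannot contain timing-3 items. Default
minimum support is 1% of case patients. The miner is validated by exact
agreement (pattern sets *and* supports) with a brute-force enumerator over
100 random small cohorts.

## Matched testing

For each pattern, the discordant pair counts are b (case has it, matched
control does not) and c (the reverse). The asymptotic McNemar statistic is
(|b−c|−1)²/(b+c) with continuity correction — the default, mirroring common
statistical software — or (b−c)²/(b+c) without; p is the upper chi-square(1)
tail, and b+c = 0 yields p = 1. Retention requires both significance and
case-enrichment (case prevalence > control prevalence); two-sided p-values
are always reported. No multiplicity adjustment is applied by default;
Benjamini–Hochberg step-up adjustment is available (`adjust=
"benjamini_hochberg"`). Type-I error of the uncorrected test is calibrated on
odds-ratio-1 null patterns (1000 patterns × 2000 pairs: rejection rate
0.05 ± 0.02 at α = 0.05). The exact binomial variant and conditional logistic
regression are out of scope.

Only the *individual temporal diagnoses* appearing in retained patterns enter
the latent class model. A pattern is the conjunction of its items, so keeping
super-pattern and sub-pattern as separate indicators would build a
deterministic dependence into a model whose defining assumption is
conditional independence given class.

## Latent class model

Binary-indicator LCA: class weights π (length K), class-conditional Bernoulli
probabilities ρ (K × J). EM in log space; E-step via log-sum-exp, M-step in
closed form. Numerical choices:

- **Initialization:** π ~ flat Dirichlet, ρ entries uniform on (0.2, 0.8);
  `n_starts` independent restarts (default 20), best final likelihood kept.
- **ρ clamping** to [1e-6, 1−1e-6] prevents log(0) without materially moving
  estimates.
- **Convergence:** |Δℓ| < 1e-8 or 5000 iterations (defaults). If the
  iteration cap is hit, the reported likelihood and posteriors are
  re-synchronized with the final parameters so ℓ(π̂, ρ̂) always equals the
  reported value.
- **Identifiability:** classes are relabelled by descending π̂ after fitting;
  argmax assignment ties go to the lowest class index.
- **Free parameters:** P = (K−1) + K·J; AIC = −2ℓ + 2P and
  BIC = −2ℓ + P·ln N hold as exact identities for every fitted model.
- **Selection:** the sweep fits K = 3..8 by default with per-K derived seeds,
  reports percent reductions (IC_{K−1} − IC_K)/IC_{K−1} × 100 rounded to two
  decimals, and selects the minimum-BIC K (ties → smallest K).

EM ascent (ℓ non-decreasing every iteration), agreement of the likelihood
with brute-force enumeration to 1e-10, and label-permutation equivariance are
all asserted in the test suite.

## Subtype characterization

Per class (of assigned patients): feature prevalence in percent (2 decimals
for display); features at ≥ 10% prevalence form the high-prevalence set that
names the subtype (auto-labels concatenate up to the 5 most prevalent;
clinical naming is editorial, so overrides are supported); a class with no
feature at ≥ 5% is labelled "Other - no characteristic morbidity pattern".
Both thresholds are inclusive and configurable. The membership matrix reports
mean and SD (population SD, ddof = 0) of posterior membership by assigned
class, with off-diagonal means above 5% flagged; an empty class produces a
NaN row, not an error. Demographic summaries use class sizes as percent
denominators, 1-decimal percents, and mean (SD) age in years. No statistical
testing of demographic differences is performed — the tables are descriptive.

## Synthetic cohort generator

The generator defines the study conditions rather than serving as a tuning
dial. Defaults emulate a large pediatric primary-care cohort with eight
archetypal comorbidity subtypes (upper-respiratory/sleep, inflammatory skin,
seizure, asthma, low-morbidity residual, GI/GU, neurodevelopmental, physical
symptoms) over a 37-item timing-tagged vocabulary; mixing weights, per-class
item probabilities, demographics (sex, race/ethnicity, Medicaid, residence,
age means/SDs) and the 0.676 post-index visit probability are all
configuration with those defaults.

Given a patient's true class, timing-tagged features are independent
Bernoulli draws — exactly the product-Bernoulli structure the LCA assumes —
with timing-3 items suppressed when the post-index visit is absent, so their
*marginal* prevalence is deflated by the post-index probability relative to
the draw probability. Ages are truncated normal on [2, 19) per class. Visit
dates are integer day offsets from the index visit (PHI-free, sufficient for
the one-year insurance window); each case carries 0–2 extra earlier visits so
the prior-visit matching covariate varies. Per-visit payer lists
(Commercial/Medicaid/CHIP, pipe-delimited, sometimes multiple, sometimes
absent) deliberately exercise the index-visit rule, the one-year fallback and
the drop rule.

Controls are synthesized 1:1, exactly matched on sex, age category and
prior-visit count by reusing the case's visit skeleton, never obese, with
feature prevalences equal to the empirical case marginals deflated by a
configurable odds ratio (default 2) on the odds scale; timing-3 draw
probabilities are rescaled by the post-index fraction so the control
*marginal* hits its target. Exact synthesis-side matching makes the McNemar
pairing unambiguous; the matching ratio and age tolerance are configurable.

What the generator does **not** emulate: ICD-level coding noise, realistic
visit cadence, growth trajectories, BMI z-score computation (the obese flag
is carried as data), or correlated features *within* a class. Passing tests
therefore demonstrate correctness of the pipeline's logic and estimators
under the model's own assumptions — not robustness to real-EHR violations of
those assumptions (e.g. within-class dependence, informative missingness).

## Validation studies and problem sizes

- **Miner equivalence:** 100 random cohorts (≤ 30 patients, ≤ 8 tagged
  items), exact agreement with exhaustive enumeration.
- **McNemar calibration:** 1000 null patterns × 2000 pairs, correction off.
- **Parameter recovery:** 20 replicates of a three-class, 5000-case, 12-item
  scenario with block-separated ρ (0.8 vs 0.1) and weights (0.5, 0.3, 0.2),
  sweeping K = 2..5. The recovery vocabulary uses timings 1 and 2 only, since
  timing-3 within-class frequencies estimate 0.676·ρ rather than ρ by design.
  EM settings for this study are n_starts = 4, tol = 1e-7, max_iter = 500:
  the true-K fit converges in tens of iterations on well-separated data,
  while over-fitted K only drift along a near-flat likelihood ridge, so the
  cap changes nothing of scientific interest. Acceptance thresholds: median
  max-abs ρ̂ error ≤ 0.05, median max-abs π̂ error ≤ 0.03 after label
  matching, true K selected by BIC in ≥ 18/20 replicates.
- **Determinism:** two full pipeline runs with one seed must be byte-identical
  (all CSV floats use a fixed `%.10g` format; every RNG stream derives from
  the master seed via keyed `SeedSequence` children, so each stage is
  independently reproducible).

## Known limitations

- The asymptotic McNemar test is anti-conservative for very rare patterns
  (small b+c); the exact variant is deliberately not provided.
- Auto-generated subtype labels are mechanical; clinically meaningful names
  require the override mechanism.
- The generator's class-conditional independence makes recovery easier than
  on real data; selection of K on real cohorts is additionally sensitive to
  violations of conditional independence, which BIC does not diagnose.
- With small cohorts the BIC merges rare archetypes into the low-morbidity
  class (see the README example: 6 of 8 classes resolved at 3000 cases);
  this is expected small-sample behaviour, not an estimator defect.
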