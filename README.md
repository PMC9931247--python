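# obesity-lca

Temporal condition-pattern mining and latent class subtyping of pediatric
obesity cohorts.

## The problem

When a child first presents with an obese BMI, the diagnoses recorded around
that moment — at the visit immediately before (*pre-index*), at the first
obese visit itself (*index*), and at the visit immediately after
(*post-index*) — carry information about clinically distinct *subtypes* of
newly obese patients: some children arrive with asthma and allergic rhinitis,
others with seizure disorders, constipation, eczema, or no notable morbidity
at all. This package implements, as a tested and reusable pipeline, the
analysis needed to find such subtypes in visit-level EHR-like tables:

1. **Cohort construction** — identify each case patient's index visit (first
   obese BMI), require a pre-index visit for inclusion, tag every diagnosis
   with its visit timing (1/2/3), and derive demographics (sex, race/ethnicity
   with Hispanic-dominant classification, Medicaid/CHIP enrollment with a
   one-year fallback window and a drop rule for uninsured patients, age
   categories 2–4 / 5–11 / 12–18, urban residence).
2. **Sequential pattern mining** — SPADE-style discovery of frequent temporal
   condition patterns such as `1-ALL04, 2-EAR01` (vertical id-lists,
   Apriori candidate generation, exact supports, default minimum support 1%
   of case patients).
3. **Matched case-control filtering** — McNemar's test on 1:1 matched
   healthy-BMI controls; patterns significantly *more* common among cases
   (p < α, default 0.05) are retained, and their constituent individual
   temporal diagnoses become model features (using whole patterns *and* their
   sub-patterns together would violate conditional independence).
4. **Latent class analysis** — a mixture of product-Bernoulli distributions
   over the binary temporal-diagnosis indicators,

   ℓ = Σᵢ log Σₖ πₖ Πⱼ ρₖⱼ^yᵢⱼ (1−ρₖⱼ)^(1−yᵢⱼ),

   fitted by EM with multiple random restarts, swept over class counts
   K = 3..8 and selected by BIC (AIC reported alongside, with the
   percent-reduction table between successive K).
5. **Subtype characterization** — max-posterior assignment, per-class feature
   prevalence with a ≥ 10% high-prevalence naming rule and a ≥ 5%
   characterization floor ("no characteristic morbidity pattern" otherwise),
   the K × K mean (SD) posterior-membership matrix, and demographic summary
   tables.

Because real pediatric EHR data of this kind cannot be shared, the package
includes a first-class **synthetic cohort generator** with a known latent
class structure (eight archetypal comorbidity profiles by default), exact
synthesis-side matching of controls on sex, age category and prior-visit
count, and an odds-ratio dial for case/control feature enrichment. Every
downstream stage is validated against this ground truth.

## Worked example

```python
from obesity_lca.pipeline import PipelineConfig, run_all
from obesity_lca.synthetic_cohort import GeneratorConfig

config = PipelineConfig(generator=GeneratorConfig(n_cases=3000), n_starts=5, seed=7)
manifest = run_all(config, "demo")
for stage, counts in manifest["stages"].items():
    print(stage, counts)
```

prints (about 45 s on one CPU):

```
simulate {'n_cases_generated': 3000, 'n_controls_generated': 3000}
build {'n_patients_in': 6000, 'n_patients_retained': 5918, 'n_patients_excluded': 82, 'n_pairs': 2959}
mine {'n_patterns_mined': 46}
test {'n_patterns_tested': 46, 'n_patterns_significant': 30, 'n_features_selected': 21}
fit-lca {'n_patients_fit': 2959, 'n_features_fit': 21, 'selected_K': 6}
characterize {'n_profiles': 6}
```

Reading the counts: of 6000 generated patients, 82 were excluded (no
insurance record within a year of the index visit, plus their match
partners), leaving 2959 matched pairs. Mining found 46 patterns at ≥ 1%
support; 30 were significantly case-enriched, contributing 21 individual
temporal diagnoses as model features. The BIC chose 6 classes — at this
cohort size the model cleanly resolves the asthma, eczema,
neurodevelopmental, gastrointestinal/genitourinary and seizure archetypes
(e.g. the seizure class shows `2-Seizure Disorder` at 85.23% prevalence)
and pools the rarer respiratory/sleep and physical-symptom archetypes into
the large low-morbidity class; larger cohorts separate all eight.
`demo/report/` then contains the prevalence-by-class table, subtype labels,
membership matrix and demographic breakdowns; `demo/manifest.json` records
the full cohort accounting.

The same run is available from a shell:

```bash
obesity-lca run-all --seed 7 --outdir demo
obesity-lca mine --outdir demo --min-support 0.01   # re-run one stage
```

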