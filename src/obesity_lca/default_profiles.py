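"""Default study conditions for the synthetic cohort generator.

The defaults emulate a large pediatric primary-care population in which newly
obese patients fall into eight archetypal comorbidity subtypes:

1. upper-respiratory and sleep disorders,
2. inflammatory skin conditions,
3. seizure disorders and epilepsy,
4. asthma,
5. no characteristic morbidity pattern (the large residual group),
6. gastrointestinal/genitourinary symptoms,
7. neurodevelopmental disorders,
8. acute physical symptoms (fever, headaches, nausea).

``DEFAULT_VOCABULARY`` lists 37 timing-tagged diagnosis categories (timing 1 =
pre-index visit, 2 = index, 3 = post-index). ``DEFAULT_ITEM_PROBS`` gives, per
archetype, the probability that each temporal diagnosis is recorded for a
patient of that class (timing-3 items are additionally suppressed for patients
without a post-index visit). ``DEFAULT_MIXING_WEIGHTS`` are the archetype
proportions. Demographic profiles give per-class sex/race/insurance/residence
distributions and age means/SDs in years.

All of these are configuration defaults: every entry can be overridden through
:class:`obesity_lca.synthetic_cohort.GeneratorConfig`.
"""

from __future__ import annotations

import numpy as np

from .temporal import TemporalDiagnosis

# (timing, code, prevalence % in classes 1..8)
_PROFILE_ROWS: list[tuple[int, str, tuple[float, ...]]] = [
    (1, "Asthma w/o Status Asthmaticus", (4.58, 6.73, 3.00, 50.20, 4.86, 4.69, 2.96, 4.58)),
    (2, "Allergic Rhinitis", (9.63, 11.89, 0.63, 31.06, 4.20, 3.47, 2.39, 7.15)),
    (2, "Asthma w/o Status Asthmaticus", (6.08, 0.03, 2.84, 98.37, 0.27, 2.16, 3.53, 5.98)),
    (1, "Deafness hearing loss", (10.92, 0.99, 2.76, 2.09, 4.46, 2.82, 20.10, 0.17)),
    (1, "Chronic pharyngitis and tonsillitis", (33.05, 0.29, 0.16, 0.93, 0.79, 0.56, 0.62, 0.07)),
    (1, "ENT Disorders other", (7.53, 0.40, 0.87, 0.81, 1.32, 0.94, 2.29, 0.17)),
    (2, "Chronic pharyngitis and tonsillitis", (45.51, 0.27, 0.16, 0.26, 0.00, 0.19, 0.10, 0.34)),
    (3, "Chronic pharyngitis and tonsillitis", (33.99, 0.32, 0.39, 0.67, 0.06, 0.38, 0.62, 0.48)),
    (1, "Constipation", (0.73, 1.82, 1.34, 1.63, 0.17, 47.07, 1.87, 1.81)),
    (1, "Gasteroenteritis", (0.60, 1.84, 0.63, 0.73, 0.12, 1.97, 1.30, 22.56)),
    (2, "Constipation", (1.63, 1.68, 1.58, 1.88, 0.00, 61.76, 4.31, 1.98)),
    (2, "Gastroesophageal reflux", (3.17, 0.61, 3.55, 3.18, 1.15, 8.82, 4.21, 1.71)),
    (1, "Fever", (1.28, 1.63, 2.29, 2.42, 0.24, 1.78, 0.31, 30.02)),
    (1, "Nausea vomiting", (0.34, 0.00, 0.71, 0.42, 0.00, 1.88, 0.36, 20.00)),
    (1, "Urinary Symptoms", (1.50, 1.34, 0.39, 1.74, 2.15, 18.58, 0.68, 0.51)),
    (2, "Urinary Symptoms", (1.28, 1.66, 0.39, 1.16, 2.20, 17.60, 0.36, 1.71)),
    (1, "Headaches", (0.43, 0.11, 0.39, 1.09, 0.09, 0.23, 0.57, 28.10)),
    (1, "Seizure Disorder", (0.47, 0.16, 62.32, 0.22, 0.10, 0.80, 0.57, 0.96)),
    (1, "Sleep Problems", (21.79, 0.24, 0.87, 0.20, 0.23, 0.38, 1.77, 0.24)),
    (1, "Autism Spectrum Disorder", (0.09, 0.11, 3.16, 0.20, 0.02, 0.23, 26.81, 0.03)),
    (2, "Neurologic signs and symptoms", (1.84, 0.61, 10.19, 0.59, 1.54, 1.50, 11.12, 2.19)),
    (2, "Headaches", (1.11, 0.96, 2.05, 0.76, 0.40, 0.28, 1.14, 21.81)),
    (2, "Seizure Disorder", (0.68, 0.11, 79.15, 0.08, 0.03, 0.23, 1.35, 0.82)),
    (2, "Sleep Problems", (22.35, 0.29, 0.95, 0.40, 0.31, 0.80, 5.09, 1.57)),
    (2, "Developmental disorder", (3.42, 2.30, 17.69, 1.95, 2.37, 3.00, 49.82, 2.29)),
    (2, "Autism Spectrum Disorder", (0.47, 0.05, 4.82, 0.61, 0.01, 0.84, 47.12, 0.38)),
    (3, "Seizure Disorder", (0.47, 0.27, 46.84, 0.16, 0.07, 0.19, 0.78, 0.10)),
    (3, "Sleep Problems", (17.81, 0.48, 0.55, 0.40, 0.07, 0.00, 2.08, 0.55)),
    (3, "Developmental disorder", (2.31, 1.15, 10.82, 0.70, 1.15, 1.13, 36.21, 1.20)),
    (3, "Autism Spectrum Disorder", (0.39, 0.21, 2.29, 0.09, 0.00, 0.47, 29.87, 0.27)),
    (1, "Respiratory signs and symptoms", (11.90, 2.35, 1.26, 4.72, 1.85, 1.50, 0.88, 1.33)),
    (1, "Sleep Apnea", (23.54, 0.29, 1.18, 0.84, 0.43, 0.75, 0.42, 0.00)),
    (2, "Respiratory signs and symptoms", (12.37, 4.25, 1.34, 4.33, 1.68, 1.36, 1.25, 2.80)),
    (2, "Sleep Apnea", (26.50, 0.00, 0.79, 0.99, 0.03, 0.61, 0.36, 0.44)),
    (3, "Sleep Apnea", (19.82, 0.16, 0.87, 0.40, 0.03, 0.33, 0.99, 0.55)),
    (1, "Dermatitis and eczema", (1.54, 54.21, 0.32, 9.28, 0.42, 1.41, 2.13, 0.58)),
    (2, "Dermatitis and eczema", (2.40, 60.65, 1.66, 13.68, 0.08, 0.89, 2.86, 3.04)),
]

#: 37 timing-tagged diagnosis categories, in the order the profiles are stated.
DEFAULT_VOCABULARY: list[TemporalDiagnosis] = [
    TemporalDiagnosis(t, code) for t, code, _ in _PROFILE_ROWS
]

#: class-conditional Bernoulli probabilities, shape (8 classes, 37 features)
DEFAULT_ITEM_PROBS: np.ndarray = (
    np.array([row for _, _, row in _PROFILE_ROWS], dtype=float).T / 100.0
)

_CLASS_SIZES = np.array([2336, 3743, 1266, 6446, 28821, 2131, 1925, 2925], dtype=float)

#: archetype mixing proportions (sum to 1)
DEFAULT_MIXING_WEIGHTS: np.ndarray = _CLASS_SIZES / _CLASS_SIZES.sum()

#: fraction of patients with a post-index visit
DEFAULT_POST_INDEX_PROB = 0.676

RACE_CATEGORIES = [
    "Asian",
    "Black/African American",
    "White",
    "Hispanic",
    "Multiple Race",
    "Heterogeneous Other",
    "Unknown",
]

# per-class race-category percentages (order as RACE_CATEGORIES); normalized at use
_RACE_PCTS = np.array(
    [
        (2.6, 28.8, 47.3, 11.0, 1.3, 0.1, 8.9),
        (2.9, 45.2, 35.9, 7.3, 0.7, 0.2, 7.8),
        (2.2, 28.9, 50.8, 12.2, 1.4, 0.2, 4.3),
        (1.9, 52.3, 31.2, 7.9, 0.9, 0.1, 5.8),
        (2.2, 28.9, 51.7, 8.7, 1.0, 0.2, 7.4),
        (2.1, 31.8, 48.0, 9.8, 0.9, 0.2, 7.1),
        (3.0, 21.7, 56.2, 10.3, 1.4, 0.2, 7.3),
        (2.4, 41.4, 41.7, 8.2, 0.9, 0.1, 5.4),
    ]
)

_MALE_PCT = (55.3, 50.7, 57.7, 58.1, 54.8, 48.1, 77.6, 50.7)
_MEDICAID_PCT = (42.3, 46.6, 51.3, 50.7, 36.4, 41.4, 57.1, 44.6)
_PHILA_PCT = (31.5, 46.7, 31.3, 53.8, 32.5, 35.3, 30.3, 48.7)
_AGE_MEAN = (7.7, 6.8, 7.9, 8.2, 9.0, 8.2, 7.1, 9.5)
_AGE_SD = (4.0, 4.3, 4.8, 4.3, 4.7, 4.2, 4.3, 4.7)


def default_demographic_params() -> list[dict]:
    """Per-class demographic parameter dictionaries for the generator.

    Each dict holds: ``male_prob``, ``race_probs`` (over ``RACE_CATEGORIES``),
    ``medicaid_prob``, ``philadelphia_prob``, ``age_mean``/``age_sd`` (years),
    ``missing_index_insurance_prob`` (index visit has no payer recorded, so the
    one-year fallback scan is exercised) and ``no_insurance_prob`` (no payer on
    any visit: the patient is dropped downstream).
    """
    params = []
    for k in range(8):
        race = _RACE_PCTS[k] / _RACE_PCTS[k].sum()
        params.append(
            {
                "male_prob": _MALE_PCT[k] / 100.0,
                "race_probs": race.tolist(),
                "medicaid_prob": _MEDICAID_PCT[k] / 100.0,
                "philadelphia_prob": _PHILA_PCT[k] / 100.0,
                "age_mean": _AGE_MEAN[k],
                "age_sd": _AGE_SD[k],
                "missing_index_insurance_prob": 0.03,
                "no_insurance_prob": 0.002,
            }
        )
    return params
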