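"""Shared vocabulary for AADC-deficiency screening.

Aromatic l-amino acid decarboxylase deficiency (AADCd) is a rare autosomal
recessive neurotransmitter-synthesis disorder. Because almost no diagnosed
cases exist in any one health system, screening is framed around ten
*concepts* — symptoms and frequently co-occurring or differential conditions
(hypotonia, oculogyric crisis, developmental delay, ...) — that are common
enough to annotate and model individually, and whose co-occurrence flags a
patient for diagnostic work-up.

This module pins down the concept list, the mention modifiers, the 3-class
sentence label, note types, and the reference model settings distributed
with the package.
"""

from __future__ import annotations

from enum import IntEnum

#: The 10 concepts modeled by sentence classifiers, alphabetical.
CONCEPTS: tuple[str, ...] = (
    "autonomic_dysfunction",
    "cerebral_palsy",
    "developmental_delay",
    "epilepsy_or_seizures",
    "feeding_issues",
    "hypotonia",
    "insomnia",
    "mood_disturbance",
    "movement_disorders",
    "oculogyric_crisis",
)

#: Direct mentions of the disease itself are annotated for completeness but
#: never modeled: a chart that already names AADCd is already under
#: consideration and gains nothing from automated flagging.
AADCD_MENTION = "aadcd_mention"

ANNOTATED_CONCEPTS: tuple[str, ...] = CONCEPTS + (AADCD_MENTION,)

#: Epilepsy/seizures has a complex relationship with AADCd (oculogyric crises
#: are misread as seizures; true comorbid epilepsy is uncommon), so it is
#: excluded from the symptom-count ranking target while remaining a predictor.
NON_EPILEPSY_CONCEPTS: tuple[str, ...] = tuple(
    c for c in CONCEPTS if c != "epilepsy_or_seizures"
)

#: Mention modifiers collapsing a present concept to "negative qualified".
MODIFIERS: tuple[str, ...] = ("negated", "not_patient", "hypothetical")

NOTE_TYPES: tuple[str, ...] = ("pediatric_neurology", "eeg", "other")

#: Note types retained for modeling (the pediatric-neurology focused corpus).
MODELED_NOTE_TYPES: frozenset[str] = frozenset({"pediatric_neurology", "eeg"})


class Klass(IntEnum):
    """Per-sentence, per-concept 3-class label."""

    NEGATIVE = 0            # concept not present in the sentence
    NEGATIVE_QUALIFIED = 1  # present but negated / not-patient / hypothetical
    POSITIVE = 2            # present, unqualified

    @property
    def label(self) -> str:
        return _KLASS_LABELS[self]


_KLASS_LABELS = {
    Klass.NEGATIVE: "negative",
    Klass.NEGATIVE_QUALIFIED: "negative_qualified",
    Klass.POSITIVE: "positive",
}

KLASS_NAMES: tuple[str, ...] = ("negative", "negative_qualified", "positive")


#: Per-concept classifier and reduction settings selected during the original
#: development study (grid search by 5x2 cross-validated log-loss on a real
#: pediatric-neurology corpus). "param" is the SVM margin penalty C.
#: These ship as the default configuration for real-corpus use; synthetic
#: corpora are typically trained with generic settings instead.
REFERENCE_CONCEPT_SETTINGS: dict[str, dict] = {
    "autonomic_dysfunction": {"kernel": "rbf", "param": 0.01, "reduction": "max", "downsample": 0.05},
    "cerebral_palsy": {"kernel": "linear", "param": 0.1, "reduction": "noisy_or", "downsample": 1.0},
    "developmental_delay": {"kernel": "linear", "param": 0.1, "reduction": "noisy_or", "downsample": 0.95},
    "epilepsy_or_seizures": {"kernel": "linear", "param": 0.01, "reduction": "noisy_or", "downsample": 1.0},
    "feeding_issues": {"kernel": "linear", "param": 0.01, "reduction": "noisy_or", "downsample": 0.90},
    "hypotonia": {"kernel": "linear", "param": 0.01, "reduction": "noisy_or", "downsample": 0.60},
    "insomnia": {"kernel": "rbf", "param": 0.0001, "reduction": "noisy_or", "downsample": 0.60},
    "mood_disturbance": {"kernel": "linear", "param": 0.005, "reduction": "noisy_or", "downsample": 1.0},
    "movement_disorders": {"kernel": "linear", "param": 0.1, "reduction": "max", "downsample": 0.75},
    "oculogyric_crisis": {"kernel": "linear", "param": 8.0, "reduction": "max", "downsample": 1.0},
}

#: Reference Poisson rank-model coefficients fitted on the development
#: cohort's training + validation patients. The intercept was not published;
#: it is set to 0, which leaves the patient ordering unchanged (the ranking
#: is intercept-invariant) but means absolute scores are site-specific.
REFERENCE_RANK_COEFFICIENTS: dict[str, float] = {
    "autonomic_dysfunction": 0.008,
    "cerebral_palsy": 0.432,
    "developmental_delay": 1.299,
    "epilepsy_or_seizures": -0.426,
    "feeding_issues": 0.705,
    "hypotonia": 0.351,
    "insomnia": 0.283,
    "mood_disturbance": 0.565,
    "movement_disorders": 0.508,
    "oculogyric_crisis": 0.919,
}
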