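"""PHI-free synthetic corpus generator.

Emulates the statistical structure the screening pipeline assumes — multi-
note patients, sentences containing concept mentions at controlled
patient-level prevalences, negated / not-patient / hypothetical phrasings —
and emits gold BRAT annotations plus patient-level truth, so every
downstream stage is testable without any clinical data.

What it does NOT emulate: realistic clinical language, section structure,
templated note boilerplate mined from real notes, or annotator noise. See
docs/methods.md for what passing tests on this generator do and do not show
about performance on real notes.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .concepts import CONCEPTS, MODIFIERS, NON_EPILEPSY_CONCEPTS, Klass
from .corpus import NoteRecord, SpanAnnotation, format_brat

__all__ = ["SynthConfig", "SynthCorpus", "default_lexicon", "load_lexicon",
           "generate_corpus", "emit_brat", "audit_prevalence"]


#: Patient-level concept prevalences used as generator defaults; these are
#: the prevalences observed in the development study's annotated validation
#: cohort, so synthetic corpora mirror that class balance.
DEFAULT_PREVALENCE: dict[str, float] = {
    "autonomic_dysfunction": 0.117,
    "cerebral_palsy": 0.230,
    "developmental_delay": 0.540,
    "epilepsy_or_seizures": 0.704,
    "feeding_issues": 0.361,
    "hypotonia": 0.186,
    "insomnia": 0.082,
    "mood_disturbance": 0.320,
    "movement_disorders": 0.041,
    "oculogyric_crisis": 0.045,
}

_TEMPLATE_KEYS = {"negated": "negated_templates",
                  "hypothetical": "hypothetical_templates",
                  "not_patient": "not_patient_templates"}


def load_lexicon(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        lex = yaml.safe_load(fh)
    _validate_lexicon(lex)
    return lex


def default_lexicon() -> dict:
    ref = importlib.resources.files("rarescreen.data") / "lexicon.yaml"
    lex = yaml.safe_load(ref.read_text(encoding="utf-8"))
    _validate_lexicon(lex)
    return lex


def _validate_lexicon(lex: dict) -> None:
    for concept in CONCEPTS:
        if not lex.get("concept_phrases", {}).get(concept):
            raise ValueError(f"lexicon has no phrases for concept {concept!r}")
    for key in ("positive_templates", "filler_sentences", *_TEMPLATE_KEYS.values()):
        if not lex.get(key):
            raise ValueError(f"lexicon missing {key!r}")
        for t in lex[key]:
            if key != "filler_sentences" and "{phrase}" not in t:
                raise ValueError(f"template {t!r} lacks a {{phrase}} slot")


@dataclass
class SynthConfig:
    """Generator knobs.

    All probabilities are per-event Bernoulli rates. ``mention_rate`` is the
    chance that any one sentence of a truly-positive patient mentions that
    concept; ``modifier_rate`` the chance such a mention carries a modifier
    (drawn uniformly from the three); ``distractor_rate`` the chance a
    sentence of a truly-negative patient emits a qualified (never positive)
    mention. ``case_fraction`` mixes in multi-symptom "case" patients who
    carry ``case_symptom_range`` of the 9 non-epilepsy concepts — the
    screening targets the pipeline should surface. ``concept_correlation``
    is a Gaussian-copula correlation across concepts within a patient.
    """

    n_patients: int = 200
    notes_per_patient: tuple[int, int] = (2, 4)
    sentences_per_note: tuple[int, int] = (4, 8)
    concept_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    mention_rate: float = 0.3
    modifier_rate: float = 0.15
    distractor_rate: float = 0.02
    case_fraction: float = 0.0
    case_symptom_range: tuple[int, int] = (6, 9)
    concept_correlation: float = 0.0
    note_type_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)
    seed: int = 0
    lexicon: dict | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        probs = [self.mention_rate, self.modifier_rate, self.distractor_rate,
                 self.case_fraction, self.concept_correlation,
                 *self.concept_prevalence.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        unknown = set(self.concept_prevalence) - set(CONCEPTS)
        if unknown:
            raise ValueError(f"prevalence given for unknown concepts {sorted(unknown)}")
        if self.lexicon is None:
            self.lexicon = default_lexicon()
        else:
            _validate_lexicon(self.lexicon)


@dataclass
class SynthCorpus:
    notes: list[NoteRecord]
    gold_annotations: list[SpanAnnotation]
    patient_truth: dict[str, frozenset[str]]
    #: (note_id, sentence_index, concept) -> intended Klass for every
    #: non-negative label the generator emitted; everything else is negative.
    intended_labels: dict[tuple[str, int, str], Klass]

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for note in self.notes:
            seen.setdefault(note.patient_id, None)
        return list(seen)


def _draw_truth(cfg: SynthConfig, rng: np.random.Generator) -> frozenset[str]:
    prev = cfg.concept_prevalence
    if rng.random() < cfg.case_fraction:
        lo, hi = cfg.case_symptom_range
        m = int(rng.integers(lo, hi + 1))
        picks = rng.choice(len(NON_EPILEPSY_CONCEPTS), size=m, replace=False)
        truth = {NON_EPILEPSY_CONCEPTS[i] for i in picks}
        if rng.random() < prev.get("epilepsy_or_seizures", 0.0):
            truth.add("epilepsy_or_seizures")
        return frozenset(truth)
    rho = cfg.concept_correlation
    if rho > 0.0:
        shared = rng.standard_normal()
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(len(CONCEPTS))
        return frozenset(
            c for i, c in enumerate(CONCEPTS)
            if prev.get(c, 0.0) > 0.0 and z[i] > norm.ppf(1.0 - prev[c])
        )
    return frozenset(c for c in CONCEPTS if rng.random() < prev.get(c, 0.0))


def _mention_sentence(
    cfg: SynthConfig, rng: np.random.Generator, concept: str,
    modifiers: frozenset[str],
) -> tuple[str, int, int]:
    """Render a mention sentence; returns (text, phrase_start, phrase_end)."""
    lex = cfg.lexicon
    phrase = lex["concept_phrases"][concept][
        int(rng.integers(len(lex["concept_phrases"][concept])))]
    if modifiers:
        # one modifier per mention; cue template matches that modifier
        (mod,) = tuple(modifiers)
        templates = lex[_TEMPLATE_KEYS[mod]]
    else:
        templates = lex["positive_templates"]
    template = templates[int(rng.integers(len(templates)))]
    start = template.index("{phrase}")
    text = template.replace("{phrase}", phrase)
    return text, start, start + len(phrase)


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Draw a corpus: patient truths, notes, mention sentences with gold
    spans. Deterministic for a fixed config (seed included)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lex = cfg.lexicon
    notes: list[NoteRecord] = []
    annotations: list[SpanAnnotation] = []
    truth: dict[str, frozenset[str]] = {}
    intended: dict[tuple[str, int, str], Klass] = {}

    base_date = np.datetime64("2019-01-01")
    for p in range(cfg.n_patients):
        pid = f"P{p:05d}"
        truth[pid] = _draw_truth(cfg, rng)
        positives = [c for c in CONCEPTS if c in truth[pid]]
        negatives = [c for c in CONCEPTS if c not in truth[pid]]
        n_notes = int(rng.integers(cfg.notes_per_patient[0],
                                   cfg.notes_per_patient[1] + 1))
        for j in range(n_notes):
            note_id = f"{pid}-N{j:02d}"
            note_type = ["pediatric_neurology", "eeg", "other"][
                int(rng.choice(3, p=cfg.note_type_probs))]
            n_sent = int(rng.integers(cfg.sentences_per_note[0],
                                      cfg.sentences_per_note[1] + 1))
            pieces: list[str] = []
            offset = 0
            for s in range(n_sent):
                mentioned = [c for c in positives if rng.random() < cfg.mention_rate]
                distract = [c for c in negatives if rng.random() < cfg.distractor_rate]
                candidates = mentioned + distract
                if candidates:
                    concept = candidates[int(rng.integers(len(candidates)))]
                    if concept in truth[pid] and rng.random() >= cfg.modifier_rate:
                        mods: frozenset[str] = frozenset()
                        klass = Klass.POSITIVE
                    else:
                        mods = frozenset({MODIFIERS[int(rng.integers(3))]})
                        klass = Klass.NEGATIVE_QUALIFIED
                    text, ps, pe = _mention_sentence(cfg, rng, concept, mods)
                    annotations.append(SpanAnnotation(
                        note_id=note_id, concept=concept,
                        start=offset + ps, end=offset + pe, modifiers=mods,
                    ))
                    intended[(note_id, s, concept)] = klass
                else:
                    fillers = lex["filler_sentences"]
                    text = fillers[int(rng.integers(len(fillers)))]
                pieces.append(text)
                offset += len(text) + 1  # sentences joined by a single space
            date = str(base_date + np.timedelta64(30 * j + int(rng.integers(30)), "D"))
            notes.append(NoteRecord(
                patient_id=pid, note_id=note_id, note_type=note_type,
                date=date, text=" ".join(pieces),
            ))
    return SynthCorpus(notes=notes, gold_annotations=annotations,
                       patient_truth=truth, intended_labels=intended)


def emit_brat(corpus: SynthCorpus, out_dir: str | Path) -> list[Path]:
    """Write the corpus as a BRAT directory: ``notes.csv`` plus one ``.txt``
    and ``.ann`` per note (empty ``.ann`` when a note has no annotations)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_note: dict[str, list[SpanAnnotation]] = {}
    for ann in corpus.gold_annotations:
        by_note.setdefault(ann.note_id, []).append(ann)
    written: list[Path] = []
    meta_path = out_dir / "notes.csv"
    with open(meta_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "note_id", "note_type", "date", "text_path"])
        for note in corpus.notes:
            txt = out_dir / f"{note.note_id}.txt"
            ann = out_dir / f"{note.note_id}.ann"
            txt.write_text(note.text, encoding="utf-8")
            ann.write_text(
                format_brat(by_note.get(note.note_id, []), note.text),
                encoding="utf-8")
            writer.writerow([note.patient_id, note.note_id, note.note_type,
                             note.date, txt.name])
            written += [txt, ann]
    return [meta_path] + written


def audit_prevalence(corpus: SynthCorpus) -> pd.DataFrame:
    """Per-concept realized patient prevalence (positive patients / total)
    and positive-sentence count; empty corpus gives an empty table."""
    pids = corpus.patient_ids
    n = len(pids)
    if n == 0:
        return pd.DataFrame(
            columns=["patient_prevalence", "sentence_positive_count"],
            index=pd.Index([], name="concept"))
    pos_sent = {c: 0 for c in CONCEPTS}
    for ann in corpus.gold_annotations:
        if ann.concept in pos_sent and ann.is_positive:
            pos_sent[ann.concept] += 1
    rows = {
        c: (sum(c in corpus.patient_truth[p] for p in pids) / n, pos_sent[c])
        for c in CONCEPTS
    }
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["patient_prevalence", "sentence_positive_count"],
    ).rename_axis("concept")
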