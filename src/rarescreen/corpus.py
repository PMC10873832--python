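"""Corpus data model and ingest.

Notes, BRAT standoff annotations, sentence segmentation, annotation-to-
sentence alignment, 3-class label derivation, and patient-level dataset
splitting/partitioning.

Offsets everywhere are 0-based, half-open character indices on the raw note
text (the BRAT convention); every span read from a ``.ann`` file is checked
against the note text it claims to annotate.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .concepts import ANNOTATED_CONCEPTS, CONCEPTS, MODIFIERS, NOTE_TYPES, Klass

__all__ = [
    "NoteRecord",
    "SpanAnnotation",
    "SentenceRecord",
    "SentenceLabel",
    "DatasetSplit",
    "PartitionMap",
    "BratParseError",
    "AnnotationIntegrityError",
    "read_brat_standoff",
    "format_brat",
    "segment_sentences",
    "align_annotations",
    "collapse_modifiers",
    "derive_sentence_labels",
    "split_by_patient",
    "partition_patients",
    "filter_notes",
    "load_corpus_dir",
]


class BratParseError(ValueError):
    """A standoff line that cannot be parsed; the message names the line."""


class AnnotationIntegrityError(ValueError):
    """An annotation whose offsets disagree with the note text."""


@dataclass(frozen=True)
class NoteRecord:
    patient_id: str
    note_id: str
    note_type: str
    date: str  # ISO-8601
    text: str

    def __post_init__(self) -> None:
        if self.note_type not in NOTE_TYPES:
            raise ValueError(f"unknown note_type {self.note_type!r}")
        if not self.text:
            raise ValueError(f"note {self.note_id!r} has empty text")


@dataclass(frozen=True)
class SpanAnnotation:
    """A concept mention: character span plus modifier set."""

    note_id: str
    concept: str
    start: int
    end: int
    modifiers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.concept not in ANNOTATED_CONCEPTS:
            raise ValueError(f"unknown concept {self.concept!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")
        unknown = set(self.modifiers) - set(MODIFIERS)
        if unknown:
            raise ValueError(f"unknown modifiers {sorted(unknown)}")

    @property
    def is_positive(self) -> bool:
        """Unqualified mention — counts as evidence for the patient."""
        return not self.modifiers


@dataclass(frozen=True)
class SentenceRecord:
    note_id: str
    patient_id: str
    sentence_index: int
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class SentenceLabel:
    note_id: str
    sentence_index: int
    concept: str
    klass: Klass


@dataclass(frozen=True)
class DatasetSplit:
    assignment: dict[str, str]  # patient_id -> train | validation | test
    fractions: tuple[float, float, float]
    seed: int

    def patients(self, subset: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == subset]


@dataclass(frozen=True)
class PartitionMap:
    assignment: dict[str, int]
    k: int
    seed: int

    def patients(self, partition: int) -> list[str]:
        return [p for p, q in self.assignment.items() if q == partition]


# --------------------------------------------------------------------------
# BRAT standoff
# --------------------------------------------------------------------------

def _normalize_label(label: str) -> str:
    return label.strip().lower()


_CONCEPT_BY_LABEL = {c: c for c in ANNOTATED_CONCEPTS}
_MODIFIER_BY_LABEL = {m: m for m in MODIFIERS} | {"notpatient": "not_patient"}


def read_brat_standoff(ann_content: str, note_text: str) -> list[SpanAnnotation]:
    """Parse a BRAT ``.ann`` document against its ``.txt`` note.

    T-lines (``Tn<TAB>Label start end<TAB>surface``) become annotations;
    A-lines (``An<TAB>Modifier Tn``) bind modifiers to them. The surface
    text of every T-line must equal ``note_text[start:end]`` exactly.
    Unknown concept labels are skipped with a warning; malformed lines and
    offset mismatches raise.
    """
    entities: dict[str, dict] = {}
    skipped: set[str] = set()
    modifier_bindings: list[tuple[str, str, str]] = []

    for lineno, raw in enumerate(ann_content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tag = line[0]
        if tag == "T":
            parts = line.split("\t")
            if len(parts) != 3:
                raise BratParseError(f"line {lineno}: expected 3 tab fields: {line!r}")
            tid, spec, surface = parts
            m = re.fullmatch(r"(\S+)\s+(\d+)\s+(\d+)", spec.strip())
            if m is None:
                raise BratParseError(
                    f"line {lineno}: cannot parse entity spec {spec!r} "
                    "(discontinuous spans are unsupported)"
                )
            label, start, end = m.group(1), int(m.group(2)), int(m.group(3))
            concept = _CONCEPT_BY_LABEL.get(_normalize_label(label))
            if concept is None:
                warnings.warn(
                    f"line {lineno}: unknown concept label {label!r}; skipped",
                    stacklevel=2,
                )
                skipped.add(tid)
                continue
            if not (0 <= start < end <= len(note_text)):
                raise AnnotationIntegrityError(
                    f"line {lineno}: span [{start}, {end}) outside note of "
                    f"length {len(note_text)}"
                )
            if note_text[start:end] != surface:
                raise AnnotationIntegrityError(
                    f"line {lineno}: surface {surface!r} does not match note "
                    f"text {note_text[start:end]!r} at [{start}, {end})"
                )
            entities[tid] = {"concept": concept, "start": start, "end": end,
                             "modifiers": set()}
        elif tag == "A":
            parts = line.split("\t")
            if len(parts) != 2:
                raise BratParseError(f"line {lineno}: expected 2 tab fields: {line!r}")
            fields = parts[1].split()
            if len(fields) != 2:
                raise BratParseError(f"line {lineno}: cannot parse attribute {parts[1]!r}")
            mod_label, target = fields
            modifier = _MODIFIER_BY_LABEL.get(_normalize_label(mod_label))
            if modifier is None:
                warnings.warn(
                    f"line {lineno}: unknown modifier {mod_label!r}; skipped",
                    stacklevel=2,
                )
                continue
            modifier_bindings.append((str(lineno), modifier, target))
        else:
            # relation/event/note lines are out of scope; ignore silently
            continue

    for lineno, modifier, target in modifier_bindings:
        if target in skipped:
            continue
        if target not in entities:
            raise BratParseError(
                f"line {lineno}: attribute bound to unknown entity {target!r}"
            )
        entities[target]["modifiers"].add(modifier)

    return [
        SpanAnnotation(
            note_id="", concept=e["concept"], start=e["start"], end=e["end"],
            modifiers=frozenset(e["modifiers"]),
        )
        for e in entities.values()
    ]


_BRAT_LABEL = {c: c.capitalize() for c in ANNOTATED_CONCEPTS}
_BRAT_MODIFIER = {"negated": "Negated", "not_patient": "Not_patient",
                  "hypothetical": "Hypothetical"}


def format_brat(annotations: list[SpanAnnotation], note_text: str) -> str:
    """Serialize annotations as BRAT standoff text (T-lines then A-lines)."""
    lines: list[str] = []
    attr_lines: list[str] = []
    a_idx = 1
    ordered = sorted(annotations, key=lambda a: (a.start, a.end, a.concept))
    for i, ann in enumerate(ordered, start=1):
        surface = note_text[ann.start:ann.end]
        if "\n" in surface:
            raise AnnotationIntegrityError(
                f"annotation [{ann.start}, {ann.end}) crosses a newline"
            )
        lines.append(f"T{i}\t{_BRAT_LABEL[ann.concept]} {ann.start} {ann.end}\t{surface}")
        for mod in sorted(ann.modifiers):
            attr_lines.append(f"A{a_idx}\t{_BRAT_MODIFIER[mod]} T{i}")
            a_idx += 1
    out = "\n".join(lines + attr_lines)
    return out + "\n" if out else ""


# --------------------------------------------------------------------------
# Sentence segmentation
# --------------------------------------------------------------------------

#: Tokens before a period that do not terminate a sentence.
_ABBREVIATIONS = frozenset({
    "dr", "mr", "mrs", "ms", "st", "vs", "etc", "approx", "dx", "hx",
    "e.g", "i.e", "pt", "wk", "mo", "yr",
})

_TERMINALS = ".!?"
_CLOSERS = "\"')]"


def _is_abbreviation(text: str, dot_index: int) -> bool:
    j = dot_index
    i = j - 1
    while i >= 0 and (text[i].isalnum() or text[i] == "."):
        i -= 1
    token = text[i + 1:j].lower().rstrip(".")
    if not token:
        return False
    if token in _ABBREVIATIONS:
        return True
    # single-letter initials ("J. Smith")
    return len(token) == 1 and token.isalpha() and text[dot_index - 1].isupper()


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Deterministic rule-based sentence segmentation.

    Splits on terminal punctuation (with an abbreviation guard, requiring
    the next sentence to open with an uppercase letter or digit) and on
    newlines. Returns ordered, non-overlapping, whitespace-trimmed half-open
    spans covering all non-whitespace content; empty text gives ``[]``.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    start: int | None = None
    i = 0
    while i < n:
        ch = text[i]
        if start is None:
            if not ch.isspace():
                start = i
            i += 1
            continue
        if ch == "\n":
            end = i
            while end > start and text[end - 1].isspace():
                end -= 1
            if end > start:
                spans.append((start, end))
            start = None
            i += 1
            continue
        if ch in _TERMINALS:
            j = i + 1
            while j < n and text[j] in _CLOSERS:
                j += 1
            k = j
            while k < n and text[k].isspace():
                k += 1
            boundary = (k == n) or (k > j and (text[k].isupper() or text[k].isdigit()))
            if boundary and not (ch == "." and _is_abbreviation(text, i)):
                spans.append((start, j))
                start = None
                i = k
                continue
        i += 1
    if start is not None:
        end = n
        while end > start and text[end - 1].isspace():
            end -= 1
        if end > start:
            spans.append((start, end))
    return spans


def sentences_for_note(note: NoteRecord) -> list[SentenceRecord]:
    return [
        SentenceRecord(
            note_id=note.note_id, patient_id=note.patient_id,
            sentence_index=i, start=s, end=e, text=note.text[s:e],
        )
        for i, (s, e) in enumerate(segment_sentences(note.text))
    ]


# --------------------------------------------------------------------------
# Annotation -> sentence alignment and label derivation
# --------------------------------------------------------------------------

def align_annotations(
    sentences: list[SentenceRecord],
    annotations: list[SpanAnnotation],
    note_length: int | None = None,
) -> dict[tuple[int, str], list[frozenset[str]]]:
    """Map each (sentence_index, concept) to the modifier sets of the
    annotations overlapping that sentence.

    A sentence is marked for a concept iff its span overlaps the annotation
    span by at least one character; an annotation crossing a sentence
    boundary marks every overlapped sentence. One entry per overlapping
    annotation, so downstream collapse can apply positive-dominates.
    """
    if note_length is not None:
        for ann in annotations:
            if ann.end > note_length:
                raise AnnotationIntegrityError(
                    f"annotation [{ann.start}, {ann.end}) outside note of "
                    f"length {note_length}"
                )
    marked: dict[tuple[int, str], list[frozenset[str]]] = {}
    for ann in annotations:
        for sent in sentences:
            if ann.start < sent.end and sent.start < ann.end:  # >=1 char overlap
                marked.setdefault((sent.sentence_index, ann.concept), []).append(
                    frozenset(ann.modifiers)
                )
    return marked


def collapse_modifiers(concept_marked: bool, modifiers: frozenset[str]) -> Klass:
    """Collapse a mention's modifier set to the 3-class label.

    Unmarked sentences are negative; a marked, unmodified mention is
    positive; any of negated / not-patient / hypothetical collapses to the
    single "negative qualified" class (too few examples of each to model
    separately).
    """
    if not concept_marked:
        return Klass.NEGATIVE
    return Klass.NEGATIVE_QUALIFIED if modifiers else Klass.POSITIVE


def derive_sentence_labels(
    sentences: list[SentenceRecord],
    annotations: list[SpanAnnotation],
    concepts: tuple[str, ...] = CONCEPTS,
    note_length: int | None = None,
) -> list[SentenceLabel]:
    """Per-(sentence, concept) 3-class labels for one note.

    When several same-concept annotations touch one sentence, positive
    dominates negative-qualified: a sentence that both asserts and negates a
    concept still evidences its presence.
    """
    marked = align_annotations(sentences, annotations, note_length=note_length)
    labels = []
    for sent in sentences:
        for concept in concepts:
            mods = marked.get((sent.sentence_index, concept))
            if mods is None:
                klass = Klass.NEGATIVE
            elif any(not m for m in mods):
                klass = Klass.POSITIVE
            else:
                klass = Klass.NEGATIVE_QUALIFIED
            labels.append(
                SentenceLabel(sent.note_id, sent.sentence_index, concept, klass)
            )
    return labels


# --------------------------------------------------------------------------
# Patient-level splitting and partitioning
# --------------------------------------------------------------------------

def split_by_patient(
    patient_ids: list[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Assign whole patients to train/validation/test.

    Assignment is by seeded shuffle then contiguous slicing; validation and
    test sizes are rounded to the nearest integer and the remainder goes to
    train (training is kept as large as possible because several concepts
    are rare). Splitting by patient, never by sentence, prevents leakage of
    a patient's language between sets.
    """
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("patient_ids must be unique")
    if len(patient_ids) < 3:
        raise ValueError("need at least 3 patients to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = [patient_ids[i] for i in rng.permutation(len(patient_ids))]
    n = len(order)
    n_val = int(np.floor(fractions[1] * n + 0.5))
    n_test = int(np.floor(fractions[2] * n + 0.5))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("fractions leave a negative subset")
    assignment = {}
    for idx, pid in enumerate(order):
        if idx < n_train:
            assignment[pid] = "train"
        elif idx < n_train + n_val:
            assignment[pid] = "validation"
        else:
            assignment[pid] = "test"
    return DatasetSplit(assignment=assignment, fractions=tuple(fractions), seed=seed)


def partition_patients(patient_ids: list[str], k: int, seed: int = 0) -> PartitionMap:
    """Seeded shuffle then round-robin into k partitions (sizes differ ≤1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(patient_ids):
        raise ValueError(f"k={k} exceeds {len(patient_ids)} patients")
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("patient_ids must be unique")
    rng = np.random.default_rng(seed)
    order = [patient_ids[i] for i in rng.permutation(len(patient_ids))]
    return PartitionMap(
        assignment={pid: i % k for i, pid in enumerate(order)}, k=k, seed=seed
    )


def filter_notes(notes: list[NoteRecord], allowed: set[str]) -> list[NoteRecord]:
    """Order-preserving note-type filter (metadata stand-in for the original
    pediatric-neurology / EEG restriction)."""
    return [n for n in notes if n.note_type in allowed]


# --------------------------------------------------------------------------
# Directory layout: notes.csv + <note_id>.txt + <note_id>.ann
# --------------------------------------------------------------------------

def load_corpus_dir(corpus_dir: str | Path) -> tuple[list[NoteRecord], list[SpanAnnotation]]:
    """Read a corpus directory: ``notes.csv`` metadata plus one ``.txt`` (and
    optional ``.ann``) file per note. Returns notes and annotations with
    ``note_id`` filled in."""
    corpus_dir = Path(corpus_dir)
    meta_path = corpus_dir / "notes.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata table {meta_path}")
    notes: list[NoteRecord] = []
    annotations: list[SpanAnnotation] = []
    with open(meta_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            text = (corpus_dir / row["text_path"]).read_text(encoding="utf-8")
            note = NoteRecord(
                patient_id=row["patient_id"], note_id=row["note_id"],
                note_type=row["note_type"], date=row["date"], text=text,
            )
            notes.append(note)
            ann_path = (corpus_dir / row["text_path"]).with_suffix(".ann")
            if ann_path.exists():
                for ann in read_brat_standoff(ann_path.read_text(encoding="utf-8"), text):
                    annotations.append(
                        SpanAnnotation(
                            note_id=note.note_id, concept=ann.concept,
                            start=ann.start, end=ann.end, modifiers=ann.modifiers,
                        )
                    )
    ids = [n.note_id for n in notes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate note_id in corpus")
    return notes, annotations
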