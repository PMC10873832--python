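"""End-to-end orchestration.

Stages communicate only through files under one output directory, so any
stage can be inspected or replaced, and the chain can be re-run piecemeal
on a new site's data:

    synth    -> corpus/ (notes.csv, *.txt, *.ann), truth.csv
    ingest   -> sentences.csv, labels.csv, splits.json
    train    -> models/ (featurizer + one calibrated classifier per concept)
    score    -> predictions.csv (per sentence x concept, 3 probabilities)
    reduce   -> reductions.json, patient_matrix.csv
    rank     -> rank_model.json, ranked.csv
    evaluate -> concept_metrics.csv, metrics.json, review_order.csv, clusters.csv

Every stage writes artifacts atomically and drops a manifest (config echo,
seeds, input hashes) beside them; re-running a stage with the same config
reproduces its artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CalibratedConceptClassifier
from .concepts import CONCEPTS, MODELED_NOTE_TYPES, REFERENCE_CONCEPT_SETTINGS, Klass
from .corpus import (
    NoteRecord,
    filter_notes,
    load_corpus_dir,
    derive_sentence_labels,
    partition_patients,
    sentences_for_note,
    split_by_patient,
)
from .evaluation import (
    ReviewTable2x2,
    chi_square_yates,
    cluster_diagnostics,
    concept_metrics,
    fisher_exact_2x2,
    select_extremes,
)
from .features import SentenceFeaturizer
from .ranking import PoissonRanker, rank_patients, symptom_count_target, d_squared
from .reduction import (
    REDUCTION_TIEBREAK_ORDER,
    ReductionKind,
    build_patient_gold,
    patient_concept_scores,
    reduce_probabilities,
    select_reduction,
)
from .synthetic import SynthConfig, audit_prevalence, emit_brat, generate_corpus

STAGES = ("synth", "ingest", "train", "score", "reduce", "rank", "evaluate")

#: Closed-form reduction kinds tried during validation selection (trained
#: combiners are available through the reduction module but are not part of
#: the default pipeline sweep).
_DEFAULT_CANDIDATES = tuple(
    k for k in REDUCTION_TIEBREAK_ORDER
    if k in (ReductionKind.NOISY_OR, ReductionKind.MAX,
             ReductionKind.MEAN, ReductionKind.MIN)
)


class PipelineDependencyError(FileNotFoundError):
    """An upstream artifact required by the requested stage is missing."""


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    corpus_dir: str | None = None  # default: <out_dir>/corpus
    seed: int = 0
    # synth
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    # ingest
    allowed_note_types: list[str] = field(
        default_factory=lambda: sorted(MODELED_NOTE_TYPES))
    k_partitions: int = 10
    dev_partition: int = 0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    # features / train
    min_df: float = 0.05
    max_df: float = 0.95
    embed_dim: int = 768
    classifier: str = "generic"  # generic | reference
    generic_kernel: str = "linear"
    generic_C: float = 1.0
    generic_downsample: float = 1.0
    # reduce
    select_reductions: bool = True
    # evaluate
    k_review: int = 100
    n_clusters: int = 5
    high_symptom_threshold: int = 6
    top_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.split_fractions = tuple(cfg.split_fractions)
        return cfg

    @property
    def corpus_path(self) -> Path:
        return Path(self.corpus_dir) if self.corpus_dir else Path(self.out_dir) / "corpus"


# --------------------------------------------------------------------------
# small I/O helpers
# --------------------------------------------------------------------------

def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _write_csv(path: Path, frame: pd.DataFrame, index: bool = False) -> None:
    _atomic_write(path, frame.to_csv(index=index, float_format="%.10g",
                                     lineterminator="\n"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(out: Path, stage: str, cfg: PipelineConfig,
              inputs: list[Path], outputs: list[Path]) -> None:
    doc = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {str(p): _sha256(p) for p in inputs if p.is_file()},
        "outputs": [str(p) for p in outputs],
    }
    _atomic_write(out / f"{stage}.manifest.json",
                  json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")


def _require(cfg_stage: str, *paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise PipelineDependencyError(
                f"stage {cfg_stage!r} needs missing upstream artifact {p} "
                "(run the earlier stages first)")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_synth(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth_cfg = SynthConfig(**{"seed": cfg.seed, **cfg.synth})
    corpus = generate_corpus(synth_cfg)
    emit_brat(corpus, cfg.corpus_path)
    truth = pd.DataFrame(
        [{"patient_id": pid, **{c: (c in t) for c in CONCEPTS}}
         for pid, t in corpus.patient_truth.items()])
    _write_csv(out / "truth.csv", truth)
    _write_csv(out / "prevalence_audit.csv", audit_prevalence(corpus), index=True)
    outputs = [cfg.corpus_path / "notes.csv", out / "truth.csv"]
    _manifest(out, "synth", cfg, [], outputs)
    return outputs


def stage_ingest(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _require("ingest", cfg.corpus_path / "notes.csv")
    notes, annotations = load_corpus_dir(cfg.corpus_path)
    notes = filter_notes(notes, set(cfg.allowed_note_types))
    kept_ids = {n.note_id for n in notes}
    ann_by_note: dict[str, list] = {}
    for ann in annotations:
        if ann.note_id in kept_ids:
            ann_by_note.setdefault(ann.note_id, []).append(ann)

    sent_rows, label_rows = [], []
    for note in notes:
        sents = sentences_for_note(note)
        for s in sents:
            sent_rows.append((s.note_id, s.patient_id, s.sentence_index,
                              s.start, s.end, s.text))
        for lab in derive_sentence_labels(sents, ann_by_note.get(note.note_id, []),
                                          note_length=len(note.text)):
            if lab.klass != Klass.NEGATIVE:
                label_rows.append((lab.note_id, lab.sentence_index,
                                   lab.concept, int(lab.klass)))
    sentences = pd.DataFrame(sent_rows, columns=[
        "note_id", "patient_id", "sentence_index", "start", "end", "text"])
    labels = pd.DataFrame(label_rows, columns=[
        "note_id", "sentence_index", "concept", "klass"])

    patient_ids = sorted({n.patient_id for n in notes})
    partition = partition_patients(patient_ids, cfg.k_partitions, seed=cfg.seed)
    dev_patients = sorted(partition.patients(cfg.dev_partition))
    split = split_by_patient(dev_patients, cfg.split_fractions, seed=cfg.seed)
    splits_doc = {
        "k_partitions": cfg.k_partitions,
        "dev_partition": cfg.dev_partition,
        "seed": cfg.seed,
        "partition": partition.assignment,
        "split": split.assignment,
    }
    _write_csv(out / "sentences.csv", sentences)
    _write_csv(out / "labels.csv", labels)
    _atomic_write(out / "splits.json",
                  json.dumps(splits_doc, indent=2, sort_keys=True) + "\n")
    outputs = [out / "sentences.csv", out / "labels.csv", out / "splits.json"]
    _manifest(out, "ingest", cfg, [cfg.corpus_path / "notes.csv"], outputs)
    return outputs


def _load_ingest(out: Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    sentences = pd.read_csv(out / "sentences.csv", dtype={"text": str},
                            keep_default_na=False)
    labels = pd.read_csv(out / "labels.csv")
    splits = json.loads((out / "splits.json").read_text())
    return sentences, labels, splits


def _sentence_targets(sentences: pd.DataFrame, labels: pd.DataFrame,
                      concept: str) -> np.ndarray:
    y = np.zeros(len(sentences), dtype=int)
    lab = labels[labels["concept"] == concept]
    if len(lab):
        key = pd.MultiIndex.from_frame(sentences[["note_id", "sentence_index"]])
        lab_idx = pd.MultiIndex.from_frame(lab[["note_id", "sentence_index"]])
        locs = key.get_indexer(lab_idx)
        y[locs[locs >= 0]] = lab["klass"].to_numpy()[locs >= 0]
    return y


def _concept_settings(cfg: PipelineConfig, concept: str) -> dict:
    if cfg.classifier == "reference":
        ref = REFERENCE_CONCEPT_SETTINGS[concept]
        return {"kernel": ref["kernel"], "C": ref["param"],
                "downsample_rate": ref["downsample"]}
    return {"kernel": cfg.generic_kernel, "C": cfg.generic_C,
            "downsample_rate": cfg.generic_downsample}


def stage_train(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    _require("train", out / "sentences.csv", out / "labels.csv", out / "splits.json")
    sentences, labels, splits = _load_ingest(out)
    train_patients = {p for p, s in splits["split"].items() if s == "train"}
    train_mask = sentences["patient_id"].isin(train_patients).to_numpy()
    if not train_mask.any():
        raise PipelineDependencyError("train: no sentences for training patients")
    train_sents = sentences.loc[train_mask]

    featurizer = SentenceFeaturizer(min_df=cfg.min_df, max_df=cfg.max_df,
                                    embed_dim=cfg.embed_dim, seed=cfg.seed)
    X_train = featurizer.fit(train_sents["text"].tolist()).transform(
        train_sents["text"].tolist())

    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    joblib.dump(featurizer, models_dir / "featurizer.joblib")
    meta = {"concepts": {}, "layout": list(featurizer.layout_), "seed": cfg.seed}
    for concept in CONCEPTS:
        y_all = _sentence_targets(sentences, labels, concept)
        y = y_all[train_mask]
        settings = _concept_settings(cfg, concept)
        clf = CalibratedConceptClassifier(seed=cfg.seed, **settings).fit(X_train, y)
        joblib.dump(clf, models_dir / f"{concept}.joblib")
        meta["concepts"][concept] = settings
    _atomic_write(models_dir / "metadata.json",
                  json.dumps(meta, indent=2, sort_keys=True) + "\n")
    outputs = [models_dir / "metadata.json"]
    _manifest(out, "train", cfg,
              [out / "sentences.csv", out / "labels.csv", out / "splits.json"],
              outputs)
    return outputs


def stage_score(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    models_dir = out / "models"
    _require("score", out / "sentences.csv", models_dir / "metadata.json")
    sentences, _, _ = _load_ingest(out)
    featurizer: SentenceFeaturizer = joblib.load(models_dir / "featurizer.joblib")
    X = featurizer.transform(sentences["text"].tolist())
    frames = []
    base = sentences[["patient_id", "note_id", "sentence_index"]]
    for concept in CONCEPTS:
        clf: CalibratedConceptClassifier = joblib.load(models_dir / f"{concept}.joblib")
        proba = clf.predict_proba(X)
        frame = base.copy()
        frame["concept"] = concept
        frame["p_neg"] = proba[:, int(Klass.NEGATIVE)]
        frame["p_negqual"] = proba[:, int(Klass.NEGATIVE_QUALIFIED)]
        frame["p_pos"] = proba[:, int(Klass.POSITIVE)]
        frames.append(frame)
    predictions = pd.concat(frames, ignore_index=True)
    _write_csv(out / "predictions.csv", predictions)
    outputs = [out / "predictions.csv"]
    _manifest(out, "score", cfg, [models_dir / "metadata.json"], outputs)
    return outputs


def _patient_gold_frame(out: Path, cfg: PipelineConfig,
                        patient_ids: list[str]) -> pd.DataFrame:
    notes, annotations = load_corpus_dir(cfg.corpus_path)
    notes = filter_notes(notes, set(cfg.allowed_note_types))
    note_patient = {n.note_id: n.patient_id for n in notes}
    return build_patient_gold(annotations, note_patient, patient_ids)


def _noisy_or_matrix(predictions: pd.DataFrame, patient_ids: list[str],
                     kind: ReductionKind) -> pd.DataFrame:
    """Vectorized reduction of the long prediction table for one kind."""
    out = pd.DataFrame(0.0, index=pd.Index(patient_ids, name="patient_id"),
                       columns=list(CONCEPTS))
    grp = predictions.groupby(["patient_id", "concept"], observed=True)["p_pos"]
    if kind is ReductionKind.NOISY_OR:
        log_surv = np.log1p(-np.clip(predictions["p_pos"].to_numpy(), 0.0, 1.0 - 1e-16))
        reduced = 1.0 - np.exp(
            pd.Series(log_surv, index=predictions.index)
            .groupby([predictions["patient_id"], predictions["concept"]],
                     observed=True).sum())
    elif kind is ReductionKind.MAX:
        reduced = grp.max()
    elif kind is ReductionKind.MIN:
        reduced = grp.min()
    elif kind is ReductionKind.MEAN:
        reduced = grp.mean()
    else:
        raise ValueError(f"unsupported vectorized kind {kind}")
    wide = reduced.unstack("concept")
    out.loc[wide.index, wide.columns] = wide
    return out.fillna(0.0)


def stage_reduce(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    _require("reduce", out / "predictions.csv", out / "splits.json",
             cfg.corpus_path / "notes.csv")
    predictions = pd.read_csv(out / "predictions.csv")
    _, _, splits = _load_ingest(out)
    all_patients = sorted(splits["partition"].keys())

    if cfg.select_reductions:
        val_patients = sorted(p for p, s in splits["split"].items()
                              if s == "validation")
        gold = _patient_gold_frame(out, cfg, val_patients)
        val_preds = predictions[predictions["patient_id"].isin(val_patients)]
        by_concept: dict[str, dict[ReductionKind, np.ndarray]] = {}
        usable_concepts = []
        for concept in CONCEPTS:
            y = gold[concept].to_numpy(dtype=int)
            if 0 < y.sum() < len(y):
                usable_concepts.append(concept)
        for kind in _DEFAULT_CANDIDATES:
            matrix = _noisy_or_matrix(val_preds, val_patients, kind)
            for concept in usable_concepts:
                by_concept.setdefault(concept, {})[kind] = matrix[concept].to_numpy()
        chosen = select_reduction(by_concept, gold.loc[val_patients])
        reductions = {c: chosen.get(c, ReductionKind.NOISY_OR).value
                      for c in CONCEPTS}
    else:
        reductions = {c: REFERENCE_CONCEPT_SETTINGS[c]["reduction"] for c in CONCEPTS}

    pieces = []
    for kind in set(reductions.values()):
        cols = [c for c in CONCEPTS if reductions[c] == kind]
        m = _noisy_or_matrix(predictions, all_patients, ReductionKind(kind))
        pieces.append(m[cols])
    matrix = pd.concat(pieces, axis=1)[list(CONCEPTS)]

    _atomic_write(out / "reductions.json",
                  json.dumps(reductions, indent=2, sort_keys=True) + "\n")
    _write_csv(out / "patient_matrix.csv", matrix, index=True)
    outputs = [out / "reductions.json", out / "patient_matrix.csv"]
    _manifest(out, "reduce", cfg, [out / "predictions.csv"], outputs)
    return outputs


def stage_rank(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    _require("rank", out / "patient_matrix.csv", out / "splits.json",
             cfg.corpus_path / "notes.csv")
    matrix = pd.read_csv(out / "patient_matrix.csv", index_col="patient_id")
    _, _, splits = _load_ingest(out)
    fit_patients = sorted(p for p, s in splits["split"].items()
                          if s in ("train", "validation"))
    gold = _patient_gold_frame(out, cfg, fit_patients)
    y = np.array([symptom_count_target(gold.loc[p]) for p in fit_patients])
    ranker = PoissonRanker().fit(matrix.loc[fit_patients], y)
    dsq = d_squared(ranker.model_, matrix.loc[fit_patients], y)

    scores = dict(zip(matrix.index, ranker.predict(matrix)))
    ranked = rank_patients(scores)
    table = pd.DataFrame(
        [{"rank": r.rank, "patient_id": r.patient_id, "score": r.score}
         for r in ranked]).merge(matrix, on="patient_id")
    _atomic_write(out / "rank_model.json", ranker.model_.to_json() + "\n")
    _write_csv(out / "ranked.csv", table)
    _atomic_write(out / "rank_fit.json", json.dumps(
        {"d_squared": dsq, "n_fit_patients": len(fit_patients),
         "mean_symptom_count": float(np.mean(y))}, indent=2) + "\n")
    outputs = [out / "rank_model.json", out / "ranked.csv", out / "rank_fit.json"]
    _manifest(out, "rank", cfg, [out / "patient_matrix.csv"], outputs)
    return outputs


def stage_evaluate(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    _require("evaluate", out / "ranked.csv", out / "patient_matrix.csv",
             out / "splits.json")
    ranked_table = pd.read_csv(out / "ranked.csv")
    matrix = pd.read_csv(out / "patient_matrix.csv", index_col="patient_id")
    _, _, splits = _load_ingest(out)
    metrics: dict = {}

    # per-concept patient-level metrics on the dev validation+test patients
    heldin = sorted(p for p, s in splits["split"].items()
                    if s in ("validation", "test"))
    gold = _patient_gold_frame(out, cfg, heldin)
    cm = concept_metrics(matrix.loc[heldin], gold)
    _write_csv(out / "concept_metrics.csv", cm, index=True)
    metrics["concept_metrics_mean_ap"] = float(cm["ap"].mean(skipna=True))
    metrics["concept_metrics_mean_auc"] = float(cm["auc"].mean(skipna=True))
    metrics["concept_metrics_mean_lift"] = float(cm["lift"].mean(skipna=True))

    # blinded review list over the held-out partitions
    dev = {p for p, q in splits["partition"].items()
           if q == splits["dev_partition"]}
    from .ranking import RankResult
    heldout = [RankResult(r.patient_id, r.score, i + 1)
               for i, r in enumerate(ranked_table.itertuples())
               if r.patient_id not in dev]
    k = min(cfg.k_review, len(heldout) // 2)
    top, bottom, review_order = select_extremes(heldout, k, seed=cfg.seed)
    _write_csv(out / "review_order.csv", pd.DataFrame(
        {"review_position": np.arange(1, len(review_order) + 1),
         "patient_id": review_order}))
    metrics["k_review"] = k

    # with synthetic truth available, score the review endpoint
    truth_path = out / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path).set_index("patient_id")
        non_epi = [c for c in CONCEPTS if c != "epilepsy_or_seizures"]
        sym_count = truth[non_epi].sum(axis=1)
        flagged = sym_count >= cfg.high_symptom_threshold
        a = int(flagged.loc[[r.patient_id for r in top]].sum())
        c = int(flagged.loc[[r.patient_id for r in bottom]].sum())
        table2 = ReviewTable2x2(a=a, b=k - a, c=c, d=k - c)
        metrics["review_table"] = {"a": a, "b": k - a, "c": c, "d": k - c}
        metrics["top_flagged_pct"] = 100.0 * table2.top_flagged_fraction
        try:
            metrics["fisher_p"] = fisher_exact_2x2(table2)
            stat, p = chi_square_yates(table2)
            metrics["chi2_yates"] = {"statistic": stat, "p": p}
        except ValueError:
            metrics["fisher_p"] = None

        n_top = max(1, int(round(cfg.top_fraction * len(ranked_table))))
        top_ids = set(ranked_table.nsmallest(n_top, "rank")["patient_id"])
        high_ids = set(flagged.index[flagged])
        if high_ids:
            recall = len(high_ids & top_ids) / len(high_ids)
            metrics["high_symptom_recovery"] = {
                "threshold": cfg.high_symptom_threshold,
                "top_fraction": cfg.top_fraction,
                "n_high_symptom": len(high_ids),
                "n_recovered": len(high_ids & top_ids),
                "recall": recall,
            }

    rank_fit = json.loads((out / "rank_fit.json").read_text())
    metrics["d_squared"] = rank_fit["d_squared"]

    labels, coords = cluster_diagnostics(matrix, n_clusters=cfg.n_clusters,
                                         seed=cfg.seed)
    _write_csv(out / "clusters.csv", pd.DataFrame(
        {"patient_id": matrix.index, "cluster": labels,
         "pc0": coords[:, 0], "pc1": coords[:, 1]}))
    if truth_path.exists():
        top_ranked = set(ranked_table.nsmallest(
            max(1, int(round(cfg.top_fraction * len(ranked_table)))),
            "rank")["patient_id"])
        cluster_of = dict(zip(matrix.index, labels))
        counts = pd.Series([cluster_of[p] for p in top_ranked]).value_counts()
        metrics["top_rank_modal_cluster_fraction"] = float(
            counts.iloc[0] / counts.sum())

    _atomic_write(out / "metrics.json",
                  json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    outputs = [out / "metrics.json", out / "concept_metrics.csv",
               out / "review_order.csv", out / "clusters.csv"]
    _manifest(out, "evaluate", cfg, [out / "ranked.csv"], outputs)
    return outputs


_STAGE_FUNCS = {
    "synth": stage_synth,
    "ingest": stage_ingest,
    "train": stage_train,
    "score": stage_score,
    "reduce": stage_reduce,
    "rank": stage_rank,
    "evaluate": stage_evaluate,
}


def run_stage(stage: str, config: PipelineConfig) -> list[Path]:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return _STAGE_FUNCS[stage](config)


def run_all(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the listed stages in order; returns the metrics dict when the
    evaluate stage ran."""
    for stage in stages:
        run_stage(stage, config)
    metrics_path = Path(config.out_dir) / "metrics.json"
    return json.loads(metrics_path.read_text()) if metrics_path.exists() else {}
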