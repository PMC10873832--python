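"""Sentence feature extraction.

Two blocks, concatenated: a document-frequency-filtered binary uni/bi-gram
block, and a fixed-width sentence-embedding block from a pluggable backend.
The default backend is deterministic, offline feature hashing of character
n-grams; a pretrained-transformer backend can be plugged in through the
same ``embed`` contract (text -> length-``dim`` vector) where such weights
are available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import CountVectorizer, HashingVectorizer
from sklearn.preprocessing import normalize
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "tokenize",
    "NgramFeaturizer",
    "HashingSentenceEmbedder",
    "SentenceFeaturizer",
    "CombinedFeatureVector",
    "fit_ngram_vocab",
    "ngram_vector",
    "embed_sentence",
    "combine_features",
    "save_vocabulary",
    "load_vocabulary",
    "save_feature_matrix",
    "load_feature_matrix",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics. Deliberately independent of
    the sentence segmenter so feature extraction is reproducible."""
    return _TOKEN_RE.findall(text.lower())


def _uni_bi_analyzer(text: str) -> list[str]:
    toks = tokenize(text)
    return toks + [f"{a} {b}" for a, b in zip(toks, toks[1:])]


class NgramFeaturizer(TransformerMixin, BaseEstimator):
    """Binary presence of uni- and bi-grams, filtered by document frequency.

    "Document" here is the training sentence — the classification unit.
    Presence, not count, defines both the document frequency and the
    encoding (sentences are short enough that counts add nothing). An
    n-gram is retained iff ``min_df <= df < max_df``: tokens in at least
    ``max_df`` of sentences carry no signal, tokens in under ``min_df`` are
    too rare to estimate. Tri-grams are excluded (no measured gain).

    Attributes
    ----------
    ngrams_ : list[str]
        Retained n-grams in fixed (lexicographic) order.
    document_frequency_ : dict[str, float]
        Fraction of training sentences containing each retained n-gram.
    """

    def __init__(self, min_df: float = 0.05, max_df: float = 0.95):
        self.min_df = min_df
        self.max_df = max_df

    def fit(self, sentences: list[str], y=None) -> "NgramFeaturizer":
        if len(sentences) == 0:
            raise ValueError("cannot fit an n-gram vocabulary on an empty training set")
        if not (0.0 <= self.min_df <= self.max_df <= 1.0):
            raise ValueError("need 0 <= min_df <= max_df <= 1")
        counter = CountVectorizer(analyzer=_uni_bi_analyzer, binary=True,
                                  lowercase=False)
        X = counter.fit_transform(sentences)
        df = np.asarray((X > 0).sum(axis=0)).ravel() / len(sentences)
        names = counter.get_feature_names_out()
        keep = (df >= self.min_df) & (df < self.max_df)
        order = np.argsort(names[keep], kind="stable")
        self.ngrams_ = [str(g) for g in names[keep][order]]
        self.document_frequency_ = dict(zip(self.ngrams_, df[keep][order]))
        self._vectorizer_ = CountVectorizer(
            analyzer=_uni_bi_analyzer, binary=True, lowercase=False,
            vocabulary=self.ngrams_)
        return self

    def transform(self, sentences: list[str]) -> sp.csr_matrix:
        check_is_fitted(self, "ngrams_")
        if not self.ngrams_:
            return sp.csr_matrix((len(sentences), 0), dtype=np.float64)
        return self._vectorizer_.transform(sentences).astype(np.float64)


class HashingSentenceEmbedder(TransformerMixin, BaseEstimator):
    """Deterministic offline sentence embedding by feature hashing.

    Character n-grams (word-boundary aware) are hashed into ``dim`` slots
    with alternating signs and the row is L2-normalized, so identical texts
    embed identically (cosine 1) and texts sharing no characters are near-
    orthogonal. The seed drives a fixed permutation and sign flip of the
    slots, i.e. it re-salts the slot assignment. Stateless: ``fit`` is a
    no-op, the transform is fully determined by the constructor arguments.
    """

    def __init__(self, dim: int = 768, seed: int = 0,
                 char_ngram_range: tuple[int, int] = (3, 5)):
        self.dim = dim
        self.seed = seed
        self.char_ngram_range = char_ngram_range

    @property
    def name(self) -> str:
        return f"hashing-char{self.char_ngram_range}-d{self.dim}-s{self.seed}"

    def _hasher(self) -> HashingVectorizer:
        return HashingVectorizer(
            analyzer="char_wb", ngram_range=self.char_ngram_range,
            n_features=self.dim, norm=None, alternate_sign=True)

    def fit(self, X=None, y=None) -> "HashingSentenceEmbedder":
        return self

    def transform(self, sentences: list[str]) -> sp.csr_matrix:
        X = self._hasher().transform(sentences)
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(self.dim)
        signs = rng.choice([-1.0, 1.0], size=self.dim)
        X = X[:, perm].multiply(sp.csr_matrix(signs)).tocsr()
        return normalize(X, norm="l2", copy=False)

    def embed(self, sentence: str) -> np.ndarray:
        """Single-sentence convenience: dense vector of length ``dim``."""
        return np.asarray(self.transform([sentence]).todense()).ravel()


@dataclass(frozen=True)
class CombinedFeatureVector:
    values: np.ndarray
    layout: tuple[int, int]  # (ngram block length, embedding block length)

    def __post_init__(self) -> None:
        if len(self.values) != sum(self.layout):
            raise ValueError("layout does not sum to vector length")


class SentenceFeaturizer(TransformerMixin, BaseEstimator):
    """N-gram block concatenated with the embedding block, n-grams first.

    Attributes
    ----------
    ngram_ : NgramFeaturizer
    embedder_ : HashingSentenceEmbedder
    layout_ : tuple[int, int]
    """

    def __init__(self, min_df: float = 0.05, max_df: float = 0.95,
                 embed_dim: int = 768, seed: int = 0):
        self.min_df = min_df
        self.max_df = max_df
        self.embed_dim = embed_dim
        self.seed = seed

    def fit(self, sentences: list[str], y=None) -> "SentenceFeaturizer":
        self.ngram_ = NgramFeaturizer(self.min_df, self.max_df).fit(sentences)
        self.embedder_ = HashingSentenceEmbedder(dim=self.embed_dim, seed=self.seed)
        self.layout_ = (len(self.ngram_.ngrams_), self.embed_dim)
        return self

    def transform(self, sentences: list[str]) -> sp.csr_matrix:
        check_is_fitted(self, "layout_")
        blocks = [self.ngram_.transform(sentences),
                  self.embedder_.transform(sentences)]
        return sp.hstack(blocks, format="csr")


# ----- thin functional wrappers ------------------------------------------

def fit_ngram_vocab(train_sentences: list[str], min_df: float = 0.05,
                    max_df: float = 0.95) -> NgramFeaturizer:
    return NgramFeaturizer(min_df=min_df, max_df=max_df).fit(train_sentences)


def ngram_vector(sentence: str, vocab: NgramFeaturizer) -> np.ndarray:
    return np.asarray(vocab.transform([sentence]).todense()).ravel()


def embed_sentence(backend: HashingSentenceEmbedder, sentence: str) -> np.ndarray:
    vec = backend.embed(sentence)
    if len(vec) != backend.dim:
        raise RuntimeError(f"backend {backend.name} returned length {len(vec)}")
    return vec


def save_vocabulary(vocab: NgramFeaturizer, path: str | Path) -> None:
    """Write the fitted vocabulary as a delimited (ngram, df) table."""
    frame = pd.DataFrame({"ngram": vocab.ngrams_,
                          "df": [vocab.document_frequency_[g]
                                 for g in vocab.ngrams_]})
    frame.to_csv(path, index=False, lineterminator="\n")


def load_vocabulary(path: str | Path, min_df: float = 0.05,
                    max_df: float = 0.95) -> NgramFeaturizer:
    frame = pd.read_csv(path, keep_default_na=False)
    vocab = NgramFeaturizer(min_df=min_df, max_df=max_df)
    vocab.ngrams_ = frame["ngram"].astype(str).tolist()
    vocab.document_frequency_ = dict(zip(vocab.ngrams_, frame["df"]))
    vocab._vectorizer_ = CountVectorizer(
        analyzer=_uni_bi_analyzer, binary=True, lowercase=False,
        vocabulary=vocab.ngrams_)
    return vocab


def save_feature_matrix(X: sp.spmatrix, row_ids, path_prefix: str | Path) -> None:
    """Write a feature matrix as Matrix-Market ``<prefix>.mtx`` plus a
    ``<prefix>.rows.csv`` row-index table."""
    prefix = Path(path_prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(X))
    pd.DataFrame({"row": range(len(row_ids)), "id": list(row_ids)}).to_csv(
        prefix.with_suffix(".rows.csv"), index=False, lineterminator="\n")


def load_feature_matrix(path_prefix: str | Path) -> tuple[sp.csr_matrix, list]:
    prefix = Path(path_prefix)
    X = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    rows = pd.read_csv(prefix.with_suffix(".rows.csv"),
                       keep_default_na=False)["id"].tolist()
    return X, rows


def combine_features(ngram_vec: np.ndarray, embed_vec: np.ndarray) -> CombinedFeatureVector:
    ngram_vec = np.asarray(ngram_vec, dtype=float)
    embed_vec = np.asarray(embed_vec, dtype=float)
    if not (np.all(np.isfinite(ngram_vec)) and np.all(np.isfinite(embed_vec))):
        raise ValueError("feature blocks must be finite")
    return CombinedFeatureVector(
        values=np.concatenate([ngram_vec, embed_vec]),
        layout=(len(ngram_vec), len(embed_vec)),
    )
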