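"""Citation corpora: loading, preprocessing, features, splits and SVMlight I/O.

A screening corpus is an ordered collection of labelled citations (title +
abstract + expert relevance judgement).  This module turns raw citations into
token streams (lower-cased, punctuation/digit-free, stop-word filtered),
removes hapax legomena, builds TF-IDF bag-of-words features, produces
class-stratified train/test splits and round-trips sparse feature files in
the SVMlight text format.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

from .errors import ParseError, SchemaError, ValidationError

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"
UNKNOWN = "unknown"

#: accepted spellings for each label, normalised on load
_LABEL_DIALECTS = {
    "1": RELEVANT, "+1": RELEVANT, "relevant": RELEVANT, "true": RELEVANT,
    "0": IRRELEVANT, "-1": IRRELEVANT, "−1": IRRELEVANT,
    "irrelevant": IRRELEVANT, "false": IRRELEVANT,
    "": UNKNOWN, "unknown": UNKNOWN, "?": UNKNOWN,
}

_TOKEN_RE = re.compile(r"[a-z]+")


def normalise_label(raw: str) -> str:
    try:
        return _LABEL_DIALECTS[str(raw).strip().lower()]
    except KeyError:
        raise SchemaError(f"unrecognised relevance label: {raw!r}") from None


@dataclass
class LabeledDocument:
    """One citation: identifier, raw text, relevance label and token stream.

    ``tokens`` is empty until :func:`preprocess` has run; afterwards it holds
    lower-case, punctuation- and digit-free, stop-word-filtered word tokens
    (term fusion may later join several of them with underscores).
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    label: str = UNKNOWN
    tokens: list[str] = field(default_factory=list)

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


@dataclass
class Corpus:
    """Ordered collection of documents plus a dense token vocabulary."""

    documents: list[LabeledDocument]
    vocabulary: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def labels(self) -> np.ndarray:
        """Labels as +1 (relevant) / -1 (irrelevant) / 0 (unknown)."""
        m = {RELEVANT: 1, IRRELEVANT: -1, UNKNOWN: 0}
        return np.array([m[d.label] for d in self.documents], dtype=int)

    @property
    def prevalence(self) -> float:
        """Fraction of relevant documents among all documents."""
        if not self.documents:
            raise ValidationError("prevalence of an empty corpus is undefined")
        n_rel = sum(d.label == RELEVANT for d in self.documents)
        return n_rel / len(self.documents)

    def build_vocabulary(self) -> None:
        """Rebuild a dense token -> 0..V-1 index (sorted for determinism)."""
        seen = sorted({t for d in self.documents for t in d.tokens})
        self.vocabulary = {t: i for i, t in enumerate(seen)}

    def token_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.documents:
            for t in d.tokens:
                counts[t] = counts.get(t, 0) + 1
        return counts


@dataclass
class FeatureMatrix:
    """Per-document feature vectors aligned with binary labels.

    ``X`` is sparse for bag-of-words (BOW) features and dense for topic
    proportions (TPC) or term-enriched topic proportions (TE); ``y`` holds
    +1/-1 labels; ``doc_ids`` keeps provenance for reporting.
    """

    X: sp.spmatrix | np.ndarray
    y: np.ndarray
    feature_kind: str  # "BOW" | "TPC" | "TE"
    doc_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.X.shape[0] != len(self.y):
            raise ValidationError(
                f"{self.X.shape[0]} feature rows vs {len(self.y)} labels"
            )
        if self.feature_kind not in ("BOW", "TPC", "TE"):
            raise ValidationError(f"unknown feature kind {self.feature_kind!r}")


# ---------------------------------------------------------------------------
# loading


def default_stopwords() -> frozenset[str]:
    """The stop-word list shipped with the package (one token per line)."""
    text = resources.files("topicscreen.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def load_stopwords(path: str | Path) -> frozenset[str]:
    return frozenset(
        w.strip() for w in Path(path).read_text("utf-8").splitlines() if w.strip()
    )


def load_corpus(path: str | Path, format: str = "csv") -> Corpus:
    """Read a citation corpus from ``csv``, ``ris`` or ``textdir`` sources.

    CSV needs columns id,title,abstract,label; RIS uses ID/TI/AB tags plus an
    optional LB tag for the relevance label; ``textdir`` reads every ``*.txt``
    file of a directory as one unlabelled document.
    """
    path = Path(path)
    if format == "csv":
        docs = _load_csv(path)
    elif format == "ris":
        docs = _load_ris(path)
    elif format == "textdir":
        docs = _load_textdir(path)
    else:
        raise ValidationError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValidationError(f"duplicate doc_id {d.doc_id!r}")
        seen.add(d.doc_id)
    return Corpus(documents=docs)


def _load_csv(path: Path) -> list[LabeledDocument]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = {"id", "title", "abstract", "label"} - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        return [
            LabeledDocument(
                doc_id=row["id"],
                title=row["title"] or "",
                abstract=row["abstract"] or "",
                label=normalise_label(row["label"]),
            )
            for row in reader
        ]


def _load_ris(path: Path) -> list[LabeledDocument]:
    docs: list[LabeledDocument] = []
    rec: dict[str, str] = {}
    n_anon = 0
    for lineno, line in enumerate(path.read_text("utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        m = re.match(r"^([A-Z][A-Z0-9])(  -\s?(.*))?$", line.rstrip())
        if m is None:
            raise ParseError(f"not an RIS tag line: {line!r}", lineno)
        tag, value = m.group(1), (m.group(3) or "").strip()
        if tag == "ER":
            n_anon += 1
            docs.append(
                LabeledDocument(
                    doc_id=rec.get("ID", f"ris-{n_anon}"),
                    title=rec.get("TI", ""),
                    abstract=rec.get("AB", ""),
                    label=normalise_label(rec.get("LB", "")),
                )
            )
            rec = {}
        else:
            rec[tag] = f"{rec[tag]} {value}".strip() if tag in rec else value
    return docs


def _load_textdir(path: Path) -> list[LabeledDocument]:
    if not path.is_dir():
        raise SchemaError(f"{path} is not a directory")
    return [
        LabeledDocument(doc_id=p.stem, abstract=p.read_text("utf-8"))
        for p in sorted(path.glob("*.txt"))
    ]


def save_corpus_csv(corpus: Corpus, path: str | Path) -> None:
    label_out = {RELEVANT: "1", IRRELEVANT: "0", UNKNOWN: ""}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "title", "abstract", "label"])
        for d in corpus:
            writer.writerow([d.doc_id, d.title, d.abstract, label_out[d.label]])


# ---------------------------------------------------------------------------
# preprocessing


def tokenize(text: str) -> list[str]:
    """Split on any non-letter character, lower-case.

    Punctuation and digits act as delimiters and never survive, so hyphenated
    words split and tokens like "covid19" drop their digits.
    """
    return _TOKEN_RE.findall(text.lower())


def preprocess(
    doc: LabeledDocument, stopwords: frozenset[str] | None = None
) -> LabeledDocument:
    """Return a copy of ``doc`` with its token stream populated.

    Tokens come from title + abstract, lower-cased, split on non-letters
    (which removes punctuation and digits) and stop-word filtered.  The raw
    text fields are retained untouched; the operation is idempotent.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    tokens = [t for t in tokenize(doc.text) if t not in stopwords]
    return replace(doc, tokens=tokens)


def preprocess_corpus(
    corpus: Corpus, stopwords: frozenset[str] | None = None
) -> Corpus:
    if stopwords is None:
        stopwords = default_stopwords()
    out = Corpus(documents=[preprocess(d, stopwords) for d in corpus])
    out.build_vocabulary()
    return out


def remove_hapax(corpus: Corpus) -> Corpus:
    """Drop every token whose total corpus frequency is one; rebuild vocabulary."""
    counts = corpus.token_counts()
    keep = {t for t, c in counts.items() if c >= 2}
    out = Corpus(
        documents=[
            replace(d, tokens=[t for t in d.tokens if t in keep]) for d in corpus
        ]
    )
    out.build_vocabulary()
    return out


# ---------------------------------------------------------------------------
# TF-IDF features


class BowTfidfVectorizer(BaseEstimator, TransformerMixin):
    """Bag-of-words TF-IDF over pre-tokenised documents.

    The weighting is the plain textbook form: entry (d, w) = tf(d, w) x
    ln(N / df(w)) with raw term counts and no row normalisation, so a token
    present in every training document receives weight zero everywhere.

    Parameters
    ----------
    vocabulary : dict, optional
        Fixed token -> column mapping; learned from the data when omitted.

    Attributes
    ----------
    vocabulary_ : dict
        Token -> column index used by :meth:`transform`.
    idf_ : ndarray of shape (V,)
        ln(N / df) per vocabulary token.
    """

    def __init__(self, vocabulary: dict[str, int] | None = None):
        self.vocabulary = vocabulary

    def fit(self, X, y=None):
        docs = _as_token_lists(X)
        if self.vocabulary is not None:
            self.vocabulary_ = dict(self.vocabulary)
        else:
            seen = sorted({t for toks in docs for t in toks})
            self.vocabulary_ = {t: i for i, t in enumerate(seen)}
        if not self.vocabulary_:
            raise ValidationError("empty vocabulary: nothing to vectorise")
        n_docs = len(docs)
        df = np.zeros(len(self.vocabulary_))
        for toks in docs:
            for t in set(toks):
                j = self.vocabulary_.get(t)
                if j is not None:
                    df[j] += 1
        with np.errstate(divide="ignore"):
            self.idf_ = np.where(df > 0, np.log(n_docs / np.maximum(df, 1)), 0.0)
        return self

    def transform(self, X) -> sp.csr_matrix:
        docs = _as_token_lists(X)
        vocab, idf = self.vocabulary_, self.idf_
        rows, cols, vals = [], [], []
        for i, toks in enumerate(docs):
            counts: dict[int, int] = {}
            for t in toks:
                j = vocab.get(t)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            for j, c in counts.items():
                rows.append(i)
                cols.append(j)
                vals.append(c * idf[j])
        M = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(docs), len(vocab)), dtype=float
        )
        M.eliminate_zeros()
        return M


def _as_token_lists(X) -> list[list[str]]:
    if isinstance(X, Corpus):
        return [d.tokens for d in X]
    return list(X)


def tfidf_vectorize(corpus: Corpus) -> FeatureMatrix:
    """TF-IDF bag-of-words features over the corpus vocabulary."""
    if not corpus.vocabulary:
        corpus.build_vocabulary()
    if not corpus.vocabulary:
        raise ValidationError("corpus has an empty vocabulary")
    vec = BowTfidfVectorizer(vocabulary=corpus.vocabulary).fit(corpus)
    X = vec.transform(corpus)
    return FeatureMatrix(
        X=X, y=corpus.labels(), feature_kind="BOW",
        doc_ids=[d.doc_id for d in corpus],
    )


# ---------------------------------------------------------------------------
# splitting


def stratified_split(
    corpus: Corpus, fraction: float = 0.5, seed: int = 0
) -> tuple[Corpus, Corpus]:
    """Random class-stratified partition into train and test corpora.

    Relevant and irrelevant documents are shuffled and split independently so
    that each side's prevalence matches the corpus prevalence to within the
    rounding of one document.  The default even split sends half of each
    class to each side.  Identical seeds give identical partitions.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie strictly between 0 and 1")
    by_class: dict[str, list[int]] = {RELEVANT: [], IRRELEVANT: []}
    for i, d in enumerate(corpus):
        if d.label not in by_class:
            raise ValidationError(f"cannot stratify on label {d.label!r}")
        by_class[d.label].append(i)
    if not by_class[RELEVANT] or not by_class[IRRELEVANT]:
        raise ValidationError("both classes must be present to stratify")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for idx in by_class.values():
        perm = rng.permutation(len(idx))
        n_train = int(round(fraction * len(idx)))
        train_idx.extend(idx[i] for i in perm[:n_train])
        test_idx.extend(idx[i] for i in perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    docs = corpus.documents
    train = Corpus(documents=[docs[i] for i in train_idx])
    test = Corpus(documents=[docs[i] for i in test_idx])
    train.build_vocabulary()
    test.build_vocabulary()
    return train, test


# ---------------------------------------------------------------------------
# SVMlight serialisation


def write_svmlight(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write features as SVMlight text lines "<label> <idx>:<value> ..." (1-based)."""
    X = matrix.X if sp.issparse(matrix.X) else sp.csr_matrix(np.asarray(matrix.X))
    dump_svmlight_file(X, matrix.y, str(path), zero_based=False)


def read_svmlight(path: str | Path, feature_kind: str = "BOW") -> FeatureMatrix:
    """Read an SVMlight file back into a :class:`FeatureMatrix`."""
    try:
        X, y = load_svmlight_file(str(path), zero_based=False)
    except ValueError as exc:
        raise ParseError(str(exc), _find_bad_line(path)) from exc
    X = X.tocsr()
    # libsvm-backed estimators require 32-bit sparse indices
    X.indices = X.indices.astype(np.int32, copy=False)
    X.indptr = X.indptr.astype(np.int32, copy=False)
    return FeatureMatrix(X=X, y=y.astype(int), feature_kind=feature_kind)


_SVMLIGHT_LINE = re.compile(
    r"^\s*[+-]?\d+(\.\d+)?(\s+\d+:[+-]?[\d.eE+-]+)*\s*(#.*)?$"
)


def _find_bad_line(path: str | Path) -> int | None:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.strip() and not _SVMLIGHT_LINE.match(line):
            return lineno
    return None
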