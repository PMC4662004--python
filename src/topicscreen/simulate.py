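"""Synthetic screening corpora with known topic structure.

Documents are generated from the LDA generative process itself: K topic-word
distributions drawn from Dir(beta), per-document topic proportions from
Dir(alpha), Poisson document lengths (truncated at one token) and tokens
sampled topic-then-word.  Screening corpora additionally draw a binary
relevance label at a configurable prevalence (default 0.1, the roughly 1:9
relevant:irrelevant imbalance typical of citation screening) and centre each
document's topic proportions on a class-specific Dirichlet profile, so the
relevant class occupies a distinct topical region.

Two vocabularies are available: neutral letter-coded symbols ("vaa", "vab",
...) for statistical tests, and a small embedded biomedical vocabulary whose
entries include planted multi-word phrases ("logistic regression model",
"teen birth rates", ...) so that term recognition and term-enriched topic
pipelines can be exercised end to end.  All generation is seed-deterministic
and the emitted documents survive the preprocessing pipeline unchanged
(letters only, no stop-words).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .corpus import RELEVANT, IRRELEVANT, UNKNOWN, Corpus, LabeledDocument
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: embedded single-word biomedical vocabulary (letters only, no stop-words)
BIOMEDICAL_WORDS = """
abstinence adolescents analysis assessment asthma baseline behaviour
biomarkers bronchitis cessation children citations classifier cohort
communities comparator copd counselling criteria curriculum diagnosis
diet disease dyspnoea education eligibility emphysema enrolment evidence
exacerbation exercise families followup guidance health hospital hygiene
inclusion infection inhaler intervention interviews lungs meta mentoring
methodology morbidity mortality nicotine nutrition outcomes oxygen
packaging participants patients placebo pneumonia population prevention
programme protocol pulmonary quality questionnaire recall recruitment
rehabilitation relapse respiratory review risk sampling schools screening
search severity smoking spirometry sputum students survey symptoms
teenagers therapy tobacco treatment trial uptake ventilation wheeze
workload youth
""".split()

#: planted multi-word phrases; each behaves as one vocabulary entry whose
#: surface form is several tokens, discoverable by C-value term mining
BIOMEDICAL_PHRASES = [
    "logistic regression model",
    "teen birth rates",
    "randomised controlled trial",
    "chronic obstructive pulmonary disease",
    "systematic review protocol",
    "smoking cessation programme",
    "public health intervention",
    "quality assessment criteria",
    "cognitive behavioural therapy",
    "youth development programme",
]


def _symbol_vocabulary(V: int) -> list[str]:
    """Letter-only token names 'vaa', 'vab', ... (fixed width, sort-stable)."""
    letters = string.ascii_lowercase
    width = 1
    while 26**width < V:
        width += 1
    names = []
    for i in range(V):
        s, x = "", i
        for _ in range(width):
            s = letters[x % 26] + s
            x //= 26
        names.append("v" + s)
    return names


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic corpus.

    Defaults describe a desk-scale screening corpus in the regime real
    screening data occupies: 10 topics over a 12,000-entry vocabulary,
    2,000 documents of about 80 tokens (so the bag-of-words space is high
    dimensional and sparse relative to the documents), broad topics
    (beta=0.2), concentrated document mixtures (alpha=0.1), a 10 % relevant
    class and partially overlapping class topic profiles.
    """

    K: int = 10
    V: int = 12000
    n_docs: int = 2000
    mean_doc_len: float = 80.0
    alpha: float = 0.1
    beta: float = 0.2
    prevalence: float = 0.1
    class_topic_profiles: tuple[np.ndarray, np.ndarray] | None = None
    class_concentration: float = 5.0
    vocabulary: str = "symbols"  # "symbols" | "biomedical"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must lie strictly in (0, 1)")
        if self.K < 1 or self.V < 1 or self.n_docs < 1:
            raise ValidationError("K, V and n_docs must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("alpha and beta must be positive")
        if self.V < self.K:
            logger.warning(
                "V=%d < K=%d: degenerate topic recovery expected", self.V, self.K
            )
        if self.class_topic_profiles is not None:
            for p in self.class_topic_profiles:
                p = np.asarray(p, dtype=float)
                if p.shape != (self.K,) or not np.isclose(p.sum(), 1.0):
                    raise ValidationError(
                        "class profiles must be probability vectors over K topics"
                    )


def default_class_profiles(K: int, focus: float = 0.75) -> tuple[np.ndarray, np.ndarray]:
    """Relevant docs concentrate on the first fifth of topics, irrelevant on
    the rest, with a uniform floor so every topic stays reachable."""
    n_rel = max(1, K // 5)
    rel = np.full(K, (1 - focus) / K)
    rel[:n_rel] += focus / n_rel
    irr = np.full(K, (1 - focus) / K)
    if K > n_rel:
        irr[n_rel:] += focus / (K - n_rel)
    else:
        irr[:] = 1.0 / K
    return rel, irr


class SyntheticLDACorpus(NamedTuple):
    corpus: Corpus
    phi: np.ndarray       # K x V ground-truth topic-word rows
    thetas: np.ndarray    # n_docs x K ground-truth proportions
    entries: list[str]    # vocabulary entry per phi column
    null_profiles: bool = False


def _vocab_entries(spec: SyntheticSpec) -> list[str]:
    if spec.vocabulary == "symbols":
        return _symbol_vocabulary(spec.V)
    if spec.vocabulary == "biomedical":
        pool = BIOMEDICAL_PHRASES + BIOMEDICAL_WORDS
        if spec.V > len(pool):
            raise ValidationError(
                f"biomedical vocabulary holds at most {len(pool)} entries"
            )
        return pool[: spec.V]
    raise ValidationError(f"unknown vocabulary kind {spec.vocabulary!r}")


def _draw_phi(rng: np.random.Generator, K: int, V: int, beta: float) -> np.ndarray:
    phi = rng.dirichlet(np.full(V, beta), size=K)
    # guard against underflow with very sparse priors
    phi = np.clip(phi, 0.0, None) + 1e-300
    return phi / phi.sum(axis=1, keepdims=True)


def _sample_doc_tokens(
    rng: np.random.Generator, theta: np.ndarray, phi: np.ndarray, length: int
) -> list[int]:
    K, V = phi.shape
    topic_counts = rng.multinomial(length, theta / theta.sum())
    ids: list[int] = []
    for k in np.flatnonzero(topic_counts):
        word_counts = rng.multinomial(topic_counts[k], phi[k])
        ids.extend(int(w) for w in np.repeat(np.arange(V), word_counts))
    ids = np.array(ids, dtype=int)
    rng.shuffle(ids)
    return [int(i) for i in ids]


def _make_document(
    doc_id: str, entry_ids: list[int], entries: list[str], label: str
) -> LabeledDocument:
    surface: list[str] = []
    tokens: list[str] = []
    for i in entry_ids:
        entry = entries[i]
        surface.append(entry)
        tokens.append(entry.replace(" ", "_") if " " in entry else entry)
    return LabeledDocument(
        doc_id=doc_id, title="", abstract=" ".join(surface),
        label=label, tokens=tokens,
    )


def generate_lda_corpus(spec: SyntheticSpec) -> SyntheticLDACorpus:
    """Unlabelled corpus drawn from the LDA generative process, with the
    ground-truth phi and theta returned for recovery experiments."""
    rng = np.random.default_rng(spec.seed)
    entries = _vocab_entries(spec)
    phi = _draw_phi(rng, spec.K, len(entries), spec.beta)
    thetas = rng.dirichlet(np.full(spec.K, spec.alpha), size=spec.n_docs)
    docs = []
    for m in range(spec.n_docs):
        length = max(1, int(rng.poisson(spec.mean_doc_len)))
        ids = _sample_doc_tokens(rng, thetas[m], phi, length)
        docs.append(_make_document(f"syn{m:05d}", ids, entries, UNKNOWN))
    corpus = Corpus(documents=docs)
    corpus.build_vocabulary()
    return SyntheticLDACorpus(corpus, phi, thetas, entries)


def generate_screening_corpus(spec: SyntheticSpec) -> SyntheticLDACorpus:
    """Labelled imbalanced corpus: Bernoulli(prevalence) labels, per-class
    Dirichlet-centred topic mixtures, shared topics."""
    rng = np.random.default_rng(spec.seed)
    profiles = spec.class_topic_profiles or default_class_profiles(spec.K)
    rel_profile = np.asarray(profiles[0], dtype=float)
    irr_profile = np.asarray(profiles[1], dtype=float)
    null_profiles = bool(np.allclose(rel_profile, irr_profile))
    if null_profiles:
        logger.warning("identical class profiles: generating a null corpus")
    entries = _vocab_entries(spec)
    phi = _draw_phi(rng, spec.K, len(entries), spec.beta)
    labels = rng.random(spec.n_docs) < spec.prevalence
    s = spec.class_concentration
    thetas = np.empty((spec.n_docs, spec.K))
    docs = []
    for m in range(spec.n_docs):
        profile = rel_profile if labels[m] else irr_profile
        theta = rng.dirichlet(s * profile + 1e-6)
        thetas[m] = theta
        length = max(1, int(rng.poisson(spec.mean_doc_len)))
        ids = _sample_doc_tokens(rng, theta, phi, length)
        docs.append(
            _make_document(
                f"doc{m:05d}", ids, entries,
                RELEVANT if labels[m] else IRRELEVANT,
            )
        )
    corpus = Corpus(documents=docs)
    corpus.build_vocabulary()
    return SyntheticLDACorpus(corpus, phi, thetas, entries, null_profiles)


def embed_fitted_phi(model, entries: list[str]) -> np.ndarray:
    """Express a fitted model's topic-word rows over the generator's entry
    space, for comparison with the ground-truth phi.

    Entries never observed in the fitted corpus get zero mass; rows are
    renormalised.
    """
    if model.vocabulary_ is None:
        raise ValidationError("model has no vocabulary")
    entry_index = {e: i for i, e in enumerate(entries)}
    est = np.zeros((model.components_.shape[0], len(entries)))
    for tok, j in model.vocabulary_.items():
        entry = tok.replace("_", " ")
        if entry in entry_index:
            est[:, entry_index[entry]] = model.components_[:, j]
    sums = est.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return est / sums


def make_count_fixture_corpus(
    n_relevant: int, n_total: int, seed: int = 0
) -> Corpus:
    """Minimal corpus with exact class counts, for prevalence arithmetic."""
    if not 0 <= n_relevant <= n_total:
        raise ValidationError("need 0 <= n_relevant <= n_total")
    rng = np.random.default_rng(seed)
    words = _symbol_vocabulary(50)
    docs = []
    for i in range(n_total):
        text = " ".join(rng.choice(words, size=3))
        docs.append(
            LabeledDocument(
                doc_id=f"c{i:06d}", title=text,
                label=RELEVANT if i < n_relevant else IRRELEVANT,
            )
        )
    return Corpus(documents=docs)
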