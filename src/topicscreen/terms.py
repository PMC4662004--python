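"""Automatic multi-word term recognition by the C-value method.

Candidate terms are contiguous token windows (2-4 tokens) whose coarse
part-of-speech pattern matches a noun-phrase filter such as ``ADJ*NOUN+``.
Each candidate is scored by C-value, a termhood measure that rewards longer
and more frequent candidates while discounting candidates that mostly occur
nested inside longer ones:

    non-nested a:  C(a) = log2(|a|) * f(a)
    nested a:      C(a) = log2(|a|) * ( f(a) - (1/|T_a|) * sum_{b in T_a} f(b) )

where |a| is the candidate's length in tokens, f its corpus frequency and
T_a the set of extracted candidates strictly containing it.  Accepted terms
form a lexicon used to fuse term occurrences in token streams into single
underscore-joined tokens (longest match wins, scanning left to right), which
makes downstream topics render multi-word units like "logistic regression
model" as one symbol.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Protocol, Sequence

from .errors import ParseError, ValidationError

NOUN, ADJ, PREP, OTHER = "NOUN", "ADJ", "PREP", "OTHER"

#: single-letter code per coarse tag, used to regex-match POS patterns
_TAG_CODE = {NOUN: "N", ADJ: "A", PREP: "P", OTHER: "O"}

DEFAULT_POS_FILTER = "ADJ*NOUN+"
#: classic richer noun-phrase filter admitting an internal preposition
NOUN_PREP_FILTER = "(ADJ|NOUN)*NOUN(PREP(ADJ|NOUN)*NOUN)?"


class TaggedToken(NamedTuple):
    token: str
    pos: str


class Tagger(Protocol):
    """Anything that maps a token sequence to coarse POS tags."""

    def tag(self, tokens: Sequence[str]) -> list[TaggedToken]: ...


class RuleBasedTagger:
    """Dependency-light coarse tagger for noun-phrase mining.

    Closed-class words (prepositions, determiners, pronouns, auxiliaries) come
    from small lexicons; adjectives are recognised by a lexicon plus common
    adjectival suffixes; everything else defaults to NOUN, which is the
    standard permissive choice when mining term candidates from abstracts.
    External taggers can replace this class via the :class:`Tagger` protocol.
    """

    PREPOSITIONS = frozenset(
        "of in on at by for with from into onto over under between among".split()
    )
    _CLOSED = frozenset(
        """a an the this that these those and or but nor not no is are was were be
        been being have has had do does did will would shall should can could may
        might must it its they them he she we you i his her their our your as if
        than then there here when where while because so such very most more each
        both all any some few other same own to too also however during after
        before about against through""".split()
    )
    ADJECTIVES = frozenset(
        """clinical logistic chronic obstructive pulmonary randomised randomized
        controlled systematic statistical medical social cognitive behavioural
        behavioral longitudinal multidimensional cultural mental public primary
        secondary acute severe mild adverse effective significant relevant
        automatic latent generative """.split()
    )
    _ADJ_SUFFIXES = (
        "al", "ive", "ous", "ful", "less", "able", "ible", "ary", "ic",
        "ical", "ish", "ent",
    )

    def tag(self, tokens: Sequence[str]) -> list[TaggedToken]:
        return [TaggedToken(t, self._tag_one(t)) for t in tokens]

    def _tag_one(self, token: str) -> str:
        if token in self.PREPOSITIONS:
            return PREP
        if token in self._CLOSED:
            return OTHER
        if token in self.ADJECTIVES:
            return ADJ
        if len(token) > 4 and token.endswith(self._ADJ_SUFFIXES):
            return ADJ
        return NOUN


@dataclass
class TermCandidate:
    """A 2-4 token candidate term with its frequency and nesting links."""

    words: tuple[str, ...]
    freq: int = 0
    containers: set[tuple[str, ...]] = field(default_factory=set)
    cvalue: float = float("nan")

    def __post_init__(self):
        if not 2 <= len(self.words) <= 4:
            raise ValidationError("candidate terms span 2 to 4 tokens")


@dataclass
class TermLexicon:
    """Accepted terms ordered by descending C-value.

    Ties break by descending length, then lexicographically, so the ordering
    is total and deterministic.
    """

    terms: list[TermCandidate]

    def __post_init__(self):
        seqs = [t.words for t in self.terms]
        if len(seqs) != len(set(seqs)):
            raise ValidationError("duplicate word sequences in lexicon")
        self.terms.sort(key=lambda t: (-t.cvalue, -len(t.words), t.words))

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def word_sequences(self) -> set[tuple[str, ...]]:
        return {t.words for t in self.terms}

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.terms:
                fh.write(f"{' '.join(t.words)}\t{t.freq}\t{t.cvalue:.6g}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "TermLexicon":
        terms = []
        for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError("expected term<TAB>freq<TAB>cvalue", lineno)
            terms.append(
                TermCandidate(
                    words=tuple(parts[0].split()),
                    freq=int(parts[1]),
                    cvalue=float(parts[2]),
                )
            )
        return cls(terms=terms)


def _compile_pos_filter(pos_filter: str) -> re.Pattern:
    pattern = pos_filter
    for name, code in _TAG_CODE.items():
        pattern = pattern.replace(name, code)
    pattern = pattern.replace(" ", "")
    return re.compile(pattern)


def extract_candidates(
    tagged_docs: Iterable[Sequence[TaggedToken]],
    pos_filter: str = DEFAULT_POS_FILTER,
    max_len: int = 4,
) -> list[TermCandidate]:
    """Enumerate every contiguous window of 2..max_len tokens matching the filter.

    Both maximal matches and all nested sub-windows are emitted (e.g. the tag
    run ADJ NOUN NOUN yields the trigram and both bigrams), with corpus-wide
    frequencies and the containment relation populated.
    """
    if max_len < 2:
        raise ValidationError("max_len must be at least 2")
    rx = _compile_pos_filter(pos_filter)
    counts: dict[tuple[str, ...], int] = {}
    for doc in tagged_docs:
        tags = "".join(_TAG_CODE[t.pos] for t in doc)
        words = [t.token for t in doc]
        n = len(doc)
        for length in range(2, max_len + 1):
            for start in range(n - length + 1):
                if rx.fullmatch(tags, start, start + length):
                    seq = tuple(words[start : start + length])
                    counts[seq] = counts.get(seq, 0) + 1
    candidates = {seq: TermCandidate(words=seq, freq=c) for seq, c in counts.items()}
    for seq, cand in candidates.items():
        for other in candidates:
            if len(other) > len(seq) and _contains(other, seq):
                cand.containers.add(other)
    return sorted(candidates.values(), key=lambda c: c.words)


def _contains(longer: tuple[str, ...], shorter: tuple[str, ...]) -> bool:
    k = len(shorter)
    return any(longer[i : i + k] == shorter for i in range(len(longer) - k + 1))


def cvalue_score(candidates: list[TermCandidate]) -> list[TermCandidate]:
    """Assign C-values, processing candidates longest-first.

    The nested penalty subtracts the mean frequency of the containing
    candidates, so a candidate seen only inside one container scores zero.
    """
    by_words = {c.words: c for c in candidates}
    for cand in sorted(candidates, key=lambda c: -len(c.words)):
        log_len = math.log2(len(cand.words))
        if not cand.containers:
            cand.cvalue = log_len * cand.freq
        else:
            container_freq = [by_words[w].freq for w in cand.containers]
            penalty = sum(container_freq) / len(container_freq)
            cand.cvalue = log_len * (cand.freq - penalty)
    return candidates


def build_lexicon(
    candidates: list[TermCandidate],
    min_cvalue: float = 0.0,
    min_freq: int = 2,
) -> TermLexicon:
    """Keep candidates with cvalue strictly above ``min_cvalue`` and
    frequency at least ``min_freq``."""
    scored = cvalue_score(candidates)
    kept = [c for c in scored if c.cvalue > min_cvalue and c.freq >= min_freq]
    return TermLexicon(terms=kept)


def extract_terms(
    token_docs: Iterable[Sequence[str]],
    tagger: Tagger | None = None,
    pos_filter: str = DEFAULT_POS_FILTER,
    max_len: int = 4,
    min_cvalue: float = 0.0,
    min_freq: int = 2,
) -> TermLexicon:
    """Tag, extract candidates, score and threshold in one call."""
    tagger = tagger or RuleBasedTagger()
    tagged = [tagger.tag(doc) for doc in token_docs]
    cands = extract_candidates(tagged, pos_filter=pos_filter, max_len=max_len)
    return build_lexicon(cands, min_cvalue=min_cvalue, min_freq=min_freq)


def locate_terms(tokens: Sequence[str], lexicon: TermLexicon) -> list[str]:
    """Fuse lexicon terms in a token stream, longest match first.

    Scans left to right; at each position the longest term (up to 4 tokens)
    starting there is joined with underscores into one token, and its tokens
    are consumed.  Splitting the output on underscores restores the input.
    """
    term_set = lexicon.word_sequences()
    max_len = max((len(t) for t in term_set), default=0)
    out: list[str] = []
    i, n = 0, len(tokens)
    while i < n:
        fused = False
        for length in range(min(max_len, n - i), 1, -1):
            seq = tuple(tokens[i : i + length])
            if seq in term_set:
                out.append("_".join(seq))
                i += length
                fused = True
                break
        if not fused:
            out.append(tokens[i])
            i += 1
    return out
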