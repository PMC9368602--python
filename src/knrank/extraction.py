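"""Finding extraction from record text: tokenization, BIO tagging, CRF decoding,
and negation scoping.

The default tagger is greedy forward maximum matching against a lexicon — a
deliberately transparent baseline.  Any external sequence model can plug in
instead by supplying :class:`CrfScores` (per-token emission scores plus a tag
transition matrix with START/STOP states) and reusing :func:`crf_decode`;
training such a model is out of scope here.

Negation handling follows the cue-dictionary convention of clinical NLP:
an extracted mention is flipped to *negated* polarity when a negation cue
occurs in a short window immediately before it, or inside its span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .kn import Lexicon

logger = logging.getLogger(__name__)

__all__ = [
    "Polarity",
    "TokenSequence",
    "TagSequence",
    "CrfScores",
    "FindingMention",
    "tokenize",
    "dictionary_tag",
    "crf_score",
    "crf_log_likelihood",
    "crf_decode",
    "tags_to_mentions",
    "apply_negation",
]


class Polarity(str, Enum):
    AFFIRMED = "affirmed"
    NEGATED = "negated"


def _is_cjk(ch: str) -> bool:
    cp = ord(ch)
    return (
        0x4E00 <= cp <= 0x9FFF
        or 0x3400 <= cp <= 0x4DBF
        or 0xF900 <= cp <= 0xFAFF
        or 0x3000 <= cp <= 0x303F
    )


@dataclass
class TokenSequence:
    """An ordered token list plus the separator that re-joins it to text.

    ``sep`` is ``""`` for character-level (CJK) tokenization and ``" "`` for
    whitespace tokenization, so ``sep.join(tokens[a:b])`` always reproduces
    the surface of a span.
    """

    tokens: list[str]
    record_id: str | None = None
    sep: str = " "

    def __post_init__(self) -> None:
        if any(t == "" for t in self.tokens):
            raise ValueError("tokens must be non-empty strings")

    def __len__(self) -> int:
        return len(self.tokens)

    def surface(self, start: int, end: int) -> str:
        return self.sep.join(self.tokens[start:end])


def tokenize(text: str, record_id: str | None = None, mode: str = "auto") -> TokenSequence:
    """Split *text* into tokens.

    ``mode="char"`` emits one token per non-space character (the faithful
    granularity for Chinese clinical text); ``mode="word"`` splits on
    whitespace; ``mode="auto"`` picks ``char`` when the text contains any CJK
    character.
    """
    if mode == "auto":
        mode = "char" if any(_is_cjk(ch) for ch in text) else "word"
    if mode == "char":
        return TokenSequence([ch for ch in text if not ch.isspace()], record_id, sep="")
    if mode == "word":
        return TokenSequence(text.split(), record_id, sep=" ")
    raise ValueError(f"unknown tokenization mode {mode!r}")


@dataclass
class TagSequence:
    """BIO (or arbitrary-label) tags aligned one-to-one with a token sequence."""

    tags: list[str]

    def __len__(self) -> int:
        return len(self.tags)


def _term_tokens(term: str, sep: str) -> tuple[str, ...]:
    if sep == "":
        return tuple(ch for ch in term if not ch.isspace())
    return tuple(term.split())


def dictionary_tag(seq: TokenSequence, lexicon: Lexicon) -> TagSequence:
    """Greedy forward maximum matching: longest lexicon term first, left to
    right, non-overlapping; matched spans become ``B I...``, the rest ``O``."""
    if not lexicon.entries:
        raise ValueError("lexicon must be non-empty")
    by_tokens: dict[tuple[str, ...], None] = {}
    for surface, _fid in lexicon.entries:
        toks = _term_tokens(surface, seq.sep)
        if toks:
            by_tokens[toks] = None
    lengths = sorted({len(t) for t in by_tokens}, reverse=True)
    n = len(seq.tokens)
    tags = ["O"] * n
    i = 0
    while i < n:
        matched = 0
        for L in lengths:
            if i + L <= n and tuple(seq.tokens[i : i + L]) in by_tokens:
                matched = L
                break
        if matched:
            tags[i] = "B"
            for j in range(i + 1, i + matched):
                tags[j] = "I"
            i += matched
        else:
            i += 1
    return TagSequence(tags)


# ---------------------------------------------------------------------------
# Linear-chain CRF over supplied score matrices
# ---------------------------------------------------------------------------


@dataclass
class CrfScores:
    """Emission and transition scores for a linear-chain CRF.

    ``emissions`` has shape (n, K); ``transitions`` has shape (K+2, K+2) with
    the START state at index K and STOP at K+1.  A path's score is

        A[START, y1] + sum_i A[y_i, y_{i+1}] + A[y_n, STOP] + sum_i P[i, y_i].
    """

    emissions: np.ndarray
    transitions: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        n, k = self.emissions.shape
        if n < 1 or k < 1:
            raise ValueError("emissions must be (n>=1, K>=1)")
        if self.transitions.shape != (k + 2, k + 2):
            raise ValueError(
                f"transitions must be (K+2, K+2)={(k + 2, k + 2)}, "
                f"got {self.transitions.shape}"
            )
        if not (np.isfinite(self.emissions).all() and np.isfinite(self.transitions).all()):
            raise ValueError("CRF scores must be finite")
        if self.labels is not None and len(self.labels) != k:
            raise ValueError("labels must have length K")

    @property
    def n(self) -> int:
        return self.emissions.shape[0]

    @property
    def k(self) -> int:
        return self.emissions.shape[1]

    @property
    def start(self) -> int:
        return self.k

    @property
    def stop(self) -> int:
        return self.k + 1

    def tag_names(self) -> list[str]:
        return self.labels if self.labels is not None else [f"y{i}" for i in range(self.k)]


def _tag_indices(scores: CrfScores, tags: Sequence[int] | TagSequence) -> list[int]:
    if isinstance(tags, TagSequence):
        names = scores.tag_names()
        index = {name: i for i, name in enumerate(names)}
        try:
            idx = [index[t] for t in tags.tags]
        except KeyError as exc:
            raise ValueError(f"tag {exc.args[0]!r} not in CRF labels {names}") from None
    else:
        idx = list(tags)
    if len(idx) != scores.n:
        raise ValueError(f"tag sequence length {len(idx)} != {scores.n} tokens")
    if any(not (0 <= t < scores.k) for t in idx):
        raise ValueError("tag index out of range")
    return idx


def crf_score(scores: CrfScores, tags: Sequence[int] | TagSequence) -> float:
    """Path score s(X, Y): transition chain from START to STOP plus emissions."""
    y = _tag_indices(scores, tags)
    a, p = scores.transitions, scores.emissions
    total = a[scores.start, y[0]]
    for i in range(len(y) - 1):
        total += a[y[i], y[i + 1]]
    total += a[y[-1], scores.stop]
    total += sum(p[i, yi] for i, yi in enumerate(y))
    return float(total)


def _log_partition(scores: CrfScores) -> float:
    a, p = scores.transitions, scores.emissions
    k = scores.k
    alpha = a[scores.start, :k] + p[0]
    for i in range(1, scores.n):
        alpha = logsumexp(alpha[:, None] + a[:k, :k], axis=0) + p[i]
    return float(logsumexp(alpha + a[:k, scores.stop]))


def crf_log_likelihood(scores: CrfScores, tags: Sequence[int] | TagSequence) -> float:
    """log P(Y|X) = s(X,Y) − log Σ_Y' exp(s(X,Y')), forward algorithm in log space."""
    return crf_score(scores, tags) - _log_partition(scores)


def crf_decode(scores: CrfScores) -> TagSequence:
    """Viterbi decoding of the best-scoring tag path.

    Ties are broken toward the lowest tag index at every argmax, so the
    decoded path is deterministic.
    """
    a, p = scores.transitions, scores.emissions
    n, k = scores.n, scores.k
    delta = a[scores.start, :k] + p[0]
    back = np.zeros((n, k), dtype=int)
    for i in range(1, n):
        cand = delta[:, None] + a[:k, :k]          # cand[prev, cur]
        back[i] = np.argmax(cand, axis=0)          # argmax -> lowest index on ties
        delta = cand[back[i], np.arange(k)] + p[i]
    final = delta + a[:k, scores.stop]
    last = int(np.argmax(final))
    path = [last]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    path.reverse()
    names = scores.tag_names()
    return TagSequence([names[t] for t in path])


# ---------------------------------------------------------------------------
# Span recovery and negation
# ---------------------------------------------------------------------------


@dataclass
class FindingMention:
    """A surface span extracted from a record, with polarity.

    Spans are 0-based half-open token offsets; ``surface`` equals the joined
    token slice.  ``finding_id`` is filled in once the mention is matched
    against the knowledge network.
    """

    surface: str
    span: tuple[int, int]
    polarity: Polarity = Polarity.AFFIRMED
    finding_id: str | None = None

    def __post_init__(self) -> None:
        start, end = self.span
        if not (0 <= start < end):
            raise ValueError(f"invalid span {self.span}")


def tags_to_mentions(seq: TokenSequence, tags: TagSequence) -> list[FindingMention]:
    """Recover mentions from maximal ``B I...`` runs; polarity starts affirmed.

    A dangling ``I`` (after ``O`` or at sequence start) is repaired by
    treating it as ``B`` and logging a warning — robust to imperfect external
    taggers.
    """
    if len(tags) != len(seq):
        raise ValueError(f"tags length {len(tags)} != tokens length {len(seq)}")
    mentions: list[FindingMention] = []
    start: int | None = None
    for i, tag in enumerate(tags.tags):
        if tag == "B":
            if start is not None:
                mentions.append(_mention(seq, start, i))
            start = i
        elif tag == "I":
            if start is None:
                logger.warning(
                    "dangling I tag at token %d of %s repaired as B", i, seq.record_id
                )
                start = i
        elif tag == "O":
            if start is not None:
                mentions.append(_mention(seq, start, i))
                start = None
        else:
            raise ValueError(f"unexpected tag {tag!r}; expected B/I/O")
    if start is not None:
        mentions.append(_mention(seq, start, len(tags)))
    return mentions


def _mention(seq: TokenSequence, start: int, end: int) -> FindingMention:
    return FindingMention(surface=seq.surface(start, end), span=(start, end))


def _find_cue_spans(seq: TokenSequence, cues: Sequence[str]) -> list[tuple[int, int]]:
    cue_tokens = sorted(
        {t for t in (_term_tokens(c, seq.sep) for c in cues) if t},
        key=len,
        reverse=True,
    )
    spans: list[tuple[int, int]] = []
    n = len(seq.tokens)
    for i in range(n):
        for toks in cue_tokens:
            L = len(toks)
            if i + L <= n and tuple(seq.tokens[i : i + L]) == toks:
                spans.append((i, i + L))
                break
    return spans


def apply_negation(
    seq: TokenSequence,
    mentions: Sequence[FindingMention],
    cues: Sequence[str],
    window: int = 2,
) -> list[FindingMention]:
    """Set each mention's polarity from the negation cues in scope.

    A mention becomes negated iff a cue span ends at most *window* tokens
    before the mention starts, or lies inside the mention span; otherwise it
    is affirmed.  Spans, order, and count are preserved, and the operation is
    idempotent (polarity is recomputed from the text alone).
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    cue_spans = _find_cue_spans(seq, cues)
    out: list[FindingMention] = []
    for m in mentions:
        ms, me = m.span
        negated = any(
            (ce <= ms and ms - ce <= window) or (cs >= ms and ce <= me)
            for cs, ce in cue_spans
        )
        out.append(replace(m, polarity=Polarity.NEGATED if negated else Polarity.AFFIRMED))
    return out
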