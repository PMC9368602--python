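"""Tokenization, dictionary BIO tagging, CRF score/decoding oracles, negation."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from knrank import (
    CrfScores,
    FindingMention,
    Lexicon,
    Polarity,
    TagSequence,
    TokenSequence,
    apply_negation,
    crf_decode,
    crf_log_likelihood,
    crf_score,
    dictionary_tag,
    tags_to_mentions,
    tokenize,
)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------


def test_tokenize_autodetects_script():
    cjk = tokenize("患者 腹痛")
    assert cjk.tokens == ["患", "者", "腹", "痛"] and cjk.sep == ""
    latin = tokenize("patient reports pain")
    assert latin.tokens == ["patient", "reports", "pain"] and latin.sep == " "


def test_tokenize_mode_override_and_surface():
    seq = tokenize("a b c", mode="word")
    assert seq.surface(1, 3) == "b c"
    with pytest.raises(ValueError):
        tokenize("abc", mode="sentence")


# ---------------------------------------------------------------------------
# Dictionary tagging
# ---------------------------------------------------------------------------


def _lex(*terms):
    return Lexicon(entries=[(t, f"F{i}") for i, t in enumerate(terms)], negation_cues=["no"])


def test_dictionary_tag_single_match():
    seq = tokenize("患者腹痛")
    tags = dictionary_tag(seq, _lex("腹痛"))
    assert tags.tags == ["O", "O", "B", "I"]


def test_dictionary_tag_longest_term_wins():
    seq = tokenize("出现腹痛待查情况")
    tags = dictionary_tag(seq, _lex("腹痛", "腹痛待查"))
    assert tags.tags == ["O", "O", "B", "I", "I", "I", "O", "O"]


def test_dictionary_tag_no_match_is_all_O():
    seq = tokenize("plain filler words", mode="word")
    assert dictionary_tag(seq, _lex("fever")).tags == ["O"] * 3


def test_dictionary_tag_rejects_empty_lexicon():
    with pytest.raises(ValueError):
        dictionary_tag(tokenize("x", mode="word"), Lexicon(entries=[]))


def _all_substring_matches(tokens, term_tuples):
    """Quadratic oracle: every position/length where some term occurs."""
    hits = set()
    for i in range(len(tokens)):
        for t in term_tuples:
            if tuple(tokens[i : i + len(t)]) == t:
                hits.add((i, i + len(t)))
    return hits


@pytest.mark.parametrize("seed", range(8))
def test_dictionary_tag_spans_are_verbatim_lexicon_terms(seed):
    rng = np.random.default_rng(seed)
    vocab = list("abcde")
    terms = sorted(
        {
            "".join(rng.choice(vocab, size=rng.integers(1, 4)))
            for _ in range(6)
        }
    )
    text = "".join(rng.choice(vocab, size=40))
    seq = TokenSequence(list(text), sep="")
    tags = dictionary_tag(seq, _lex(*terms))
    mentions = tags_to_mentions(seq, tags)
    oracle = _all_substring_matches(seq.tokens, [tuple(t) for t in terms])
    spans = [m.span for m in mentions]
    # every tagged span is a verbatim occurrence of a lexicon term
    assert set(spans) <= oracle
    # non-overlapping, in order
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


# ---------------------------------------------------------------------------
# CRF: score, likelihood, decoding against enumeration oracles
# ---------------------------------------------------------------------------


def random_crf(rng, n, k):
    return CrfScores(
        emissions=rng.normal(size=(n, k)),
        transitions=rng.normal(size=(k + 2, k + 2)),
    )


def enum_scores(scores):
    """Score of every one of the K^n tag paths, via independent summation."""
    n, k = scores.n, scores.k
    a, p = scores.transitions, scores.emissions
    out = {}
    for path in itertools.product(range(k), repeat=n):
        s = a[k, path[0]] + a[path[-1], k + 1]
        for i in range(n - 1):
            s += a[path[i], path[i + 1]]
        for i, y in enumerate(path):
            s += p[i, y]
        out[path] = s
    return out


def test_crf_score_zero_transitions_is_emission_sum():
    p = np.array([[1.0, 2.0], [0.5, -1.0], [3.0, 0.0]])
    scores = CrfScores(p, np.zeros((4, 4)))
    assert crf_score(scores, [1, 0, 0]) == pytest.approx(2.0 + 0.5 + 3.0)


def test_crf_score_single_token():
    scores = CrfScores(np.array([[1.0, 2.0]]), np.zeros((4, 4)))
    assert crf_score(scores, [1]) == pytest.approx(2.0)


def test_crf_score_length_mismatch_rejected():
    scores = CrfScores(np.zeros((3, 2)), np.zeros((4, 4)))
    with pytest.raises(ValueError):
        crf_score(scores, [0, 1])
    with pytest.raises(ValueError):
        crf_score(scores, [0, 1, 5])


@pytest.mark.parametrize("seed", range(5))
def test_crf_score_matches_term_by_term_oracle(seed):
    rng = np.random.default_rng(seed)
    scores = random_crf(rng, 4, 3)
    oracle = enum_scores(scores)
    for path in [(0, 1, 2, 0), (2, 2, 2, 2), (1, 0, 1, 0)]:
        assert crf_score(scores, list(path)) == pytest.approx(oracle[path], abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_crf_log_likelihood_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    scores = random_crf(rng, 5, 3)
    oracle = enum_scores(scores)
    log_z = logsumexp(list(oracle.values()))
    path = [0, 2, 1, 1, 0]
    expected = oracle[tuple(path)] - log_z
    assert crf_log_likelihood(scores, path) == pytest.approx(expected, abs=1e-9)


def test_crf_probabilities_sum_to_one():
    rng = np.random.default_rng(42)
    scores = random_crf(rng, 3, 3)
    total = sum(
        np.exp(crf_log_likelihood(scores, list(path)))
        for path in itertools.product(range(3), repeat=3)
    )
    assert total == pytest.approx(1.0, abs=1e-9)


def test_crf_log_likelihood_degenerate_single_tag_is_zero():
    scores = CrfScores(np.array([[0.7], [0.1]]), np.random.default_rng(0).normal(size=(3, 3)))
    assert crf_log_likelihood(scores, [0, 0]) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_crf_decode_attains_enumeration_max(seed):
    rng = np.random.default_rng(seed)
    scores = random_crf(rng, 6, 4)
    decoded = crf_decode(scores)
    idx = [scores.tag_names().index(t) for t in decoded.tags]
    best = max(enum_scores(scores).values())
    assert crf_score(scores, idx) == pytest.approx(best, abs=1e-9)


def test_crf_decode_zero_transitions_is_argmax():
    p = np.array([[0.0, 1.0, 0.5], [2.0, 0.1, 0.3]])
    scores = CrfScores(p, np.zeros((5, 5)), labels=["B", "I", "O"])
    assert crf_decode(scores).tags == ["I", "B"]


def test_crf_decode_all_equal_ties_to_lowest_index():
    scores = CrfScores(np.zeros((4, 3)), np.zeros((5, 5)))
    assert crf_decode(scores).tags == ["y0"] * 4


def test_crf_decode_beats_random_paths():
    rng = np.random.default_rng(7)
    scores = random_crf(rng, 8, 4)
    decoded = crf_decode(scores)
    idx = [scores.tag_names().index(t) for t in decoded.tags]
    best = crf_score(scores, idx)
    for _ in range(1000):
        rand = rng.integers(0, 4, size=8).tolist()
        assert crf_score(scores, rand) <= best + 1e-12


def test_crf_scores_validation():
    with pytest.raises(ValueError):
        CrfScores(np.zeros((2, 2)), np.zeros((3, 3)))  # wrong transition shape
    with pytest.raises(ValueError):
        CrfScores(np.array([[np.inf, 0.0]]), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# BIO span recovery
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "tags, spans",
    [
        (["O", "O", "B", "I", "O"], [(2, 4)]),
        (["B", "I", "B", "I"], [(0, 2), (2, 4)]),
        (["B", "B", "B"], [(0, 1), (1, 2), (2, 3)]),
        (["O", "O", "O"], []),
        (["B", "I", "I"], [(0, 3)]),
    ],
)
def test_tags_to_mentions_spans(tags, spans):
    seq = TokenSequence(list("abcde")[: len(tags)], sep="")
    mentions = tags_to_mentions(seq, TagSequence(tags))
    assert [m.span for m in mentions] == spans
    assert all(m.polarity is Polarity.AFFIRMED for m in mentions)
    assert all(m.surface == seq.surface(*m.span) for m in mentions)


def test_tags_to_mentions_repairs_dangling_I(caplog):
    seq = TokenSequence(list("abcd"), sep="")
    with caplog.at_level("WARNING", logger="knrank.extraction"):
        mentions = tags_to_mentions(seq, TagSequence(["O", "I", "I", "O"]))
    assert [m.span for m in mentions] == [(1, 3)]
    assert any("repaired" in r.message for r in caplog.records)
    # strict parse of the explicitly repaired sequence agrees
    repaired = tags_to_mentions(seq, TagSequence(["O", "B", "I", "O"]))
    assert [m.span for m in repaired] == [(1, 3)]


def test_tags_to_mentions_length_mismatch():
    with pytest.raises(ValueError):
        tags_to_mentions(TokenSequence(["a"], sep=""), TagSequence(["O", "O"]))


# ---------------------------------------------------------------------------
# Negation scoping
# ---------------------------------------------------------------------------


def _mention(seq, start, end):
    return FindingMention(surface=seq.surface(start, end), span=(start, end))


def test_negation_cue_before_mention():
    seq = tokenize("无腹痛")
    out = apply_negation(seq, [_mention(seq, 1, 3)], ["无"], window=2)
    assert out[0].polarity is Polarity.NEGATED


def test_negation_no_cues_leaves_affirmed():
    seq = tokenize("patient has nausea", mode="word")
    out = apply_negation(seq, [_mention(seq, 2, 3)], ["no"], window=2)
    assert out[0].polarity is Polarity.AFFIRMED


@pytest.mark.parametrize("gap, negated", [(0, True), (1, True), (2, True), (3, False)])
def test_negation_window_boundary(gap, negated):
    # cue ends `gap` tokens before the mention starts; window 2
    tokens = ["no"] + ["x"] * gap + ["pain"]
    seq = TokenSequence(tokens, sep=" ")
    m = _mention(seq, 1 + gap, 2 + gap)
    out = apply_negation(seq, [m], ["no"], window=2)
    # brute-force distance scan agrees
    brute = any(
        (ce <= m.span[0] and m.span[0] - ce <= 2)
        for ce in [i + 1 for i, t in enumerate(tokens) if t == "no"]
    )
    assert (out[0].polarity is Polarity.NEGATED) == negated == brute


def test_negation_cue_inside_span():
    seq = tokenize("mass not palpable region", mode="word")
    m = _mention(seq, 0, 3)  # span contains "not"
    out = apply_negation(seq, [m], ["not"], window=0)
    assert out[0].polarity is Polarity.NEGATED


def test_negation_idempotent_and_preserves_spans():
    seq = tokenize("no fever and chills", mode="word")
    mentions = [_mention(seq, 1, 2), _mention(seq, 3, 4)]
    once = apply_negation(seq, mentions, ["no"], window=2)
    twice = apply_negation(seq, once, ["no"], window=2)
    assert [(m.span, m.polarity) for m in once] == [(m.span, m.polarity) for m in twice]
    assert [m.span for m in once] == [m.span for m in mentions]
    assert len(once) == len(mentions)
    assert once[0].polarity is Polarity.NEGATED  # gap 0
    assert once[1].polarity is Polarity.NEGATED  # gap 2, within window
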