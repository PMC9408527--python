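"""Frame parsing and the adjacent / within-sentence matching engine."""

import numpy as np
import pytest

from narraquery.corpus_io import segment_sentences
from narraquery.frames import (
    Binding,
    Constituent,
    ConstituentKind,
    Frame,
    FrameParseError,
    match_document,
    match_frame,
    parse_frame,
    parse_frame_file,
)
from narraquery.lexicon import Lexicon, WordGroup

from conftest import brute_force_matches, make_document


def _lex(**groups):
    return Lexicon(
        groups={
            name: WordGroup(name=name, members=frozenset(members))
            for name, members in groups.items()
        }
    )


def _sent(text):
    (sent,) = segment_sentences(text)
    return sent


def test_parse_literals_adjacent():
    frame = parse_frame('"not" ++ "speak"')
    assert [c.value for c in frame.constituents] == ["not", "speak"]
    assert [c.kind for c in frame.constituents] == [ConstituentKind.LITERAL] * 2
    assert frame.bindings == (Binding.ADJACENT,)


def test_parse_group_refs_within_sentence():
    frame = parse_frame("G:physician_noun + G:negative_verb")
    assert [c.kind for c in frame.constituents] == [ConstituentKind.GROUP_REF] * 2
    assert frame.bindings == (Binding.WITHIN_SENTENCE,)


def test_parse_is_whitespace_insensitive():
    a = parse_frame('"language"+G:difficulty_noun++"here"')
    b = parse_frame('  "language" +  G:difficulty_noun ++ "here" ')
    assert a.constituents == b.constituents and a.bindings == b.bindings


@pytest.mark.parametrize(
    "expr",
    [
        '"language" ++ + "problem"',  # stacked operators
        '+ "x"',                      # leading operator
        '"x" ++',                     # dangling operator
        '"x" "y"',                    # missing operator
        "bare_word",                  # unquoted, unprefixed
        "",                           # empty expression
    ],
)
def test_parse_errors(expr):
    with pytest.raises(FrameParseError):
        parse_frame(expr)


def test_parse_error_carries_position():
    with pytest.raises(FrameParseError, match="position"):
        parse_frame('"x" ++ ++ "y"')


def test_parse_frame_file_skips_comments(tmp_path):
    f = tmp_path / "q.txt"
    f.write_text('# comment\n"a" + "b"\n\n"c" ++ "d"  # trailing\n', encoding="utf-8")
    frames = parse_frame_file(f)
    assert len(frames) == 2
    assert frames[0].id == "q:2"


def test_within_sentence_match_and_adjacent_miss():
    lex = _lex()
    sent = _sent("The language was a big problem.")
    within = parse_frame('"language" + "problem"')
    adjacent = parse_frame('"language" ++ "problem"')
    hits = match_frame(within, sent, lex)
    assert [m.positions for m in hits] == [(1, 5)]
    assert match_frame(adjacent, sent, lex) == []


def test_no_match_across_sentence_boundary():
    lex = _lex()
    doc = make_document("d", "The doctor came. English was hard.")
    frame = parse_frame('"doctor" + "english"')
    assert match_document(frame, doc, lex) == []
    assert match_frame(parse_frame('"doctor"'), doc.sentences[0], lex, "d") != []


def test_punctuation_transparent_for_adjacency():
    lex = _lex()
    sent = _sent("It was a big, real problem.")
    frame = parse_frame('"big" ++ "real"')
    assert [m.positions for m in match_frame(frame, sent, lex)] == [(3, 4)]


def test_group_reference_matches_members(lexicon):
    sent = _sent("The doctor and the nurse helped.")
    frame = parse_frame("G:physician_noun + G:personnel_noun")
    hits = match_frame(frame, sent, lexicon)
    assert [m.positions for m in hits] == [(1, 4)]


def test_single_constituent_counts_every_occurrence(lexicon):
    doc = make_document("d", "A nurse came. Then another nurse and a technician.")
    frame = parse_frame("G:personnel_noun")
    hits = match_document(frame, doc, lexicon)
    assert len(hits) == 3
    assert [m.sentence_index for m in hits] == [0, 1, 1]


def test_illegible_token_never_matches():
    lex = _lex(things={"xxx", "closed"})
    sent = _sent("The xxx was closed.")
    assert match_frame(parse_frame('"xxx"'), sent, lex) == []
    assert len(match_frame(parse_frame("G:things"), sent, lex)) == 1  # "closed" only


def test_unresolved_group_is_an_error():
    with pytest.raises(KeyError, match="no_such_group"):
        match_frame(parse_frame("G:no_such_group"), _sent("Hi there."), _lex())


def test_all_matches_returned_in_order():
    lex = _lex()
    sent = _sent("pain here pain there pain.")
    hits = match_frame(parse_frame('"pain" + "pain"'), sent, lex)
    assert [m.positions for m in hits] == [(0, 2), (0, 4), (2, 4)]


def _random_case(rng):
    vocab = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta"]
    lex = _lex(
        g1=set(rng.choice(vocab, size=3, replace=False)),
        g2=set(rng.choice(vocab, size=2, replace=False)),
    )
    n_words = int(rng.integers(1, 16))
    words = [vocab[rng.integers(len(vocab))] for _ in range(n_words)]
    # sprinkle punctuation and an illegible placeholder
    if rng.random() < 0.3:
        words.insert(int(rng.integers(len(words) + 1)), "xxx")
    text = ""
    for w in words:
        text += w + ("," if rng.random() < 0.2 else "") + " "
    sent = _sent(text.strip() + ".")
    k = int(rng.integers(1, 5))
    constituents = []
    for _ in range(k):
        if rng.random() < 0.5:
            constituents.append(
                Constituent(ConstituentKind.LITERAL, vocab[rng.integers(len(vocab))])
            )
        else:
            constituents.append(
                Constituent(ConstituentKind.GROUP_REF, ["g1", "g2"][rng.integers(2)])
            )
    bindings = tuple(
        Binding.ADJACENT if rng.random() < 0.5 else Binding.WITHIN_SENTENCE
        for _ in range(k - 1)
    )
    return Frame(constituents=tuple(constituents), bindings=bindings), sent, lex


def test_matching_engine_equals_brute_force_oracle():
    rng = np.random.default_rng(20240817)
    for _ in range(400):
        frame, sent, lex = _random_case(rng)
        got = sorted(m.positions for m in match_frame(frame, sent, lex))
        assert got == brute_force_matches(frame, sent, lex)


def test_adjacent_matches_survive_relaxation():
    rng = np.random.default_rng(99)
    for _ in range(200):
        frame, sent, lex = _random_case(rng)
        strict = {m.positions for m in match_frame(frame, sent, lex)}
        relaxed = {m.positions for m in match_frame(frame.relaxed(), sent, lex)}
        assert strict <= relaxed


def test_adding_group_member_never_removes_matches(lexicon):
    sent = _sent("The doctor saw my helper at the desk.")
    frame = parse_frame("G:physician_noun + G:personnel_noun")
    before = {m.positions for m in match_frame(frame, sent, lexicon)}
    grown = Lexicon(
        groups={
            **lexicon.groups,
            "personnel_noun": WordGroup(
                name="personnel_noun",
                members=lexicon["personnel_noun"].members | {"helper"},
            ),
        }
    )
    after = {m.positions for m in match_frame(frame, sent, grown)}
    assert before <= after and len(after) > len(before)


def test_inserted_period_breaks_matches():
    """Fuzz: splitting a matching sentence at any word boundary kills
    matches that would have to span the new boundary."""
    lex = _lex()
    frame = parse_frame('"alpha" + "beta"')
    words = ["alpha", "gamma", "beta", "delta", "beta"]
    rng = np.random.default_rng(7)
    for cut in range(1, len(words)):
        raw = " ".join(words[:cut]) + ". " + " ".join(words[cut:]) + "."
        doc = make_document("d", raw)
        for m in match_document(frame, doc, lex):
            sent = doc.sentences[m.sentence_index]
            forms = [t.form for t in sent.word_tokens]
            assert forms[m.positions[0]] == "alpha"
            assert forms[m.positions[1]] == "beta"
        # matches never pair tokens from different sides of the cut
        n_before = sum(1 for m in match_document(frame, doc, lex))
        expected = sum(
            1
            for part in (words[:cut], words[cut:])
            if "alpha" in part
            for i, w in enumerate(part)
            if w == "beta" and i > part.index("alpha")
        )
        assert n_before == expected
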