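"""Cohort-model lexicon: loading, filtering, probabilities, surprisal, entropy."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hyp

import speechtrf as st
from speechtrf.lexicon import PHONEME_TIER, WORD_TIER
from speechtrf.textgrid import Interval, IntervalTier, write_textgrid

from conftest import (brute_conditional_probability, brute_next_entropy,
                      brute_prefix_mass, random_lexicon)


# --- loading and filtering -------------------------------------------------

def _write_lexicon(path, rows):
    path.write_text("# word\tfrequency\tphonemes\n"
                    + "\n".join(f"{w}\t{f}\t{p}" for w, f, p in rows),
                    encoding="utf-8")


def test_load_keeps_alphabetic_words(tmp_path):
    p = tmp_path / "lex.tsv"
    _write_lexicon(p, [("ba", 2, "b a"), ("bi", 1, "b i"), ("da", 1, "d a")])
    lex = st.load_lexicon(p)
    assert len(lex) == 3 and lex.total_frequency == 4


def test_load_drops_nonalphabetic_forms(tmp_path):
    p = tmp_path / "lex.tsv"
    _write_lexicon(p, [("a1b", 5, "a b"), ("ok", 1, "o k")])
    lex = st.load_lexicon(p)
    assert [e.form for e in lex.entries] == ["ok"]
    assert lex.n_rejected_nonalpha == 1


def test_load_merges_duplicates_by_summing(tmp_path):
    p = tmp_path / "lex.tsv"
    _write_lexicon(p, [("ba", 2, "b a"), ("ba", 3, "b a")])
    lex = st.load_lexicon(p)
    assert len(lex) == 1 and lex.entries[0].frequency == 5


def test_load_rejects_nonpositive_frequency_with_warning(tmp_path):
    p = tmp_path / "lex.tsv"
    _write_lexicon(p, [("ba", 0, "b a"), ("bi", 2, "b i")])
    with pytest.warns(UserWarning, match="non-positive"):
        lex = st.load_lexicon(p)
    assert len(lex) == 1 and lex.n_rejected_nonpositive == 1


def test_load_empty_after_filtering_is_fatal(tmp_path):
    p = tmp_path / "lex.tsv"
    _write_lexicon(p, [("a1", 1, "a"), ("b2", 1, "b")])
    with pytest.raises(ValueError, match="empty"):
        st.load_lexicon(p)


def test_unicode_letters_survive_filter(tmp_path):
    p = tmp_path / "lex.tsv"
    _write_lexicon(p, [("kği", 3, "k ğ i"), ("电视", 2, "d s")])
    lex = st.load_lexicon(p)
    assert len(lex) == 2


# --- cohort advance, worked examples ---------------------------------------

def test_cohort_probabilities_toy_example(toy_lexicon):
    s0 = st.word_initial_state(toy_lexicon)
    assert s0.mass == 4
    s1, p1 = st.advance_cohort(toy_lexicon, s0, "b")
    assert p1 == Fraction(3, 4)
    assert sorted(toy_lexicon.entries[i].form for i in s1.members) == ["ba", "bi"]
    s2, p2 = st.advance_cohort(toy_lexicon, s1, "a")
    assert p2 == Fraction(2, 3)
    assert [toy_lexicon.entries[i].form for i in s2.members] == ["ba"]


def test_unknown_phoneme_names_symbol(toy_lexicon):
    with pytest.raises(KeyError, match="'x'"):
        st.advance_cohort(toy_lexicon, st.word_initial_state(toy_lexicon), "x")


def test_single_word_lexicon_probability_one_everywhere():
    lex = st.make_lexicon([("pada", "p a d a", 7)])
    state = st.word_initial_state(lex)
    for ph in "pada":
        state, prob = st.advance_cohort(lex, state, ph)
        assert prob == 1
    assert st.word_surprisal_profile(lex, "p a d a").surprisals.max() == 0.0


def test_entropy_toy_example(toy_lexicon):
    s1, _ = st.advance_cohort(toy_lexicon, st.word_initial_state(toy_lexicon),
                              "b")
    e = st.next_phoneme_entropy(toy_lexicon, s1)
    assert e == pytest.approx(-(2 / 3) * math.log2(2 / 3)
                              - (1 / 3) * math.log2(1 / 3), abs=1e-12)
    assert e == pytest.approx(0.918, abs=5e-4)


def test_entropy_degenerate_cases():
    lex = st.make_lexicon([("ba", "b a", 2), ("bi", "b i", 2)])
    s1, _ = st.advance_cohort(lex, st.word_initial_state(lex), "b")
    # uniform two-way continuation -> 1 bit
    assert st.next_phoneme_entropy(lex, s1) == pytest.approx(1.0)
    s2, _ = st.advance_cohort(lex, s1, "a")
    # single member, exact match -> all mass on the word-end outcome
    assert st.next_phoneme_entropy(lex, s2) == pytest.approx(0.0)


def test_word_end_symbol_switch():
    lex = st.make_lexicon([("a", "a", 1), ("ab", "a b", 1)])
    s1, _ = st.advance_cohort(lex, st.word_initial_state(lex), "a")
    assert st.next_phoneme_entropy(lex, s1) == pytest.approx(1.0)
    assert st.next_phoneme_entropy(lex, s1, include_word_end=False) == 0.0


def test_zero_mass_state_entropy_directs_to_fallback(toy_lexicon):
    state = st.CohortState(("z",), (), 0)
    with pytest.raises(ValueError, match="fallback"):
        st.next_phoneme_entropy(toy_lexicon, state)


def test_surprisal_profile_toy_example(toy_lexicon):
    prof = st.word_surprisal_profile(toy_lexicon, "b a")
    assert prof.surprisals == pytest.approx(
        [-math.log2(3 / 4), -math.log2(2 / 3)], abs=1e-12)
    assert prof.surprisals == pytest.approx([0.415, 0.585], abs=5e-4)
    # telescoping: total surprisal of "ba" = -log2(freq/total)
    assert prof.surprisals.sum() == pytest.approx(-math.log2(2 / 4), abs=1e-9)


def test_fallback_policies(toy_lexicon):
    # 'a' is never word-initial in the toy lexicon
    state = st.word_initial_state(toy_lexicon)
    s1, p1 = st.advance_cohort(toy_lexicon, state, "a", fallback="uniform")
    assert s1.fallback and p1 == Fraction(1, len(toy_lexicon.inventory))
    s1r, p1r = st.advance_cohort(toy_lexicon, state, "a", fallback="restart")
    assert s1r.fallback
    # restart re-enters the lexicon: 'a' still empty word-initially -> uniform
    assert p1r == Fraction(1, len(toy_lexicon.inventory))
    # restart after a valid prefix: "b a" then "d" restarts into {da}
    s, _ = st.advance_cohort(toy_lexicon, state, "b")
    s, _ = st.advance_cohort(toy_lexicon, s, "a")
    s2, p2 = st.advance_cohort(toy_lexicon, s, "d", fallback="restart")
    assert s2.fallback and p2 == Fraction(1, 4)


# --- property tests against the brute-force oracle --------------------------

@given(hyp.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_cohort_oracle_equivalence(oracle_seed):
    """Conditional probabilities and entropies on random lexicons equal
    exhaustive enumeration exactly."""
    rng = np.random.default_rng(oracle_seed)
    lex = random_lexicon(rng)
    word = lex.entries[int(rng.integers(len(lex.entries)))].phonemes
    state = st.word_initial_state(lex)
    prefix = []
    for ph in word:
        expected = brute_conditional_probability(lex, prefix, ph)
        state, prob = st.advance_cohort(lex, state, ph)
        assert prob == expected
        prefix.append(ph)
        assert state.mass == brute_prefix_mass(lex, prefix)
        assert st.next_phoneme_entropy(lex, state) == pytest.approx(
            brute_next_entropy(lex, prefix), abs=1e-12)


@given(hyp.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_cohort_mass_monotone_and_entropy_bounds(oracle_seed):
    rng = np.random.default_rng(oracle_seed)
    lex = random_lexicon(rng)
    word = lex.entries[int(rng.integers(len(lex.entries)))].phonemes
    state = st.word_initial_state(lex)
    bound = math.log2(len(lex.inventory) + 1)
    for ph in word:
        before = state.mass
        state, _ = st.advance_cohort(lex, state, ph)
        assert state.mass <= before
        e = st.next_phoneme_entropy(lex, state)
        assert 0.0 <= e <= bound + 1e-12


@given(hyp.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_telescoping_surprisal_identity(seed):
    rng = np.random.default_rng(seed)
    lex = random_lexicon(rng)
    word = lex.entries[int(rng.integers(len(lex.entries)))].phonemes
    prof = st.word_surprisal_profile(lex, word)
    expected = -math.log2(brute_prefix_mass(lex, word) / lex.total_frequency)
    assert prof.surprisals.sum() == pytest.approx(expected, abs=1e-9)


def test_surprisal_matches_negative_log_probability(toy_lexicon):
    prof = st.word_surprisal_profile(toy_lexicon, "b i")
    for rec in prof.records:
        assert rec.surprisal == pytest.approx(-math.log2(rec.probability),
                                              abs=1e-12)


# --- event annotation -------------------------------------------------------

def _segmentation(words):
    rows, t = [], 0.0
    for wi, word in enumerate(words):
        rows.append((t, WORD_TIER, "".join(word), wi))
        for ph in word:
            rows.append((t, PHONEME_TIER, ph, wi))
            t += 0.1
    return pd.DataFrame(rows, columns=["onset_s", "tier", "label",
                                       "word_index"])


def test_annotate_matches_per_word_profiles(toy_lexicon):
    events = _segmentation([("b", "a"), ("d", "a")])
    ann = st.annotate_events(events, toy_lexicon)
    phon = ann[ann["tier"] == PHONEME_TIER]
    assert len(phon) == 4
    assert (phon["onset_flag"] == 1).all()
    expected = np.concatenate([
        st.word_surprisal_profile(toy_lexicon, "b a").surprisals,
        st.word_surprisal_profile(toy_lexicon, "d a").surprisals])
    assert phon["surprisal_bits"].to_numpy() == pytest.approx(expected)
    assert not phon["fallback"].any()
    assert ann.attrs["n_fallback"] == 0


def test_annotate_empty_segmentation(toy_lexicon):
    events = pd.DataFrame(columns=["onset_s", "tier", "label", "word_index"])
    ann = st.annotate_events(events, toy_lexicon)
    assert len(ann) == 0


def test_annotate_unknown_word_flagged(toy_lexicon):
    events = _segmentation([("i", "d")])   # 'i' never word-initial
    ann = st.annotate_events(events, toy_lexicon)
    phon = ann[ann["tier"] == PHONEME_TIER]
    assert phon["fallback"].all()
    n = len(toy_lexicon.inventory)
    assert phon["surprisal_bits"].to_numpy() == pytest.approx(
        [math.log2(n)] * 2)
    assert ann.attrs["n_fallback"] == 2


# --- segmentation I/O -------------------------------------------------------

def test_read_segmentation_tsv_roundtrip(tmp_path, toy_lexicon):
    events = _segmentation([("b", "a")])
    p = tmp_path / "seg.tsv"
    events.to_csv(p, sep="\t", index=False)
    df = st.read_segmentation(p)
    assert list(df["label"]) == ["ba", "b", "a"]


def test_read_segmentation_textgrid(tmp_path):
    tiers = [
        IntervalTier("phoneme", 0, 0.5, [Interval(0.0, 0.1, "b"),
                                         Interval(0.1, 0.25, "a"),
                                         Interval(0.25, 0.35, "d"),
                                         Interval(0.35, 0.5, "a")]),
        IntervalTier("word", 0, 0.5, [Interval(0.0, 0.25, "ba"),
                                      Interval(0.25, 0.5, "da")]),
    ]
    p = tmp_path / "seg.TextGrid"
    write_textgrid(p, tiers, 0.0, 0.5)
    df = st.read_segmentation(p)
    phon = df[df["tier"] == PHONEME_TIER]
    assert list(phon["label"]) == ["b", "a", "d", "a"]
    assert list(phon["word_index"]) == [0, 0, 1, 1]
    assert list(phon["onset_s"]) == pytest.approx([0.0, 0.1, 0.25, 0.35])
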