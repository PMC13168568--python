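"""Frequency lexicons and incremental cohort statistics.

The cohort model of spoken-word recognition: as the phonemes of a word unfold,
the set of lexical candidates consistent with the heard prefix (the *cohort*)
shrinks. With word frequencies as weights, each phoneme has

* a conditional probability  P(ph_i) = mass(cohort_i) / mass(cohort_{i-1}),
* a surprisal                S_i     = -log2 P(ph_i)   (bits),
* an entropy                 E_i     = Shannon entropy (bits) of the
  frequency-weighted distribution over possible next phonemes given the
  current cohort.

Probabilities are kept as exact integer-mass ratios (``fractions.Fraction``)
whenever frequencies are integers; logarithms are taken only at the last step.

A lexicon is loaded from a UTF-8 TSV with columns ``word``, ``frequency``,
``phonemes`` (space-separated symbols); ``#`` lines are comments. Orthographic
forms containing non-alphabetic characters (Unicode letter classification,
which covers Turkish dotted/dotless i and Chinese characters) are removed, as
is conventional when cleaning SUBTLEX-style frequency lists.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from .textgrid import read_textgrid

__all__ = [
    "LexEntry", "Lexicon", "CohortState", "PhonemeRecord", "PhonemeStats",
    "load_lexicon", "make_lexicon", "word_initial_state", "advance_cohort",
    "next_phoneme_entropy", "word_surprisal_profile", "annotate_events",
    "read_segmentation", "write_annotated_tsv",
    "WORD_END",
]

#: Terminal symbol used when a cohort member's phoneme sequence is an exact
#: match of the consumed prefix ("the word ends here" outcome).
WORD_END = "#"

PHONEME_TIER = "phoneme"
WORD_TIER = "word"


@dataclass(frozen=True)
class LexEntry:
    form: str
    phonemes: tuple[str, ...]
    frequency: int


@dataclass
class Lexicon:
    entries: list[LexEntry]
    inventory: frozenset[str]
    total_frequency: int
    n_rejected_nonalpha: int = 0
    n_rejected_nonpositive: int = 0

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CohortState:
    """Cohort after consuming ``prefix``: member entry indices and their mass."""
    prefix: tuple[str, ...]
    members: tuple[int, ...]
    mass: int
    fallback: bool = False


@dataclass(frozen=True)
class PhonemeRecord:
    phoneme: str
    probability: float
    surprisal: float
    entropy: float
    fallback: bool


@dataclass
class PhonemeStats:
    records: list[PhonemeRecord] = field(default_factory=list)

    @property
    def surprisals(self) -> np.ndarray:
        return np.array([r.surprisal for r in self.records])

    @property
    def entropies(self) -> np.ndarray:
        return np.array([r.entropy for r in self.records])


def make_lexicon(entries: list[tuple[str, str | tuple[str, ...], int]]) -> Lexicon:
    """Build a Lexicon from (form, phonemes, frequency) triples (no filtering).

    ``phonemes`` may be a space-separated string or a tuple of symbols.
    """
    lex_entries = []
    for form, phon, freq in entries:
        if isinstance(phon, str):
            phon = tuple(phon.split())
        if freq <= 0:
            raise ValueError(f"non-positive frequency for {form!r}")
        lex_entries.append(LexEntry(form, tuple(phon), int(freq)))
    if not lex_entries:
        raise ValueError("empty lexicon")
    inventory = frozenset(ph for e in lex_entries for ph in e.phonemes)
    return Lexicon(lex_entries, inventory,
                   sum(e.frequency for e in lex_entries))


def load_lexicon(path, case: str = "fold") -> Lexicon:
    """Load and filter a frequency lexicon TSV.

    Forms containing non-alphabetic characters are dropped; duplicate
    (form, pronunciation) records are merged by summing their frequencies;
    records with non-positive frequency are rejected with a warning count.
    Raises ``ValueError`` if nothing survives filtering.
    """
    if case not in ("fold", "preserve"):
        raise ValueError(f"unknown case policy {case!r}")
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["word", "frequency", "phonemes"],
                     dtype={"word": str, "phonemes": str},
                     encoding="utf-8")
    if len(df) and str(df.iloc[0]["word"]).lower() == "word":
        df = df.iloc[1:]
    merged: dict[tuple[str, tuple[str, ...]], int] = {}
    n_nonalpha = n_nonpos = 0
    for _, row in df.iterrows():
        form = str(row["word"])
        if case == "fold":
            form = form.casefold()
        if not form.isalpha():
            n_nonalpha += 1
            continue
        freq = float(row["frequency"])
        if freq <= 0:
            n_nonpos += 1
            continue
        phon = tuple(str(row["phonemes"]).split())
        key = (form, phon)
        merged[key] = merged.get(key, 0) + int(round(freq))
    if not merged:
        raise ValueError(f"lexicon {path} is empty after filtering")
    if n_nonpos:
        warnings.warn(f"rejected {n_nonpos} records with non-positive frequency")
    entries = [LexEntry(f, p, q) for (f, p), q in sorted(merged.items())]
    inventory = frozenset(ph for e in entries for ph in e.phonemes)
    return Lexicon(entries, inventory, sum(e.frequency for e in entries),
                   n_rejected_nonalpha=n_nonalpha,
                   n_rejected_nonpositive=n_nonpos)


def word_initial_state(lexicon: Lexicon) -> CohortState:
    """The cohort before any phoneme has been heard: the whole lexicon."""
    return CohortState((), tuple(range(len(lexicon.entries))),
                       lexicon.total_frequency)


def advance_cohort(lexicon: Lexicon, state: CohortState, phoneme: str,
                   fallback: str = "uniform") -> tuple[CohortState, Fraction]:
    """Consume one phoneme; return the new cohort and P(ph | previous cohort).

    When the new cohort would be empty (guaranteed for pseudoword streams),
    the fallback policy applies and the state's ``fallback`` flag is raised:

    * ``"uniform"`` — probability 1/|inventory|, cohort left empty;
    * ``"restart"`` — re-enter the full lexicon as if word-initial and
      consume ``phoneme`` from there (uniform if that too is empty).
    """
    if phoneme not in lexicon.inventory:
        raise KeyError(f"phoneme {phoneme!r} not in lexicon inventory")
    pos = len(state.prefix)
    if state.fallback and fallback == "uniform":
        # already out of the lexicon: stay in the uniform regime
        return (CohortState(state.prefix + (phoneme,), (), 0, True),
                Fraction(1, len(lexicon.inventory)))
    members = tuple(i for i in state.members
                    if len(lexicon.entries[i].phonemes) > pos
                    and lexicon.entries[i].phonemes[pos] == phoneme)
    mass = sum(lexicon.entries[i].frequency for i in members)
    if mass > 0:
        return (CohortState(state.prefix + (phoneme,), members, mass,
                            state.fallback),
                Fraction(mass, state.mass))
    if fallback == "uniform":
        return (CohortState(state.prefix + (phoneme,), (), 0, True),
                Fraction(1, len(lexicon.inventory)))
    if fallback == "restart":
        restarted, prob = advance_cohort(lexicon, word_initial_state(lexicon),
                                         phoneme, fallback="uniform")
        return replace(restarted, fallback=True), prob
    raise ValueError(f"unknown fallback policy {fallback!r}")


def _next_distribution(lexicon: Lexicon, state: CohortState,
                       include_word_end: bool) -> dict[str, int]:
    pos = len(state.prefix)
    dist: dict[str, int] = {}
    for i in state.members:
        e = lexicon.entries[i]
        if len(e.phonemes) > pos:
            dist[e.phonemes[pos]] = dist.get(e.phonemes[pos], 0) + e.frequency
        elif include_word_end:
            dist[WORD_END] = dist.get(WORD_END, 0) + e.frequency
    return dist


def next_phoneme_entropy(lexicon: Lexicon, state: CohortState,
                         include_word_end: bool = True) -> float:
    """Shannon entropy (bits) of the next-phoneme distribution given ``state``.

    When a cohort member's sequence equals the consumed prefix, a terminal
    "word ends here" outcome is included (switch off with
    ``include_word_end=False``); without it the next-phoneme distribution can
    be improper when words are prefixes of longer words.
    """
    if state.mass <= 0:
        raise ValueError(
            "zero-mass cohort has no next-phoneme distribution; "
            "apply the fallback policy (see advance_cohort)")
    dist = _next_distribution(lexicon, state, include_word_end)
    total = sum(dist.values())
    return -sum((m / total) * math.log2(m / total) for m in dist.values())


def _fallback_values(lexicon: Lexicon) -> tuple[float, float]:
    n = len(lexicon.inventory)
    return math.log2(n), math.log2(n)  # (surprisal, entropy) of uniform


def word_surprisal_profile(lexicon: Lexicon, word,
                           fallback: str = "uniform",
                           include_word_end: bool = True,
                           entropy_conditioning: str = "current") -> PhonemeStats:
    """Per-phoneme cohort statistics for one word, from the word-initial cohort.

    ``entropy_conditioning`` selects whether position i's entropy describes
    uncertainty about phoneme i+1 given the cohort *after* consuming phoneme i
    (``"current"``, the default) or given the cohort *before* it
    (``"previous"``).
    """
    word = tuple(word.split()) if isinstance(word, str) else tuple(word)
    if not word:
        raise ValueError("empty word")
    if entropy_conditioning not in ("current", "previous"):
        raise ValueError(f"unknown entropy conditioning {entropy_conditioning!r}")
    state = word_initial_state(lexicon)
    stats = PhonemeStats()
    for ph in word:
        prev = state
        state, prob = advance_cohort(lexicon, state, ph, fallback=fallback)
        cond_state = state if entropy_conditioning == "current" else prev
        if cond_state.mass > 0:
            ent = next_phoneme_entropy(lexicon, cond_state,
                                       include_word_end=include_word_end)
        else:
            _, ent = _fallback_values(lexicon)
        stats.records.append(PhonemeRecord(
            ph, float(prob), -math.log2(prob), ent, state.fallback))
    return stats


# ---------------------------------------------------------------------------
# Segmentation I/O and event annotation
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["onset_s", "tier", "label", "word_index"]


def read_segmentation(path) -> pd.DataFrame:
    """Read a segmentation as an event table (columns onset_s, tier, label,
    word_index), from either a TSV or a Praat TextGrid with a phoneme and a
    word interval tier (interval start = onset)."""
    path = str(path)
    if path.lower().endswith(".textgrid"):
        tiers = read_textgrid(path)
        names = {n.lower(): n for n in tiers}
        if "phoneme" not in names or "word" not in names:
            raise ValueError(
                f"TextGrid {path} needs 'phoneme' and 'word' interval tiers; "
                f"found {sorted(tiers)}")
        words = [iv for iv in tiers[names["word"]].intervals if iv.text.strip()]
        phones = [iv for iv in tiers[names["phoneme"]].intervals if iv.text.strip()]
        rows = []
        for wi, w in enumerate(words):
            rows.append((w.xmin, WORD_TIER, w.text.strip(), wi))
        for p in phones:
            wi = next((i for i, w in enumerate(words)
                       if w.xmin - 1e-9 <= p.xmin < w.xmax - 1e-9), -1)
            rows.append((p.xmin, PHONEME_TIER, p.text.strip(), wi))
        df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        return df.sort_values(["onset_s", "tier"], kind="stable",
                              ignore_index=True)
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segmentation {path} lacks columns {sorted(missing)}")
    return df


def annotate_events(events: pd.DataFrame, lexicon: Lexicon,
                    fallback: str = "uniform",
                    include_word_end: bool = True,
                    entropy_conditioning: str = "current") -> pd.DataFrame:
    """Attach cohort statistics to each phoneme event.

    Phoneme events are grouped by ``word_index`` (the cohort resets at every
    word onset) and gain columns ``onset_flag`` (always 1), ``surprisal_bits``,
    ``entropy_bits`` and ``fallback``. Words whose phonemes leave the lexicon
    are handled per the fallback policy and flagged; the number of flagged
    events is available as ``df.attrs["n_fallback"]``.
    """
    out = events.copy()
    for col, default in (("onset_flag", 0.0), ("surprisal_bits", np.nan),
                         ("entropy_bits", np.nan)):
        out[col] = default
    out["fallback"] = False
    n_fallback = 0
    phon = out[out["tier"] == PHONEME_TIER]
    for _, group in phon.groupby("word_index", sort=False):
        group = group.sort_values("onset_s", kind="stable")
        word = [str(l) for l in group["label"]]
        stats = word_surprisal_profile(
            lexicon, word, fallback=fallback,
            include_word_end=include_word_end,
            entropy_conditioning=entropy_conditioning)
        for idx, rec in zip(group.index, stats.records):
            out.loc[idx, ["onset_flag", "surprisal_bits", "entropy_bits",
                          "fallback"]] = [1.0, rec.surprisal, rec.entropy,
                                          rec.fallback]
            n_fallback += int(rec.fallback)
    out.attrs["n_fallback"] = n_fallback
    return out


def write_annotated_tsv(events: pd.DataFrame, path) -> None:
    cols = ["onset_s", "label", "word_index", "onset_flag",
            "surprisal_bits", "entropy_bits", "fallback"]
    df = events[events["tier"] == PHONEME_TIER].copy()
    df = df.rename(columns={"label": "phoneme"})
    cols = [c if c != "label" else "phoneme" for c in cols]
    df[cols].to_csv(path, sep="\t", index=False)
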