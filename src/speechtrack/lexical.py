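"""Lexical stimulus functions for continuous speech.

Turns word alignments, ranked next-word guess lists, frequency tables and
n-gram counts into continuous *contrastive* regressors sampled at 32 Hz:
zero during pauses, constant within each word at the word's signed,
duration-weighted-centered lexical value, with the sign chosen so that
lexically *harder* words (low frequency, low probability, high guess rank)
are positive.
"""

from __future__ import annotations

import json
import math
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STIM_FS = 32.0  #: sampling rate (Hz) shared by all stimulus functions

#: gaps between consecutive words shorter than this are alignment artifacts
#: and are closed; longer gaps are genuine pauses
MIN_PAUSE_S = 0.25

UNMATCHED_RANK = 11  #: rank assigned when no guess matches the word

#: floor applied to n-gram probabilities so unseen continuations stay finite
NGRAM_PROB_FLOOR = 1e-3


class InvalidAlignmentError(ValueError):
    """Word tokens overlap or are out of order."""


class InvalidGuessListError(ValueError):
    """A guess list does not contain exactly 10 guesses."""


class IncompleteAnnotationError(ValueError):
    """A token lacks the attribute required for the requested function."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class WordToken:
    """One aligned word with its lexical annotations.

    Times are block-relative seconds.  ``log_freq`` is a log10 word
    frequency (Zipf-like scale), ``pred_rank`` the 1-based serial position
    of the word in a language model's ranked guesses (11 = unguessed) and
    ``ngram_log10p`` a floored log10 n-gram probability.
    """

    index: int
    word: str
    onset_s: float
    offset_s: float
    log_freq: float | None = None
    pred_rank: int | None = None
    ngram_log10p: float | None = None

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise InvalidAlignmentError(
                f"token {self.index} ({self.word!r}): offset must exceed onset"
            )
        if self.pred_rank is not None and not 1 <= self.pred_rank <= UNMATCHED_RANK:
            raise ValueError(f"pred_rank must be in 1..{UNMATCHED_RANK}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class StimulusFunction:
    """A regressor time series for one block and one measure.

    ``measure`` is one of ``delta_env``, ``theta_env``, ``broadband_env``,
    ``lexfreq``, ``lexpred`` or ``ngram``.
    """

    values: np.ndarray
    fs: float
    measure: str
    block_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("stimulus function must be one-dimensional")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs


# ---------------------------------------------------------------------------
# alignment handling
# ---------------------------------------------------------------------------

def filter_word_boundaries(tokens: Sequence[WordToken]) -> list[WordToken]:
    """Close sub-250 ms inter-word gaps; keep longer gaps as pauses.

    Forced alignment inserts word boundaries even where speech is
    continuous, so short gaps are artifacts: each gap shorter than
    :data:`MIN_PAUSE_S` is removed by extending the preceding word's offset
    to the next word's onset (onsets are preserved, which anchors
    word-half analyses).  Gaps of exactly 250 ms or more are retained.
    """
    out: list[WordToken] = []
    prev: WordToken | None = None
    for tok in tokens:
        if prev is not None:
            gap = tok.onset_s - prev.offset_s
            if gap < -1e-9:
                raise InvalidAlignmentError(
                    f"tokens {prev.index} and {tok.index} overlap by {-gap:.3f} s"
                )
            if 0 < gap < MIN_PAUSE_S:
                prev.offset_s = tok.onset_s
        cur = WordToken(
            tok.index, tok.word, tok.onset_s, tok.offset_s,
            tok.log_freq, tok.pred_rank, tok.ngram_log10p,
        )
        out.append(cur)
        prev = cur
    return out


# ---------------------------------------------------------------------------
# predictability scoring
# ---------------------------------------------------------------------------

def _normalize_word(s: str) -> str:
    """Lower-case and strip punctuation, keeping internal apostrophes."""
    s = s.strip().lower().replace("’", "'")
    kept = []
    n = len(s)
    for i, ch in enumerate(s):
        if ch == "'":
            if 0 < i < n - 1:  # internal apostrophe only
                kept.append(ch)
        elif not unicodedata.category(ch).startswith("P"):
            kept.append(ch)
    return "".join(kept).strip()


def _stem_at_apostrophe(s: str) -> str:
    return s.split("'", 1)[0]


def score_gpt_guess(word: str, guesses: Sequence[str]) -> int:
    """Rank a word within a list of exactly 10 ranked guesses.

    Returns the 1-based position of the first matching guess, or
    :data:`UNMATCHED_RANK` (11) if none match.  Matching is exact after
    lower-casing and punctuation removal; contractions match up to the
    apostrophe on either side (``he'd`` matches ``he``), and multiword or
    hyphenated guesses match on their first word (``and`` matches
    ``and white``).
    """
    if len(guesses) != 10:
        raise InvalidGuessListError(
            f"expected exactly 10 guesses, got {len(guesses)}"
        )
    target = _normalize_word(word)
    target_stem = _stem_at_apostrophe(target)
    for pos, guess in enumerate(guesses, start=1):
        first = guess.strip().replace("-", " ").split()
        cand = _normalize_word(first[0]) if first else ""
        if not cand:
            continue
        if target_stem == _stem_at_apostrophe(cand):
            return pos
    return UNMATCHED_RANK


def ngram_log10_probability(target_count: float, context_total: float) -> float:
    """Floored log10 conditional probability of an n-gram continuation.

    ``target_count / context_total`` floored at 0.001 so unseen
    continuations do not diverge; an empty context (``context_total = 0``)
    is treated as unmatched.
    """
    if target_count < 0 or context_total < 0:
        raise ValueError("counts must be nonnegative")
    if target_count > context_total:
        raise ValueError("target count cannot exceed context total")
    if context_total == 0:
        return math.log10(NGRAM_PROB_FLOOR)
    return math.log10(max(target_count / context_total, NGRAM_PROB_FLOOR))


# ---------------------------------------------------------------------------
# frequency lookup
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """log10 word-frequency look-up with an out-of-vocabulary floor."""

    values: Mapping[str, float]
    floor: float

    @classmethod
    def from_tsv(cls, path, floor: float) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["word", "log_freq"])
        return cls({str(w).lower(): float(v) for w, v in zip(df.word, df.log_freq)}, floor)


def lookup_log_frequency(word: str, table: FrequencyTable) -> float:
    """Tabulated log10 frequency of a word; the table's floor if absent."""
    if not word or not _normalize_word(word):
        raise ValueError("empty word")
    return table.values.get(_normalize_word(word), table.floor)


# ---------------------------------------------------------------------------
# contrastive stimulus functions
# ---------------------------------------------------------------------------

#: attribute accessor and hardness sign per lexical measure: −1 flips
#: log-frequency and log-probability so low values (hard words) come out
#: positive; rank is already increasing in hardness.
_MEASURES = {
    "lexfreq": ("log_freq", -1.0),
    "lexpred": ("pred_rank", +1.0),
    "ngram": ("ngram_log10p", -1.0),
}


def word_sample_slices(
    tokens: Sequence[WordToken], fs: float, n_samples: int
) -> list[tuple[WordToken, slice]]:
    """Half-open sample assignment: sample i (time i/fs) belongs to word w
    iff onset <= i/fs < offset."""
    out = []
    for tok in tokens:
        lo = int(math.ceil(tok.onset_s * fs - 1e-9))
        hi = int(math.ceil(tok.offset_s * fs - 1e-9))
        lo, hi = max(lo, 0), min(hi, n_samples)
        out.append((tok, slice(lo, hi)))
    return out


def build_contrastive_function(
    tokens: Sequence[WordToken],
    attribute: str,
    fs: float = STIM_FS,
    block_duration: float | None = None,
    block_id: str = "",
) -> StimulusFunction:
    """Build a contrastive lexical regressor from boundary-filtered tokens.

    Each word's value is centered around the duration-weighted average of
    all word values in the block and sign-flipped so that harder lexical
    processing is positive; samples outside words are exactly zero.  The
    duration-weighted mean of the emitted function over words is therefore
    zero by construction.
    """
    if attribute not in _MEASURES:
        raise ValueError(f"unknown attribute {attribute!r}")
    if not tokens:
        raise ValueError("no tokens")
    attr, sign = _MEASURES[attribute]
    vals = []
    for tok in tokens:
        v = getattr(tok, attr)
        if v is None:
            raise IncompleteAnnotationError(
                f"token {tok.index} ({tok.word!r}) lacks {attr}"
            )
        vals.append(float(v))
    vals = np.asarray(vals)
    durs = np.array([t.duration_s for t in tokens])
    center = float(np.sum(vals * durs) / np.sum(durs))

    if block_duration is None:
        block_duration = tokens[-1].offset_s
    n = int(math.ceil(block_duration * fs))
    out = np.zeros(n)
    n_short = 0
    for (tok, sl), v in zip(word_sample_slices(tokens, fs, n), vals):
        if sl.stop <= sl.start:
            n_short += 1
            continue
        out[sl] = sign * (v - center)
    return StimulusFunction(
        out, fs, attribute, block_id,
        meta={"center": center, "sign": sign, "n_short_words": n_short},
    )


# ---------------------------------------------------------------------------
# file round trips (plain-text formats)
# ---------------------------------------------------------------------------

_ALIGN_COLS = ["word", "onset_s", "offset_s", "log_freq", "pred_rank", "ngram_log10p"]


def write_alignment(tokens: Iterable[WordToken], path) -> None:
    rows = [
        {
            "word": t.word, "onset_s": t.onset_s, "offset_s": t.offset_s,
            "log_freq": t.log_freq, "pred_rank": t.pred_rank,
            "ngram_log10p": t.ngram_log10p,
        }
        for t in tokens
    ]
    pd.DataFrame(rows, columns=_ALIGN_COLS).to_csv(path, sep="\t", index=False)


def read_alignment(path) -> list[WordToken]:
    df = pd.read_csv(path, sep="\t")
    tokens = []
    for i, row in df.iterrows():
        rank = row.get("pred_rank")
        tokens.append(
            WordToken(
                index=int(i),
                word=str(row["word"]),
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                log_freq=None if pd.isna(row.get("log_freq")) else float(row["log_freq"]),
                pred_rank=None if pd.isna(rank) else int(rank),
                ngram_log10p=(
                    None if pd.isna(row.get("ngram_log10p")) else float(row["ngram_log10p"])
                ),
            )
        )
    return tokens


def write_guesses(records: Iterable[dict], path) -> None:
    """Line-delimited JSON records ``{"index": i, "word": w, "guesses": [...10]}``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_guesses(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
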