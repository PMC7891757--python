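"""Sequence-pattern metrics: Lempel-Ziv complexity and n-gram mining.

Both metrics operate on the chronological AOI label sequence of a cleaned
recording (a categorical symbol sequence).

Lempel-Ziv complexity (LZC) counts the distinct patterns seen when the
sequence is scanned left to right: the current word grows symbol by symbol
while it matches a previously recorded phrase, and is recorded as a new
phrase the moment it does not (e.g. ``101001010010111`` parses into
``1|0|10|01|010|0101|11`` — seven phrases).  A final word left incomplete
at the end of the sequence counts as a phrase.  Higher LZC means more
varied, less compressible scanning.

N-gram mining counts overlapping windows of n consecutive AOIs (stride 1);
group-level analysis intersects each member's n-gram inventory to find the
patterns common to a group.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import pandas as pd

from .errors import InputError


def lempel_ziv_complexity(symbols: Sequence[Hashable]) -> int:
    """Number of distinct phrases in the left-to-right parse of *symbols*.

    Accepts any sequence of hashable symbols (a string is parsed character
    by character).  The trailing word, if the sequence ends before it
    becomes a new phrase, is counted as a phrase.
    """
    if len(symbols) == 0:
        raise InputError("cannot compute LZC of an empty sequence")
    phrases: set[tuple] = set()
    word: tuple = ()
    count = 0
    for s in symbols:
        word += (s,)
        if word not in phrases:
            phrases.add(word)
            count += 1
            word = ()
    if word:
        count += 1
    return count


@dataclass(frozen=True)
class NGramTable:
    """Occurrence counts of the overlapping n-grams of one sequence."""

    n: int
    entries: dict[tuple, int]

    def __post_init__(self) -> None:
        if any(len(k) != self.n for k in self.entries):
            raise InputError(f"all keys must have length n={self.n}")
        if any(v < 1 for v in self.entries.values()):
            raise InputError("counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


def ngram_counts(symbols: Sequence[Hashable], n: int) -> NGramTable:
    """Sliding-window (stride 1) n-gram counts; total = L - n + 1.

    A sequence shorter than *n* yields an empty table with a warning.
    """
    if n < 2:
        raise InputError("n-gram length must be >= 2")
    L = len(symbols)
    if n > L:
        warnings.warn(f"sequence of length {L} has no {n}-grams", stacklevel=2)
        return NGramTable(n=n, entries={})
    grams = Counter(tuple(symbols[i : i + n]) for i in range(L - n + 1))
    return NGramTable(n=n, entries=dict(grams))


def common_ngrams(
    group: Sequence[NGramTable], support: float = 1.0
) -> frozenset[tuple]:
    """N-grams present in at least ``ceil(support * group size)`` members.

    With the default ``support=1.0`` this is the strict intersection: the
    patterns every member of the group produced at least once.  The number
    of common patterns is the cardinality of the returned set.
    """
    if len(group) < 2:
        raise InputError("a group needs at least 2 members")
    ns = {t.n for t in group}
    if len(ns) > 1:
        raise InputError(f"mixed n-gram lengths in group: {sorted(ns)}")
    if not (0 < support <= 1):
        raise InputError("support must be in (0, 1]")
    threshold = math.ceil(support * len(group))
    membership: Counter = Counter()
    for table in group:
        membership.update(table.entries.keys())
    return frozenset(g for g, k in membership.items() if k >= threshold)


def unique_aoi_ngrams(table: NGramTable) -> NGramTable:
    """Retain only n-grams whose AOIs are pairwise distinct.

    Separates genuinely multi-instrument patterns (e.g. OTW->VS->ATT) from
    back-and-forth redundancies (e.g. OTW->VS->OTW).
    """
    kept = {g: c for g, c in table.entries.items() if len(set(g)) == len(g)}
    return NGramTable(n=table.n, entries=kept)


def ngram_frequency_table(
    group: Sequence[NGramTable],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ranked group-level n-gram report.

    One row per n-gram observed by any member, with the mean occurrences per
    member (members lacking the pattern count as 0) and the member support
    (fraction of members that produced it), sorted by mean occurrences.
    ``labels`` optionally maps 1-based AOI ids to display names.
    """
    if not group:
        raise InputError("empty group")
    n_members = len(group)
    totals: Counter = Counter()
    membership: Counter = Counter()
    for table in group:
        totals.update(table.entries)
        membership.update(table.entries.keys())

    def fmt(gram: tuple) -> str:
        if labels is not None:
            return "->".join(labels[int(a) - 1] for a in gram)
        return "->".join(str(a) for a in gram)

    rows = [
        {
            "ngram": fmt(g),
            "mean_occurrences": totals[g] / n_members,
            "member_support": membership[g] / n_members,
        }
        for g in totals
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["mean_occurrences", "ngram"], ascending=[False, True])
        .reset_index(drop=True)
    )
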