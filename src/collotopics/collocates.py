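"""Windowed collocate counting and Mutual-Information scoring.

For each occurrence of a target keyword, every content token within a fixed
window of ±``half_width`` content positions (default 6, so Span = 12) counts
as one co-occurrence. A collocate's association with the target is scored by
the base-2 log of the observed-to-expected co-occurrence ratio,

    MI = log2( (C * Size) / (A * B * Span) )

where A is the corpus frequency of the target keyword(s), B that of the
collocate, C the joint window co-occurrence count, Size the number of
retained (content) tokens in the corpus, and Span the total window width.
Collocates with MI at or above a threshold (default 3) are shortlisted.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocess import AnnotatedToken

__all__ = [
    "WindowSpec",
    "CollocateRecord",
    "count_cooccurrences",
    "unigram_counts",
    "mi_score",
    "score_collocates",
    "shortlist",
    "records_to_frame",
]

DEFAULT_MI_MIN = 3.0


@dataclass(frozen=True)
class WindowSpec:
    """Collocation window: ±``half_width`` tokens on the chosen stream.

    ``stream`` selects whether positions are counted on the content-filtered
    stream (default, so function words do not consume window slots) or the
    raw token stream.
    """

    half_width: int = 6
    stream: str = "content"

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("window half_width must be >= 1")
        if self.stream not in {"content", "raw"}:
            raise ValueError("window stream must be 'content' or 'raw'")

    @property
    def span(self) -> int:
        return 2 * self.half_width


@dataclass(frozen=True)
class CollocateRecord:
    """A scored collocate candidate with the counts entering its MI score."""

    lemma: str
    count_A: int
    count_B: int
    count_C: int
    corpus_size: int
    span: int
    mi: float
    country: str = "ALL"


def _positions(doc: Sequence[AnnotatedToken], window: WindowSpec) -> list[str]:
    """Lemma sequence on which window positions are counted."""
    if window.stream == "content":
        return [t.lemma for t in doc if t.is_content]
    return [t.lemma for t in doc]


def count_cooccurrences(
    docs: Iterable[Sequence[AnnotatedToken]],
    targets: Iterable[str],
    window: WindowSpec = WindowSpec(),
) -> Counter:
    """Count windowed target–collocate co-occurrences (the MI formula's C).

    Each (target occurrence, collocate occurrence) position pair within
    ±half_width counts once; windows never cross document boundaries, and
    target lemmas are never their own collocates. Occurrences of all targets
    pool into a single count table.
    """
    target_set = frozenset(targets)
    if not target_set:
        raise ValueError("targets must be non-empty")
    h = window.half_width
    counts: Counter = Counter()
    for doc in docs:
        lemmas = _positions(doc, window)
        for p, lemma in enumerate(lemmas):
            if lemma not in target_set:
                continue
            lo = max(0, p - h)
            hi = min(len(lemmas), p + h + 1)
            for q in range(lo, hi):
                if q == p:
                    continue
                other = lemmas[q]
                if other in target_set:
                    continue
                counts[other] += 1
    return counts


def unigram_counts(
    docs: Iterable[Sequence[AnnotatedToken]],
) -> tuple[Counter, int]:
    """Content-stream lemma frequencies and total content token count (Size)."""
    counts: Counter = Counter()
    for doc in docs:
        counts.update(t.lemma for t in doc if t.is_content)
    return counts, sum(counts.values())


def mi_score(count_C: int, corpus_size: int, count_A: int, count_B: int, span: int) -> float:
    """Base-2 log of the observed-to-expected co-occurrence ratio.

    Undefined (raises ``ValueError``) when any argument is non-positive: a
    pair that never co-occurs has no finite score and is never silently 0.
    """
    if min(count_C, corpus_size, count_A, count_B, span) <= 0:
        raise ValueError(
            "MI score undefined for non-positive counts "
            f"(C={count_C}, Size={corpus_size}, A={count_A}, B={count_B}, Span={span})"
        )
    return math.log2((count_C * corpus_size) / (count_A * count_B * span))


def score_collocates(
    docs: Sequence[Sequence[AnnotatedToken]],
    targets: Iterable[str],
    window: WindowSpec = WindowSpec(),
    country: str = "ALL",
) -> list[CollocateRecord]:
    """Count and score every collocate candidate of the pooled targets.

    A (pooled target frequency) and Size are computed over the content
    stream of ``docs``; candidates with zero window co-occurrence are not
    emitted (their MI is undefined).
    """
    target_set = frozenset(targets)
    cooc = count_cooccurrences(docs, target_set, window)
    uni, size = unigram_counts(docs)
    count_a = sum(uni[t] for t in target_set)
    records = []
    if count_a == 0 or size == 0:
        return records
    for lemma, c in cooc.items():
        b = uni[lemma]
        records.append(
            CollocateRecord(
                lemma=lemma,
                count_A=count_a,
                count_B=b,
                count_C=c,
                corpus_size=size,
                span=window.span,
                mi=mi_score(c, size, count_a, b, window.span),
                country=country,
            )
        )
    return records


def shortlist(
    records: Iterable[CollocateRecord], mi_min: float = DEFAULT_MI_MIN
) -> list[CollocateRecord]:
    """Retain records with MI >= mi_min (inclusive), sorted by MI descending.

    Ties break lexicographically by lemma, making the output deterministic.
    """
    kept = [r for r in records if r.mi >= mi_min]
    return sorted(kept, key=lambda r: (-r.mi, r.lemma))


def records_to_frame(records: Sequence[CollocateRecord]) -> pd.DataFrame:
    """Collocate records as a DataFrame (the CSV export schema)."""
    return pd.DataFrame(
        [
            {
                "lemma": r.lemma,
                "A": r.count_A,
                "B": r.count_B,
                "C": r.count_C,
                "size": r.corpus_size,
                "span": r.span,
                "mi": r.mi,
                "country": r.country,
            }
            for r in records
        ],
        columns=["lemma", "A", "B", "C", "size", "span", "mi", "country"],
    )
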